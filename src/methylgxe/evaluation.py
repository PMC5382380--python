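"""Recovery scoring of pipeline output against planted ground truth, plus
the end-to-end simulation experiments used to validate the pipeline:
null calibration, planted-effect recovery, deconvolution accuracy and
mediation operating characteristics.  Both the test suite and the
reproduction script drive these functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cells import estimate_proportions, select_signature_probes
from .datatypes import MethylationDataset
from .dmp import run_dmp_scan
from .dmr import run_dmr_scan
from .mediation import baron_kenny, bootstrap_acme
from .preprocess import run_preprocess
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    generate_dataset,
    generate_reference_methylomes,
    null_config,
)


def interval_jaccard(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> float:
    """Jaccard index of two closed genomic intervals."""
    inter = max(0, min(a_hi, b_hi) - max(a_lo, b_lo) + 1)
    union = (a_hi - a_lo + 1) + (b_hi - b_lo + 1) - inter
    return inter / union


def score_dmp_recovery(dmp_results: pd.DataFrame, truth: GroundTruth) -> dict:
    """Fraction of planted DMPs passing the interaction-model criteria with
    the planted direction."""
    planted = [p for p in truth.planted_dmp_ids if p in dmp_results.index]
    sub = dmp_results.loc[planted]
    expected = np.where(
        [truth.dmp_signs[p] > 0 for p in planted], "hyper", "hypo"
    )
    ok = sub["sig_model_A"] & (sub["direction"] == expected)
    return {"n_planted": len(planted), "n_recovered": int(ok.sum()),
            "rate": float(ok.mean()) if planted else float("nan")}


def score_dmr_recovery(regions: pd.DataFrame, truth: GroundTruth) -> list:
    """Best interval Jaccard of each planted DMR against the called regions."""
    out = []
    for iv in truth.planted_dmr_intervals:
        sub = regions[regions["chromosome"] == iv["chromosome"]] if len(regions) else regions
        best = 0.0
        for r in sub.itertuples():
            best = max(best, interval_jaccard(iv["start"], iv["end"], r.start, r.end))
        out.append(best)
    return out


# ---------------------------------------------------------------------------
# simulation experiments
# ---------------------------------------------------------------------------

def null_dmp_calibration(seed: int, n_probes: int = 20_000) -> dict:
    """Zero-effect simulation: the fraction of probes with the
    exposure-in-carriers p-value at or below 1e-3 should match the nominal
    rate within binomial noise."""
    ds, _ = generate_dataset(null_config(n_probes=n_probes, seed=seed))
    clean, _, _ = run_preprocess(ds)
    res, _ = run_dmp_scan(clean)
    p = res["p_exposure_in_carriers"].dropna()
    frac = float((p <= 0.001).mean())
    sd = float(np.sqrt(0.001 * 0.999 / len(p)))
    return {"fraction": frac, "n": int(len(p)), "binomial_sd": sd}


def null_dmr_region_counts(seed: int, n_seeds: int = 20, n_probes: int = 20_000) -> list:
    """Region counts emitted by the DMR caller on zero-effect simulations."""
    counts = []
    for k in range(n_seeds):
        ds, _ = generate_dataset(null_config(n_probes=n_probes, seed=seed + k))
        clean, _, _ = run_preprocess(ds)
        counts.append(int(len(run_dmr_scan(clean))))
    return counts


def dmp_recovery_experiment(seed: int, n_probes: int = 20_000) -> dict:
    """Default planted-effect simulation (50 DMPs at delta-beta 0.15)."""
    cfg = SimulationConfig(n_probes=n_probes, seed=seed)
    ds, gt = generate_dataset(cfg)
    clean, _, _ = run_preprocess(ds)
    res, _ = run_dmp_scan(clean)
    return score_dmp_recovery(res, gt)


def dmr_recovery_experiment(
    seed: int, n_seeds: int = 20, n_probes: int = 20_000
) -> list:
    """Planted 5-8-probe DMRs across seeds; returns all best-Jaccard scores."""
    scores = []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            n_probes=n_probes, seed=seed + k, dmr_width_probes=5 + k % 4
        )
        ds, gt = generate_dataset(cfg)
        clean, _, _ = run_preprocess(ds)
        regions = run_dmr_scan(clean)
        scores.extend(score_dmr_recovery(regions, gt))
    return scores


def deconvolution_experiment(seed: int, n_probes: int = 20_000) -> dict:
    """Dirichlet-mixture simulation: per-type mean absolute error of the
    estimated proportions, plus exact recovery of pure-type samples."""
    cfg = SimulationConfig(n_probes=n_probes, seed=seed)
    ds, gt = generate_dataset(cfg)
    ref = generate_reference_methylomes(cfg)
    clean, _, _ = run_preprocess(ds)
    sig = select_signature_probes(clean, ref)
    props = estimate_proportions(clean, ref, sig)
    mae = (props.weights - gt.true_cell_proportions).abs().mean(axis=0)

    # pure-type samples: each reference methylome presented as a sample
    pure_beta = ref.copy()
    pure_beta.columns = [f"P{i}" for i in range(ref.shape[1])]
    pure_samples = pd.DataFrame(
        {"exposure": 0, "carrier": 0, "sex": 0}, index=pure_beta.columns
    )
    pure_ds = MethylationDataset(
        beta=pure_beta, manifest=ds.manifest, samples=pure_samples
    )
    pure = estimate_proportions(pure_ds, ref, sig)
    expected = np.eye(ref.shape[1])
    pure_err = float(np.abs(pure.weights.to_numpy() - expected).max())
    return {
        "mae_per_type": mae.to_dict(),
        "max_mae": float(mae.max()),
        "pure_type_max_error": pure_err,
        "n_samples": int(ds.n_samples),
    }


def mediation_experiment(seed: int, n_seeds: int = 50, n: int = 24) -> dict:
    """Operating characteristics of the four-model classifier and the
    bootstrap ACME on directly simulated chains."""
    full = 0
    product_diff = 0.0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        exposure = pd.Series(np.arange(n) % 2, dtype=float)
        mark = pd.Series(1.0 * exposure + rng.normal(0, 0.4, n))
        outcome = pd.Series(1.0 * mark + rng.normal(0, 0.4, n))
        res = baron_kenny(mark, outcome, exposure, adjust_sex=False)
        full += res.classification == "full"
        acme, _, _, _ = bootstrap_acme(
            mark, outcome, exposure, adjust_sex=False, n_boot=200, seed=seed + k
        )
        product_diff = max(
            product_diff, abs(acme - res.model2[0] * res.model4_mark[0])
        )
    return {
        "full_rate": full / n_seeds,
        "n_seeds": n_seeds,
        "acme_product_max_diff": product_diff,
    }


def acme_null_coverage(seed: int, n_reps: int = 200, n: int = 24) -> dict:
    """95% bootstrap CI coverage of zero under the a = b = 0 null."""
    cover = 0
    for k in range(n_reps):
        rng = np.random.default_rng(seed + k)
        exposure = pd.Series(np.arange(n) % 2, dtype=float)
        mark = pd.Series(rng.normal(0, 0.4, n))
        outcome = pd.Series(rng.normal(0, 0.4, n))
        _, ci, _, _ = bootstrap_acme(
            mark, outcome, exposure, adjust_sex=False, n_boot=200, seed=seed + k
        )
        cover += ci[0] <= 0.0 <= ci[1]
    sd = float(np.sqrt(0.95 * 0.05 / n_reps))
    return {"coverage": cover / n_reps, "n_reps": n_reps, "binomial_sd": sd}


def fisher_oracle_sweep(seed: int, exhaustive_n: int = 40, n_random: int = 500,
                        max_n: int = 200) -> dict:
    """Maximum absolute difference between the Fisher p and the exhaustive
    hypergeometric two-sided tail sum, over all 2x2 tables with total at
    most ``exhaustive_n`` plus a seeded random sweep up to ``max_n``."""
    import math

    from scipy.stats import fisher_exact

    def oracle(a, b, c, d):
        row1, row2, col1 = a + b, c + d, a + c
        n = row1 + row2
        denom = math.comb(n, col1)

        def table_p(k):
            return math.comb(row1, k) * math.comb(row2, col1 - k) / denom

        lo, hi = max(0, col1 - row2), min(col1, row1)
        obs = table_p(a)
        return min(
            1.0,
            sum(table_p(k) for k in range(lo, hi + 1) if table_p(k) <= obs * (1 + 1e-9)),
        )

    tables = []
    for n in range(1, exhaustive_n + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    tables.append((a, b, c, n - a - b - c))
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        n = int(rng.integers(exhaustive_n + 1, max_n + 1))
        cuts = np.sort(rng.integers(0, n + 1, size=3))
        a, b, c = int(cuts[0]), int(cuts[1] - cuts[0]), int(cuts[2] - cuts[1])
        tables.append((a, b, c, n - a - b - c))

    max_diff = 0.0
    for a, b, c, d in tables:
        _, p = fisher_exact([[a, b], [c, d]])
        max_diff = max(max_diff, abs(p - oracle(a, b, c, d)))
    return {"max_abs_diff": max_diff, "n_tables": len(tables)}
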