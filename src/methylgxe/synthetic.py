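"""Synthetic 450K-style methylation datasets with known ground truth.

The generator emulates the study design the pipeline targets: a 4-cell
exposure x PON1-192 genotype layout (default n = 11/13/12/12 unexposed-QQ /
exposed-QQ / unexposed-carrier / exposed-carrier), beta-distributed probe
noise around a bimodal baseline, per-sample betas convolved from six
leukocyte reference methylomes, planted interaction DMPs and DMRs whose
effect lives only in the exposed-carrier cell, an additively SNP-driven
9-probe promoter cluster, batch shifts on the M scale, and outcomes
partially mediated by specific methylation marks.

Everything is a deterministic function of ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CELL_TYPES,
    GROUPS,
    MethylationDataset,
    beta_to_m,
    m_to_beta,
)

GENE_ELEMENTS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic")
GENE_ELEMENT_P = (0.08, 0.08, 0.08, 0.05, 0.35, 0.05, 0.31)
CPG_CONTEXTS = ("island", "shore", "shelf", "open-sea")
CPG_CONTEXT_P = (0.31, 0.23, 0.10, 0.36)
CHROMATIN_STATES = (
    "active_promoter",
    "poised_promoter",
    "strong_enhancer",
    "weak_enhancer",
    "txn_elongation",
    "weak_txn",
    "heterochromatin",
    "repressed",
)
CHROMATIN_STATE_P = (0.12, 0.03, 0.08, 0.10, 0.15, 0.20, 0.25, 0.07)

PROBES_PER_CHROM = 10_000
PLANT_GAP = 10  # probes kept free around each planted feature


def default_mediation_spec():
    """Three planted exposure -> mark -> outcome paths (M-scale a; outcome
    units for b and the direct effect c').  Marks are resolved to the centre
    probes of the first planted DMRs so they qualify as DMP-and-DMR hits."""
    return (
        ("auto0", "leptin_ln", 1.5, 0.8, 0.4),
        ("auto1", "delta_bmi_z", -1.5, -0.8, 0.4),
        ("auto2", "bodyfat", 1.5, 3.0, 1.5),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_probes: int = 20_000
    group_sizes: tuple = (11, 13, 12, 12)  # order follows datatypes.GROUPS
    n_dmp_planted: int = 50
    dmp_effect: float = 0.15  # beta-scale shift in the exposed-carrier cell
    n_dmr_planted: int = 8
    dmr_width_probes: int = 6
    dmr_effect: Optional[float] = None  # defaults to dmp_effect
    probe_spacing_bp: int = 500
    noise_dispersion: float = 100.0  # beta precision phi
    n_celltypes: int = 6
    batch_levels: int = 2
    batch_shift: float = 0.0  # M-scale offset between batches
    snp_cluster_size: int = 9
    snp_effect_per_allele: float = 0.05  # beta scale, per T allele
    mark_bio_sd: float = 0.6  # M-scale inter-individual sd of mediation marks
    mediation_spec: tuple = field(default_factory=default_mediation_spec)
    seed: int = 0
    # secondary structure knobs
    frac_snp_flagged: float = 0.02
    frac_non_cpg: float = 0.01
    frac_sex_chrom: float = 0.01
    frac_bad_detection: float = 0.001
    n_discriminating: int = 600  # reference marker probes per cell type
    n_tfbs: int = 161
    confounded_batch: bool = False
    identical_celltypes: Optional[tuple] = None  # debug: force two types equal

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))

    def validate(self):
        if self.n_probes <= 0 or self.n_samples <= 0:
            raise ValueError("counts must be positive")
        if len(self.group_sizes) != 4 or any(g <= 0 for g in self.group_sizes):
            raise ValueError("group_sizes must be 4 positive counts")
        if self.n_celltypes != 6:
            raise ValueError("the deconvolution reference is fixed at 6 cell types")
        if not 0 < self.dmp_effect < 1 and self.n_dmp_planted > 0:
            if self.dmp_effect != 0:
                raise ValueError("dmp_effect must lie in [0, 1)")
        if self.noise_dispersion <= 0:
            raise ValueError("noise_dispersion must be positive")
        if self.batch_levels < 1:
            raise ValueError("batch_levels must be >= 1")
        if len(self.mediation_spec) > self.n_dmr_planted and self.n_dmr_planted >= 0:
            if len(self.mediation_spec) > max(self.n_dmr_planted, 0):
                raise ValueError(
                    "need at least one planted DMR per mediation path "
                    "(marks are centre probes of planted DMRs)"
                )

    @property
    def effective_dmr_effect(self) -> float:
        return self.dmp_effect if self.dmr_effect is None else self.dmr_effect


def null_config(**kwargs) -> SimulationConfig:
    """A configuration with every planted effect switched off."""
    base = dict(
        n_dmp_planted=0,
        dmp_effect=0.0,
        n_dmr_planted=0,
        snp_effect_per_allele=0.0,
        batch_shift=0.0,
        mediation_spec=(),
    )
    base.update(kwargs)
    return SimulationConfig(**base)


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery downstream."""

    planted_dmp_ids: list
    dmp_signs: dict  # probe id -> +1 (hyper) / -1 (hypo)
    planted_dmr_intervals: list  # dicts: chromosome, start, end, probes, sign
    snp_cluster_ids: list
    true_cell_proportions: pd.DataFrame  # samples x 6, rows sum to 1
    true_mediation_paths: list  # dicts: mark, outcome, a, b, c_prime

    def all_planted_probe_ids(self) -> set:
        out = set(self.planted_dmp_ids) | set(self.snp_cluster_ids)
        for iv in self.planted_dmr_intervals:
            out |= set(iv["probes"])
        return out


# ---------------------------------------------------------------------------
# internal builders (each consumes its own child rng, in a fixed order)
# ---------------------------------------------------------------------------

def _child_rngs(seed: int) -> dict:
    names = [
        "layout", "baseline", "reference", "proportions", "design",
        "planting", "detection", "noise", "batch", "outcomes",
    ]
    streams = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, streams)}


def _build_manifest(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_probes
    ids = [f"cg{i:08d}" for i in range(1, n + 1)]
    chrom_idx = np.arange(n) // PROBES_PER_CHROM + 1
    chroms = np.array([f"chr{k}" for k in chrom_idx], dtype=object)
    n_sex = int(round(cfg.frac_sex_chrom * n))
    if n_sex:
        chroms[-n_sex:] = "chrX"

    # positions: cumulative spacing with +-20% jitter, restarting per chromosome
    spacing = cfg.probe_spacing_bp * (1.0 + rng.uniform(-0.2, 0.2, size=n))
    positions = np.empty(n, dtype=np.int64)
    for c in np.unique(chroms):
        mask = chroms == c
        positions[mask] = 10_000 + np.round(np.cumsum(spacing[mask])).astype(np.int64)

    probe_class = np.full(n, "cg", dtype=object)
    n_ch = int(round(cfg.frac_non_cpg * n))
    if n_ch:
        ch_idx = rng.choice(n, size=n_ch, replace=False)
        probe_class[ch_idx] = "ch"
    snp_flag = rng.random(n) < cfg.frac_snp_flagged

    gene_element = rng.choice(GENE_ELEMENTS, size=n, p=GENE_ELEMENT_P)
    gene = np.array([f"GENE{i // 8:05d}" for i in range(n)], dtype=object)
    gene[gene_element == "intergenic"] = ""
    cpg_context = rng.choice(CPG_CONTEXTS, size=n, p=CPG_CONTEXT_P)
    chromatin_state = rng.choice(CHROMATIN_STATES, size=n, p=CHROMATIN_STATE_P)

    tf_labels = [f"TF{i:03d}" for i in range(1, cfg.n_tfbs + 1)]
    n_tf_per_probe = rng.poisson(0.8, size=n)
    tfbs = []
    for k in n_tf_per_probe:
        if k == 0:
            tfbs.append("")
        else:
            picks = rng.choice(cfg.n_tfbs, size=min(k, cfg.n_tfbs), replace=False)
            tfbs.append(";".join(tf_labels[p] for p in sorted(picks)))

    return pd.DataFrame(
        {
            "chromosome": chroms,
            "position": positions,
            "probe_class": probe_class,
            "snp_within_3bp": snp_flag,
            "gene": gene,
            "gene_element": gene_element,
            "cpg_context": cpg_context,
            "chromatin_state": chromatin_state,
            "tfbs": tfbs,
        },
        index=pd.Index(ids, name="probe"),
    )


def _baseline_means(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Bimodal per-probe baselines mimicking the boundary-heavy 450K histogram."""
    n = cfg.n_probes
    comp = rng.choice(3, size=n, p=(0.35, 0.35, 0.30))
    m = np.empty(n)
    m[comp == 0] = rng.beta(1.5, 8.0, size=(comp == 0).sum())   # unmethylated mode
    m[comp == 1] = rng.beta(8.0, 1.5, size=(comp == 1).sum())   # methylated mode
    m[comp == 2] = rng.beta(5.0, 5.0, size=(comp == 2).sum())   # intermediate
    return np.clip(m, 0.03, 0.97)


def _reference_from_baseline(
    cfg: SimulationConfig,
    baseline: np.ndarray,
    eligible: np.ndarray,
    rng: np.random.Generator,
) -> tuple:
    """Reference matrix (probes x 6) plus the per-type marker index sets.

    Each cell type receives ``n_discriminating`` disjoint marker probes whose
    reference value is shifted by ~0.38 away from every other type, so each
    type carries >= 500 probes with |between-type delta beta| >= 0.3.
    """
    n = cfg.n_probes
    R = np.tile(baseline[:, None], (1, cfg.n_celltypes)).astype(float)
    candidates = np.where(eligible & (baseline >= 0.35) & (baseline <= 0.65))[0]
    # cap the per-type marker count for small simulations, leaving a fifth
    # of the mid-range pool free for planting
    n_disc = min(cfg.n_discriminating, int(0.8 * len(candidates)) // cfg.n_celltypes)
    if n_disc < 10:
        raise ValueError(
            f"not enough mid-range probes for reference markers "
            f"({len(candidates)} candidates); increase n_probes"
        )
    need = n_disc * cfg.n_celltypes
    picks = rng.choice(candidates, size=need, replace=False)
    marker_sets = {}
    for t in range(cfg.n_celltypes):
        idx = picks[t * n_disc : (t + 1) * n_disc]
        shift = np.where(baseline[idx] <= 0.5, 0.38, -0.38)
        R[idx, t] = np.clip(baseline[idx] + shift, 0.02, 0.98)
        marker_sets[CELL_TYPES[t]] = idx
    if cfg.identical_celltypes is not None:
        a, b = cfg.identical_celltypes
        ia, ib = CELL_TYPES.index(a), CELL_TYPES.index(b)
        R[:, ib] = R[:, ia]
    return R, marker_sets


def generate_reference_methylomes(config: SimulationConfig) -> pd.DataFrame:
    """Stand-alone reference methylome matrix (probes x 6 cell types).

    Identical to the reference used inside :func:`generate_dataset` for the
    same config (the relevant random sub-streams are shared).
    """
    config.validate()
    rngs = _child_rngs(config.seed)
    manifest = _build_manifest(config, rngs["layout"])
    baseline = _baseline_means(config, rngs["baseline"])
    eligible = _eligibility(config, manifest, baseline, rngs["detection"])[0]
    R, _ = _reference_from_baseline(config, baseline, eligible, rngs["reference"])
    return pd.DataFrame(R, index=manifest.index, columns=list(CELL_TYPES))


def _eligibility(cfg, manifest, baseline, det_rng):
    """Probes usable for planting: survive every filter, mid-range baseline.

    Also draws the detection-p matrix deterministically (the bad-probe set
    must be known before planting so planted probes are never discarded).
    """
    n = cfg.n_probes
    det = det_rng.uniform(0.0, 0.005, size=(n, cfg.n_samples))
    n_bad = int(round(cfg.frac_bad_detection * n))
    bad_probes = np.zeros(n, dtype=bool)
    if n_bad:
        bad_idx = det_rng.choice(n, size=n_bad, replace=False)
        bad_probes[bad_idx] = True
        for j in bad_idx:
            cols = det_rng.choice(
                cfg.n_samples, size=max(2, int(0.6 * cfg.n_samples)), replace=False
            )
            det[j, cols] = det_rng.uniform(0.02, 0.5, size=len(cols))
    eligible = (
        (manifest["probe_class"].to_numpy() == "cg")
        & (~manifest["snp_within_3bp"].to_numpy())
        & (manifest["chromosome"].to_numpy() != "chrX")
        & (~bad_probes)
    )
    return eligible, det


def _pick_block(available, chroms, width, rng, max_tries=10_000):
    n = len(available)
    for _ in range(max_tries):
        start = int(rng.integers(0, n - width))
        block = np.arange(start, start + width)
        if available[block].all() and len(set(chroms[block])) == 1:
            return block
    raise RuntimeError("could not place a planted block; too few eligible probes")


def _signed_shift(mean, effect, rng, lo=0.02, hi=0.98):
    """Pick +-1 so the shifted mean stays inside (lo, hi); error if neither fits."""
    s = 1 if rng.random() < 0.5 else -1
    if not (lo < mean + s * effect < hi):
        s = -s
    if not (lo < mean + s * effect < hi):
        raise ValueError(
            f"effect size {effect} pushes planted mean {mean:.3f} outside (0,1)"
        )
    return s


def generate_dataset(config: SimulationConfig):
    """Generate a full synthetic dataset.

    Returns
    -------
    (MethylationDataset, GroundTruth)
    """
    cfg = config
    cfg.validate()
    rngs = _child_rngs(cfg.seed)
    n, ns = cfg.n_probes, cfg.n_samples

    manifest = _build_manifest(cfg, rngs["layout"])
    baseline = _baseline_means(cfg, rngs["baseline"])
    eligible, det = _eligibility(cfg, manifest, baseline, rngs["detection"])
    R, marker_sets = _reference_from_baseline(cfg, baseline, eligible, rngs["reference"])

    # --- design -----------------------------------------------------------
    rng_d = rngs["design"]
    sample_ids = [f"S{i:02d}" for i in range(1, ns + 1)]
    exposure = np.concatenate(
        [np.full(g, x) for g, x in zip(cfg.group_sizes, (0, 1, 0, 1))]
    )
    carrier = np.concatenate(
        [np.full(g, c) for g, c in zip(cfg.group_sizes, (0, 0, 1, 1))]
    )
    # block (not alternating) sex assignment, so sex stays orthogonal to the
    # round-robin batch factor; female counts per cell follow the design
    sex = np.concatenate(
        [
            (np.arange(g) < (g + (i % 2)) // 2).astype(int)
            for i, g in enumerate(cfg.group_sizes)
        ]
    )
    age = np.round(rng_d.uniform(6.0, 11.0, size=ns), 1)
    if cfg.confounded_batch:
        batch = exposure % cfg.batch_levels
    else:
        batch = np.arange(ns) % cfg.batch_levels
    pon1_108 = rng_d.binomial(2, 0.5, size=ns)  # T-allele count, HWE p=0.5

    # --- cell mixtures ----------------------------------------------------
    W = rngs["proportions"].dirichlet((6, 1, 1, 1, 1, 1), size=ns)  # samples x 6
    Mu = R @ W.T  # probes x samples mixture means

    # markers are excluded from the planting pool: their cross-sample
    # variance comes from the mixture, not from the design
    plantable = eligible.copy()
    for idx in marker_sets.values():
        plantable[idx] = False

    # --- planting ---------------------------------------------------------
    rng_p = rngs["planting"]
    chroms = manifest["chromosome"].to_numpy()
    available = plantable.copy()
    ec_cols = np.where((exposure == 1) & (carrier == 1))[0]

    def reserve(block):
        lo = max(0, block[0] - PLANT_GAP)
        hi = min(n, block[-1] + PLANT_GAP + 1)
        available[lo:hi] = False

    def relevel_block(block):
        """Give a planted block a shared mid-range methylation level (a
        coherent region), updating baseline, reference and mixture means."""
        level = rng_p.uniform(0.35, 0.65)
        jitter = rng_p.uniform(-0.03, 0.03, size=len(block))
        baseline[block] = np.clip(level + jitter, 0.3, 0.7)
        R[block, :] = baseline[block][:, None]
        Mu[block, :] = R[block, :] @ W.T

    # SNP-driven promoter cluster (9 adjacent probes, gene PON1)
    snp_cluster_ids: list = []
    if cfg.snp_cluster_size > 0:
        block = _pick_block(available, chroms, cfg.snp_cluster_size, rng_p)
        reserve(block)
        relevel_block(block)
        snp_cluster_ids = list(manifest.index[block])
        manifest.loc[snp_cluster_ids, "gene"] = "PON1"
        manifest.loc[snp_cluster_ids, "gene_element"] = "TSS1500"
        if cfg.snp_effect_per_allele:
            shift = cfg.snp_effect_per_allele * pon1_108[None, :]
            Mu[block, :] = np.clip(Mu[block, :] + shift, 0.02, 0.98)

    # planted DMRs: coherent shift across adjacent probes, exposed carriers only
    dmr_intervals = []
    eff_dmr = cfg.effective_dmr_effect
    med_spec = list(cfg.mediation_spec)
    for b in range(cfg.n_dmr_planted):
        block = _pick_block(available, chroms, cfg.dmr_width_probes, rng_p)
        reserve(block)
        relevel_block(block)
        mean_b = float(np.mean(baseline[block]))
        if b < len(med_spec):
            sign = 1 if med_spec[b][2] >= 0 else -1  # match the path's a
            if not (0.02 < mean_b + sign * eff_dmr < 0.98):
                raise ValueError(
                    f"dmr_effect {eff_dmr} pushes planted region mean outside (0,1)"
                )
        else:
            sign = _signed_shift(mean_b, eff_dmr, rng_p)
        probes_b = list(manifest.index[block])
        dmr_intervals.append(
            {
                "chromosome": chroms[block[0]],
                "start": int(manifest["position"].iloc[block[0]]),
                "end": int(manifest["position"].iloc[block[-1]]),
                "probes": probes_b,
                "sign": int(sign),
            }
        )
        shifted = Mu[np.ix_(block, ec_cols)] + sign * eff_dmr
        if np.any(shifted <= 0.0) or np.any(shifted >= 1.0):
            raise ValueError("dmr_effect pushes planted means outside (0,1)")
        Mu[np.ix_(block, ec_cols)] = shifted

    # mediation marks: centre probe of the first planted DMRs, shifted on the
    # M scale by the path coefficient a (exposed carriers only) instead of
    # the region's beta shift
    mediation_paths = []
    mark_rows = []
    for b, (label, outcome, a, bcoef, cprime) in enumerate(med_spec):
        block_probes = dmr_intervals[b]["probes"]
        mark = block_probes[len(block_probes) // 2]
        row = manifest.index.get_loc(mark)
        mark_rows.append(row)
        # undo the beta-scale region shift on the mark, apply the M-scale one,
        # and give the mark inter-individual (biological) variability so the
        # mark -> outcome path is identifiable within exposure groups
        Mu[row, ec_cols] -= dmr_intervals[b]["sign"] * eff_dmr
        bio = rng_p.normal(0.0, cfg.mark_bio_sd, size=Mu.shape[1])
        shift_m = bio + np.where(np.isin(np.arange(Mu.shape[1]), ec_cols), a, 0.0)
        Mu[row, :] = np.clip(m_to_beta(beta_to_m(Mu[row, :]) + shift_m), 0.01, 0.99)
        mediation_paths.append(
            {"mark": mark, "outcome": outcome, "a": a, "b": bcoef, "c_prime": cprime}
        )

    # single planted DMPs
    planted_dmp_ids: list = []
    dmp_signs: dict = {}
    if cfg.n_dmp_planted > 0:
        if cfg.dmp_effect < 0 or cfg.dmp_effect >= 1:
            raise ValueError("dmp_effect must lie in [0, 1)")
        pool = np.where(available & (baseline >= 0.25) & (baseline <= 0.75))[0]
        if len(pool) < cfg.n_dmp_planted:
            raise RuntimeError("too few eligible probes for requested DMPs")
        rows = np.sort(rng_p.choice(pool, size=cfg.n_dmp_planted, replace=False))
        for row in rows:
            available[max(0, row - 2) : row + 3] = False
            s = _signed_shift(baseline[row], cfg.dmp_effect, rng_p)
            shifted = Mu[row, ec_cols] + s * cfg.dmp_effect
            if np.any(shifted <= 0.0) or np.any(shifted >= 1.0):
                raise ValueError("dmp_effect pushes planted means outside (0,1)")
            Mu[row, ec_cols] = shifted
            pid = manifest.index[row]
            planted_dmp_ids.append(pid)
            dmp_signs[pid] = int(s)

    # --- beta draws -------------------------------------------------------
    phi = cfg.noise_dispersion
    Mu = np.clip(Mu, 0.005, 0.995)
    B = rngs["noise"].beta(Mu * phi, (1.0 - Mu) * phi)
    B = np.clip(B, 1e-4, 1.0 - 1e-4)

    # --- batch shift (M scale, per-probe loading) -------------------------
    if cfg.batch_shift != 0.0 and cfg.batch_levels > 1:
        loading = rngs["batch"].uniform(0.5, 1.5, size=n)
        centred = batch - batch.mean()
        M = beta_to_m(B) + cfg.batch_shift * loading[:, None] * centred[None, :]
        B = m_to_beta(M)

    beta = pd.DataFrame(B, index=manifest.index, columns=sample_ids)
    detection_p = pd.DataFrame(det, index=manifest.index, columns=sample_ids)

    # --- outcomes ---------------------------------------------------------
    rng_o = rngs["outcomes"]
    leptin_ln = 1.0 + 0.3 * sex + rng_o.normal(0, 0.4, size=ns)
    bodyfat = 18.0 + 3.0 * sex + rng_o.normal(0, 3.0, size=ns)
    delta_bmi_z = rng_o.normal(0, 0.9, size=ns)
    bmi_z = rng_o.normal(0, 1.0, size=ns)
    outcomes = {
        "leptin_ln": leptin_ln,
        "bodyfat": bodyfat,
        "delta_bmi_z": delta_bmi_z,
        "bmi_z": bmi_z,
    }
    for path, row in zip(mediation_paths, mark_rows):
        mark_m = beta_to_m(B[row, :])
        outcomes[path["outcome"]] = outcomes[path["outcome"]] + (
            path["c_prime"] * exposure * carrier
            + path["b"] * (mark_m - mark_m.mean())
        )

    if snp_cluster_ids:
        cluster_rows = [manifest.index.get_loc(p) for p in snp_cluster_ids]
        cluster_m = beta_to_m(B[cluster_rows, :]).mean(axis=0)
        cluster_term = -10.0 * (cluster_m - cluster_m.mean())
    else:
        cluster_term = 0.0
    pon1_activity = 28.0 + 30.0 * carrier + cluster_term + rng_o.normal(0, 4.0, size=ns)

    samples = pd.DataFrame(
        {
            "exposure": exposure.astype(int),
            "carrier": carrier.astype(int),
            "pon1_192": np.where(carrier == 1, "QR/RR", "QQ"),
            "pon1_108": pon1_108,
            "pon1_108_genotype": np.array(["CC", "CT", "TT"], dtype=object)[pon1_108],
            "sex": sex.astype(int),
            "age": age,
            "batch": np.array([f"B{b + 1}" for b in batch], dtype=object),
            "leptin": np.exp(outcomes["leptin_ln"]),
            "leptin_ln": outcomes["leptin_ln"],
            "bodyfat": outcomes["bodyfat"],
            "bmi_z": outcomes["bmi_z"],
            "delta_bmi_z": outcomes["delta_bmi_z"],
            "pon1_activity": pon1_activity,
        },
        index=pd.Index(sample_ids, name="sample"),
    )

    ds = MethylationDataset(
        beta=beta, manifest=manifest, samples=samples, detection_p=detection_p
    )
    truth = GroundTruth(
        planted_dmp_ids=planted_dmp_ids,
        dmp_signs=dmp_signs,
        planted_dmr_intervals=dmr_intervals,
        snp_cluster_ids=snp_cluster_ids,
        true_cell_proportions=pd.DataFrame(
            W, index=pd.Index(sample_ids, name="sample"), columns=list(CELL_TYPES)
        ),
        true_mediation_paths=mediation_paths,
    )
    return ds, truth
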