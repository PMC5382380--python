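"""Filtering rules, the beta/M bijection, and batch handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylgxe import SimulationConfig, beta_to_m, generate_dataset, m_to_beta, null_config
from methylgxe.datatypes import EPS
from methylgxe.preprocess import (
    adjust_batch,
    batch_diagnostics,
    filter_probes_post_norm,
    filter_probes_pre_norm,
    greedycut,
    normalize_beta,
)

from conftest import make_toy_dataset, make_toy_samples


def _toy(n_probes=6, n_samples=8, seed=0, **manifest_cols):
    rng = np.random.default_rng(seed)
    beta = pd.DataFrame(
        rng.uniform(0.2, 0.8, size=(n_probes, n_samples)),
        index=[f"p{i}" for i in range(n_probes)],
        columns=[f"S{i:02d}" for i in range(n_samples)],
    )
    return make_toy_dataset(beta, samples=make_toy_samples(2), **manifest_cols)


class TestPreNormFilter:
    def test_snp_probe_removed_with_reason(self):
        ds = _toy()
        ds.manifest.loc["p2", "snp_within_3bp"] = True
        out, rep = filter_probes_pre_norm(ds)
        assert "p2" not in out.beta.index
        assert rep.removed["p2"] == "snp_within_3bp"

    def test_clean_dataset_unchanged(self):
        ds = _toy()
        ds.detection_p = pd.DataFrame(
            0.001, index=ds.beta.index, columns=ds.beta.columns
        )
        out, rep = filter_probes_pre_norm(ds)
        assert rep.n_removed == 0 and not rep.removed_samples
        pd.testing.assert_frame_equal(out.beta, ds.beta)

    def test_missing_value_probe_removed(self):
        ds = _toy()
        ds.beta.loc["p1", ds.beta.columns[0]] = np.nan
        out, rep = filter_probes_pre_norm(ds)
        assert rep.removed["p1"] == "missing_value"

    def test_reason_priority_snp_over_missing(self):
        ds = _toy()
        ds.manifest.loc["p1", "snp_within_3bp"] = True
        ds.beta.loc["p1", ds.beta.columns[0]] = np.nan
        _, rep = filter_probes_pre_norm(ds)
        assert rep.removed["p1"] == "snp_within_3bp"

    def test_all_removed_is_hard_error(self):
        ds = _toy(n_probes=2)
        ds.manifest["snp_within_3bp"] = True
        with pytest.raises(ValueError, match="all probes removed"):
            filter_probes_pre_norm(ds)

    def test_report_counts_sum_to_total(self, sim8k):
        _, ds, _ = sim8k
        _, rep = filter_probes_pre_norm(ds)
        assert sum(rep.counts().values()) == rep.n_removed


class TestGreedycut:
    def test_toy_removal_order(self):
        # p1 fails in 3/4 samples (worst offender), then s4 fails 3 of the
        # remaining 4 probes; after both removals nothing fails.
        det = pd.DataFrame(
            0.001,
            index=[f"p{i}" for i in range(1, 6)],
            columns=[f"s{i}" for i in range(1, 5)],
        )
        det.loc["p1", ["s1", "s2", "s3"]] = 0.5
        det.loc[["p2", "p3", "p4"], "s4"] = 0.5
        probes, samples = greedycut(det, threshold=0.01)
        assert probes == ["p1"]
        assert samples == ["s4"]

    def test_probe_preferred_on_tie(self):
        det = pd.DataFrame(
            0.001, index=["p1", "p2"], columns=["s1", "s2"]
        )
        det.loc["p1", "s1"] = 0.5  # p1 fails 1/2, s1 fails 1/2: tie
        probes, samples = greedycut(det, threshold=0.01)
        assert probes == ["p1"] and samples == []

    def test_filter_idempotent(self, sim8k):
        _, ds, _ = sim8k
        once, _ = filter_probes_pre_norm(ds)
        twice, rep2 = filter_probes_pre_norm(once)
        assert rep2.n_removed == 0
        pd.testing.assert_frame_equal(once.beta, twice.beta)


class TestPostNormFilter:
    def test_non_cpg_removed_autosomal_cg_kept(self):
        ds = _toy()
        ds.manifest.loc["p0", "probe_class"] = "ch"
        ds.manifest.loc["p1", "probe_class"] = "rs"
        out, rep = filter_probes_post_norm(ds)
        assert rep.removed["p0"] == "non_cpg" and rep.removed["p1"] == "non_cpg"
        assert "p2" in out.beta.index

    def test_chromosome_aliases_all_treated_as_sex(self):
        ds = _toy(n_probes=7)
        aliases = ["X", "chrX", "23", "Y", "chrY", "24", "chr5"]
        ds.manifest["chromosome"] = aliases
        out, rep = filter_probes_post_norm(ds)
        assert list(out.beta.index) == ["p6"]  # only the chr5 probe survives
        assert set(rep.removed.values()) == {"sex_chromosome"}

    def test_idempotent(self, sim8k):
        _, ds, _ = sim8k
        once, _ = filter_probes_post_norm(ds)
        twice, rep = filter_probes_post_norm(once)
        assert rep.n_removed == 0


class TestBetaMTransform:
    @pytest.mark.parametrize(
        "beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)]
    )
    def test_known_values(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta_to_m(1.2)
        with pytest.raises(ValueError):
            beta_to_m(-0.1)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=EPS, max_value=1 - EPS))
    def test_round_trip_bijection(self, x):
        assert m_to_beta(beta_to_m(x)) == pytest.approx(x, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=EPS, max_value=1 - EPS),
        st.floats(min_value=EPS, max_value=1 - EPS),
    )
    def test_strictly_monotone(self, a, b):
        if a < b:
            assert beta_to_m(a) < beta_to_m(b)
        elif a > b:
            assert beta_to_m(a) > beta_to_m(b)


def test_quantile_normalization_aligns_distributions():
    ds = _toy(n_probes=50, n_samples=8, seed=5)
    out = normalize_beta(ds, "quantile")
    sorted_cols = np.sort(out.beta.to_numpy(), axis=0)
    assert np.allclose(sorted_cols, sorted_cols[:, [0]])


class TestBatch:
    def test_planted_shift_detected_by_pca(self):
        ds, _ = generate_dataset(
            null_config(n_probes=3000, seed=21, batch_shift=1.0)
        )
        diag = batch_diagnostics(ds, ["batch", "exposure"])
        batch_p = diag.association_p.query("covariate == 'batch'")["p"]
        assert batch_p.min() < 0.05

    def test_single_level_covariate_skipped_with_warning(self):
        ds = _toy(n_samples=8)
        ds.samples["site"] = "A"
        with pytest.warns(UserWarning, match="single level"):
            diag = batch_diagnostics(ds, ["site"])
        assert diag.skipped == ["site"]
        assert diag.association_p.empty

    def test_adjustment_near_identity_without_batch_effect(self):
        ds, _ = generate_dataset(null_config(n_probes=2000, seed=22))
        adj = adjust_batch(ds)
        delta = (beta_to_m(adj.beta) - beta_to_m(ds.beta)).abs().to_numpy()
        assert delta.max() < 0.05

    def test_adjustment_removes_planted_shift(self):
        removed = 0
        reps = 10
        for s in range(reps):
            ds, _ = generate_dataset(
                null_config(n_probes=2000, seed=300 + s, batch_shift=1.0)
            )
            pre = batch_diagnostics(ds, ["batch"]).association_p
            top_pc = pre.loc[pre["p"].idxmin(), "pc"]
            post = batch_diagnostics(adjust_batch(ds), ["batch"]).association_p
            p_post = post.query("pc == @top_pc")["p"].iloc[0]
            removed += p_post > 0.05
        assert removed >= 8

    def test_single_sample_batch_rejected(self):
        ds = _toy(n_samples=8)
        ds.samples["batch"] = ["B1"] * 7 + ["B2"]
        with pytest.raises(ValueError, match="fewer than 2"):
            adjust_batch(ds)

    def test_confounded_batch_rejected(self):
        ds = _toy(n_samples=8)
        ds.samples["batch"] = [f"B{e + 1}" for e in ds.samples["exposure"]]
        with pytest.raises(ValueError, match="confounded"):
            adjust_batch(ds, protect=("exposure",))

    def test_adjustment_preserves_planted_dmp_recovery(self):
        from methylgxe.dmp import run_dmp_scan
        from methylgxe.preprocess import run_preprocess

        cfg = SimulationConfig(
            n_probes=6000, n_dmp_planted=30, n_dmr_planted=3, seed=77,
            batch_shift=0.5,
        )
        ds, gt = generate_dataset(cfg)
        clean, _, _ = run_preprocess(ds)
        rates = []
        for d in (clean, adjust_batch(clean)):
            res, _ = run_dmp_scan(d)
            planted = [p for p in gt.planted_dmp_ids if p in res.index]
            rates.append(res.loc[planted, "sig_model_A"].mean())
        assert abs(rates[0] - rates[1]) < 0.02 + 1e-9
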