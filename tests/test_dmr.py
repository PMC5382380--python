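"""Kernel smoothing, moment-matched p-values, and region calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methylgxe import m_to_beta
from methylgxe.dmr import (
    call_regions,
    dmr_to_bed,
    per_cpg_contrast_stats,
    run_dmr_scan,
    smooth_and_score,
    summarize_dmr,
)

from conftest import make_toy_dataset, make_toy_samples


def _stats_frame(positions, t, df=22, chromosome="chr1"):
    return pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": np.asarray(positions),
            "t": np.asarray(t, dtype=float),
            "df": df,
            "zero_variance": False,
        },
        index=[f"p{i}" for i in range(len(positions))],
    )


class TestPerCpgStats:
    def test_identical_groups_give_t0(self):
        samples = make_toy_samples(6)
        beta = pd.DataFrame(
            np.full((4, len(samples)), 0.5),
            index=[f"p{i}" for i in range(4)], columns=samples.index,
        )
        ds = make_toy_dataset(beta, samples=samples)
        st = per_cpg_contrast_stats(ds, "unexposed_QQ")
        assert (st["t"] == 0).all()
        assert st["zero_variance"].all()

    def test_planted_shift_dominates_ranking(self, sim8k, clean8k):
        _, _, gt = sim8k
        st = per_cpg_contrast_stats(clean8k, "unexposed_carrier")
        planted = [
            p
            for iv in gt.planted_dmr_intervals
            for p in iv["probes"]
            if p in st.index
        ]
        cutoff = st["t"].abs().quantile(0.99)
        assert (st.loc[planted, "t"].abs() > cutoff).mean() > 0.8

    def test_single_sample_group_rejected(self):
        samples = make_toy_samples(6)
        keep = samples.index[
            ~((samples["exposure"] == 0) & (samples["carrier"] == 0))
        ].tolist() + [samples.index[0]]
        sub = samples.loc[keep]
        rng = np.random.default_rng(0)
        beta = pd.DataFrame(
            rng.uniform(0.3, 0.7, size=(3, len(sub))),
            index=["a", "b", "c"], columns=sub.index,
        )
        ds = make_toy_dataset(beta, samples=sub)
        with pytest.raises(ValueError, match="at least 2"):
            per_cpg_contrast_stats(ds, "unexposed_QQ")


class TestSmoothing:
    def test_isolated_probe_score_is_own_t2(self):
        st = _stats_frame([1000, 50_000, 120_000], [2.0, -3.0, 1.0])
        out = smooth_and_score(st, lambda_bp=1000, C=2)
        assert np.allclose(out["score"], [4.0, 9.0, 1.0])

    def test_constant_t2_window_returns_constant(self):
        st = _stats_frame(np.arange(10) * 100, np.full(10, 2.5))
        out = smooth_and_score(st, lambda_bp=1000, C=2)
        assert np.allclose(out["score"], 6.25)

    def test_hand_computed_kernel_oracle(self):
        # five probes; weights and moments recomputed here with explicit
        # loops, independently of the vectorized implementation
        positions = [0, 400, 800, 1600, 3000]
        t = [1.0, -2.0, 3.0, 0.5, 2.0]
        df = 22
        lam, C = 1000.0, 2.0
        sigma = lam / C
        st = _stats_frame(positions, t, df=df)
        out = smooth_and_score(st, lambda_bp=lam, C=C)

        e = df / (df - 2)
        v = 2 * df**2 * (df - 1) / ((df - 2) ** 2 * (df - 4))
        for i, pos_i in enumerate(positions):
            weights, vals = [], []
            for j, pos_j in enumerate(positions):
                d = abs(pos_j - pos_i)
                if d <= lam:
                    weights.append(np.exp(-0.5 * (d / sigma) ** 2))
                    vals.append(t[j] ** 2)
            weights = np.array(weights) / np.sum(weights)
            score = float(np.sum(weights * vals))
            var_s = v * float(np.sum(weights**2))
            g = var_s / (2 * e)
            k = 2 * e**2 / var_s
            p = float(sps.chi2.sf(score / g, k))
            assert out["score"].iloc[i] == pytest.approx(score, rel=1e-12)
            assert out["p"].iloc[i] == pytest.approx(p, rel=1e-10)

    def test_bh_adjustment_order_preserving(self):
        rng = np.random.default_rng(5)
        st = _stats_frame(np.arange(200) * 5000, rng.normal(0, 1, 200))
        out = smooth_and_score(st, lambda_bp=1000, C=2)
        srt = out.sort_values("p")
        assert (srt["p_adj"].diff().dropna() >= -1e-12).all()

    def test_unsorted_positions_rejected(self):
        st = _stats_frame([1000, 500, 2000], [1, 1, 1])
        with pytest.raises(ValueError, match="not sorted"):
            smooth_and_score(st)


class TestRegions:
    def _scored_dataset(self, ec_shift, other_shift=0.0, n_sig=4):
        """Dataset with a block of probes shifted in chosen design cells."""
        samples = make_toy_samples(6)
        rng = np.random.default_rng(7)
        n = 30
        M = rng.normal(0, 0.2, size=(n, len(samples)))
        ec = ((samples["exposure"] == 1) & (samples["carrier"] == 1)).to_numpy()
        uq = ((samples["exposure"] == 0) & (samples["carrier"] == 0)).to_numpy()
        block = slice(10, 10 + n_sig)
        M[block, ec] += ec_shift
        M[block, uq] += other_shift
        beta = pd.DataFrame(
            m_to_beta(M), index=[f"p{i}" for i in range(n)],
            columns=samples.index,
        )
        return make_toy_dataset(beta, samples=samples), [f"p{i}" for i in range(10, 10 + n_sig)]

    def test_planted_block_called_with_direction(self):
        ds, block_ids = self._scored_dataset(ec_shift=3.0)
        regions = run_dmr_scan(ds)
        assert len(regions) > 0
        best = regions.sort_values("p_adj").iloc[0]
        assert best["direction"] == "hyper"
        member = set(best["probes"].split(";"))
        assert len(member & set(block_ids)) >= 3

    def test_intermediate_exposed_carrier_region_excluded(self):
        # unexposed-QQ pushed above the exposed carriers: carriers are
        # intermediate, so no region may be reported for this block
        ds, block_ids = self._scored_dataset(ec_shift=3.0, other_shift=4.0)
        regions = run_dmr_scan(ds)
        if len(regions):
            called = {p for ps in regions["probes"] for p in ps.split(";")}
            assert not (called & set(block_ids))

    def test_gap_rule_and_min_cpgs(self):
        scored = _stats_frame([0, 20_000], [9.0, 9.0])
        scored["score"] = scored["t"] ** 2
        scored["p"] = 1e-12
        scored["p_adj"] = 1e-10
        samples = make_toy_samples(6)
        beta = pd.DataFrame(
            np.tile(np.array([[0.8], [0.8]]), (1, len(samples))),
            index=scored.index, columns=samples.index,
        )
        ec = ((samples["exposure"] == 1) & (samples["carrier"] == 1)).to_numpy()
        beta.loc[:, ec] = 0.9
        ds = make_toy_dataset(beta, samples=samples)
        ds.manifest["position"] = scored["position"].to_numpy()
        # two significant probes 20 kb apart: two candidate clusters, both
        # dropped at min_cpgs=2 ...
        none = call_regions(scored, ds, "unexposed_QQ", min_cpgs=2)
        assert len(none) == 0
        # ... and both kept as singleton regions at min_cpgs=1
        both = call_regions(scored, ds, "unexposed_QQ", min_cpgs=1)
        assert len(both) == 2

    def test_region_bounds_inside_member_span(self, dmr8k, clean8k):
        for row in dmr8k.itertuples():
            members = row.probes.split(";")
            pos = clean8k.manifest.loc[members, "position"]
            assert row.start == pos.min() and row.end == pos.max()

    def test_planted_dmrs_recovered_with_jaccard(self, sim8k, dmr8k):
        _, _, gt = sim8k

        def jaccard(a, b, c, d):
            inter = max(0, min(b, d) - max(a, c) + 1)
            return inter / ((b - a + 1) + (d - c + 1) - inter)

        for iv in gt.planted_dmr_intervals:
            sub = dmr8k[dmr8k["chromosome"] == iv["chromosome"]]
            best = max(
                (
                    jaccard(iv["start"], iv["end"], r.start, r.end)
                    for r in sub.itertuples()
                ),
                default=0.0,
            )
            assert best >= 0.6
            # direction agrees with the planted sign
            hit = sub[(sub["start"] <= iv["end"]) & (sub["end"] >= iv["start"])]
            expected = "hyper" if iv["sign"] > 0 else "hypo"
            assert (hit["direction"] == expected).any()

    def test_summary_and_bed_export(self, dmr8k):
        summ = summarize_dmr(dmr8k)
        assert summ["n_hyper"] + summ["n_hypo"] == summ["n_regions"]
        bed = dmr_to_bed(dmr8k)
        assert (bed["chromEnd"] > bed["chromStart"]).all()
        assert (bed["score"] <= 1000).all()
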