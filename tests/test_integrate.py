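"""Overlap book-keeping and Fisher-exact enrichment against independent
hypergeometric oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylgxe.integrate import (
    annotation_enrichment,
    bonferroni,
    disease_mapping,
    gene_set_enrichment,
    overlap_dmps_dmrs,
    overlap_percentage,
    tfbs_enrichment,
)

from conftest import make_toy_dataset, make_toy_samples


def hypergeom_two_sided(a, b, c, d):
    """Two-sided Fisher p as the exhaustive sum of table probabilities not
    exceeding the observed one (margins fixed)."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def table_p(k):
        return (
            math.comb(row1, k)
            * math.comb(row2, col1 - k)
            / math.comb(n, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    observed = table_p(a)
    return sum(
        table_p(k) for k in range(lo, hi + 1) if table_p(k) <= observed * (1 + 1e-9)
    )


class TestOverlap:
    def test_reported_percentages(self):
        assert overlap_percentage(547, 767) == 71.3
        assert overlap_percentage(57, 70) == 81.4

    def test_boundary_positions_inclusive(self):
        manifest = pd.DataFrame(
            {"chromosome": ["chr1"] * 3, "position": [100, 200, 201],
             "gene": ["A", "B", "C"]},
            index=["p1", "p2", "p3"],
        )
        regions = pd.DataFrame(
            {"chromosome": ["chr1"], "start": [100], "end": [200]}
        )
        out = overlap_dmps_dmrs(["p1", "p2", "p3"], regions, manifest)
        assert out["overlapping_dmps"] == ["p1", "p2"]  # start and end inclusive
        assert out["genes"] == ["A", "B"]
        assert out["percentage"] == 66.7

    @settings(derandomize=True, max_examples=30)
    @given(st.randoms(use_true_random=False))
    def test_order_invariance(self, rnd):
        manifest = pd.DataFrame(
            {"chromosome": ["chr1"] * 6,
             "position": [50, 150, 250, 350, 450, 550],
             "gene": list("ABCDEF")},
            index=[f"p{i}" for i in range(6)],
        )
        regions = pd.DataFrame(
            {"chromosome": ["chr1", "chr1"], "start": [100, 400], "end": [300, 500]}
        )
        dmps = [f"p{i}" for i in range(6)]
        rnd.shuffle(dmps)
        shuffled_regions = regions.sample(frac=1, random_state=rnd.randint(0, 99))
        out = overlap_dmps_dmrs(dmps, shuffled_regions, manifest)
        assert out["percentage"] == 50.0
        assert set(out["overlapping_dmps"]) == {"p1", "p2", "p4"}

    def test_multi_gene_annotations_split(self):
        manifest = pd.DataFrame(
            {"chromosome": ["chr1"], "position": [100], "gene": ["A;B"]},
            index=["p1"],
        )
        regions = pd.DataFrame(
            {"chromosome": ["chr1"], "start": [50], "end": [150]}
        )
        out = overlap_dmps_dmrs(["p1"], regions, manifest)
        assert out["genes"] == ["A", "B"]


class TestFisher:
    def test_matches_exhaustive_hypergeometric_small_tables(self):
        # exhaustive sweep of all 2x2 tables with total n <= 25
        from scipy.stats import fisher_exact

        for n in range(1, 26):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        _, p = fisher_exact([[a, b], [c, d]])
                        oracle = hypergeom_two_sided(a, b, c, d)
                        assert p == pytest.approx(min(oracle, 1.0), abs=1e-10)

    def test_island_enrichment_toy(self):
        # 10 DMPs all in islands against a 50% island background
        idx = [f"p{i}" for i in range(100)]
        manifest = pd.DataFrame(
            {"cpg_context": ["island"] * 50 + ["open-sea"] * 50}, index=idx
        )
        dmps = idx[:10]
        out = annotation_enrichment(dmps, idx, manifest, "cpg_context")
        island = out.set_index("category").loc["island"]
        assert island["odds_ratio"] > 1
        assert island["call"] == "enriched"
        oracle = hypergeom_two_sided(
            int(island["a"]),
            int(island["b"]),
            int(island["c"] - island["a"]),  # disjoint rest-of-background
            int(island["d"] - island["b"]),
        )
        assert island["p"] == pytest.approx(oracle, abs=1e-10)

    def test_background_matched_distribution_not_called(self):
        idx = [f"p{i}" for i in range(100)]
        manifest = pd.DataFrame(
            {"cpg_context": (["island"] * 5 + ["open-sea"] * 5) * 10}, index=idx
        )
        dmps = [i for i in idx if manifest.loc[i, "cpg_context"] == "island"][:5] + [
            i for i in idx if manifest.loc[i, "cpg_context"] == "open-sea"
        ][:5]
        out = annotation_enrichment(dmps, idx, manifest, "cpg_context")
        assert (out["p"] > 0.5).all()
        assert (out["call"] == "ns").all()

    def test_zero_cell_reported_with_flag(self):
        idx = [f"p{i}" for i in range(60)]
        manifest = pd.DataFrame(
            {"cpg_context": ["island"] * 30 + ["open-sea"] * 30}, index=idx
        )
        dmps = idx[30:40]  # none in islands
        out = annotation_enrichment(dmps, idx, manifest, "cpg_context").set_index(
            "category"
        )
        assert out.loc["island", "odds_ratio"] == 0.0
        assert bool(out.loc["island", "zero_cell"])
        assert np.isfinite(out.loc["island", "p"])

    def test_absent_category_level_error_path(self):
        idx = [f"p{i}" for i in range(10)]
        manifest = pd.DataFrame({"cpg_context": ["island"] * 10}, index=idx)
        out = annotation_enrichment(idx[:3], idx, manifest, "cpg_context")
        assert len(out) == 1  # single level: one (degenerate) table


class TestTfbs:
    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.0001, 161) == pytest.approx(0.0161)
        assert bonferroni(0.0001, 161) < 0.05
        assert bonferroni(0.001, 161) == pytest.approx(0.161)
        assert bonferroni(0.001, 161) >= 0.05
        assert bonferroni(0.5, 161) == 1.0

    def test_planted_tfbs_preference_detected(self):
        n_probes, n_tfs = 3000, 161
        hits_target, misses = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            idx = pd.Index([f"p{i}" for i in range(n_probes)])
            member = rng.random((n_probes, n_tfs)) < 0.05
            tfbs = [
                ";".join(f"TF{j:03d}" for j in np.where(member[i])[0]) for i in range(n_probes)
            ]
            manifest = pd.DataFrame({"tfbs": tfbs}, index=idx)
            # DMPs drawn with 3x preference for TF000 members
            w = np.where(member[:, 0], 3.0, 1.0)
            dmps = rng.choice(idx, size=300, replace=False, p=w / w.sum())
            out = tfbs_enrichment(dmps, idx, manifest).set_index("category")
            if out.loc["TF000", "p_adj"] < 0.05 and out.loc["TF000", "call"] == "enriched":
                hits_target += 1
            others = out.drop("TF000")
            misses += int((others["p_adj"] >= 0.05).all())
        assert hits_target >= 18
        assert misses >= 18

    def test_adjusted_p_monotone_in_p(self, sim8k):
        _, ds, _ = sim8k
        bg = ds.manifest.index[:2000]
        dmps = bg[::40]
        out = tfbs_enrichment(dmps, bg, ds.manifest)
        srt = out.sort_values("p")
        assert (srt["p_adj"].diff().dropna() >= -1e-12).all()


class TestGeneSets:
    def test_perfect_overlap_hypergeometric_tail(self):
        universe = [f"G{i}" for i in range(100)]
        sets = {"S": universe[:5]}
        out = gene_set_enrichment(universe[:5], sets, universe)
        expected = 1.0 / math.comb(100, 5)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_list_not_enriched(self):
        universe = [f"G{i}" for i in range(50)]
        sets = {"S1": universe[:10], "S2": universe[10:20]}
        out = gene_set_enrichment(universe[40:45], sets, universe)
        assert (out["p"] > 0.2).all()
        assert (out["call"] == "ns").all()

    def test_neglog10_formatting_round_trip(self):
        p = 10 ** (-3.98)
        assert round(-np.log10(p), 2) == 3.98

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gene_set_enrichment(["A"], {"S": ["A"]}, [])


class TestDiseaseMapping:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            {
                "gene": ["UQCRC2", "UQCRC2", "LRP8", "OTHER"],
                "disease": [
                    "mitochondrial complex iii deficiency",
                    "obesity",
                    "myocardial infarction",
                    "x",
                ],
                "score": [0.41, 0.1, 0.22, 0.9],
            }
        )

    def test_strictly_above_threshold(self, table):
        out = disease_mapping(["UQCRC2", "LRP8"], table)
        assert len(out) == 2  # the 0.1 association is excluded
        assert 0.41 in out["score"].values and 0.22 in out["score"].values

    def test_empty_gene_list(self, table):
        assert disease_mapping([], table).empty
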