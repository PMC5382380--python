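#!/usr/bin/env python
"""Overlap the sig-DMPs with the sig-DMRs into a high-confidence gene list,
then run the Fisher-exact enrichment battery: genomic annotation categories
(gene element, CpG context, chromatin state), TFBS with Bonferroni
adjustment, gene sets (GMT file), and disease-association mapping
(score strictly > 0.1).

Gene sets and the disease table default to synthetic stand-ins derived from
the simulated manifest (labelled synthetic; supply --gene-sets /
--disease-table for real resources).  Writes tables under
results/integration/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from methylgxe.integrate import (
    annotation_enrichment,
    disease_mapping,
    gene_set_enrichment,
    overlap_dmps_dmrs,
    read_gmt,
    tfbs_enrichment,
)
from methylgxe.io import read_dataset_dir

ROOT = Path(__file__).resolve().parents[1]


def synthetic_gene_sets(universe, seed=0):
    """Synthetic pathway stand-ins: random slices of the gene universe."""
    rng = np.random.default_rng(seed)
    sets = {}
    for k in range(12):
        size = int(rng.integers(10, 40))
        sets[f"synthetic_pathway_{k:02d}"] = list(
            rng.choice(universe, size=min(size, len(universe)), replace=False)
        )
    return sets


def synthetic_disease_table(universe, include=(), seed=0):
    """Synthetic gene-disease stand-in with scores spanning the cut-off;
    ``include`` genes are guaranteed an entry so the join is exercised."""
    rng = np.random.default_rng(seed)
    pool = [g for g in universe if g not in set(include)]
    genes = list(include) + list(
        rng.choice(pool, size=min(60, len(pool)), replace=False)
    )
    return pd.DataFrame(
        {
            "gene": genes,
            "disease": [f"synthetic_disease_{i % 15:02d}" for i in range(len(genes))],
            "score": np.round(rng.uniform(0.02, 0.6, len(genes)), 2),
        }
    )


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=ROOT / "results" / "preprocess")
    ap.add_argument("--dmp", type=Path, default=ROOT / "results" / "dmp" / "dmp_results.tsv")
    ap.add_argument("--dmr", type=Path, default=ROOT / "results" / "dmr" / "dmr_results.tsv")
    ap.add_argument("--gene-sets", type=Path, default=None)
    ap.add_argument("--disease-table", type=Path, default=None)
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "integration")
    args = ap.parse_args()

    ds = read_dataset_dir(args.indir)
    dmp = pd.read_csv(args.dmp, sep="\t", index_col=0)
    regions = pd.read_csv(args.dmr, sep="\t")
    sig_dmps = list(dmp.index[dmp["sig_model_A"]])
    background = list(dmp.index)

    ov = overlap_dmps_dmrs(sig_dmps, regions, ds.manifest)
    print(f"{ov['n_overlap']} of {ov['n_dmps']} sig-DMPs ({ov['percentage']}%) "
          f"fall inside a sig-DMR -> high-confidence gene list of "
          f"{len(ov['genes'])} genes")

    args.outdir.mkdir(parents=True, exist_ok=True)
    Path(args.outdir / "high_confidence_genes.txt").write_text(
        "\n".join(ov["genes"]) + "\n"
    )

    for column in ("gene_element", "cpg_context", "chromatin_state"):
        table = annotation_enrichment(sig_dmps, background, ds.manifest, column)
        table.to_csv(args.outdir / f"enrichment_{column}.tsv", sep="\t", index=False)
        called = table.query("call != 'ns'")
        print(f"{column}: {len(called)} of {len(table)} levels enriched/depleted")

    tf = tfbs_enrichment(sig_dmps, background, ds.manifest)
    tf.to_csv(args.outdir / "enrichment_tfbs.tsv", sep="\t", index=False)
    n_enr = int((tf["call"] == "enriched").sum())
    print(f"TFBS: {n_enr} of {len(tf)} binding-site sets Bonferroni-enriched")

    universe = sorted({g for g in ds.manifest["gene"] if g})
    gene_sets = (
        read_gmt(args.gene_sets) if args.gene_sets
        else synthetic_gene_sets(universe)
    )
    gs = gene_set_enrichment(ov["genes"], gene_sets, universe)
    gs.to_csv(args.outdir / "gene_set_enrichment.tsv", sep="\t", index=False)
    print("top gene sets by -log10(p):")
    print(gs[["category", "neg_log10_p", "call"]].head(3).to_string(index=False))

    disease = (
        pd.read_csv(args.disease_table) if args.disease_table
        else synthetic_disease_table(universe, include=ov["genes"][:20])
    )
    dm = disease_mapping(ov["genes"], disease)
    dm.to_csv(args.outdir / "disease_mapping.tsv", sep="\t", index=False)
    print(f"disease mapping: {len(dm)} associations with score > 0.1")
    print(f"wrote {args.outdir}")


if __name__ == "__main__":
    main()
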