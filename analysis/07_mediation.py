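#!/usr/bin/env python
"""Baron-Kenny mediation screen on the DMP-and-DMR overlap, within R-allele
carriers: does methylation at a mark lie on the path from prenatal
exposure to ln-leptin, delta BMI Z, body fat, or BMI Z?  Marks classified
partial/full get a bootstrap ACME interval.

Writes the per-(mark, outcome) table under results/mediation/.
"""

import argparse
from pathlib import Path

import pandas as pd

from methylgxe.integrate import overlap_dmps_dmrs
from methylgxe.io import read_dataset_dir
from methylgxe.mediation import mediation_screen, summarize_mediation

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=ROOT / "results" / "preprocess")
    ap.add_argument("--dmp", type=Path, default=ROOT / "results" / "dmp" / "dmp_results.tsv")
    ap.add_argument("--dmr", type=Path, default=ROOT / "results" / "dmr" / "dmr_results.tsv")
    ap.add_argument("--n-boot", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--scope", choices=("carriers", "all"), default="carriers")
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "mediation")
    args = ap.parse_args()

    ds = read_dataset_dir(args.indir)
    dmp = pd.read_csv(args.dmp, sep="\t", index_col=0)
    regions = pd.read_csv(args.dmr, sep="\t")
    sig_dmps = list(dmp.index[dmp["sig_model_A"]])
    candidates = overlap_dmps_dmrs(sig_dmps, regions, ds.manifest)["overlapping_dmps"]
    print(f"mediation restricted to the {len(candidates)} sig-DMPs inside sig-DMRs")

    screen = mediation_screen(
        ds, candidates, scope=args.scope, n_boot=args.n_boot, seed=args.seed
    )
    counts = summarize_mediation(screen)
    for outcome, n in sorted(counts.items()):
        print(f"{outcome}: {n} candidate mediating marks (partial or full)")

    mediators = screen[screen["classification"] != "none"]
    if len(mediators):
        cols = ["mark", "outcome", "classification", "acme", "acme_ci_lo",
                "acme_ci_hi", "acme_p"]
        print(mediators[cols].round(4).head(10).to_string(index=False))

    args.outdir.mkdir(parents=True, exist_ok=True)
    screen.to_csv(args.outdir / "mediation_screen.tsv", sep="\t", index=False)
    print(f"wrote {args.outdir}")


if __name__ == "__main__":
    main()
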