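#!/usr/bin/env python
"""Single-CpG scan with the two sex-adjusted regression models on M-values:
the interaction model (exposure x carrier cross-product; interaction
p <= 0.1 and exposure-in-carriers p <= 0.001) and the no-interaction model
(exposure p <= 0.001, genotype p <= 0.1), each combined with the
extreme-group filter (exposed carriers highest or lowest of the 4 cells).

Writes the per-probe table and summary counts under results/dmp/.
"""

import argparse
import json
from pathlib import Path

from methylgxe.dmp import run_dmp_scan
from methylgxe.io import read_dataset_dir

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=ROOT / "results" / "preprocess")
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "dmp")
    ap.add_argument("--p-int", type=float, default=0.1)
    ap.add_argument("--p-exp-carriers", type=float, default=0.001)
    ap.add_argument("--p-exp", type=float, default=0.001)
    ap.add_argument("--p-geno", type=float, default=0.1)
    args = ap.parse_args()

    ds = read_dataset_dir(args.indir)
    res, summ = run_dmp_scan(
        ds,
        thresholds={
            "p_interaction": args.p_int,
            "p_exposure_in_carriers": args.p_exp_carriers,
            "p_exposure_main": args.p_exp,
            "p_genotype_main": args.p_geno,
        },
    )
    print(f"{summ['n_sig_model_A']} sig-DMPs in the interaction model "
          f"({summ['n_hyper_model_A']} hyper / {summ['n_hypo_model_A']} hypo "
          f"in exposed carriers)")
    print(f"{summ['n_sig_model_B']} sig-DMPs in the no-interaction model "
          f"({summ['n_hyper_model_B']} hyper / {summ['n_hypo_model_B']} hypo)")

    args.outdir.mkdir(parents=True, exist_ok=True)
    res.to_csv(args.outdir / "dmp_results.tsv", sep="\t")
    with open(args.outdir / "dmp_summary.json", "w") as fh:
        json.dump(summ, fh, indent=1)
    print(f"wrote {args.outdir}")


if __name__ == "__main__":
    main()
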