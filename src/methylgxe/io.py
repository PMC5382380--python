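"""Plain-text readers/writers for every artifact the pipeline exchanges.

Beta / M / detection-p matrices travel as TSV (probe ids as row labels,
sample ids as columns); manifest and sample sheet as CSV; the reference
methylome as TSV; ground truth as JSON.  The writers emit exactly what the
readers accept, so synthetic datasets round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import MethylationDataset
from .synthetic import GroundTruth


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_dataset(ds: MethylationDataset, outdir) -> dict:
    """Write the full dataset; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "manifest": outdir / "manifest.csv",
        "samples": outdir / "samples.csv",
    }
    write_matrix_tsv(ds.beta, paths["beta"])
    ds.manifest.to_csv(paths["manifest"])
    ds.samples.to_csv(paths["samples"])
    if ds.detection_p is not None:
        paths["detection_p"] = outdir / "detection_p.tsv"
        write_matrix_tsv(ds.detection_p, paths["detection_p"])
    return paths


def read_dataset(
    beta_path, manifest_path, samples_path, detection_p_path=None
) -> MethylationDataset:
    beta = read_matrix_tsv(beta_path)
    manifest = pd.read_csv(manifest_path, index_col=0)
    # empty annotation strings round-trip as NaN in CSV
    for col in ("gene", "tfbs"):
        if col in manifest.columns:
            manifest[col] = manifest[col].fillna("")
    samples = pd.read_csv(samples_path, index_col=0)
    det = read_matrix_tsv(detection_p_path) if detection_p_path else None
    return MethylationDataset(
        beta=beta, manifest=manifest, samples=samples, detection_p=det
    )


def read_dataset_dir(indir) -> MethylationDataset:
    indir = Path(indir)
    det = indir / "detection_p.tsv"
    return read_dataset(
        indir / "beta.tsv",
        indir / "manifest.csv",
        indir / "samples.csv",
        det if det.exists() else None,
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "planted_dmp_ids": list(truth.planted_dmp_ids),
        "dmp_signs": {k: int(v) for k, v in truth.dmp_signs.items()},
        "planted_dmr_intervals": truth.planted_dmr_intervals,
        "snp_cluster_ids": list(truth.snp_cluster_ids),
        "true_mediation_paths": truth.true_mediation_paths,
        "true_cell_proportions": {
            "index": list(truth.true_cell_proportions.index),
            "columns": list(truth.true_cell_proportions.columns),
            "values": truth.true_cell_proportions.values.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    props = payload["true_cell_proportions"]
    return GroundTruth(
        planted_dmp_ids=payload["planted_dmp_ids"],
        dmp_signs={k: int(v) for k, v in payload["dmp_signs"].items()},
        planted_dmr_intervals=payload["planted_dmr_intervals"],
        snp_cluster_ids=payload["snp_cluster_ids"],
        true_mediation_paths=payload["true_mediation_paths"],
        true_cell_proportions=pd.DataFrame(
            props["values"], index=props["index"], columns=props["columns"]
        ),
    )
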