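import numpy as np
import pandas as pd
import pytest

from methylgxe import MethylationDataset, SimulationConfig, generate_dataset
from methylgxe.dmp import run_dmp_scan
from methylgxe.dmr import run_dmr_scan
from methylgxe.preprocess import run_preprocess


@pytest.fixture(scope="session")
def sim8k():
    """Mid-size simulated study with planted effects, shared across tests."""
    cfg = SimulationConfig(n_probes=8000, n_dmp_planted=30, n_dmr_planted=4, seed=42)
    ds, gt = generate_dataset(cfg)
    return cfg, ds, gt


@pytest.fixture(scope="session")
def clean8k(sim8k):
    _, ds, _ = sim8k
    clean, _, _ = run_preprocess(ds)
    return clean


@pytest.fixture(scope="session")
def dmp8k(clean8k):
    return run_dmp_scan(clean8k)


@pytest.fixture(scope="session")
def dmr8k(clean8k):
    return run_dmr_scan(clean8k)


def make_toy_samples(n_per_cell=6, seed=0):
    """Balanced 4-cell design sheet: exposure x carrier, alternating sex."""
    rows = []
    i = 0
    for car in (0, 1):
        for exp in (0, 1):
            for k in range(n_per_cell):
                rows.append(
                    {"sample": f"S{i:02d}", "exposure": exp, "carrier": car,
                     "sex": k % 2, "batch": f"B{i % 2 + 1}", "age": 8.0}
                )
                i += 1
    return pd.DataFrame(rows).set_index("sample")


def make_toy_dataset(beta: pd.DataFrame, samples=None, chromosome="chr1",
                     spacing=500, **manifest_cols) -> MethylationDataset:
    """Wrap a raw beta matrix into a dataset with a minimal manifest."""
    n = len(beta)
    manifest = pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": 10_000 + spacing * np.arange(n),
            "probe_class": "cg",
            "snp_within_3bp": False,
            "gene": [f"G{i}" for i in range(n)],
            "gene_element": "Body",
            "cpg_context": "open-sea",
            "chromatin_state": "weak_txn",
            "tfbs": "",
        },
        index=beta.index,
    )
    for k, v in manifest_cols.items():
        manifest[k] = v
    if samples is None:
        samples = make_toy_samples(max(2, len(beta.columns) // 4))
        samples = samples.iloc[: len(beta.columns)]
        samples.index = beta.columns
    return MethylationDataset(beta=beta, manifest=manifest, samples=samples)
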