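import numpy as np
import pandas as pd
import pytest

from polyti.io import CountDataset


def make_sheet(replicates: int = 2) -> pd.DataFrame:
    rows = []
    for frac, tag in (("cytoplasmic", "cyto"), ("polysomal", "poly")):
        for cond in ("NT", "T"):
            for rep in range(1, replicates + 1):
                rows.append(
                    {"sample_id": f"{tag}_{cond}_{rep}", "fraction": frac,
                     "condition": cond, "replicate": rep}
                )
    return pd.DataFrame(rows).set_index("sample_id")


def make_dataset(counts: np.ndarray, replicates: int = 2,
                 genes: list[str] | None = None) -> CountDataset:
    sheet = make_sheet(replicates)
    if genes is None:
        genes = [f"g{i}" for i in range(counts.shape[0])]
    frame = pd.DataFrame(np.asarray(counts, dtype=np.int64),
                         index=genes, columns=sheet.index)
    return CountDataset(counts=frame, sheet=sheet)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_dataset(rng):
    """8 genes x 8 samples (2 replicates per group), moderate counts."""
    counts = rng.poisson(200, size=(8, 8))
    return make_dataset(counts, replicates=2)
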