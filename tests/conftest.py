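import numpy as np
import pandas as pd
import pytest

from noisedimorph import ExpressionDataset


def make_expression(values_by_sample: dict[str, np.ndarray], meta: list[dict]):
    """Build an ExpressionDataset from explicit per-sample columns."""
    n = len(next(iter(values_by_sample.values())))
    idx = pd.Index([f"t{i}" for i in range(n)], name="transcript_id")
    values = pd.DataFrame(values_by_sample, index=idx)
    samples = pd.DataFrame(meta).set_index("sample_id")
    return ExpressionDataset(values=values, samples=samples)


@pytest.fixture
def single_strain_dataset():
    """One strain, 3 replicates per sex, 4 transcripts, hand-set values."""
    rng = np.random.default_rng(42)
    cols, meta = {}, []
    for sex in ("female", "male"):
        for r in (1, 2, 3):
            sid = f"S1_{sex}_r{r}"
            cols[sid] = rng.uniform(5, 15, size=4)
            meta.append(
                {"sample_id": sid, "strain": "S1", "genotype": "G1",
                 "sex": sex, "replicate": r}
            )
    return make_expression(cols, meta)


@pytest.fixture
def paired_table():
    return pd.DataFrame(
        {"unit_id": ["a", "b", "c"], "cv_f": [0.5, 0.3, 0.9], "cv_m": [0.2, 0.4, 0.9]}
    )
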