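import numpy as np
import pandas as pd
import pytest

from ptrvoc.synthetic import SampleRun


def make_run(
    background: np.ndarray,
    sample: np.ndarray,
    mzs,
    sample_id: str = "s1",
    treatment: str = "fungal",
    category: str = "fungal",
) -> SampleRun:
    """Assemble a SampleRun from raw background/sample blocks (cycles x channels)."""
    background = np.atleast_2d(np.asarray(background, dtype=float))
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    ids = [f"{mz:.3f}" for mz in mzs]
    return SampleRun(
        sample_id=sample_id,
        treatment=treatment,
        category=category,
        background=pd.DataFrame(
            background, index=pd.RangeIndex(1, background.shape[0] + 1, name="cycle"), columns=ids
        ),
        sample=pd.DataFrame(
            sample, index=pd.RangeIndex(1, sample.shape[0] + 1, name="cycle"), columns=ids
        ),
        channel_mz=pd.Series(dict(zip(ids, mzs))),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20200902)
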