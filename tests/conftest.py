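import numpy as np
import pandas as pd
import pytest

from cnvmod.config import PipelineConfig
from cnvmod.io import IntensityReport


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture
def make_report():
    """Factory building an IntensityReport from per-sample signal arrays."""

    def _make(lrr, baf, positions=None, chromosome="chr1", samples=None):
        lrr = np.atleast_2d(np.asarray(lrr, dtype=float))
        if lrr.shape[0] == 1 and lrr.shape[1] > 1:
            lrr = lrr.T
        baf = np.atleast_2d(np.asarray(baf, dtype=float))
        if baf.shape[0] == 1 and baf.shape[1] > 1:
            baf = baf.T
        n = lrr.shape[0]
        if positions is None:
            positions = 1000 + 5000 * np.arange(n)
        if samples is None:
            samples = [f"S{j}" for j in range(lrr.shape[1])]
        probes = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(n)],
                "chromosome": chromosome,
                "position": np.asarray(positions, dtype=np.int64),
            }
        )
        return IntensityReport(probes=probes, samples=samples, lrr=lrr, baf=baf)

    return _make


@pytest.fixture
def diploid_baf():
    """Deterministic noiseless diploid BAF track (cycling 0, 0.5, 1)."""

    def _make(n):
        return np.tile([0.0, 0.5, 1.0], n // 3 + 1)[:n]

    return _make
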