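import numpy as np
import pandas as pd
import pytest

from mapanchor.config import PipelineConfig
from mapanchor.genotypes import GQ_UNKNOWN, MarkerGenotypeMatrix


@pytest.fixture
def toy_config():
    """Thresholds scaled down for hand-built matrices."""
    return PipelineConfig(min_genotyped_individuals=2, min_ld_pairs=1, seed=0)


def make_matrix(
    calls,
    contigs=None,
    positions=None,
    samples=None,
    gq=None,
    parents=None,
):
    """Build a MarkerGenotypeMatrix from a small nested list of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_m, n_s = calls.shape
    if contigs is None:
        contigs = ["ctgA"] * n_m
    if positions is None:
        positions = list(range(0, n_m * 1000, 1000))
    if samples is None:
        samples = [f"S{j}" for j in range(n_s)]
    if gq is None:
        gq = np.full(calls.shape, GQ_UNKNOWN, dtype=np.int16)
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(n_m)],
            "contig": contigs,
            "pos": positions,
        }
    )
    return MarkerGenotypeMatrix(
        markers=markers,
        samples=samples,
        calls=calls,
        gq=np.asarray(gq, dtype=np.int16),
        parents=parents,
    )
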