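import numpy as np
import pandas as pd
import pytest

from hcrtkit.expression import CountMatrix
from hcrtkit.motifs import PositionWeightMatrix


@pytest.fixture
def small_counts() -> CountMatrix:
    """Six genes, three groups x two replicates, hand-sized counts."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples = {
        "pos_r1": "egfp_pos",
        "pos_r2": "egfp_pos",
        "neg_r1": "egfp_neg",
        "neg_r2": "egfp_neg",
        "head_r1": "whole_head",
        "head_r2": "whole_head",
    }
    counts = pd.DataFrame(
        rng.integers(0, 200, size=(6, 6)), index=genes, columns=list(samples)
    )
    lengths = pd.Series(rng.integers(500, 3000, size=6), index=genes)
    return CountMatrix(counts, lengths, pd.Series(samples))


def consensus_pwm(consensus: str, p: float = 0.97, **kwargs) -> PositionWeightMatrix:
    """Near-deterministic PWM whose top base at each position spells ``consensus``."""
    order = "ACGT"
    off = (1 - p) / 3
    matrix = np.full((len(consensus), 4), off)
    for i, base in enumerate(consensus):
        matrix[i, order.index(base)] = p
    kwargs.setdefault("tf_name", consensus)
    return PositionWeightMatrix(matrix=matrix, **kwargs)
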