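import numpy as np
import pandas as pd
import pytest

from riskenhancer import GenomeSpec, HaplotypePanel, PWM


@pytest.fixture
def small_genome():
    return GenomeSpec(("chr1", "chr2"), (2_000_000, 1_000_000), seed=0)


@pytest.fixture
def toy_panel():
    """Four variants, 100 haplotypes, hand-set columns."""
    rng = np.random.default_rng(7)
    cols = (rng.random((100, 4)) < 0.3).astype(np.int8)
    cols[:, 1] = cols[:, 0]                      # perfect proxy
    variants = pd.DataFrame({
        "id": ["v0", "v1", "v2", "v3"],
        "chrom": "chr1",
        "pos": [1000, 2000, 500_000, 900_000],
        "ref": ["A", "C", "G", "T"],
        "alt": ["G", "T", "A", "C"],
    })
    return HaplotypePanel("EUR", variants, cols)


@pytest.fixture
def toy_pwm():
    """Length-4 PWM with a zero-frequency base and a flat column."""
    m = np.array([
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 0.8, 0.2, 0.0],
        [0.0, 0.0, 1.0, 0.0],
        [0.25, 0.25, 0.25, 0.25],
    ])
    return PWM("toy", m, pseudocount=0.0)
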