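import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from landlock import seqdata, synthetic


@pytest.fixture(scope="session")
def default_system():
    """One full synthetic system at the study's default settings."""
    return synthetic.simulate_system(synthetic.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A cheap configuration for replicate studies: 2 waterfalls, short pool."""
    return synthetic.SimulationConfig(
        heights_m=(27.9, 58.7),
        waterfall_names=("Nakara Fall", "Pinai Fall"),
        n_per_population=5,
        n_source=10,
        seed=7,
    )


@pytest.fixture
def toy_table():
    """Three-individual toy alignment with two identical sequences."""
    meta = pd.DataFrame(
        {
            "individual_id": ["a1", "a2", "b1"],
            "population": ["A", "A", "B"],
            "species": ["X", "X", "Y"],
            "sex": ["male", "female", "male"],
        }
    )
    seqs = ["ACGTACGTAC", "ACGTACGTAC", "ACGTACGTAT"]
    return seqdata.SequenceTable(meta=meta, sequences=seqs, region_name="toy")


def random_sequences(n, length, seed, diverge=0.05):
    """Random alignment: a reference sequence plus per-sequence mutations."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), size=length)
    out = []
    for _ in range(n):
        seq = base.copy()
        k = rng.binomial(length, diverge)
        pos = rng.choice(length, size=k, replace=False)
        for p in pos:
            seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
        out.append("".join(seq))
    return out
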