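import numpy as np
import pytest

from immunoga import PeptideDataset, Peptide, SignalSpec, generate
from immunoga.peptides import ALPHABET


def random_peptides(rng: np.random.Generator, n: int) -> list[str]:
    letters = np.array(list(ALPHABET))
    seqs = set()
    while len(seqs) < n:
        seqs.add("".join(rng.choice(letters, size=9)))
    return sorted(seqs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150528)


@pytest.fixture(scope="session")
def peptides20(rng):
    """20 random 9-mers for encoder oracle checks."""
    return random_peptides(rng, 20)


@pytest.fixture(scope="session")
def motif_ds():
    """Strong positional-motif signal: visible to position-aware encoders only."""
    return generate(
        SignalSpec(n_pos=75, n_neg=75, mechanism="positional-motif", effect_size=0.9, seed=7)
    )


@pytest.fixture(scope="session")
def shift_ds():
    """Hydropathy property-shift signal: visible to many encoders."""
    return generate(
        SignalSpec(n_pos=75, n_neg=75, mechanism="property-shift", effect_size=1.0, seed=11)
    )


@pytest.fixture(scope="session")
def null_ds():
    """No signal at all: classes exchangeable."""
    return generate(
        SignalSpec(n_pos=100, n_neg=100, mechanism="composition-bias", effect_size=0.0, seed=13)
    )


@pytest.fixture(scope="session")
def tiny_ds():
    """10 fixed labelled peptides for cheap structural checks."""
    seqs = random_peptides(np.random.default_rng(3), 10)
    return PeptideDataset(
        "tiny", [Peptide(s, i % 2) for i, s in enumerate(seqs)]
    )
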