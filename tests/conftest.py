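import numpy as np
import pytest

from beringia.io_manifest import DemeAlignment, TaxonPairData


def make_pair(seqs_a, seqs_b, name="pair", **meta) -> TaxonPairData:
    """Build a TaxonPairData from two lists of residue strings."""
    deme_a = DemeAlignment("OW", [(f"a{i}", s) for i, s in enumerate(seqs_a)])
    deme_b = DemeAlignment("NW", [(f"b{i}", s) for i, s in enumerate(seqs_b)])
    return TaxonPairData(name=name, deme_a=deme_a, deme_b=deme_b, **meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_sequences(rng, n, length, missing_rate=0.0):
    """Random ACGT strings with optional N/- missing characters."""
    bases = np.array(list("ACGT"))
    mat = bases[rng.integers(0, 4, size=(n, length))]
    if missing_rate > 0:
        mask = rng.random((n, length)) < missing_rate
        gaps = np.where(rng.random((n, length)) < 0.5, "N", "-")
        mat = np.where(mask, gaps, mat)
    return ["".join(row) for row in mat]
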