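import numpy as np
import pandas as pd
import pytest

from poex.pileup import PileupTable


def make_pileup(rows, library_id="lib"):
    """rows: list of (gene_id, pos, A, C, G, T)."""
    df = pd.DataFrame(rows, columns=["gene_id", "pos", "A", "C", "G", "T"])
    return PileupTable(library_id=library_id, data=df)


def make_reference(entries):
    """entries: list of (gene_id, pos, ref_base)."""
    return pd.DataFrame(entries, columns=["gene_id", "pos", "ref_base"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_pileup(rng):
    """A 40-gene random pileup with matching reference map."""
    rows, ref = [], []
    for g in range(40):
        gid = f"g{g:03d}"
        for pos in range(1, 31):
            counts = rng.multinomial(int(rng.integers(0, 40)), [0.25] * 4)
            rows.append((gid, pos, *counts))
            ref.append((gid, pos, "ACGT"[rng.integers(0, 4)]))
    return make_pileup(rows), make_reference(ref)
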