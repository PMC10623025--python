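import numpy as np
import pytest

from herdvar.pedigree import PedigreeRecord, renumber_pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(20240801)


def random_pedigree(q: int, rng, founder_frac: float = 0.2):
    """Random acyclic pedigree with disjoint sire/dam identifier pools."""
    records, sires, dams = [], [], []
    for i in range(q):
        name = f"X{i}"
        if i < 4 or rng.random() < founder_frac:
            records.append(PedigreeRecord(name))
        else:
            s = sires[rng.integers(len(sires))] if sires else None
            d = dams[rng.integers(len(dams))] if dams else None
            records.append(PedigreeRecord(name, sire=s, dam=d))
        (sires if i % 2 == 0 else dams).append(name)
    return records


@pytest.fixture
def random_pedigree_factory(rng):
    def make(q: int, seed: int | None = None):
        local = np.random.default_rng(seed) if seed is not None else rng
        return renumber_pedigree(random_pedigree(q, local))

    return make
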