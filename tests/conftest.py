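import numpy as np
import pytest

from riverpop.seqcore import Alignment, PopulationMap


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment.from_pairs(
        [
            ("a1", "AAA"),
            ("a2", "AAA"),
            ("a3", "AAA"),
            ("a4", "AAT"),
            ("a5", "AAT"),
            ("b1", "AAT"),
        ]
    )


@pytest.fixture
def toy_popmap() -> PopulationMap:
    pop = {f"a{i}": "pop1" for i in range(1, 6)} | {"b1": "pop2"}
    region = {k: "west" for k in pop}
    return PopulationMap(pop, region)


@pytest.fixture
def random_alignment():
    """Factory for random alignments (optionally with missing data)."""

    def make(n=8, k=40, seed=0, missing=0.0) -> Alignment:
        rng = np.random.default_rng(seed)
        mat = rng.choice(list("ACGT"), size=(n, k))
        if missing:
            mask = rng.random((n, k)) < missing
            mat[mask] = "N"
        return Alignment.from_pairs(
            (f"s{i}", "".join(row)) for i, row in enumerate(mat)
        )

    return make
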