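import numpy as np
import pytest

from mitonuc.core import Alignment, Phylogeny


@pytest.fixture
def quartet_tree() -> Phylogeny:
    """((A,B),(C,D)) with unit-ish branch lengths."""
    return Phylogeny.from_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")


@pytest.fixture
def small_alignment() -> Alignment:
    return Alignment(["A", "B", "C", "D"],
                     ["KKRA", "KKRA", "RKRA", "RKRC"], molecule="amino")


def star_tree(n: int, length: float = 1.0) -> Phylogeny:
    width = max(3, len(str(n)))
    tips = ",".join(f"t{i:0{width}d}:{length:g}" for i in range(1, n + 1))
    return Phylogeny.from_newick(f"({tips});")


def random_amino(rng: np.random.Generator, n: int) -> str:
    from mitonuc.core import AMINO_ACIDS
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))
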