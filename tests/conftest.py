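import numpy as np
import pytest

from mtqsar.chemio import MolecularGraph
from mtqsar.pipeline import MultiTargetQSAR
from mtqsar.synthdata import SynthConfig, generate_pair_frame


def path_graph(n: int) -> MolecularGraph:
    return MolecularGraph(
        atoms=tuple(("C", False) for _ in range(n)),
        bonds=tuple((i, i + 1, 1.0) for i in range(n - 1)),
    )


def random_graph(rng: np.random.Generator, max_atoms: int = 12) -> MolecularGraph:
    """Random connected graph: a spanning tree plus a few extra edges."""
    n = int(rng.integers(1, max_atoms + 1))
    bonds = [(int(rng.integers(0, k)), k, 1.0) for k in range(1, n)]
    present = {(i, j) for i, j, _ in bonds}
    for _ in range(int(rng.integers(0, 3))):
        if n < 3:
            break
        i, j = sorted(int(x) for x in rng.choice(n, size=2, replace=False))
        if (i, j) not in present:
            present.add((i, j))
            bonds.append((i, j, 1.0))
    return MolecularGraph(
        atoms=tuple(("C", False) for _ in range(n)), bonds=tuple(sorted(bonds))
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic dataset shared across tests: 4 subclasses,
    480 pairs, planted effect size 2."""
    cfg = SynthConfig(seed=11, n_classes=4, n_drugs=300, n_pairs_per_class=120)
    pairs, gt = generate_pair_frame(cfg)
    return pairs, gt


@pytest.fixture(scope="session")
def fitted_model(small_dataset):
    pairs, _ = small_dataset
    est = MultiTargetQSAR(n_hidden=20, max_features=6, random_state=11, max_iter=200)
    est.fit(pairs)
    return est
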