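"""Classic topological molecular descriptors.

A fixed, version-stamped registry of graph-theoretic descriptors computed on
the hydrogen-suppressed molecular graph.  Every registry entry carries both a
fast implementation (built on networkx shortest paths) and a brute-force
oracle (:mod:`mtqsar._desc_oracles`) that recomputes the same quantity by
exhaustive enumeration; the test suite asserts their agreement.

Conventions
-----------
* Distances are unweighted bond counts; bond order is ignored by
  distance-based descriptors.
* Multi-fragment molecules: descriptors are computed on the largest fragment,
  which avoids infinite distances and matches common QSAR practice.
* A descriptor whose applicability predicate fails for a molecule (e.g. the
  Petitjean index of a single atom) contributes the fill value 0 and a
  warning flag, never an exception.
* ``chi1``, the Kier–Hall simple path connectivity of order 1, is identical
  to the Randić index and is exposed only as ``randic``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from .chemio import MolecularGraph
from .errors import DescriptorApplicabilityWarning, UnknownDescriptorError

#: Version stamp of the descriptor set; recorded in outputs and model bundles.
REGISTRY_VERSION = "topo-17-v1"

#: Sentinel distance for disconnected atom pairs (never leaks into descriptors).
DISCONNECTED = -1


def to_networkx(g: MolecularGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(g.n_atoms))
    G.add_edges_from((i, j) for i, j, _ in g.bonds)
    return G


def largest_fragment(g: MolecularGraph) -> nx.Graph:
    """Largest connected component, relabeled to contiguous 0-based indices."""
    G = to_networkx(g)
    if G.number_of_nodes() == 0:
        return G
    comp = max(nx.connected_components(G), key=lambda c: (len(c), -min(c)))
    sub = G.subgraph(comp)
    return nx.convert_node_labels_to_integers(sub, ordering="sorted")


def distance_matrix(g: MolecularGraph) -> np.ndarray:
    """All-pairs shortest-path bond counts for the full (possibly
    disconnected) graph; ``DISCONNECTED`` marks unreachable pairs."""
    n = g.n_atoms
    if n == 0:
        raise ValueError("empty graph")
    D = np.full((n, n), DISCONNECTED, dtype=np.int64)
    G = to_networkx(g)
    for src, lengths in nx.all_pairs_shortest_path_length(G):
        for dst, d in lengths.items():
            D[src, dst] = d
    return D


# ---------------------------------------------------------------------------
# fast implementations (operate on a connected networkx graph)
# ---------------------------------------------------------------------------

def _dist(G: nx.Graph) -> np.ndarray:
    n = G.number_of_nodes()
    D = np.zeros((n, n), dtype=np.int64)
    for src, lengths in nx.all_pairs_shortest_path_length(G):
        for dst, d in lengths.items():
            D[src, dst] = d
    return D


def _degrees(G: nx.Graph) -> dict[int, int]:
    return dict(G.degree())


def _heavy_atom_count(G):  # noqa: ANN001 - uniform signature
    return float(G.number_of_nodes())


def _bond_count(G):
    return float(G.number_of_edges())


def _ring_count(G):
    # cyclomatic number of a connected graph
    return float(G.number_of_edges() - G.number_of_nodes() + 1)


def _wiener(G):
    D = _dist(G)
    return float(D.sum() / 2)


def _zagreb_m1(G):
    return float(sum(d * d for _, d in G.degree()))


def _zagreb_m2(G):
    deg = _degrees(G)
    return float(sum(deg[u] * deg[v] for u, v in G.edges()))


def _randic(G):
    deg = _degrees(G)
    return float(sum(1.0 / math.sqrt(deg[u] * deg[v]) for u, v in G.edges()))


def _chi0(G):
    return float(sum(1.0 / math.sqrt(d) for _, d in G.degree()))


def _chi2(G):
    deg = _degrees(G)
    total = 0.0
    for j in G.nodes():
        nbrs = sorted(G.neighbors(j))
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                i, k = nbrs[a], nbrs[b]
                total += 1.0 / math.sqrt(deg[i] * deg[j] * deg[k])
    return float(total)


def _path_count_2(G) -> int:
    return sum(d * (d - 1) // 2 for _, d in G.degree())


def _path_count_3(G) -> int:
    deg = _degrees(G)
    walks = sum((deg[u] - 1) * (deg[v] - 1) for u, v in G.edges())
    triangles = sum(nx.triangles(G).values()) // 3
    return walks - 3 * triangles


def _kappa1(G):
    n, m = G.number_of_nodes(), G.number_of_edges()
    return float(n * (n - 1) ** 2 / m**2)


def _kappa2(G):
    n, p2 = G.number_of_nodes(), _path_count_2(G)
    return float((n - 1) * (n - 2) ** 2 / p2**2)


def _kappa3(G):
    n, p3 = G.number_of_nodes(), _path_count_3(G)
    if n % 2:
        return float((n - 1) * (n - 3) ** 2 / p3**2)
    return float((n - 3) * (n - 2) ** 2 / p3**2)


def _balaban_j(G):
    m = G.number_of_edges()
    mu = m - G.number_of_nodes() + 1
    S = _dist(G).sum(axis=1)
    acc = sum(1.0 / math.sqrt(S[u] * S[v]) for u, v in G.edges())
    return float(m / (mu + 1) * acc)


def _eccentricities(G) -> np.ndarray:
    return _dist(G).max(axis=1)


def _eccentric_connectivity(G):
    ecc = _eccentricities(G)
    deg = _degrees(G)
    return float(sum(deg[i] * int(ecc[i]) for i in G.nodes()))


def _diameter(G):
    return float(_eccentricities(G).max())


def _radius(G):
    return float(_eccentricities(G).min())


def _petitjean(G):
    ecc = _eccentricities(G)
    dia, rad = int(ecc.max()), int(ecc.min())
    return float((dia - rad) / rad)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorDef:
    name: str
    fast: Callable[[nx.Graph], float]
    oracle: Callable[[nx.Graph], float]
    applicable: Callable[[nx.Graph], bool]


@dataclass
class DescriptorVector:
    """Ordered descriptor name → value map for one molecule."""

    values: dict[str, float]
    registry_version: str = REGISTRY_VERSION
    flags: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self, names: Sequence[str] | None = None) -> np.ndarray:
        keys = list(self.values) if names is None else list(names)
        return np.array([self.values[k] for k in keys], dtype=float)


def _always(G) -> bool:
    return G.number_of_nodes() >= 1


def _needs_bond(G) -> bool:
    return G.number_of_edges() >= 1


def _needs_atoms(k: int):
    return lambda G: G.number_of_nodes() >= k and G.number_of_edges() >= 1


def _kappa2_ok(G) -> bool:
    return G.number_of_nodes() >= 3 and _path_count_2(G) >= 1


def _kappa3_ok(G) -> bool:
    return G.number_of_nodes() >= 4 and _path_count_3(G) >= 1


def _petitjean_ok(G) -> bool:
    return G.number_of_nodes() >= 2


def _wiener_ok(G) -> bool:
    return G.number_of_nodes() >= 1


def build_default_registry() -> "DescriptorRegistry":
    from . import _desc_oracles as o

    defs = [
        DescriptorDef("heavy_atom_count", _heavy_atom_count, o.heavy_atom_count, _always),
        DescriptorDef("bond_count", _bond_count, o.bond_count, _always),
        DescriptorDef("ring_count", _ring_count, o.ring_count, _always),
        DescriptorDef("wiener", _wiener, o.wiener, _wiener_ok),
        DescriptorDef("zagreb_m1", _zagreb_m1, o.zagreb_m1, _always),
        DescriptorDef("zagreb_m2", _zagreb_m2, o.zagreb_m2, _always),
        DescriptorDef("randic", _randic, o.randic, _always),
        DescriptorDef("chi0", _chi0, o.chi0, _needs_bond),
        DescriptorDef("chi2", _chi2, o.chi2, _needs_bond),
        DescriptorDef("kappa1", _kappa1, o.kappa1, _needs_bond),
        DescriptorDef("kappa2", _kappa2, o.kappa2, _kappa2_ok),
        DescriptorDef("kappa3", _kappa3, o.kappa3, _kappa3_ok),
        DescriptorDef("balaban_j", _balaban_j, o.balaban_j, _needs_atoms(2)),
        DescriptorDef(
            "eccentric_connectivity", _eccentric_connectivity, o.eccentric_connectivity, _always
        ),
        DescriptorDef("diameter", _diameter, o.diameter, _always),
        DescriptorDef("radius", _radius, o.radius, _always),
        DescriptorDef("petitjean", _petitjean, o.petitjean, _petitjean_ok),
    ]
    return DescriptorRegistry(defs)


class DescriptorRegistry:
    """Ordered collection of descriptor definitions with unique names."""

    def __init__(self, defs: Sequence[DescriptorDef]):
        names = [d.name for d in defs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate descriptor names in registry")
        self._defs = list(defs)
        self._by_name = {d.name: d for d in defs}
        self.version = REGISTRY_VERSION

    @property
    def names(self) -> list[str]:
        return [d.name for d in self._defs]

    def __len__(self) -> int:
        return len(self._defs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> DescriptorDef:
        try:
            return self._by_name[name]
        except KeyError:
            raise UnknownDescriptorError(name) from None


_DEFAULT_REGISTRY: DescriptorRegistry | None = None


def default_registry() -> DescriptorRegistry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = build_default_registry()
    return _DEFAULT_REGISTRY


def compute_descriptors(
    g: MolecularGraph, registry: DescriptorRegistry | None = None
) -> DescriptorVector:
    """One value per registry entry, in registry order.

    Non-applicable descriptors yield the fill value 0 and are flagged (and a
    :class:`DescriptorApplicabilityWarning` is emitted once per molecule).
    """
    registry = registry or default_registry()
    if g.n_atoms == 0:
        raise ValueError("empty molecular graph")
    G = largest_fragment(g)
    values: dict[str, float] = {}
    flags: list[str] = []
    for d in registry._defs:
        if d.applicable(G):
            values[d.name] = float(d.fast(G))
        else:
            values[d.name] = 0.0
            flags.append(d.name)
    if flags:
        warnings.warn(
            f"descriptors not applicable, filled with 0: {flags}",
            DescriptorApplicabilityWarning,
            stacklevel=2,
        )
    return DescriptorVector(values=values, flags=tuple(flags))


def oracle_check(
    g: MolecularGraph, name: str, registry: DescriptorRegistry | None = None
) -> tuple[float, float]:
    """(fast value, brute-force oracle value) for one descriptor on one graph."""
    registry = registry or default_registry()
    d = registry[name]
    G = largest_fragment(g)
    if not d.applicable(G):
        return 0.0, 0.0
    return float(d.fast(G)), float(d.oracle(G))


def descriptor_table(
    graphs: Sequence[MolecularGraph], registry: DescriptorRegistry | None = None
):
    """Descriptor values for many molecules as a pandas DataFrame
    (rows follow input order, columns follow registry order)."""
    import pandas as pd

    registry = registry or default_registry()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DescriptorApplicabilityWarning)
        rows = [compute_descriptors(g, registry).values for g in graphs]
    return pd.DataFrame(rows, columns=registry.names)
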