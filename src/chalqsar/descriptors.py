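"""Molecular descriptors for the 3-parameter MAO-B QSAR model.

Implements the Barysz weighted-distance-matrix eigenvector descriptors
(VE1/VE2/VE3 with Sanderson-electronegativity weighting, descriptor name
``VE3_DzE``) together with topological polar surface area (``TPSA``) and the
count of para-hydroxylation-susceptible aryl sites
(``fr_para_hydroxylation``), plus a small auxiliary pool for descriptor
subset selection.

TPSA and the para-hydroxylation fragment count are computed with RDKit's
published fragment schemes; the Barysz-matrix family and the simple graph
indices are computed here from the molecular graph.

Conventions for the Barysz matrix (heavy atoms only, carbon reference
electronegativity ``w_C``):

* diagonal ``d_ii = 1 - w_C / w_i``;
* each bond contributes ``w_C**2 / (pi_b * w_i * w_j)`` with conventional
  bond order ``pi_b`` (aromatic = 1.5);
* the off-diagonal entry ``d_ij`` sums bond contributions along the
  topological (fewest-bond) shortest path, ties broken by the smaller
  weight sum;
* ``VE1`` is the absolute coefficient sum of the unit-norm eigenvector of
  the largest eigenvalue, ``VE2 = VE1/n`` and ``VE3 = ln(0.1 * n * VE1)``.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import Fragments, rdMolDescriptors

from .errors import DescriptorError, StructureError

__all__ = [
    "MolecularGraph",
    "BaryszMatrix",
    "DescriptorVector",
    "SANDERSON_ELECTRONEGATIVITY",
    "MODEL_DESCRIPTORS",
    "build_graph",
    "barysz_matrix",
    "ve1",
    "ve2",
    "ve3",
    "tpsa",
    "count_para_hydroxylation_sites",
    "wiener_index",
    "zagreb_m1",
    "descriptor_pool",
    "descriptor_table",
]

#: Descriptor names entering the published 3-parameter model, in order.
MODEL_DESCRIPTORS = ("VE3_DzE", "TPSA", "fr_para_hydroxylation")


def _load_sanderson() -> dict[str, float]:
    payload = json.loads(
        resources.files("chalqsar").joinpath("data/sanderson.json").read_text()
    )
    return {k: float(v) for k, v in payload["values"].items()}


#: Sanderson electronegativities (dimensionless), shipped as package data.
SANDERSON_ELECTRONEGATIVITY: dict[str, float] = _load_sanderson()


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom molecular graph with perceived aromaticity.

    ``atoms`` holds (element, aromatic, formal_charge, n_implicit_H) and
    ``bonds`` holds (i, j, order) with aromatic order 1.5.  The source RDKit
    molecule is retained for the fragment-scheme descriptors.
    """

    atoms: tuple[tuple[str, bool, int, int], ...]
    bonds: tuple[tuple[int, int, float], ...]
    mol: Chem.Mol = field(repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def build_graph(smiles: str) -> MolecularGraph:
    """Parse SMILES into a connected heavy-atom graph.

    Raises :class:`StructureError` on parse failure or disconnection.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"SMILES does not parse: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise StructureError(f"molecule is disconnected: {smiles!r}")
    atoms = tuple(
        (a.GetSymbol(), a.GetIsAromatic(), a.GetFormalCharge(), a.GetTotalNumHs())
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            1.5 if b.GetIsAromatic() else b.GetBondTypeAsDouble(),
        )
        for b in mol.GetBonds()
    )
    return MolecularGraph(atoms=atoms, bonds=bonds, mol=mol)


@dataclass(frozen=True)
class BaryszMatrix:
    n: int
    entries: np.ndarray
    weighting: str = "Sanderson electronegativity"


def barysz_matrix(
    g: MolecularGraph, weights: dict[str, float] | None = None
) -> BaryszMatrix:
    """Barysz weighted distance matrix of the heavy-atom graph.

    Raises :class:`DescriptorError` if the weight table lacks an element
    present in the molecule (no silent defaults).
    """
    if weights is None:
        weights = SANDERSON_ELECTRONEGATIVITY
    w_c = weights["C"]
    n = g.n_atoms
    try:
        w = np.array([weights[el] for el, *_ in g.atoms], dtype=float)
    except KeyError as exc:
        raise DescriptorError(f"no electronegativity weight for element {exc}") from exc

    adjacency: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j, order in g.bonds:
        contrib = w_c**2 / (order * w[i] * w[j])
        adjacency[i].append((j, contrib))
        adjacency[j].append((i, contrib))

    entries = np.zeros((n, n))
    for source in range(n):
        # Dijkstra on (hop count, weight sum): topological shortest path,
        # equal-hop ties resolved toward the smaller weight sum.
        best: dict[int, tuple[int, float]] = {source: (0, 0.0)}
        queue: list[tuple[int, float, int]] = [(0, 0.0, source)]
        while queue:
            hops, wsum, u = heapq.heappop(queue)
            if (hops, wsum) > best.get(u, (n + 1, np.inf)):
                continue
            for v, contrib in adjacency[u]:
                cand = (hops + 1, wsum + contrib)
                if cand < best.get(v, (n + 1, np.inf)):
                    best[v] = cand
                    heapq.heappush(queue, (hops + 1, cand[1], v))
        if len(best) != n:
            raise DescriptorError("graph is disconnected")
        for target, (_, wsum) in best.items():
            entries[source, target] = wsum
    np.fill_diagonal(entries, 1.0 - w_c / w)
    return BaryszMatrix(n=n, entries=entries)


def _leading_eigvec(m: BaryszMatrix) -> np.ndarray:
    eigvals, eigvecs = np.linalg.eigh(m.entries)
    return eigvecs[:, int(np.argmax(eigvals))]


def ve1(m: BaryszMatrix) -> float:
    """Absolute coefficient sum of the unit-norm leading eigenvector."""
    if m.n < 2:
        raise DescriptorError("VE descriptors undefined for a single atom")
    return float(np.abs(_leading_eigvec(m)).sum())


def ve2(m: BaryszMatrix) -> float:
    return ve1(m) / m.n


def ve3(m: BaryszMatrix) -> float:
    """VE3 = ln(0.1 * n * VE1)."""
    return float(np.log(0.1 * m.n * ve1(m)))


def tpsa(g: MolecularGraph, include_s_p: bool = False) -> float:
    """Topological polar surface area (Å²) by the published fragment scheme.

    N/O contributions only by default; ``include_s_p`` adds the S/P terms.
    """
    return float(rdMolDescriptors.CalcTPSA(g.mol, includeSandP=include_s_p))


def count_para_hydroxylation_sites(g: MolecularGraph) -> int:
    """Number of para-hydroxylation-susceptible aryl sites (substructure count)."""
    return int(Fragments.fr_para_hydroxylation(g.mol))


def _hop_distance_matrix(g: MolecularGraph) -> np.ndarray:
    n = g.n_atoms
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i, j, _ in g.bonds:
        dist[i, j] = dist[j, i] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
    return dist


def wiener_index(g: MolecularGraph) -> float:
    """Sum of topological distances over unordered heavy-atom pairs."""
    return float(_hop_distance_matrix(g).sum() / 2.0)


def zagreb_m1(g: MolecularGraph) -> float:
    """First Zagreb index: sum of squared heavy-atom degrees."""
    degrees = np.zeros(g.n_atoms)
    for i, j, _ in g.bonds:
        degrees[i] += 1
        degrees[j] += 1
    return float((degrees**2).sum())


@dataclass(frozen=True)
class DescriptorVector:
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def descriptor_pool(g: MolecularGraph) -> DescriptorVector:
    """The three model descriptors plus auxiliaries for subset selection."""
    matrix = barysz_matrix(g)
    values = {
        "VE3_DzE": ve3(matrix),
        "TPSA": tpsa(g),
        "fr_para_hydroxylation": float(count_para_hydroxylation_sites(g)),
        "VE1_DzE": ve1(matrix),
        "VE2_DzE": ve2(matrix),
        "heavy_atoms": float(g.n_atoms),
        "ring_count": float(rdMolDescriptors.CalcNumRings(g.mol)),
        "wiener": wiener_index(g),
        "zagreb_m1": zagreb_m1(g),
        "hbd": float(rdMolDescriptors.CalcNumHBD(g.mol)),
        "hba": float(rdMolDescriptors.CalcNumHBA(g.mol)),
    }
    return DescriptorVector(values=values)


def descriptor_table(smiles_by_id: dict[str, str]):
    """Descriptor pool for a set of molecules as a pandas DataFrame (id index)."""
    import pandas as pd

    rows = {cid: descriptor_pool(build_graph(smi)).values for cid, smi in smiles_by_id.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "id"
    return frame
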