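"""Atomic contact graphs and spatial partition plans.

An edge joins two atoms whose Euclidean distance is strictly below the cutoff
(7 Å by default).  Neighbor search goes through a KD-tree, so the full N×N
distance matrix is never materialized; peak memory scales with the number of
contacts.  The partition planner splits the atom list into consecutive
whole-residue cores and augments each core with a spatial environment, which
is what makes memory-bounded by-parts orbit counting possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, ParameterError
from .structure_io import AtomTable


@dataclass(frozen=True)
class GraphParams:
    """Contact-graph construction parameters."""

    cutoff: float = 7.0  # Å; edge iff distance < cutoff (strict)

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ParameterError(f"cutoff must be positive, got {self.cutoff}")


class ContactGraph:
    """Simple undirected graph over node indices 0..n_nodes-1."""

    def __init__(self, n_nodes: int, edges: np.ndarray | Sequence[tuple[int, int]]):
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if len(edges):
            if edges.min() < 0 or edges.max() >= n_nodes:
                raise ParameterError("edge endpoint outside [0, n_nodes)")
            lo = edges.min(axis=1)
            hi = edges.max(axis=1)
            keep = lo != hi  # drop self-loops
            edges = np.unique(np.column_stack([lo[keep], hi[keep]]), axis=0)
        else:
            edges = edges.reshape(0, 2)
        self.n_nodes = int(n_nodes)
        self.edges = edges
        self._indptr: Optional[np.ndarray] = None
        self._indices: Optional[np.ndarray] = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def _build_csr(self) -> None:
        u = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        v = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        counts = np.bincount(u, minlength=self.n_nodes)
        indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        order = np.lexsort((v, u))
        self._indptr = indptr
        self._indices = v[order].astype(np.int32)

    @property
    def indptr(self) -> np.ndarray:
        if self._indptr is None:
            self._build_csr()
        return self._indptr

    @property
    def indices(self) -> np.ndarray:
        """Sorted adjacency lists in CSR layout."""
        if self._indices is None:
            self._build_csr()
        return self._indices

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr).astype(np.int64)

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    def adjacency(self) -> csr_matrix:
        """0/1 adjacency as a scipy CSR matrix (int64 data)."""
        data = np.ones(len(self.indices), dtype=np.int64)
        return csr_matrix(
            (data, self.indices.astype(np.int64), self.indptr),
            shape=(self.n_nodes, self.n_nodes),
        )

    def has_edge(self, u: int, v: int) -> bool:
        nb = self.neighbors(u)
        j = np.searchsorted(nb, v)
        return bool(j < len(nb) and nb[j] == v)


def build_contact_graph(atoms: AtomTable, params: GraphParams = GraphParams()) -> ContactGraph:
    """Contact graph with an edge for every atom pair at distance < cutoff."""
    if atoms.n_atoms < 2:
        raise DegenerateInputError("need at least 2 atoms to build a contact graph")
    coords = atoms.coords
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=params.cutoff, output_type="ndarray")
    if len(pairs):
        # query_pairs returns pairs at distance <= r; enforce the strict
        # inequality on squared distances (exact for representable inputs).
        d2 = ((coords[pairs[:, 0]] - coords[pairs[:, 1]]) ** 2).sum(axis=1)
        pairs = pairs[d2 < params.cutoff**2]
    return ContactGraph(atoms.n_atoms, pairs)


@dataclass(frozen=True)
class Part:
    """One core of consecutive residues plus its spatial environment."""

    core_atoms: np.ndarray  # atom indices, ascending
    env_atoms: np.ndarray  # atom indices, ascending, disjoint from core
    core_residues: np.ndarray  # residue codes of the core

    @property
    def subset(self) -> np.ndarray:
        """Core ∪ environment atom indices, ascending."""
        return np.sort(np.concatenate([self.core_atoms, self.env_atoms]))


@dataclass
class PartitionPlan:
    parts: list[Part] = field(default_factory=list)
    chunk_size: int = 100
    surround_radius: float = 15.0


def plan_partitions(
    atoms: AtomTable,
    chunk_size: int = 100,
    surround_radius: float = 15.0,
    anchor: str = "ca",
) -> PartitionPlan:
    """Split residues into consecutive cores of ~chunk_size and attach environments.

    A residue belongs to the environment of a core when any of its atoms lies
    within ``surround_radius`` of an anchor atom of the core.  Anchors are the
    core's Cα atoms (``anchor="ca"``, the memory-lean default) or every core
    atom (``anchor="all"``, used for exact-mode decomposition).  Cores are
    disjoint and jointly cover all atoms; the last core may be smaller.
    """
    if chunk_size < 1:
        raise ParameterError(f"chunk_size must be >= 1, got {chunk_size}")
    if anchor not in ("ca", "all"):
        raise ParameterError(f"anchor must be 'ca' or 'all', got {anchor!r}")
    if atoms.n_atoms == 0:
        raise DegenerateInputError("cannot partition an empty atom table")
    res_ids = atoms.residue_ids
    n_res = int(res_ids.max()) + 1
    coords = atoms.coords
    ca_mask = atoms.ca_mask
    tree = cKDTree(coords)
    plan = PartitionPlan(chunk_size=chunk_size, surround_radius=surround_radius)
    for start in range(0, n_res, chunk_size):
        core_res = np.arange(start, min(start + chunk_size, n_res))
        core_mask = np.isin(res_ids, core_res)
        core_atoms = np.flatnonzero(core_mask)
        if anchor == "ca":
            anchors = np.flatnonzero(core_mask & ca_mask)
            if len(anchors) == 0:  # residues without Cα: fall back to all atoms
                anchors = core_atoms
        else:
            anchors = core_atoms
        hit_lists = tree.query_ball_point(coords[anchors], r=surround_radius)
        hit_atoms = np.unique(np.concatenate([np.asarray(h, dtype=np.int64) for h in hit_lists]))
        hit_res = np.unique(res_ids[hit_atoms])
        env_res = np.setdiff1d(hit_res, core_res, assume_unique=True)
        env_atoms = np.flatnonzero(np.isin(res_ids, env_res))
        plan.parts.append(
            Part(
                core_atoms=core_atoms,
                env_atoms=env_atoms,
                core_residues=core_res,
            )
        )
    return plan


def extract_subgraph(
    atoms: AtomTable, part: Part, params: GraphParams = GraphParams()
) -> tuple[ContactGraph, np.ndarray, np.ndarray]:
    """Contact graph over one part's core ∪ environment atoms.

    Returns ``(graph, core_mask, subset_indices)`` where ``core_mask`` marks
    core nodes within the subgraph and ``subset_indices`` maps subgraph node
    index -> original atom index.
    """
    subset = part.subset
    if len(subset) == 0:
        raise DegenerateInputError("empty part")
    sub = AtomTable(atoms.df.iloc[subset], model_id=atoms.model_id)
    if len(subset) >= 2:
        graph = build_contact_graph(sub, params)
    else:
        graph = ContactGraph(len(subset), np.empty((0, 2), dtype=np.int64))
    core_mask = np.isin(subset, part.core_atoms)
    return graph, core_mask, subset
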