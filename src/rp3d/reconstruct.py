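"""Coarse 3D reconstruction from a recurrence map.

The pipeline follows the recurrence-plot view of a single-cell Hi-C contact
map.  Consecutive segments on the same allele are declared neighbors
(backbone), the map becomes a graph whose edges carry a Jaccard-style local
distance between neighbor sets, all-pairs shortest paths supply global
distances, and classical (Torgerson) multidimensional scaling turns those
into 3D coordinates.  With all local distances forced to 1 the procedure
degrades to the unweighted hop-count variant used by earlier single-cell
Hi-C embeddings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csgraph

from .contacts_io import (
    Allele,
    ContactRecord,
    PhasingClass,
    RecurrenceMap,
    SegmentID,
    bin_contacts,
)

__all__ = [
    "DistanceGraph",
    "Embedding3D",
    "DisconnectedGraphError",
    "add_backbone",
    "neighbor_sets",
    "local_distance",
    "build_graph",
    "shortest_path_distances",
    "embed_mds",
    "reconstruct_cell",
]

logger = logging.getLogger(__name__)


class DisconnectedGraphError(ValueError):
    """The contact graph has several connected components.

    Carries ``component_sizes`` so callers can report or fall back to the
    largest component.
    """

    def __init__(self, component_sizes: list[int]):
        self.component_sizes = component_sizes
        super().__init__(
            "contact graph is disconnected; component sizes: "
            f"{sorted(component_sizes, reverse=True)} — the chromosomes are "
            "separated into two or more pieces (consider largest_component=True)"
        )


def add_backbone(rmap: RecurrenceMap) -> RecurrenceMap:
    """Return a copy with consecutive same-allele segments joined.

    For every ``(chrom, allele)`` chain, bins ``(i, i+1)`` over the observed
    range become contact pairs.  Existing pairs are preserved (set
    semantics), so re-applying is a no-op.
    """
    out = rmap.copy()
    for (chrom, allele), mx in rmap.max_bins.items():
        for b in range(mx):
            out.add_pair(
                SegmentID(chrom, allele, b, rmap.resolution),
                SegmentID(chrom, allele, b + 1, rmap.resolution),
            )
    return out


def neighbor_sets(rmap: RecurrenceMap, include_self: bool = True
                  ) -> dict[SegmentID, frozenset[SegmentID]]:
    """Neighbor set of every segment in the universe.

    ``include_self`` adds each segment to its own set (default), so two
    backbone-adjacent segments always share at least two members and their
    local distance stays below 1.
    """
    adj: dict[SegmentID, set[SegmentID]] = {s: set() for s in rmap.segments}
    for a, b in rmap.pairs:
        adj[a].add(b)
        adj[b].add(a)
    if include_self:
        for s, nb in adj.items():
            nb.add(s)
    return {s: frozenset(nb) for s, nb in adj.items()}


def local_distance(i: SegmentID, j: SegmentID, rmap: RecurrenceMap,
                   include_self: bool = True) -> float:
    """Jaccard distance between the neighbor sets of two segments.

    ``|N(i) symdiff N(j)| / |N(i) union N(j)|`` on the backbone-augmented
    map; 0 iff the sets are identical, 1 iff disjoint.
    """
    if i == j:
        raise ValueError("local_distance is defined for distinct segments")
    nbs = neighbor_sets(rmap, include_self=include_self)
    if i not in nbs or j not in nbs:
        raise KeyError("segment outside the map universe")
    return _jaccard_distance(nbs[i], nbs[j])


def _jaccard_distance(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    if union == 0:
        raise ValueError("both neighbor sets empty (isolated nodes)")
    return (union - len(a & b)) / union


@dataclass
class DistanceGraph:
    """Weighted contact graph over an ordered segment universe.

    ``weights[e]`` is the local distance of edge ``edges[e]`` (index pairs
    into ``nodes``).  ``component_labels`` partitions nodes into connected
    components.
    """

    nodes: list[SegmentID]
    edges: list[tuple[int, int]]
    weights: np.ndarray
    component_labels: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if len(self.nodes) else 0

    def component_sizes(self) -> list[int]:
        return np.bincount(self.component_labels).tolist()

    def adjacency_dense(self) -> np.ndarray:
        """Dense adjacency with ``inf`` marking non-edges (keeps zero-weight
        edges representable)."""
        n = len(self.nodes)
        A = np.full((n, n), np.inf)
        for (i, j), w in zip(self.edges, self.weights):
            A[i, j] = A[j, i] = w
        np.fill_diagonal(A, 0.0)
        return A


def build_graph(rmap: RecurrenceMap, uniform_weights: bool = False,
                include_self: bool = True) -> DistanceGraph:
    """Weight every recurrence-map pair by its local distance.

    ``uniform_weights=True`` sets every edge weight to 1 — the
    constant-distance variant in which global distances reduce to hop
    counts.  The map should already be backbone-augmented.
    """
    nodes = rmap.segments
    index = {s: k for k, s in enumerate(nodes)}
    nbs = neighbor_sets(rmap, include_self=include_self)
    edges: list[tuple[int, int]] = []
    weights = np.empty(len(rmap.pairs))
    for e, (a, b) in enumerate(sorted(rmap.pairs)):
        edges.append((index[a], index[b]))
        weights[e] = 1.0 if uniform_weights else _jaccard_distance(nbs[a], nbs[b])
    n = len(nodes)
    from scipy.sparse import coo_matrix

    ii = [i for i, _ in edges]
    jj = [j for _, j in edges]
    conn = coo_matrix((np.ones(len(edges)), (ii, jj)), shape=(n, n))
    n_comp, labels = csgraph.connected_components(conn, directed=False)
    g = DistanceGraph(nodes=nodes, edges=edges, weights=weights,
                      component_labels=labels)
    logger.info("graph: %d nodes, %d edges, %d component(s)",
                n, len(edges), n_comp)
    return g


def shortest_path_distances(g: DistanceGraph) -> np.ndarray:
    """All-pairs shortest-path lengths (global distances).

    Dijkstra from every node; entries across components are ``inf``.  Built
    from a dense adjacency via ``csgraph_from_dense`` so zero-weight edges
    are genuine edges.
    """
    A = g.adjacency_dense()
    sparse_graph = csgraph.csgraph_from_dense(A, null_value=np.inf)
    D = csgraph.shortest_path(sparse_graph, method="D", directed=False)
    return D


@dataclass
class Embedding3D:
    """3D coordinates per segment, with resolution provenance.

    Coordinates are in arbitrary units (the method preserves distance
    ratios, not physical scale).  ``provenance`` marks, for refined
    embeddings, how each segment's coordinate was obtained.
    """

    segments: list[SegmentID]
    coords: np.ndarray  # (n, 3)
    resolution: int
    eigenvalue_report: dict = field(default_factory=dict)
    provenance: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.segments), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.segments)} segments"
            )

    @property
    def index(self) -> dict[SegmentID, int]:
        return {s: k for k, s in enumerate(self.segments)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "chrom": [s.chrom for s in self.segments],
            "allele": [s.allele.value for s in self.segments],
            "bin_start": [s.start for s in self.segments],
            "bin_end": [s.end for s in self.segments],
            "x": self.coords[:, 0],
            "y": self.coords[:, 1],
            "z": self.coords[:, 2],
        })
        if self.provenance is not None:
            df["provenance"] = self.provenance
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Embedding3D":
        df = pd.read_csv(path, sep="\t")
        widths = (df["bin_end"] - df["bin_start"]).unique()
        if len(widths) != 1:
            raise ValueError(f"{path}: mixed bin widths {widths}")
        resolution = int(widths[0])
        segments = [
            SegmentID(str(r.chrom), Allele(r.allele),
                      int(r.bin_start) // resolution, resolution)
            for r in df.itertuples()
        ]
        provenance = (df["provenance"].tolist()
                      if "provenance" in df.columns else None)
        return cls(segments=segments, coords=df[["x", "y", "z"]].to_numpy(),
                   resolution=resolution, provenance=provenance)

    def to_pdb(self, path: str | Path, scale: float = 10.0) -> None:
        """Pseudo-PDB export: one CA pseudo-atom per segment, one chain per
        (chrom, allele), for molecular viewers.  Coordinates are scaled into
        a viewer-friendly range."""
        chain_ids = {}
        alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"
        lines = []
        serial = 1
        for s, (x, y, z) in zip(self.segments, self.coords * scale):
            key = (s.chrom, s.allele)
            if key not in chain_ids:
                chain_ids[key] = alphabet[len(chain_ids) % len(alphabet)]
            ch = chain_ids[key]
            resseq = (s.bin % 9999) + 1
            lines.append(
                f"ATOM  {serial % 100000:5d}  CA  GLY {ch}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        Path(path).write_text("\n".join(lines) + "\nEND\n")


def embed_mds(D: np.ndarray, dim: int = 3,
              segments: Sequence[SegmentID] | None = None,
              resolution: int | None = None) -> Embedding3D:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centers ``-D**2 / 2``, takes the ``dim`` leading nonnegative
    eigenpairs and scales eigenvectors by the square roots of their
    eigenvalues.  Deterministic: each eigenvector's sign is fixed so that
    its largest-magnitude entry is positive.  Raises
    :class:`DisconnectedGraphError` on non-finite entries (nodes in
    different components have infinite global distance).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(D)):
        finite_adj = np.isfinite(D) & (D > 0)
        conn = csgraph.csgraph_from_dense(
            np.where(np.isfinite(D), 1.0, 0.0), null_value=0.0)
        _, labels = csgraph.connected_components(conn, directed=False)
        raise DisconnectedGraphError(np.bincount(labels).tolist())
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals[:dim].copy()
    n_nonneg = int((pos > 0).sum())
    coords = np.zeros((n, dim))
    for k in range(min(dim, n)):
        if eigvals[k] <= 0:
            break
        v = eigvecs[:, k]
        if v[np.argmax(np.abs(v))] < 0:  # deterministic sign convention
            v = -v
        coords[:, k] = v * np.sqrt(eigvals[k])
    if n_nonneg < dim:
        logger.warning(
            "only %d nonnegative eigenvalues; padding %d coordinate(s) with "
            "zeros", n_nonneg, dim - n_nonneg)
    report = {
        "top_eigenvalues": eigvals[:dim].tolist(),
        "positive_mass": float(eigvals[eigvals > 0].sum()),
        "negative_mass": float(-eigvals[eigvals < 0].sum()),
        "retained_mass": float(pos[pos > 0].sum()),
    }
    coords -= coords.mean(axis=0, keepdims=True)
    segs = list(segments) if segments is not None else [
        SegmentID("seg", Allele.MATERNAL, k, resolution or 1) for k in range(n)
    ]
    return Embedding3D(segments=segs, coords=coords,
                       resolution=resolution or segs[0].resolution,
                       eigenvalue_report=report)


def _restrict_to_largest_component(g: DistanceGraph) -> DistanceGraph:
    sizes = np.bincount(g.component_labels)
    keep_label = int(np.argmax(sizes))
    keep = np.flatnonzero(g.component_labels == keep_label)
    remap = {old: new for new, old in enumerate(keep)}
    keep_set = set(keep.tolist())
    edges, weights = [], []
    for (i, j), w in zip(g.edges, g.weights):
        if i in keep_set and j in keep_set:
            edges.append((remap[i], remap[j]))
            weights.append(w)
    return DistanceGraph(
        nodes=[g.nodes[k] for k in keep],
        edges=edges,
        weights=np.asarray(weights),
        component_labels=np.zeros(len(keep), dtype=int),
    )


def reconstruct_cell(contacts: Sequence[ContactRecord],
                     resolution: int = 1_000_000,
                     uniform_weights: bool = False,
                     largest_component: bool = False,
                     ignore_phasing: bool = False) -> Embedding3D:
    """Full coarse reconstruction of one cell from its contact list.

    Composition: bin phased contacts -> add backbone -> weighted graph ->
    all-pairs shortest paths -> classical MDS.  A disconnected graph is a
    hard error unless ``largest_component`` is set, in which case only the
    largest connected component is embedded.
    """
    rmap = bin_contacts(contacts, resolution, ignore_phasing=ignore_phasing)
    rmap = add_backbone(rmap)
    g = build_graph(rmap, uniform_weights=uniform_weights)
    if g.n_components > 1:
        if not largest_component:
            raise DisconnectedGraphError(g.component_sizes())
        logger.warning("embedding largest of %d components (sizes %s)",
                       g.n_components, g.component_sizes())
        g = _restrict_to_largest_component(g)
    D = shortest_path_distances(g)
    emb = embed_mds(D, dim=3, segments=g.nodes, resolution=resolution)
    logger.info("embedded %d segments at %d bp", len(g.nodes), resolution)
    return emb
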