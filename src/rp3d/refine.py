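"""Resolution refinement of a coarse embedding.

The coarse 1-Mb reconstruction is upscaled to 40-kb or 100-kb bins with a
method-of-analogues step borrowed from nonlinear time-series forecasting:
for each fine segment, the coarse nodes whose neighbor sets look most like
the fine segment's own (coarse-mapped) neighbor profile are found, and the
fine coordinate is a distance-weighted average of those coarse coordinates.
The coverage argument behind the coarse step — a fine-level detection
probability q per pair becomes p = 1 - (1-q)^(W^2) per coarse pair when the
resolution ratio is W — is exposed as :func:`coverage_probability`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contacts_io import RecurrenceMap, SegmentID, segment_for
from .reconstruct import Embedding3D, add_backbone, neighbor_sets

__all__ = [
    "RefinementParams",
    "coverage_probability",
    "coarsen_map",
    "fine_neighbor_profile",
    "refine_embedding",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RefinementParams:
    """Knobs of the coarse-to-fine refinement.

    ``k_neighbors`` coarse analogues per fine segment (default 4);
    ``weight_epsilon`` regularizes the inverse-distance weights so an exact
    profile match (distance 0) dominates without dividing by zero.
    ``similarity`` is ``"jaccard"`` (default, coherent with the local
    distance of the coarse stage) or ``"overlap"`` (shared-member count).
    ``weight_mode`` is ``"inverse"`` (w_i = 1/(d_i + eps)) or
    ``"exponential"`` (w_i = exp(-d_i/d_1)).
    """

    fine_resolution: int
    coarse_resolution: int = 1_000_000
    k_neighbors: int = 4
    weight_epsilon: float = 1e-6
    similarity: str = "jaccard"
    weight_mode: str = "inverse"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.coarse_resolution % self.fine_resolution:
            raise ValueError(
                f"coarse resolution {self.coarse_resolution} not divisible "
                f"by fine resolution {self.fine_resolution}"
            )
        if self.similarity not in ("jaccard", "overlap"):
            raise ValueError(f"unknown similarity {self.similarity!r}")
        if self.weight_mode not in ("inverse", "exponential"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")

    @property
    def W(self) -> int:
        """Resolution ratio coarse/fine (25 for 1 Mb -> 40 kb)."""
        return self.coarse_resolution // self.fine_resolution


def coverage_probability(q: float, W: int) -> float:
    """Probability a coarse bin pair holds >= 1 detected contact.

    If each of the W*W fine pairs inside a coarse box is detected
    independently with probability ``q``, the coarse pair is covered with
    probability ``1 - (1-q)**(W**2)``.  With q=0.01 and W=25 this is ~0.998:
    even 1%-detected fine contacts give an almost complete 1-Mb map.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if W < 1:
        raise ValueError(f"W must be a positive integer, got {W}")
    return 1.0 - (1.0 - q) ** (W * W)


def _coarse_bin(s: SegmentID, coarse_resolution: int) -> SegmentID:
    ratio = coarse_resolution // s.resolution
    return SegmentID(s.chrom, s.allele, s.bin // ratio, coarse_resolution)


def coarsen_map(fine_rmap: RecurrenceMap, coarse_resolution: int
                ) -> RecurrenceMap:
    """Aggregate a fine recurrence map into coarse bins (pairs landing in
    one coarse bin become intra-bin and are dropped)."""
    if coarse_resolution % fine_rmap.resolution:
        raise ValueError("coarse resolution must be a multiple of fine")
    out = RecurrenceMap(resolution=coarse_resolution)
    for (chrom, allele), mx in fine_rmap.max_bins.items():
        ratio = coarse_resolution // fine_rmap.resolution
        out.observe_segment(SegmentID(chrom, allele, mx // ratio,
                                      coarse_resolution))
    for a, b in fine_rmap.pairs:
        ca, cb = _coarse_bin(a, coarse_resolution), _coarse_bin(b, coarse_resolution)
        if ca != cb:
            out.add_pair(ca, cb)
    return out


def fine_neighbor_profile(s: SegmentID, fine_rmap: RecurrenceMap,
                          coarse_resolution: int,
                          _nbs: dict | None = None) -> frozenset[SegmentID]:
    """Coarse-mapped neighbor profile of a fine segment.

    Maps every neighbor of ``s`` in the (backbone-augmented) fine map —
    including ``s`` itself, matching the neighbor-set convention of the
    coarse stage — onto its containing coarse bin.
    """
    nbs = _nbs if _nbs is not None else neighbor_sets(fine_rmap)
    if s not in nbs:
        raise KeyError(f"{s} not in fine map universe")
    return frozenset(_coarse_bin(t, coarse_resolution) for t in nbs[s])


def _profile_distance(profile: frozenset, candidate: frozenset,
                      similarity: str) -> float:
    if similarity == "jaccard":
        union = len(profile | candidate)
        return (union - len(profile & candidate)) / union if union else 1.0
    # overlap: more shared members = closer; normalized to [0, 1]
    denom = max(len(profile), 1)
    return 1.0 - len(profile & candidate) / denom


def refine_embedding(coarse: Embedding3D, fine_rmap: RecurrenceMap,
                     params: RefinementParams) -> Embedding3D:
    """Upscale a coarse embedding to the fine map's resolution.

    For every fine segment the ``k_neighbors`` coarse nodes with the most
    similar neighbor sets are selected (ties broken by (chrom, allele, bin)
    order, so runs are deterministic) and their coarse coordinates averaged
    with weights decaying in profile distance.  Fine segments whose profile
    is empty fall back to linear interpolation along their own allele's
    backbone between the nearest refined flanking segments; the per-segment
    ``provenance`` column records ``knn`` or ``interpolated``.
    """
    if fine_rmap.resolution != params.fine_resolution:
        raise ValueError("fine map resolution disagrees with params")
    if coarse.resolution != params.coarse_resolution:
        raise ValueError("coarse embedding resolution disagrees with params")

    coarse_index = coarse.index
    # Candidate neighbor sets come from the coarsened fine map (the coarse
    # contact map implied by the same contacts), backbone-augmented.
    coarse_rmap = add_backbone(coarsen_map(fine_rmap, params.coarse_resolution))
    coarse_nbs = neighbor_sets(coarse_rmap)
    candidates = [c for c in coarse_rmap.segments if c in coarse_index]
    missing = [c for c in coarse_rmap.segments if c not in coarse_index]
    if missing:
        raise KeyError(
            f"coarse embedding is missing {len(missing)} required node(s), "
            f"first: {missing[0]}"
        )
    cand_sets = [coarse_nbs[c] for c in candidates]
    cand_coords = np.array([coarse.coords[coarse_index[c]] for c in candidates])

    fine_nbs = neighbor_sets(fine_rmap)
    fine_segments = fine_rmap.segments
    coords = np.zeros((len(fine_segments), 3))
    provenance = ["knn"] * len(fine_segments)
    pending: list[int] = []

    for idx, s in enumerate(fine_segments):
        profile = frozenset(
            _coarse_bin(t, params.coarse_resolution) for t in fine_nbs[s]
        )
        if not profile:
            pending.append(idx)
            provenance[idx] = "interpolated"
            continue
        dists = np.array([
            _profile_distance(profile, cs, params.similarity)
            for cs in cand_sets
        ])
        # stable tie-break: candidates are already in (chrom, allele, bin) order
        order = np.argsort(dists, kind="stable")[: params.k_neighbors]
        d = dists[order]
        if params.weight_mode == "inverse":
            w = 1.0 / (d + params.weight_epsilon)
        else:
            scale = d[0] if d[0] > 0 else params.weight_epsilon
            w = np.exp(-d / scale)
        w = w / w.sum()
        coords[idx] = w @ cand_coords[order]

    if pending:
        _interpolate_backbone(fine_segments, coords, pending)
        logger.info("interpolated %d fine segment(s) with empty profiles",
                    len(pending))

    return Embedding3D(segments=fine_segments, coords=coords,
                       resolution=params.fine_resolution,
                       provenance=provenance)


def _interpolate_backbone(segments: list[SegmentID], coords: np.ndarray,
                          pending: list[int]) -> None:
    """Fill pending coordinates by linear interpolation along each allele's
    backbone between the nearest resolved flanking segments."""
    pending_set = set(pending)
    by_chain: dict[tuple[str, object], list[int]] = {}
    for idx, s in enumerate(segments):
        by_chain.setdefault((s.chrom, s.allele), []).append(idx)
    for chain in by_chain.values():
        chain.sort(key=lambda k: segments[k].bin)
        resolved = [k for k in chain if k not in pending_set]
        if not resolved:
            raise ValueError(
                "an entire chain has empty neighbor profiles; nothing to "
                "interpolate from"
            )
        res_bins = np.array([segments[k].bin for k in resolved])
        for k in chain:
            if k not in pending_set:
                continue
            b = segments[k].bin
            pos = np.searchsorted(res_bins, b)
            if pos == 0:
                coords[k] = coords[resolved[0]]
            elif pos == len(resolved):
                coords[k] = coords[resolved[-1]]
            else:
                lo, hi = resolved[pos - 1], resolved[pos]
                t = (b - segments[lo].bin) / (segments[hi].bin - segments[lo].bin)
                coords[k] = (1 - t) * coords[lo] + t * coords[hi]
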