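"""Validation and structure-characterization metrics.

Two families live here.  Self-validation checks a reconstruction against
the Hi-C contacts themselves, stratified by phasing class: phased contacts
must place their two resolved segments within the detection-limit distance,
while half-phased and unphased contacts are scored by the best of their 2
or 4 possible allele assignments — the ambiguous contacts are never
resolved, only tested.  Structure characterization computes the fractal
correlation dimension, the intra-chromosomal ("territory") contact ratio
against shuffled nulls, per-allele radial-distance summaries and the
normalized central-hole radius.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .contacts_io import (
    Allele,
    ContactRecord,
    PhasingClass,
    RecurrenceMap,
    SegmentID,
    classify_phasing,
    segment_for,
)
from .reconstruct import Embedding3D

__all__ = [
    "DETECTION_LIMIT",
    "ClassConsistency",
    "ConsistencyReport",
    "StructureMetrics",
    "consistency_ratios",
    "contact_map_reproduction",
    "corr3d",
    "align_similarity",
    "correlation_dimension",
    "territory_ratio",
    "radial_metrics",
    "structure_metrics",
]

logger = logging.getLogger(__name__)

#: Detection-limit distance (embedding units) within which a Hi-C contact
#: counts as satisfied by a reconstruction.
DETECTION_LIMIT = 22.0 / 27.0


@dataclass
class ClassConsistency:
    """Consistency tally for one phasing class."""

    satisfied: int = 0
    total: int = 0
    excluded: int = 0

    @property
    def ratio(self) -> float:
        return self.satisfied / self.total if self.total else float("nan")


@dataclass
class ConsistencyReport:
    """Phasing-stratified self-validation of an embedding.

    Denominators are all evaluable contacts of each class in the cell;
    contacts whose every candidate assignment falls outside the embedding
    are counted in ``excluded`` instead.
    """

    per_class: dict[PhasingClass, ClassConsistency]
    detection_limit: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pc in PhasingClass:
            cc = self.per_class[pc]
            rows.append({"class": pc.value, "satisfied": cc.satisfied,
                         "total": cc.total, "excluded": cc.excluded,
                         "ratio": cc.ratio})
        return pd.DataFrame(rows)


def _candidate_alleles(allele: Allele) -> tuple[Allele, ...]:
    if allele is Allele.UNKNOWN:
        return (Allele.MATERNAL, Allele.PATERNAL)
    return (allele,)


def consistency_ratios(emb: Embedding3D, contacts: Sequence[ContactRecord],
                       limit: float = DETECTION_LIMIT,
                       limit_scale: float = 1.0) -> ConsistencyReport:
    """Score every contact against the embedding within the detection limit.

    A phased contact is satisfied iff the distance between its two resolved
    segments is <= limit; a half-phased (unphased) contact iff the minimum
    over its 2 (4) candidate allele assignments is.  ``limit_scale`` is an
    optional mean-distance rescaling factor for comparing embeddings with
    different overall scales.
    """
    eff_limit = limit * limit_scale
    index = emb.index
    coords = emb.coords
    report = {pc: ClassConsistency() for pc in PhasingClass}
    for c in contacts:
        pc = classify_phasing(c)
        tally = report[pc]
        best = np.inf
        evaluable = False
        for aa in _candidate_alleles(c.allele_a):
            sa = segment_for(c.chrom_a, c.pos_a, aa, emb.resolution)
            ia = index.get(sa)
            if ia is None:
                continue
            for ab in _candidate_alleles(c.allele_b):
                sb = segment_for(c.chrom_b, c.pos_b, ab, emb.resolution)
                ib = index.get(sb)
                if ib is None:
                    continue
                evaluable = True
                d = float(np.linalg.norm(coords[ia] - coords[ib]))
                best = min(best, d)
        if not evaluable:
            tally.excluded += 1
            continue
        tally.total += 1
        if best <= eff_limit:
            tally.satisfied += 1
    return ConsistencyReport(per_class=report, detection_limit=eff_limit)


def contact_map_reproduction(emb: Embedding3D, truth_rmap: RecurrenceMap,
                             threshold: float | None = None,
                             recurrence_rate: float | None = None
                             ) -> tuple[RecurrenceMap, float, float]:
    """Reproduce a contact map from coordinates; score against the truth.

    The threshold rule is either a fixed distance or a target recurrence
    rate (the reproduced map then keeps the closest ``rate``-fraction of all
    segment pairs).  Returns ``(reproduced_map, precision, recall)``; recall
    is measured over truth pairs whose both segments the embedding covers.
    """
    if (threshold is None) == (recurrence_rate is None):
        raise ValueError("give exactly one of threshold / recurrence_rate")
    n = len(emb.segments)
    d = pdist(emb.coords)
    if recurrence_rate is not None:
        if not 0.0 < recurrence_rate <= 1.0:
            raise ValueError("recurrence_rate must be in (0, 1]")
        k = int(round(recurrence_rate * len(d)))
        k = max(k, 1)
        threshold = float(np.partition(d, k - 1)[k - 1])
    mask = squareform(d <= threshold)
    repro = RecurrenceMap(resolution=emb.resolution)
    for s in emb.segments:
        repro.observe_segment(s)
    ii, jj = np.nonzero(np.triu(mask, k=1))
    for i, j in zip(ii, jj):
        repro.add_pair(emb.segments[i], emb.segments[j])
    covered = set(emb.segments)
    truth_pairs = {p for p in truth_rmap.pairs
                   if p[0] in covered and p[1] in covered}
    hit = len(repro.pairs & truth_pairs)
    precision = hit / len(repro.pairs) if repro.pairs else float("nan")
    recall = hit / len(truth_pairs) if truth_pairs else float("nan")
    repro.diagnostics["threshold"] = threshold
    repro.diagnostics["recurrence_rate"] = len(repro.pairs) / max(len(d), 1)
    return repro, precision, recall


def _coords_pair(emb, truth):
    """Common-segment coordinate matrices of an embedding and a truth."""
    if isinstance(truth, Embedding3D):
        common = [s for s in emb.segments if s in truth.index]
        if len(common) < 4:
            raise ValueError("fewer than 4 common segments")
        ti = truth.index
        X = np.array([emb.coords[emb.index[s]] for s in common])
        Y = np.array([truth.coords[ti[s]] for s in common])
        return X, Y
    Y = np.asarray(truth, dtype=float)
    X = np.asarray(emb.coords if isinstance(emb, Embedding3D) else emb,
                   dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {Y.shape}")
    if X.shape[0] < 4:
        raise ValueError("fewer than 4 points")
    return X, Y


def align_similarity(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Best similarity transform (translation, rotation, isotropic scale,
    reflection allowed) of ``X`` onto ``Y``; returns transformed ``X``."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc.T @ Yc)
    Q = U @ Vt
    denom = (Xc ** 2).sum()
    scale = S.sum() / denom if denom > 0 else 1.0
    return scale * Xc @ Q + Y.mean(axis=0)


def corr3d(emb: "Embedding3D | np.ndarray", truth) -> float:
    """3D correlation coefficient between an embedding and a known truth.

    The embedding is first aligned onto the truth by the optimal similarity
    transform (reflection permitted — MDS output has arbitrary chirality),
    then the Pearson correlation of the stacked 3N aligned coordinates with
    the 3N truth coordinates is returned.  Invariant to any similarity
    transform of either argument; 1 means shape identity.
    """
    X, Y = _coords_pair(emb, truth)
    Xa = align_similarity(X, Y)
    # center per axis so the value is exactly translation invariant
    A = (Xa - Xa.mean(axis=0)).ravel()
    B = (Y - Y.mean(axis=0)).ravel()
    r = float(A @ B / np.sqrt((A @ A) * (B @ B)))
    return r


def correlation_dimension(emb: "Embedding3D | np.ndarray",
                          c_range: tuple[float, float] = (2e-4, 5e-3),
                          n_radii: int = 100
                          ) -> tuple[float, tuple[float, float]]:
    """Correlation dimension D2 by the correlation-integral slope.

    The correlation integral C(r) is the fraction of point pairs within
    distance r; D2 is the least-squares slope of log C(r) versus log r over
    radii whose C(r) lies in ``c_range``.  The default window sits at small
    C where the log-log curve is in its scaling regime; at larger C the
    slope of bounded point sets is biased low by boundary effects.  The
    window's lower edge is raised automatically so that it always contains
    at least ~10 pairs, and the window widens upward if it would hold fewer
    than 5 radii.  Returns ``(D2, (r_min, r_max))``.
    """
    pts = emb.coords if isinstance(emb, Embedding3D) else np.asarray(emb, float)
    n = pts.shape[0]
    if n < 100:
        warnings.warn(f"correlation_dimension with only {n} points is noisy",
                      stacklevel=2)
    d = pdist(pts)
    d.sort()
    if d[-1] <= 0:
        raise ValueError("degenerate point set: all points coincide")
    n_pairs = len(d)
    c_lo = max(c_range[0], 10.0 / n_pairs)
    c_hi = max(c_range[1], 50.0 / n_pairs)
    d_pos = d[d > 0]
    radii = np.geomspace(d_pos[0], d[-1], n_radii)
    C = np.searchsorted(d, radii, side="right") / n_pairs
    mask = (C >= c_lo) & (C <= c_hi) & (C > 0)
    while mask.sum() < 5 and c_hi < 1.0:
        c_hi = min(1.0, c_hi * 2)
        mask = (C >= c_lo) & (C <= c_hi) & (C > 0)
    if mask.sum() < 2:
        raise ValueError("no usable scaling window for this point set")
    slope = float(np.polyfit(np.log(radii[mask]), np.log(C[mask]), 1)[0])
    r_window = (float(radii[mask].min()), float(radii[mask].max()))
    return slope, r_window


def territory_ratio(emb: Embedding3D, closeness: float = DETECTION_LIMIT,
                    n_shuffles: int = 20, seed: int | None = None
                    ) -> tuple[float, list[float]]:
    """Intra-chromosomal contact ratio, with a shuffled null.

    Among all segment pairs within ``closeness``, the fraction belonging to
    the same (chrom, allele) chain.  The null shuffles the coordinate-to-
    segment assignment uniformly at random ``n_shuffles`` times and
    recomputes; clustered chromosome territories put the observed value far
    above the shuffled ones.
    """
    chains = sorted({(s.chrom, s.allele) for s in emb.segments})
    chain_id = {c: k for k, c in enumerate(chains)}
    labels = np.array([chain_id[(s.chrom, s.allele)] for s in emb.segments])
    if len(chains) < 2:
        logger.warning("territory_ratio with a single chain is trivially 1")
    d = pdist(emb.coords)
    n = len(emb.segments)
    ii, jj = np.triu_indices(n, k=1)
    close = d <= closeness
    if not close.any():
        raise ValueError("no segment pairs within the closeness threshold")
    ci, cj = ii[close], jj[close]

    def intra(lab: np.ndarray) -> float:
        return float(np.mean(lab[ci] == lab[cj]))

    observed = intra(labels)
    rng = np.random.default_rng(seed)
    shuffled = [intra(rng.permutation(labels)) for _ in range(n_shuffles)]
    return observed, shuffled


@dataclass
class RadialMetrics:
    """Radial-distance summaries of an embedding around its centroid."""

    radial: np.ndarray
    by_allele: pd.DataFrame
    hole_radius_normalized: float


def radial_metrics(emb: Embedding3D, hole_method: str = "nearest"
                   ) -> RadialMetrics:
    """Radial distances from the centroid, per-chain summaries, and the
    normalized central-hole radius.

    ``hole_method="nearest"`` takes the minimum radial distance over all
    points, normalized by the mean radial distance; ``"histogram"``
    instead locates the innermost empty radial shell of a 50-bin histogram
    (first bin edge below the first occupied bin).
    """
    center = emb.coords.mean(axis=0)
    radial = np.linalg.norm(emb.coords - center, axis=1)
    mean_r = float(radial.mean())
    if mean_r == 0:
        raise ValueError("degenerate embedding: all points at the centroid")
    if hole_method == "nearest":
        hole = float(radial.min()) / mean_r
    elif hole_method == "histogram":
        hist, edges = np.histogram(radial, bins=50, range=(0.0, radial.max()))
        first_occupied = int(np.argmax(hist > 0))
        hole = float(edges[first_occupied]) / mean_r
    else:
        raise ValueError(f"unknown hole_method {hole_method!r}")
    rows = []
    for (chrom, allele) in sorted({(s.chrom, s.allele) for s in emb.segments}):
        sel = np.array([s.chrom == chrom and s.allele == allele
                        for s in emb.segments])
        r = radial[sel]
        rows.append({
            "chrom": chrom, "allele": allele.value, "n": int(sel.sum()),
            "median": float(np.median(r)),
            "q1": float(np.percentile(r, 25)),
            "q3": float(np.percentile(r, 75)),
            "mean": float(r.mean()),
        })
    return RadialMetrics(radial=radial, by_allele=pd.DataFrame(rows),
                         hole_radius_normalized=hole)


@dataclass
class StructureMetrics:
    """Bundle of structure-characterization results for one embedding."""

    correlation_dimension: float
    scaling_range: tuple[float, float]
    intra_ratio: float
    shuffled_intra_ratios: list[float]
    hole_radius_normalized: float
    radial_by_allele: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "correlation_dimension": self.correlation_dimension,
            "scaling_range": list(self.scaling_range),
            "intra_ratio": self.intra_ratio,
            "shuffled_intra_ratios": self.shuffled_intra_ratios,
            "hole_radius_normalized": self.hole_radius_normalized,
            "radial_by_allele": self.radial_by_allele.to_dict(orient="records"),
        }


def structure_metrics(emb: Embedding3D, closeness: float = DETECTION_LIMIT,
                      n_shuffles: int = 20, seed: int | None = None
                      ) -> StructureMetrics:
    """Convenience wrapper computing every structure metric at once."""
    d2, rng_window = correlation_dimension(emb)
    intra, shuffled = territory_ratio(emb, closeness=closeness,
                                      n_shuffles=n_shuffles, seed=seed)
    rad = radial_metrics(emb)
    return StructureMetrics(
        correlation_dimension=d2,
        scaling_range=rng_window,
        intra_ratio=intra,
        shuffled_intra_ratios=shuffled,
        hole_radius_normalized=rad.hole_radius_normalized,
        radial_by_allele=rad.by_allele,
    )
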