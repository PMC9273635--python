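"""Synthetic diploid polymer experiments.

A ground-truth structure is a set of chains (one per chromosome copy)
generated as fixed-step random walks confined to a nucleus-like sphere.
Contacts are derived exactly the way a single-cell Hi-C experiment sees
them: every non-adjacent bead pair closer than a capture threshold is a
potential contact, each detected with probability ``q_detect``, and each
leg keeps its true allele label only with probability ``phasing_rate`` —
mimicking the sparse SNV coverage that leaves most real contacts
half-phased or unphased.  The generator is the engine of the polymer
validation protocol: reconstruct from the synthetic contacts, compare to
the known coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .contacts_io import Allele, ContactRecord, RecurrenceMap, SegmentID
from .reconstruct import Embedding3D

__all__ = [
    "PolymerTruth",
    "SyntheticExperiment",
    "simulate_polymer",
    "derive_contacts",
    "subsample_points",
    "threshold_for_recurrence_rate",
]

logger = logging.getLogger(__name__)


@dataclass
class PolymerTruth:
    """Ground-truth bead coordinates per (chrom, allele) chain.

    One bead per fine-resolution segment; bead ``k`` of a chain is segment
    bin ``k``.  Coordinates are in step-length units.
    """

    chains: dict[tuple[str, Allele], np.ndarray]
    resolution: int
    nucleus_radius: float
    step: float
    seed: int | None = None

    @property
    def segments(self) -> list[SegmentID]:
        return [
            SegmentID(chrom, allele, k, self.resolution)
            for (chrom, allele) in sorted(self.chains)
            for k in range(len(self.chains[(chrom, allele)]))
        ]

    def coords_matrix(self) -> np.ndarray:
        return np.vstack([self.chains[key] for key in sorted(self.chains)])

    def as_embedding(self) -> Embedding3D:
        """The truth viewed as an Embedding3D (for corr3d and metrics)."""
        return Embedding3D(segments=self.segments,
                           coords=self.coords_matrix(),
                           resolution=self.resolution)

    def n_beads(self) -> int:
        return sum(len(c) for c in self.chains.values())


@dataclass
class SyntheticExperiment:
    """One simulated single-cell Hi-C experiment over a known truth."""

    truth: PolymerTruth
    contacts: list[ContactRecord]
    contact_threshold: float
    q_detect: float
    phasing_rate: float
    seed: int | None
    n_true_pairs: int

    @property
    def recurrence_rate(self) -> float:
        """Realized fraction of all bead pairs that are true contacts."""
        n = self.truth.n_beads()
        return self.n_true_pairs / (n * (n - 1) / 2)

    def true_map(self) -> RecurrenceMap:
        """The complete thresholded contact map of the truth (q=1), at the
        truth's resolution."""
        segs = self.truth.segments
        coords = self.truth.coords_matrix()
        rmap = RecurrenceMap(resolution=self.truth.resolution)
        for s in segs:
            rmap.observe_segment(s)
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(self.contact_threshold):
            a, b = segs[i], segs[j]
            if a.chrom == b.chrom and a.allele == b.allele and abs(a.bin - b.bin) == 1:
                continue
            rmap.add_pair(a, b)
        return rmap


def simulate_polymer(n_chroms: int = 1, beads_per_chain: int = 500,
                     two_alleles: bool = True, step: float = 1.0,
                     nucleus_radius: float = 6.0, resolution: int = 40_000,
                     seed: int | None = None) -> PolymerTruth:
    """Confined random-walk chains inside a nucleus-like sphere.

    Each chain starts uniformly inside the sphere and takes fixed-length
    steps in uniformly random directions; a step that would leave the
    sphere is re-drawn, so bond lengths are exactly ``step`` and every bead
    stays confined.  ``two_alleles`` generates a maternal and a paternal
    copy of every chromosome.  Deterministic given ``seed``.
    """
    if step <= 0 or nucleus_radius <= 0 or beads_per_chain < 1 or n_chroms < 1:
        raise ValueError("parameters must be positive")
    if step > 2 * nucleus_radius:
        raise ValueError(
            f"step {step} exceeds the sphere diameter {2 * nucleus_radius}; "
            "no confined walk exists"
        )
    rng = np.random.default_rng(seed)
    alleles = (Allele.MATERNAL, Allele.PATERNAL) if two_alleles else (Allele.MATERNAL,)
    chains: dict[tuple[str, Allele], np.ndarray] = {}
    for c in range(1, n_chroms + 1):
        for allele in alleles:
            beads = np.empty((beads_per_chain, 3))
            beads[0] = _uniform_in_sphere(rng, nucleus_radius)
            for k in range(1, beads_per_chain):
                for _ in range(10_000):
                    cand = beads[k - 1] + step * _uniform_direction(rng)
                    if np.dot(cand, cand) <= nucleus_radius ** 2:
                        beads[k] = cand
                        break
                else:  # pragma: no cover - geometrically unreachable
                    raise RuntimeError("confined step resampling failed")
            chains[(f"chr{c}", allele)] = beads
    return PolymerTruth(chains=chains, resolution=resolution,
                        nucleus_radius=nucleus_radius, step=step, seed=seed)


def _uniform_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = _uniform_direction(rng)
    return radius * rng.random() ** (1.0 / 3.0) * v


def _uniform_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def threshold_for_recurrence_rate(truth: PolymerTruth, rate: float) -> float:
    """Distance threshold at which the thresholded map's recurrence rate
    (fraction of all bead pairs in contact) equals ``rate``."""
    if not 0.0 < rate < 1.0:
        raise ValueError("rate must be in (0, 1)")
    d = pdist(truth.coords_matrix())
    return float(np.quantile(d, rate))


def derive_contacts(truth: PolymerTruth, contact_threshold: float,
                    q_detect: float = 1.0, phasing_rate: float = 1.0,
                    seed: int | None = None, cell_id: str = "synthetic"
                    ) -> SyntheticExperiment:
    """Capture contacts from the truth with detection and phasing noise.

    All non-adjacent bead pairs within ``contact_threshold`` are the true
    contact set (adjacent beads are backbone, added deterministically by the
    reconstruction, so emitting them would only inflate consistency).  Each
    true contact is detected with probability ``q_detect``; each leg of a
    detected contact carries its true allele label with probability
    ``phasing_rate`` and is otherwise unknown.  Genomic positions are bead
    midpoints in bp at the truth's resolution.
    """
    if contact_threshold <= 0:
        raise ValueError("contact_threshold must be positive")
    for name, v in (("q_detect", q_detect), ("phasing_rate", phasing_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    segs = truth.segments
    coords = truth.coords_matrix()
    tree = cKDTree(coords)
    pairs = []
    for i, j in sorted(tree.query_pairs(contact_threshold)):
        a, b = segs[i], segs[j]
        if a.chrom == b.chrom and a.allele == b.allele and abs(a.bin - b.bin) == 1:
            continue
        pairs.append((a, b))
    n_true = len(pairs)
    keep = rng.random(n_true) < q_detect if n_true else np.empty(0, bool)
    contacts: list[ContactRecord] = []
    res = truth.resolution
    for (a, b), kept in zip(pairs, keep):
        if not kept:
            continue
        phased_a = rng.random() < phasing_rate
        phased_b = rng.random() < phasing_rate
        contacts.append(ContactRecord(
            chrom_a=a.chrom, pos_a=a.bin * res + res // 2,
            allele_a=a.allele if phased_a else Allele.UNKNOWN,
            chrom_b=b.chrom, pos_b=b.bin * res + res // 2,
            allele_b=b.allele if phased_b else Allele.UNKNOWN,
            cell_id=cell_id,
        ))
    logger.info(
        "derived %d/%d true contacts (q=%.3g, phasing=%.3g, threshold=%.3g)",
        len(contacts), n_true, q_detect, phasing_rate, contact_threshold)
    return SyntheticExperiment(
        truth=truth, contacts=contacts, contact_threshold=contact_threshold,
        q_detect=q_detect, phasing_rate=phasing_rate, seed=seed,
        n_true_pairs=n_true,
    )


def subsample_points(truth: PolymerTruth, stride: int = 5) -> PolymerTruth:
    """Keep every ``stride``-th bead of each chain, renumbered.

    The retained beads are the starts of width-``stride`` blocks, so the
    subsampled truth's resolution is ``stride *`` the original — retained
    bead ``k`` represents coarse bin ``k``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride == 1:
        return PolymerTruth(
            chains={k: v.copy() for k, v in truth.chains.items()},
            resolution=truth.resolution, nucleus_radius=truth.nucleus_radius,
            step=truth.step, seed=truth.seed)
    return PolymerTruth(
        chains={k: v[::stride].copy() for k, v in truth.chains.items()},
        resolution=truth.resolution * stride,
        nucleus_radius=truth.nucleus_radius,
        step=truth.step, seed=truth.seed,
    )
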