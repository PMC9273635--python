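"""Reading, writing and binning of single-cell Hi-C contact lists.

A contact is one ligation event between two genomic loci ("legs").  In a
diploid cell each leg may or may not carry allele-identifying SNVs, so each
leg has an allele label: maternal, paternal or unknown.  Contacts where both
legs are labelled ("phased") drive the 3D reconstruction; the rest
("half-phased", "unphased") are reserved for self-validation and are never
resolved to an allele by this package — avoiding allele imputation is the
point of the method.

Binning turns contacts into a :class:`RecurrenceMap`: a symmetric binary
structure over allele-resolved chromosome segments at a chosen resolution,
which the reconstruction stage treats as a recurrence plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Allele",
    "PhasingClass",
    "ContactRecord",
    "SegmentID",
    "RecurrenceMap",
    "Dialect",
    "DEFAULT_DIALECT",
    "ContactParseError",
    "NoPhasedContactsError",
    "read_contacts",
    "write_contacts",
    "classify_phasing",
    "segment_for",
    "bin_contacts",
]

logger = logging.getLogger(__name__)


class Allele(str, Enum):
    """Parental origin of one leg of a contact."""

    MATERNAL = "mat"
    PATERNAL = "pat"
    UNKNOWN = "unknown"


class PhasingClass(str, Enum):
    """How much allele information a contact carries.

    ``PHASED``: both legs labelled; usable for reconstruction.
    ``HALF_PHASED``: exactly one leg labelled; usable for validation.
    ``UNPHASED``: neither leg labelled; usable for validation.
    """

    PHASED = "phased"
    HALF_PHASED = "half_phased"
    UNPHASED = "unphased"


@dataclass(frozen=True)
class ContactRecord:
    """One Hi-C ligation event between two genomic legs.

    Positions are 1-based base-pair coordinates, as in the input files.
    """

    chrom_a: str
    pos_a: int
    allele_a: Allele
    chrom_b: str
    pos_b: int
    allele_b: Allele
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError(
                f"positions must be >= 1 (got {self.pos_a}, {self.pos_b})"
            )


@dataclass(frozen=True, order=True)
class SegmentID:
    """One binned chromosome segment on one allele at a stated resolution.

    The genomic interval is half-open: ``[bin*resolution, (bin+1)*resolution)``
    in 0-based coordinates.  This is the node identity used throughout the
    pipeline.
    """

    chrom: str
    allele: Allele
    bin: int
    resolution: int

    def __post_init__(self) -> None:
        if self.bin < 0:
            raise ValueError(f"bin must be >= 0, got {self.bin}")
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.allele is Allele.UNKNOWN:
            raise ValueError("a SegmentID must be allele-resolved (mat or pat)")

    @property
    def start(self) -> int:
        """0-based inclusive start of the genomic interval (bp)."""
        return self.bin * self.resolution

    @property
    def end(self) -> int:
        """0-based exclusive end of the genomic interval (bp)."""
        return (self.bin + 1) * self.resolution


def segment_for(chrom: str, pos: int, allele: Allele, resolution: int) -> SegmentID:
    """Map a 1-based genomic position onto its containing segment.

    Positions exactly on a bin boundary belong to the higher bin
    (floor division of ``pos - 1``), consistent with half-open intervals.
    """
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    return SegmentID(chrom=chrom, allele=allele, bin=(pos - 1) // resolution,
                     resolution=resolution)


Pair = tuple[SegmentID, SegmentID]


def _canonical(a: SegmentID, b: SegmentID) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass
class RecurrenceMap:
    """Symmetric binary contact structure over chromosome segments.

    ``pairs`` holds unordered segment pairs in canonical (sorted) order; no
    self-pairs are stored.  The segment universe covers, for every
    ``(chrom, allele)`` ever seen, bins ``0..max_bin`` — so chains are
    contiguous ranges even where no contact landed.
    """

    resolution: int
    pairs: set[Pair] = field(default_factory=set)
    max_bins: dict[tuple[str, Allele], int] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def observe_segment(self, s: SegmentID) -> None:
        """Extend the universe to include ``s`` (and all lower bins)."""
        if s.resolution != self.resolution:
            raise ValueError(
                f"segment resolution {s.resolution} != map resolution {self.resolution}"
            )
        key = (s.chrom, s.allele)
        if self.max_bins.get(key, -1) < s.bin:
            self.max_bins[key] = s.bin

    def add_pair(self, a: SegmentID, b: SegmentID) -> None:
        """Mark an unordered contact pair; self-pairs are rejected."""
        if a == b:
            raise ValueError("self-pairs are not stored in a RecurrenceMap")
        self.observe_segment(a)
        self.observe_segment(b)
        self.pairs.add(_canonical(a, b))

    def has_pair(self, a: SegmentID, b: SegmentID) -> bool:
        return _canonical(a, b) in self.pairs

    @property
    def segments(self) -> list[SegmentID]:
        """Ordered segment universe (sorted by chrom, allele, bin)."""
        out = [
            SegmentID(chrom, allele, b, self.resolution)
            for (chrom, allele), mx in sorted(self.max_bins.items())
            for b in range(mx + 1)
        ]
        return out

    def __len__(self) -> int:
        return sum(mx + 1 for mx in self.max_bins.values())

    def copy(self) -> "RecurrenceMap":
        return RecurrenceMap(
            resolution=self.resolution,
            pairs=set(self.pairs),
            max_bins=dict(self.max_bins),
            diagnostics=dict(self.diagnostics),
        )


class ContactParseError(ValueError):
    """A contact file line could not be parsed; carries the line number."""


class NoPhasedContactsError(ValueError):
    """Binning retained no contacts after the phasing filter."""


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping and allele vocabulary of a contact TSV file.

    The defaults match the package's own format: a header line with columns
    ``cell, chrom_a, pos_a, allele_a, chrom_b, pos_b, allele_b`` and allele
    vocabulary ``mat`` / ``pat`` / ``.``.  Real datasets with different
    headers are one remapping away.
    """

    cell: str = "cell"
    chrom_a: str = "chrom_a"
    pos_a: str = "pos_a"
    allele_a: str = "allele_a"
    chrom_b: str = "chrom_b"
    pos_b: str = "pos_b"
    allele_b: str = "allele_b"
    # file label -> allele; lookups are case-insensitive and fall back to
    # the enum values themselves, so "maternal"/"mat" both parse.
    allele_vocab: tuple[tuple[str, Allele], ...] = (
        ("mat", Allele.MATERNAL),
        ("maternal", Allele.MATERNAL),
        ("m", Allele.MATERNAL),
        ("pat", Allele.PATERNAL),
        ("paternal", Allele.PATERNAL),
        ("p", Allele.PATERNAL),
        (".", Allele.UNKNOWN),
        ("unknown", Allele.UNKNOWN),
        ("u", Allele.UNKNOWN),
        ("ambig", Allele.UNKNOWN),
    )

    def parse_allele(self, label: str) -> Allele:
        key = label.strip().lower()
        for file_label, allele in self.allele_vocab:
            if key == file_label:
                return allele
        raise ValueError(f"unrecognised allele label {label!r}")

    def format_allele(self, allele: Allele) -> str:
        return "." if allele is Allele.UNKNOWN else allele.value

    @classmethod
    def from_mapping(cls, mapping: dict) -> "Dialect":
        known = {f for f in cls.__dataclass_fields__ if f != "allele_vocab"}
        cols = {k: v for k, v in mapping.items() if k in known}
        return cls(**cols)


DEFAULT_DIALECT = Dialect()


def read_contacts(path: str | Path, dialect: Dialect = DEFAULT_DIALECT
                  ) -> list[ContactRecord]:
    """Read a tab-separated contact list into records.

    The file must have a header naming the dialect's columns; lines starting
    with ``#`` are comments.  Malformed lines raise
    :class:`ContactParseError` naming the offending 1-based line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ContactRecord] = []
    header: list[str] | None = None
    col_idx: dict[str, int] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                wanted = [dialect.chrom_a, dialect.pos_a, dialect.allele_a,
                          dialect.chrom_b, dialect.pos_b, dialect.allele_b]
                missing = [c for c in wanted if c not in header]
                if missing:
                    raise ContactParseError(
                        f"{path}: header is missing column(s) {missing}"
                    )
                col_idx = {c: header.index(c) for c in header}
                continue
            try:
                cell = (fields[col_idx[dialect.cell]]
                        if dialect.cell in col_idx else "")
                rec = ContactRecord(
                    chrom_a=fields[col_idx[dialect.chrom_a]],
                    pos_a=int(fields[col_idx[dialect.pos_a]]),
                    allele_a=dialect.parse_allele(fields[col_idx[dialect.allele_a]]),
                    chrom_b=fields[col_idx[dialect.chrom_b]],
                    pos_b=int(fields[col_idx[dialect.pos_b]]),
                    allele_b=dialect.parse_allele(fields[col_idx[dialect.allele_b]]),
                    cell_id=cell,
                )
            except (ValueError, IndexError) as exc:
                raise ContactParseError(
                    f"{path}:{lineno}: cannot parse contact line: {exc}"
                ) from exc
            records.append(rec)
    if not records:
        logger.warning("no contact records read from %s", path)
    return records


def write_contacts(records: Iterable[ContactRecord], path: str | Path,
                   dialect: Dialect = DEFAULT_DIALECT,
                   header_comment: str | None = None) -> None:
    """Write records as a tab-separated contact list (round-trips with
    :func:`read_contacts`)."""
    path = Path(path)
    cols = [dialect.cell, dialect.chrom_a, dialect.pos_a, dialect.allele_a,
            dialect.chrom_b, dialect.pos_b, dialect.allele_b]
    with path.open("w") as fh:
        if header_comment:
            for cl in header_comment.splitlines():
                fh.write(f"# {cl}\n")
        fh.write("\t".join(str(c) for c in cols) + "\n")
        for r in records:
            fh.write("\t".join([
                r.cell_id,
                r.chrom_a, str(r.pos_a), dialect.format_allele(r.allele_a),
                r.chrom_b, str(r.pos_b), dialect.format_allele(r.allele_b),
            ]) + "\n")


def classify_phasing(c: ContactRecord) -> PhasingClass:
    """Three-way classification of a contact by its allele information."""
    known = (c.allele_a is not Allele.UNKNOWN) + (c.allele_b is not Allele.UNKNOWN)
    if known == 2:
        return PhasingClass.PHASED
    if known == 1:
        return PhasingClass.HALF_PHASED
    return PhasingClass.UNPHASED


def bin_contacts(contacts: Sequence[ContactRecord], resolution: int,
                 phase_filter: frozenset[PhasingClass] | set[PhasingClass]
                 = frozenset({PhasingClass.PHASED}),
                 ignore_phasing: bool = False) -> RecurrenceMap:
    """Bin contacts into an allele-resolved recurrence map.

    Only contacts whose phasing class is in ``phase_filter`` are retained
    (default: phased only — the reconstruction input).  Contacts with an
    unknown-allele leg cannot be placed on a homolog and are rejected unless
    ``ignore_phasing`` is set, which maps every leg onto the maternal label:
    a single-copy interpretation reproducing the behaviour of methods that
    do not discriminate homologs.  Intra-bin contacts (both legs in one
    segment) are dropped from the pair set but counted in
    ``diagnostics["intra_bin_dropped"]``.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    rmap = RecurrenceMap(resolution=resolution)
    n_intra = 0
    n_used = 0
    for c in contacts:
        if not ignore_phasing and classify_phasing(c) not in phase_filter:
            continue
        if ignore_phasing:
            allele_a = allele_b = Allele.MATERNAL
        else:
            allele_a, allele_b = c.allele_a, c.allele_b
            if Allele.UNKNOWN in (allele_a, allele_b):
                raise ValueError(
                    "cannot bin a contact with an unknown-allele leg; "
                    "half-phased/unphased contacts are only ever evaluated "
                    "lazily against candidate alleles"
                )
        sa = segment_for(c.chrom_a, c.pos_a, allele_a, resolution)
        sb = segment_for(c.chrom_b, c.pos_b, allele_b, resolution)
        n_used += 1
        if sa == sb:
            n_intra += 1
            rmap.observe_segment(sa)
            continue
        rmap.add_pair(sa, sb)
    if n_used == 0:
        raise NoPhasedContactsError(
            f"no contacts retained by phase filter {sorted(p.value for p in phase_filter)}"
        )
    rmap.diagnostics["intra_bin_dropped"] = n_intra
    rmap.diagnostics["contacts_used"] = n_used
    logger.info(
        "binned %d contacts at %d bp into %d pairs over %d segments "
        "(%d intra-bin dropped)",
        n_used, resolution, len(rmap.pairs), len(rmap), n_intra,
    )
    return rmap
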