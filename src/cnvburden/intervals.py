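"""Canonical genomic interval types and overlap arithmetic.

All coordinates are internally 0-based, half-open ``[start, end)``; file
dialects that use other conventions (PennCNV's 1-based inclusive) are
converted at the IO boundary only, so length arithmetic is uniform
(``length = end - start``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "CnvCall",
    "RegionSet",
    "GeneModel",
    "ChromStyleError",
    "normalize_chrom",
    "overlap_bp",
    "covered_fraction",
    "exon_hit_fraction",
    "distance_bp",
    "min_distance_to_set",
]


class ChromStyleError(ValueError):
    """Two chromosome labels differ only by the ``chr`` prefix.

    Mixing label styles ("chr1" vs "1") silently yields zero overlap, which
    is almost always a data-preparation bug; it is therefore an error, while
    genuinely different chromosomes compare as zero overlap.
    """


def normalize_chrom(label: str, style: str = "chr") -> str:
    """Normalize a chromosome label to the given style ("chr" or "plain")."""
    if not label:
        raise ValueError("empty chromosome label")
    bare = label[3:] if label.lower().startswith("chr") else label
    if style == "chr":
        return "chr" + bare
    if style == "plain":
        return bare
    raise ValueError(f"unknown chromosome style {style!r}")


def _check_chrom_style(a: str, b: str) -> bool:
    """True if same chromosome; raise if they differ only by prefix style."""
    if a == b:
        return True
    if normalize_chrom(a) == normalize_chrom(b):
        raise ChromStyleError(
            f"chromosome labels {a!r} and {b!r} differ only in 'chr' prefix; "
            "normalize inputs to one style"
        )
    return False


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __repr__(self) -> str:  # compact, bed-like
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class CnvCall:
    """One called copy-number segment for one sample.

    ``cn_state`` 0/1 are deletions, 3 and above duplications; 2 (normal
    diploid) is not a call and is rejected.
    """

    sample_id: str
    interval: GenomicInterval
    cn_state: int
    n_probes: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.cn_state == 2:
            raise ValueError("cn_state 2 is diploid, not a CNV call")
        if self.cn_state < 0:
            raise ValueError(f"cn_state must be >= 0, got {self.cn_state}")
        if self.n_probes < 1:
            raise ValueError(f"n_probes must be >= 1, got {self.n_probes}")

    @property
    def is_deletion(self) -> bool:
        return self.cn_state < 2

    @property
    def is_duplication(self) -> bool:
        return self.cn_state > 2

    @property
    def length(self) -> int:
        return self.interval.length

    def key(self) -> tuple[str, str, int, int]:
        """Exact identity key used by exclusion lists."""
        return (self.sample_id, self.interval.chrom, self.interval.start,
                self.interval.end)


@dataclass
class RegionSet:
    """A named collection of intervals with per-region attributes.

    Attributes commonly carried: ``name`` (syndrome/locus label) and
    ``dosage`` ("del"/"dup") for dosage-typed region lists.
    """

    name: str
    regions: list[tuple[GenomicInterval, dict[str, Any]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        names = [a.get("name") for _, a in self.regions if a.get("name")]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate region names in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.regions]

    def subset(self, predicate) -> "RegionSet":
        """New RegionSet keeping regions whose attribute dict satisfies
        ``predicate``."""
        return RegionSet(
            self.name, [(iv, a) for iv, a in self.regions if predicate(a)]
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure, pLI score and ID-gene flag."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    pli: float | None = None
    is_id_gene: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(
                    f"exon {ex} of {self.gene_id} on wrong chromosome"
                )
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(
                    f"exon {ex} outside gene interval {self.interval}"
                )
        srt = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(srt, srt[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in {self.gene_id}: {a} / {b}"
                )
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValueError(f"pLI must be in [0,1], got {self.pli}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)


# ---------------------------------------------------------------------------
# overlap arithmetic


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals; 0 for different chromosomes."""
    if not _check_chrom_style(a.chrom, b.chrom):
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _union_length(segments: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of [start, end) segments."""
    segs = sorted(segments)
    total = 0
    cur_s = cur_e = None
    for s, e in segs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def covered_fraction(a: GenomicInterval, rs: RegionSet | Sequence) -> float:
    """Fraction of ``a`` covered by the union of a region set.

    Overlapping regions are unioned first so covered bases are not counted
    twice; the result is always in [0, 1].
    """
    if a.length <= 0:
        raise ValueError("zero-length interval has no covered fraction")
    regions = rs.intervals() if isinstance(rs, RegionSet) else list(rs)
    pieces = []
    for iv in regions:
        if not _check_chrom_style(a.chrom, iv.chrom):
            continue
        s, e = max(a.start, iv.start), min(a.end, iv.end)
        if e > s:
            pieces.append((s, e))
    return _union_length(pieces) / a.length


def exon_hit_fraction(deletion: CnvCall, gene: GeneModel) -> float:
    """Fraction of a gene's exons touched (>= 1 bp) by a deletion call.

    An exon counts as deleted if any part of it overlaps the deletion; the
    "50% or more of the exons" classification rule thresholds this value.
    """
    if not deletion.is_deletion:
        raise ValueError(
            f"exon_hit_fraction requires a deletion, got cn={deletion.cn_state}"
        )
    hit = sum(
        1 for ex in gene.exons if overlap_bp(ex, deletion.interval) >= 1
    )
    return hit / gene.n_exons


def distance_bp(a: GenomicInterval, b: GenomicInterval) -> float:
    """Edge-to-edge distance in bp; 0 if overlapping/adjacent-overlapping,
    ``inf`` across chromosomes."""
    if not _check_chrom_style(a.chrom, b.chrom):
        return float("inf")
    if a.start < b.end and b.start < a.end:
        return 0.0
    return float(max(a.start, b.start) - min(a.end, b.end))


def min_distance_to_set(a: GenomicInterval, rs: RegionSet) -> float:
    """Smallest edge-to-edge distance from ``a`` to any region in the set."""
    if len(rs) == 0:
        return float("inf")
    return min(distance_bp(a, iv) for iv in rs.intervals())
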