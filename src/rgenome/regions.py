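"""Genomic region sets and the interval algebra used to combine partitions.

A :class:`RegionSet` is a labelled collection of sorted, merged, half-open
0-based intervals validated against a genome (contig -> length map).  It backs
the concordant/discordant partitions produced by thresholding the concordance
signal as well as externally supplied region sets (low-complexity regions,
high-confidence benchmark regions, ...) read from BED.

The algebra (union, intersection, subtraction, padding, complement, coverage)
is what derived partitions are built from, e.g. subtracting low-complexity
or high-discordance-density windows from a concordance partition, or
intersecting partitions computed from independent cohorts.

Coordinate convention: everything in this module is 0-based half-open (the
BED convention).  VCF-facing modules use 1-based inclusive coordinates and
convert only at this boundary.
"""

from __future__ import annotations

from bisect import bisect_right
from pathlib import Path
from typing import Iterable, Iterator, Mapping

Interval = tuple[int, int]


def _merge(ivs: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping or book-ended intervals."""
    ivs = sorted(ivs)
    out: list[list[int]] = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


class RegionSet:
    """Sorted, merged, genome-validated half-open intervals with a label."""

    __slots__ = ("label", "genome", "_by")

    def __init__(
        self,
        label: str,
        genome: Mapping[str, int],
        intervals: Iterable[tuple[str, int, int]] = (),
    ):
        self.label = label
        self.genome = dict(genome)
        for contig, length in self.genome.items():
            if length < 1:
                raise ValueError(f"contig {contig} has non-positive length {length}")
        by: dict[str, list[Interval]] = {}
        for contig, start, end in intervals:
            if contig not in self.genome:
                raise ValueError(f"interval on unknown contig {contig!r}")
            if not 0 <= start < end <= self.genome[contig]:
                raise ValueError(
                    f"interval {contig}:{start}-{end} outside contig bounds "
                    f"[0, {self.genome[contig]})"
                )
            by.setdefault(contig, []).append((int(start), int(end)))
        self._by: dict[str, list[Interval]] = {c: _merge(v) for c, v in by.items()}

    # -- accessors ---------------------------------------------------------

    def intervals(self, contig: str) -> list[Interval]:
        return list(self._by.get(contig, []))

    def iter_intervals(self) -> Iterator[tuple[str, int, int]]:
        for contig in sorted(self._by):
            for s, e in self._by[contig]:
                yield contig, s, e

    @property
    def total_bases(self) -> int:
        return sum(e - s for ivs in self._by.values() for s, e in ivs)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.genome == other.genome and self._by == other._by

    def __repr__(self) -> str:
        return (
            f"RegionSet({self.label!r}, {len(self)} intervals, "
            f"{self.total_bases} bases)"
        )

    def contains(self, contig: str, pos: int) -> bool:
        """Membership of a single 0-based position."""
        ivs = self._by.get(contig)
        if not ivs:
            return False
        i = bisect_right(ivs, (pos, float("inf"))) - 1
        return i >= 0 and ivs[i][1] > pos

    # -- IO ----------------------------------------------------------------

    @classmethod
    def from_bed(
        cls, path: str | Path, genome: Mapping[str, int], label: str | None = None
    ) -> "RegionSet":
        """Read a 3+ column BED file; track/browser/comment lines tolerated."""
        ivs = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
                ivs.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(label or Path(path).stem, genome, ivs)

    def to_bed(self, path: str | Path, track_name: str | None = None) -> None:
        with open(path, "w") as fh:
            if track_name is not None:
                fh.write(f'track name="{track_name}"\n')
            for contig, s, e in self.iter_intervals():
                fh.write(f"{contig}\t{s}\t{e}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column contig/length file (UCSC chrom.sizes dialect)."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{ln}: expected 'contig<TAB>length'")
            genome[fields[0]] = int(fields[1])
    if not genome:
        raise ValueError(f"{path}: empty genome file")
    return genome


def write_chrom_sizes(genome: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(genome):
            fh.write(f"{contig}\t{genome[contig]}\n")


# -- algebra ---------------------------------------------------------------


def _check_same_genome(a: RegionSet, b: RegionSet) -> None:
    if a.genome != b.genome:
        raise ValueError(
            f"region sets {a.label!r} and {b.label!r} are on different genomes"
        )


def union(a: RegionSet, b: RegionSet, label: str | None = None) -> RegionSet:
    _check_same_genome(a, b)
    ivs = list(a.iter_intervals()) + list(b.iter_intervals())
    return RegionSet(label or f"{a.label}+{b.label}", a.genome, ivs)


def intersect(a: RegionSet, b: RegionSet, label: str | None = None) -> RegionSet:
    _check_same_genome(a, b)
    out = []
    for contig in a.genome:
        for s1, e1 in a.intervals(contig):
            for s2, e2 in b.intervals(contig):
                s, e = max(s1, s2), min(e1, e2)
                if s < e:
                    out.append((contig, s, e))
    return RegionSet(label or f"{a.label}&{b.label}", a.genome, out)


def subtract(a: RegionSet, b: RegionSet, label: str | None = None) -> RegionSet:
    """Set difference a \\ b, re-merged."""
    _check_same_genome(a, b)
    out = []
    for contig in a.genome:
        cuts = b.intervals(contig)
        for s, e in a.intervals(contig):
            cur = s
            for cs, ce in cuts:
                if ce <= cur or cs >= e:
                    continue
                if cs > cur:
                    out.append((contig, cur, cs))
                cur = max(cur, ce)
                if cur >= e:
                    break
            if cur < e:
                out.append((contig, cur, e))
    return RegionSet(label or f"{a.label}-{b.label}", a.genome, out)


def expand(a: RegionSet, pad: int, label: str | None = None) -> RegionSet:
    """Pad every interval by ``pad`` bases on both sides, clip and re-merge."""
    if pad < 0:
        raise ValueError("pad must be non-negative")
    out = [
        (contig, max(0, s - pad), min(a.genome[contig], e + pad))
        for contig, s, e in a.iter_intervals()
    ]
    return RegionSet(label or a.label, a.genome, out)


def complement(a: RegionSet, label: str | None = None) -> RegionSet:
    out = []
    for contig, length in a.genome.items():
        cur = 0
        for s, e in a.intervals(contig):
            if s > cur:
                out.append((contig, cur, s))
            cur = e
        if cur < length:
            out.append((contig, cur, length))
    return RegionSet(label or f"not-{a.label}", a.genome, out)


def coverage_fraction(a: RegionSet, denominator: RegionSet | None = None) -> float:
    """Fraction of ``denominator`` (whole genome when None) covered by ``a``."""
    if denominator is None:
        denom_bases = sum(a.genome.values())
        covered = a.total_bases
    else:
        _check_same_genome(a, denominator)
        denom_bases = denominator.total_bases
        if denom_bases == 0:
            raise ValueError("empty denominator region set")
        covered = intersect(a, denominator).total_bases
    return covered / denom_bases
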