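"""Detection of windows with high density of interrupted discordant stretches.

Cohort-level score points are reduced to a three-way label: majority
discordant (s < 0), majority concordant (s > 0), or neutral (s = 0, which
neither breaks nor extends a stretch).  A *discordant stretch* is a maximal
run of discordant positions separated from the next by at least one
concordant position.  Around every variant position a window reaching
``flank`` bases up- and downstream (default 1000) is scanned; windows
containing at least ``min_count`` (default 10) such stretches -- counting a
stretch as soon as one of its positions lies inside the window -- are
emitted and merged.  The resulting "HD" regions flag territory where
discordance keeps flickering on and off, a hallmark of systematic calling
artefacts, and are typically subtracted from the concordant partition.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping

from .regions import RegionSet
from .scoring import ScorePoint


@dataclass(frozen=True)
class HdParams:
    flank: int = 1000
    min_count: int = 10

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValueError("flank must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def _contig_runs(pts: list[ScorePoint]) -> tuple[list[int], list[int]]:
    """Positions of discordant points and their stretch (run) ids.

    Run ids increase along the contig; neutral points are transparent.
    """
    d_pos: list[int] = []
    d_run: list[int] = []
    run = -1
    last_was_disc = False
    for p in pts:
        if p.s is None:
            raise ValueError(f"unscored point at {p.contig}:{p.pos}")
        if p.s < 0:
            if not last_was_disc:
                run += 1
            last_was_disc = True
            d_pos.append(p.pos)
            d_run.append(run)
        elif p.s > 0:
            last_was_disc = False
        # s == 0: neither breaks nor extends the current stretch
    return d_pos, d_run


def _group(points: Iterable[ScorePoint]) -> dict[str, list[ScorePoint]]:
    per: dict[str, list[ScorePoint]] = {}
    for p in points:
        per.setdefault(p.contig, []).append(p)
    for pts in per.values():
        pts.sort(key=lambda p: p.pos)
    return per


def discordant_stretches(
    points: Iterable[ScorePoint], contig: str, interval: tuple[int, int]
) -> int:
    """Number of discordant stretches with >= 1 position inside the closed
    1-based ``interval`` on ``contig``."""
    pts = _group(points).get(contig, [])
    d_pos, d_run = _contig_runs(pts)
    lo, hi = interval
    i = bisect_left(d_pos, lo)
    j = bisect_right(d_pos, hi) - 1
    if j < i:
        return 0
    return d_run[j] - d_run[i] + 1


def hd_regions(
    points: Iterable[ScorePoint],
    params: HdParams | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> RegionSet:
    """Merged windows around variant positions holding >= min_count stretches."""
    params = params or HdParams()
    if contig_lengths is None:
        raise ValueError("contig_lengths is required")
    out: list[tuple[str, int, int]] = []
    for contig, pts in _group(points).items():
        if contig not in contig_lengths:
            raise ValueError(f"score point on unknown contig {contig!r}")
        length = contig_lengths[contig]
        d_pos, d_run = _contig_runs(pts)
        for p in pts:
            lo, hi = p.pos - params.flank, p.pos + params.flank
            i = bisect_left(d_pos, lo)
            j = bisect_right(d_pos, hi) - 1
            count = 0 if j < i else d_run[j] - d_run[i] + 1
            if count >= params.min_count:
                out.append((contig, max(1, lo) - 1, min(length, hi)))
    return RegionSet("hd", contig_lengths, out)
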