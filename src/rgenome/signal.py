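"""Genome-wide concordance signal: linear-decay interpolation + partition.

Scores exist only at polymorphic positions; every other base receives an
interpolated value so the whole genome can be partitioned.  Each scored
position radiates its score into a window of ``2x + 1`` bases centred on it
(default ``x = 1000``), decaying linearly to 0 -- the neutral state -- at
distance ``x``.  Between two consecutive scored positions closer than ``x``
the signal is the direct linear segment between their scores.  For wider
gaps each side decays towards 0; when the two decay ramps overlap
(``x < gap < 2x``) their contributions superpose, which keeps the signal
continuous, bounded by 1 in magnitude and exact at every data point.
Contig edges clip the decay; contigs without any data are neutral (0).

The signal is stored as per-contig piecewise-linear breakpoints (all at
integer coordinates), not as per-base arrays.  Thresholding the signal with
``t_c`` (concordant: signal > t_c) and ``t_d`` (discordant: signal <= t_d)
yields two region sets; with ``t_c = t_d`` they tile the genome completely,
the neutral no-data state falling on the discordant -- conservative -- side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .regions import RegionSet
from .scoring import ScorePoint


@dataclass(frozen=True)
class InterpolationParams:
    """``x``: half-width (bases) of the radiation window ``2x + 1``."""

    x: int = 1000

    def __post_init__(self) -> None:
        if self.x < 1:
            raise ValueError("window half-width x must be >= 1")


@dataclass(frozen=True)
class PartitionThresholds:
    """Concordant (> t_c) and discordant (<= t_d) cutoffs; t_d <= t_c."""

    t_c: float = 0.0
    t_d: float = 0.0

    def __post_init__(self) -> None:
        if self.t_d > self.t_c:
            raise ValueError("t_d must not exceed t_c")


class ScoreSignal:
    """Continuous piecewise-linear concordance track per contig."""

    def __init__(
        self,
        breakpoints: Mapping[str, tuple[Sequence[float], Sequence[float]]],
        contig_lengths: Mapping[str, int],
    ):
        self.contig_lengths = dict(contig_lengths)
        self.breakpoints: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig, (xs, ys) in breakpoints.items():
            if contig not in self.contig_lengths:
                raise ValueError(f"breakpoints on unknown contig {contig!r}")
            xa = np.asarray(xs, dtype=float)
            ya = np.asarray(ys, dtype=float)
            if xa.size != ya.size:
                raise ValueError("breakpoint coordinate/score length mismatch")
            if xa.size and (np.any(np.diff(xa) <= 0)):
                raise ValueError(f"breakpoints on {contig} not strictly increasing")
            if xa.size and (xa[0] < 1 or xa[-1] > self.contig_lengths[contig]):
                raise ValueError(f"breakpoints outside contig {contig} bounds")
            self.breakpoints[contig] = (xa, ya)

    def evaluate(self, contig: str, pos: int) -> float:
        """Signal value at a 1-based position; 0 beyond all breakpoints."""
        return float(self.evaluate_many(contig, np.asarray([pos]))[0])

    def evaluate_many(self, contig: str, positions: Sequence[int]) -> np.ndarray:
        if contig not in self.contig_lengths:
            raise ValueError(f"unknown contig {contig!r}")
        pos = np.asarray(positions, dtype=float)
        xs, ys = self.breakpoints.get(contig, (None, None))
        if xs is None or xs.size == 0:
            return np.zeros(pos.shape)
        return np.interp(pos, xs, ys, left=0.0, right=0.0)

    # -- export ------------------------------------------------------------

    def write_breakpoints(self, path: str | Path, provenance: str | None = None) -> None:
        """Lossless breakpoint TSV: contig, 1-based coordinate, score."""
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            fh.write("contig\tpos\tscore\n")
            for contig in sorted(self.breakpoints):
                xs, ys = self.breakpoints[contig]
                for x, y in zip(xs, ys):
                    fh.write(f"{contig}\t{int(x)}\t{y:.9g}\n")

    def to_bedgraph(self, path: str | Path, step: int = 100) -> None:
        """Stepwise-constant BedGraph approximation sampled every ``step`` bases."""
        if step < 1:
            raise ValueError("step must be >= 1")
        with open(path, "w") as fh:
            fh.write('track type=bedGraph name="concordance_signal"\n')
            for contig in sorted(self.contig_lengths):
                length = self.contig_lengths[contig]
                starts = np.arange(1, length + 1, step)
                vals = self.evaluate_many(contig, starts)
                for s, v in zip(starts, vals):
                    fh.write(f"{contig}\t{s - 1}\t{min(s - 1 + step, length)}\t{v:.6f}\n")


def interpolate(
    points: Iterable[ScorePoint],
    params: InterpolationParams | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> ScoreSignal:
    """Build the genome-wide piecewise-linear signal from scored positions."""
    params = params or InterpolationParams()
    if contig_lengths is None:
        raise ValueError("contig_lengths is required")
    x = params.x
    per_contig: dict[str, list[ScorePoint]] = {}
    for p in points:
        if p.s is None:
            raise ValueError(f"unscored point at {p.contig}:{p.pos}")
        if p.contig not in contig_lengths:
            raise ValueError(f"score point on unknown contig {p.contig!r}")
        if not 1 <= p.pos <= contig_lengths[p.contig]:
            raise ValueError(
                f"score point {p.contig}:{p.pos} beyond contig length "
                f"{contig_lengths[p.contig]}"
            )
        per_contig.setdefault(p.contig, []).append(p)

    breakpoints = {}
    for contig, pts in per_contig.items():
        pts.sort(key=lambda p: p.pos)
        length = contig_lengths[contig]
        xs: list[float] = []
        ys: list[float] = []

        def push(c: float, v: float) -> None:
            if xs and xs[-1] == c:
                return  # coincident breakpoint (clipped edge / gap == 2x)
            xs.append(c)
            ys.append(v)

        p0, s0 = pts[0].pos, pts[0].s
        if p0 - x >= 1:
            push(p0 - x, 0.0)
        else:
            push(1, s0 * (1 - (p0 - 1) / x))
        push(p0, s0)
        for prev, cur in zip(pts, pts[1:]):
            pa, sa, pb, sb = prev.pos, prev.s, cur.pos, cur.s
            if pb == pa:
                raise ValueError(f"duplicate score point at {contig}:{pa}")
            gap = pb - pa
            if gap <= x:
                pass  # direct segment pa -> pb
            elif gap >= 2 * x:
                push(pa + x, 0.0)
                push(pb - x, 0.0)
            else:
                # overlapping decay ramps: superpose both contributions
                def ramp_sum(t: float) -> float:
                    return sa * (1 - (t - pa) / x) + sb * (1 - (pb - t) / x)

                push(pb - x, ramp_sum(pb - x))
                push(pa + x, ramp_sum(pa + x))
            push(pb, sb)
        pn, sn = pts[-1].pos, pts[-1].s
        if pn + x <= length:
            push(pn + x, 0.0)
        else:
            push(length, sn * (1 - (length - pn) / x))
        breakpoints[contig] = (xs, ys)
    return ScoreSignal(breakpoints, contig_lengths)


def evaluate_signal(signal: ScoreSignal, contig: str, pos: int) -> float:
    """Exact piecewise-linear evaluation at one position."""
    return signal.evaluate(contig, pos)


# -- thresholding ----------------------------------------------------------


def _segment_bases(
    x0: int, y0: float, x1: int, y1: float, op: str, thr: float
) -> list[tuple[int, int]]:
    """1-based inclusive integer runs in [x0, x1] where the linear value
    satisfies ``> thr`` (op='gt') or ``<= thr`` (op='le')."""

    def val(b: int) -> float:
        # endpoints must return the breakpoint scores exactly, so that a
        # junction base shared by two segments is classified consistently
        if b == x0:
            return y0
        if b == x1:
            return y1
        return y0 + (b - x0) * (y1 - y0) / (x1 - x0)

    def ok(v: float) -> bool:
        return v > thr if op == "gt" else v <= thr

    if y0 == y1:
        return [(x0, x1)] if ok(y0) else []
    increasing = y1 > y0
    # on a monotone segment the satisfying bases form a suffix or a prefix
    suffix = (op == "gt") == increasing
    tstar = x0 + (thr - y0) * (x1 - x0) / (y1 - y0)
    b = min(max(int(math.floor(tstar)), x0), x1)
    if suffix:
        while b > x0 and ok(val(b - 1)):
            b -= 1
        while b <= x1 and not ok(val(b)):
            b += 1
        return [(b, x1)] if b <= x1 else []
    else:
        while b < x1 and ok(val(b + 1)):
            b += 1
        while b >= x0 and not ok(val(b)):
            b -= 1
        return [(x0, b)] if b >= x0 else []


def _merge_runs(runs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    runs.sort()
    out: list[list[int]] = []
    for lo, hi in runs:
        if out and lo <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [(lo, hi) for lo, hi in out]


def partition(
    signal: ScoreSignal, thresholds: PartitionThresholds | None = None
) -> tuple[RegionSet, RegionSet]:
    """Threshold the signal into (concordant, discordant) region sets.

    Every base with signal strictly above ``t_c`` is concordant; every base
    at or below ``t_d`` is discordant.  Crossing coordinates are derived
    analytically from the segment endpoints.  With ``t_c = t_d`` the two
    sets tile every contig with empty intersection.
    """
    thresholds = thresholds or PartitionThresholds()
    conc: list[tuple[str, int, int]] = []
    disc: list[tuple[str, int, int]] = []
    for contig in sorted(signal.contig_lengths):
        length = signal.contig_lengths[contig]
        xs, ys = signal.breakpoints.get(contig, (np.empty(0), np.empty(0)))
        pts = [(int(x), float(y)) for x, y in zip(xs, ys)]
        if not pts or pts[0][0] > 1:
            pts.insert(0, (1, 0.0))
        if pts[-1][0] < length:
            pts.append((length, 0.0))

        for op, thr, sink in (("gt", thresholds.t_c, conc),
                              ("le", thresholds.t_d, disc)):
            runs: list[tuple[int, int]] = []
            if len(pts) == 1:
                b, v = pts[0]
                if (v > thr) if op == "gt" else (v <= thr):
                    runs.append((b, b))
            for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
                runs.extend(_segment_bases(x0, y0, x1, y1, op, thr))
            for lo, hi in _merge_runs(runs):
                sink.append((contig, lo - 1, hi))
    genome = signal.contig_lengths
    return (
        RegionSet("concordant", genome, conc),
        RegionSet("discordant", genome, disc),
    )
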