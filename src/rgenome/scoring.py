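"""Cohort-level concordance scoring of polymorphic positions.

Per-sample join decisions are aggregated across a cohort: at every genomic
position that carries a matched site in at least one sample, ``n_c`` and
``n_d`` count the samples whose decision there was concordant respectively
discordant.  The concordance score is the weighted, normalized balance

    s = (n_c * w_c + n_d * w_d) / (n_c * w_c + |n_d * w_d|),   s in [-1, 1]

with configurable weights ``w_c > 0`` and ``w_d < 0`` (defaults 1 and -3;
the asymmetry penalises discordance, trading sensitivity for a low false
discovery rate of the derived concordant regions).  ``s = 1`` iff no sample
was discordant, ``s = -1`` iff none was concordant, and with the default
weights ``s = 0`` exactly when ``n_c = 3 * n_d`` -- the "neutral" state of
contradictory evidence.  SNV and INDEL decisions feed one common score
track.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from .calls import Decision, JoinedDecision


@dataclass(frozen=True)
class ScoreWeights:
    """Concordant/discordant decision weights; ``w_c > 0``, ``w_d < 0``."""

    w_c: float = 1.0
    w_d: float = -3.0

    def __post_init__(self) -> None:
        if not self.w_c > 0:
            raise ValueError("w_c must be positive")
        if not self.w_d < 0:
            raise ValueError("w_d must be negative")


@dataclass(frozen=True)
class ScorePoint:
    """Counts and score of one polymorphic position; ``s`` may be unset."""

    contig: str
    pos: int  # 1-based
    n_c: int
    n_d: int
    s: float | None = None


def concordance_score(n_c: int, n_d: int, w: ScoreWeights | None = None) -> float:
    """Evaluate the weighted concordance balance for one position."""
    w = w or ScoreWeights()
    if n_c < 0 or n_d < 0:
        raise ValueError("counts must be non-negative")
    if n_c + n_d == 0:
        raise ValueError("concordance score undefined for n_c = n_d = 0")
    num = n_c * w.w_c + n_d * w.w_d
    den = n_c * w.w_c + abs(n_d * w.w_d)
    return num / den


def aggregate_counts(
    samples: Iterable[Iterable[JoinedDecision]],
) -> list[ScorePoint]:
    """Tally per-position concordant/discordant decisions across samples.

    One :class:`ScorePoint` (score unset) per distinct (contig, pos) seen in
    any sample; samples without a site there contribute nothing.  Two
    decisions of one sample may share a position only when they are an SNV
    and an INDEL anchor; a true duplicate raises.
    """
    counts: dict[tuple[str, int], list[int]] = {}
    n_samples = 0
    for stream in samples:
        n_samples += 1
        seen: set[tuple[str, int, str]] = set()
        for d in stream:
            key = (d.contig, d.pos, d.vclass.value)
            if key in seen:
                raise ValueError(
                    f"sample {d.sample_id}: duplicate {d.vclass.value} "
                    f"decision at {d.contig}:{d.pos}"
                )
            seen.add(key)
            c = counts.setdefault((d.contig, d.pos), [0, 0])
            if d.decision is Decision.CONCORDANT:
                c[0] += 1
            else:
                c[1] += 1
    if n_samples == 0:
        raise ValueError("aggregate_counts requires at least one sample")
    return [
        ScorePoint(contig, pos, n_c, n_d)
        for (contig, pos), (n_c, n_d) in sorted(counts.items())
    ]


def score_points(
    points: Iterable[ScorePoint], w: ScoreWeights | None = None
) -> list[ScorePoint]:
    """Return the points with ``s`` evaluated under the given weights."""
    w = w or ScoreWeights()
    return [replace(p, s=concordance_score(p.n_c, p.n_d, w)) for p in points]


# -- serialization ---------------------------------------------------------

_HEADER = ["contig", "pos", "n_c", "n_d", "s"]


def write_scores(
    points: Iterable[ScorePoint], path: str | Path, provenance: str | None = None
) -> None:
    """Tab-separated score track: contig, 1-based pos, n_c, n_d, s (6 dp)."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("\t".join(_HEADER) + "\n")
        for p in points:
            s = "" if p.s is None else f"{p.s:.6f}"
            fh.write(f"{p.contig}\t{p.pos}\t{p.n_c}\t{p.n_d}\t{s}\n")


def read_scores(path: str | Path) -> list[ScorePoint]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("contig\t"):
                continue
            contig, pos, n_c, n_d, s = line.split("\t")
            out.append(ScorePoint(contig, int(pos), int(n_c), int(n_d),
                                  float(s) if s else None))
    return out


def scores_to_bedgraph(points: Iterable[ScorePoint], path: str | Path) -> None:
    """Export raw per-position scores as BedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="concordance_score"\n')
        for p in points:
            if p.s is None:
                raise ValueError("scores must be evaluated before export")
            fh.write(f"{p.contig}\t{p.pos - 1}\t{p.pos}\t{p.s:.6f}\n")
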