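"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: per-base arrays, pairwise scans and
direct formula transcription, sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def render_signal_per_base(
    positions: list[int], scores: list[float], x: int, length: int
) -> np.ndarray:
    """Materialize the linear-decay concordance signal at every base.

    Index i holds the value at 1-based position i + 1.  Consecutive points
    closer than the window half-width x are joined by a direct segment;
    wider gaps are filled by the superposition of the two clipped linear
    ramps radiating from the flanking points; contig edges decay to zero.
    """
    arr = np.zeros(length)
    if not positions:
        return arr
    b = np.arange(1, length + 1, dtype=float)
    p = np.asarray(positions, dtype=float)
    s = np.asarray(scores, dtype=float)

    mask = b <= p[0]
    arr[mask] = s[0] * np.clip(1 - (p[0] - b[mask]) / x, 0, None)
    mask = b >= p[-1]
    arr[mask] = s[-1] * np.clip(1 - (b[mask] - p[-1]) / x, 0, None)
    for (pa, sa), (pb, sb) in zip(zip(p, s), zip(p[1:], s[1:])):
        mask = (b >= pa) & (b <= pb)
        bb = b[mask]
        if pb - pa <= x:
            arr[mask] = sa + (bb - pa) * (sb - sa) / (pb - pa)
        else:
            arr[mask] = sa * np.clip(1 - (bb - pa) / x, 0, None) + \
                sb * np.clip(1 - (pb - bb) / x, 0, None)
    return arr


def partition_per_base(
    arr: np.ndarray, t_c: float, t_d: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean per-base masks (concordant, discordant)."""
    return arr > t_c, arr <= t_d


def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """0-based half-open intervals of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return [(int(a), int(b)) for a, b in zip(idx[::2], idx[1::2])]


def regionset_to_mask(rs, contig: str, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in rs.intervals(contig):
        mask[s:e] = True
    return mask


def indel_pair_matches(
    pos_a: int, ref_a: str, pos_b: int, ref_b: str, l: int
) -> bool:
    """Brute-force extended-footprint overlap check for one INDEL pair."""
    a = (pos_a - l, pos_a + max(len(ref_a), 1) - 1 + l)
    b = (pos_b - l, pos_b + max(len(ref_b), 1) - 1 + l)
    return max(a[0], b[0]) <= min(a[1], b[1])


def naive_stretch_count(
    labeled: list[tuple[int, int]], lo: int, hi: int
) -> int:
    """Count discordant stretches touching [lo, hi] on one contig.

    ``labeled``: sorted (pos, label) with label -1 discordant, +1 concordant,
    0 neutral.  A stretch is a maximal run of -1 positions with no +1
    position in between (0s are transparent); it counts when at least one
    of its positions lies inside the closed window.
    """
    stretches: list[list[int]] = []
    current: list[int] | None = None
    for pos, lab in labeled:
        if lab == -1:
            if current is None:
                current = []
                stretches.append(current)
            current.append(pos)
        elif lab == 1:
            current = None
    return sum(1 for st in stretches if any(lo <= p <= hi for p in st))


def naive_hd_windows(
    labeled: list[tuple[int, int]], flank: int, min_count: int, length: int
) -> list[tuple[int, int]]:
    """O(positions x window) scan; 0-based half-open merged windows."""
    hits = []
    for pos, _ in labeled:
        lo, hi = pos - flank, pos + flank
        if naive_stretch_count(labeled, lo, hi) >= min_count:
            hits.append((max(1, lo) - 1, min(length, hi)))
    merged: list[list[int]] = []
    for s, e in sorted(hits):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
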