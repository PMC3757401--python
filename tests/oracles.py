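"""Independent brute-force reference implementations used only by tests.

Everything here works by direct enumeration on small inputs and deliberately
shares no code with the package internals it checks.
"""

from typing import Dict, List, Tuple

import numpy as np


def brute_half_sites(seq: str, meth_by_pos: Dict[int, float], threshold: float = 0.5) -> List[int]:
    """Positions of purine-methylC half-sites on both strands, by direct scan.

    ``meth_by_pos`` maps the plus-strand C position of each CpG to its
    methylation value. Plus-strand site at p needs seq[p-1] in AG; the
    minus-strand C sits at p+1 and needs a minus-strand purine before it,
    i.e. seq[p+2] in CT.
    """
    sites = []
    for p in range(len(seq) - 1):
        if seq[p] != "C" or seq[p + 1] != "G":
            continue
        if meth_by_pos.get(p, 0.0) < threshold:
            continue
        if p > 0 and seq[p - 1] in "AG":
            sites.append(p)
        if p + 2 < len(seq) and seq[p + 2] in "CT":
            sites.append(p + 1)
    return sorted(sites)


def brute_digest(
    seq_len: int,
    sites: List[int],
    min_spacing: int = 40,
    max_spacing: int = 3000,
) -> List[Tuple[int, int]]:
    """Fragments from midpoint cuts between eligible consecutive site pairs."""
    cuts = sorted(
        {
            (a + b) // 2
            for a, b in zip(sites, sites[1:])
            if min_spacing <= b - a <= max_spacing
        }
    )
    cuts = [c for c in cuts if 0 < c < seq_len]
    edges = [0] + cuts + [seq_len]
    return list(zip(edges[:-1], edges[1:]))


def brute_coverage_fraction(
    start: int, end: int, fragments: List[Tuple[int, int]]
) -> float:
    """Per-bp covered fraction of [start, end)."""
    covered = 0
    for p in range(start, end):
        if any(s <= p < e for s, e in fragments):
            covered += 1
    return covered / (end - start)


def brute_window_cpg_counts(seq: str, window: int) -> List[int]:
    """CpG occurrences per fixed window by substring counting."""
    counts = []
    for w0 in range(0, len(seq), window):
        chunk = seq[w0 : w0 + window + 1]  # +1 catches a CpG spanning the boundary C
        n = sum(
            1
            for i in range(min(window, len(chunk) - 1))
            if chunk[i] == "C" and chunk[i + 1] == "G"
        )
        counts.append(n)
    return counts


def textbook_pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def brute_interval_mean(
    window_starts, width: int, values, start: int, end: int
) -> float:
    """Per-bp average of a window track over [start, end)."""
    total = 0.0
    n = 0
    lookup = {int(s): float(v) for s, v in zip(window_starts, values)}
    for p in range(start, end):
        w0 = (p // width) * width
        if w0 in lookup:
            total += lookup[w0]
            n += 1
    return total / n


def brute_moving_average(values, window: int) -> List[float]:
    """Centered moving average with shrinking edge windows (pandas convention:
    for even windows the extra element is taken from the trailing side)."""
    n = len(values)
    out = []
    half_lo = (window - 1) // 2
    half_hi = window // 2
    for i in range(n):
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi + 1)
        out.append(float(np.mean(values[lo:hi])))
    return out


def brute_jaccard(
    a: List[Tuple[str, int, int]], b: List[Tuple[str, int, int]]
) -> float:
    """Base-level Jaccard by explicit position sets (small inputs only)."""
    sa = {(c, p) for c, s, e in a for p in range(s, e)}
    sb = {(c, p) for c, s, e in b for p in range(s, e)}
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
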