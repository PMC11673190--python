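"""LTR pair detection, insertion-age divergence profiles, RT motif scan.

A retroelement that inserted recently carries two identical long terminal
repeats; substitutions accumulate independently in the two copies
afterwards, so their K2P distance dates the insertion.  This module finds
the repeat pair with an ungapped seed-and-extend search, profiles the
divergence distribution of a population of elements, and calls the
population "active" when enough pairs are near zero divergence.

The detector is deliberately simple — exact k-mer seeds between the two
element termini, ungapped X-drop extension, identity and length filters —
and makes no use of target-site duplications or TG...CA box motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import k2p_distance
from .exceptions import SaturationError, UndefinedDistanceError

__all__ = [
    "LTRPairRecord",
    "MotifHit",
    "detect_ltr_pair",
    "divergence_profile",
    "infer_activity",
    "scan_rt_motif",
]


@dataclass
class LTRPairRecord:
    """One element's detected (or ground-truth) LTR pair.

    Intervals are 0-based half-open; ``k2p`` is None when the pair is
    saturated (``saturated=True``).
    """

    element_id: str
    element_length: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    identity: float
    k2p: float | None
    P: float = 0.0
    Q: float = 0.0
    saturated: bool = False

    @property
    def ltr_length(self) -> int:
        return self.ltr5[1] - self.ltr5[0]


def _extend(
    seq: str,
    i0: int,
    i1: int,
    j0: int,
    j1: int,
    left_floor: int,
    right_ceil: int,
    match: int = 1,
    mismatch: int = -2,
    x_drop: int = 20,
) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension of a seed on one diagonal.

    ``[i0,i1)`` vs ``[j0,j1)`` are the seed copies; extension keeps the two
    windows in lockstep, stops after the running score falls ``x_drop``
    below its maximum, and trims back to the best-scoring endpoints.
    """
    # right extension
    score = best = 0
    ext_r = 0
    k = 0
    while i1 + k < j0 and j1 + k < right_ceil:
        score += match if seq[i1 + k] == seq[j1 + k] else mismatch
        k += 1
        if score > best:
            best, ext_r = score, k
        if best - score > x_drop:
            break
    # left extension
    score = best = 0
    ext_l = 0
    k = 0
    while i0 - (k + 1) > left_floor and j0 - (k + 1) > i1:
        k += 1
        score += match if seq[i0 - k] == seq[j0 - k] else mismatch
        if score > best:
            best, ext_l = score, k
        if best - score > x_drop:
            break
    return i0 - ext_l, i1 + ext_r, j0 - ext_l, j1 + ext_r


def detect_ltr_pair(
    element: str,
    element_id: str = "element",
    min_len: int = 100,
    max_len: int = 1000,
    seed_k: int = 20,
    min_identity: float = 0.80,
    window_slack: int = 200,
) -> LTRPairRecord | None:
    """Find the 5'/3' terminal-repeat pair of one element, or None.

    Exact ``seed_k``-mers shared between a 5' window (first
    ``max_len + window_slack`` nt) and a 3' window (last
    ``max_len + window_slack`` nt) seed ungapped extensions; the longest
    extension with length in ``[min_len, max_len]`` and identity >=
    ``min_identity`` wins (ties: higher identity, then leftmost).  K2P
    divergence is computed on the reported pair.
    """
    element = element.upper()
    n = len(element)
    if n <= 2 * min_len:
        return None
    win = min(max_len + window_slack, n // 2)
    suffix_start = n - win
    # index 5' window k-mers
    kmers: dict[str, list[int]] = {}
    for i in range(0, win - seed_k + 1):
        kmers.setdefault(element[i : i + seed_k], []).append(i)
    # one seed per diagonal (same-diagonal seeds extend identically)
    diagonals: dict[int, tuple[int, int]] = {}
    for j in range(suffix_start, n - seed_k + 1):
        hits = kmers.get(element[j : j + seed_k])
        if not hits:
            continue
        for i in hits:
            diag = j - i
            if diag not in diagonals:
                diagonals[diag] = (i, j)
    best: tuple[tuple[int, float, int], LTRPairRecord] | None = None
    for i, j in diagonals.values():
        a0, a1, b0, b1 = _extend(
            element, i, i + seed_k, j, j + seed_k, left_floor=-1, right_ceil=n
        )
        length = a1 - a0
        if not (min_len <= length <= max_len):
            continue
        seg5, seg3 = element[a0:a1], element[b0:b1]
        matches = sum(x == y for x, y in zip(seg5, seg3))
        identity = matches / length
        if identity < min_identity:
            continue
        try:
            d, P, Q = k2p_distance(seg5, seg3)
            rec = LTRPairRecord(
                element_id, n, (a0, a1), (b0, b1), identity, d, P, Q, False
            )
        except SaturationError:
            rec = LTRPairRecord(
                element_id, n, (a0, a1), (b0, b1), identity, None, 0.0, 0.0, True
            )
        except UndefinedDistanceError:
            continue
        key = (length, identity, -a0)
        if best is None or key > best[0]:
            best = (key, rec)
    return best[1] if best else None


def detect_all(
    elements, **kwargs
) -> list[LTRPairRecord]:
    """Run :func:`detect_ltr_pair` over an AlignmentSet of elements."""
    out = []
    for ident, seq in elements.records:
        rec = detect_ltr_pair(seq, element_id=ident, **kwargs)
        if rec is not None:
            out.append(rec)
    return out


def divergence_profile(
    records: list[LTRPairRecord],
    bin_width: float = 0.01,
    recent_cutoff: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Histogram + summary of K2P divergences across elements.

    Saturated pairs are excluded from the histogram and counted in
    ``n_saturated``.  The summary reports n, mean, median and the fraction
    of pairs below ``recent_cutoff``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    defined = [r.k2p for r in records if not r.saturated and r.k2p is not None]
    n_sat = sum(1 for r in records if r.saturated)
    if not defined:
        raise UndefinedDistanceError("no unsaturated LTR pairs to profile")
    vals = np.array(defined)
    n_bins = int(np.floor(vals.max() / bin_width)) + 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    hist = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    summary = {
        "n": int(vals.size),
        "n_saturated": int(n_sat),
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        "recent_cutoff": float(recent_cutoff),
        "recent_fraction": float((vals < recent_cutoff).mean()),
    }
    return hist, summary


def infer_activity(
    records: list[LTRPairRecord],
    recent_cutoff: float = 0.01,
    min_recent_fraction: float = 0.05,
) -> dict:
    """Call a population 'active' when enough LTR pairs are near-identical.

    The call is 'active' iff the fraction of unsaturated pairs with
    k2p < ``recent_cutoff`` is >= ``min_recent_fraction``; the fraction and
    both cutoffs are always reported alongside the call.
    """
    _, summary = divergence_profile(records, recent_cutoff=recent_cutoff)
    frac = summary["recent_fraction"]
    return {
        "call": "active" if frac >= min_recent_fraction else "quiescent",
        "recent_fraction": frac,
        "recent_cutoff": recent_cutoff,
        "min_recent_fraction": min_recent_fraction,
        "n": summary["n"],
        "n_saturated": summary["n_saturated"],
    }


@dataclass
class MotifHit:
    """One occurrence of the RT catalytic-motif pattern (ends in DD)."""

    sequence_id: str
    motif: str
    position: int  # 0-based start of the 4-residue motif
    motif_class: str  # canonical | variant | other-XADD


def scan_rt_motif(protein: str, sequence_id: str = "protein") -> list[MotifHit]:
    """Scan for the RT catalytic motif YxDD and its xADD variants.

    Canonical RT enzymes carry YxDD at the polymerase active site; in some
    lineages the tyrosine is replaced, giving IADD/VADD/LADD.  Hits are
    4-residue windows ending in DD that are either Y-x-D-D (canonical) or
    X-A-D-D (variant when X is I/V/L, else other-XADD).  Overlapping hits
    are all reported.
    """
    protein = protein.upper()
    hits: list[MotifHit] = []
    for i in range(len(protein) - 3):
        window = protein[i : i + 4]
        if window[2:] != "DD":
            continue
        first, second = window[0], window[1]
        if first == "Y":
            cls = "canonical"
        elif second == "A" and first in "IVL":
            cls = "variant"
        elif second == "A" and first not in "-X":
            cls = "other-XADD"
        else:
            continue
        hits.append(MotifHit(sequence_id, window, i, cls))
    return hits
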