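"""Pairwise evolutionary distances.

Three models:

* ``p`` — uncorrected proportion of mismatched sites (pairwise deletion of
  gap/ambiguity columns);
* ``poisson`` — Poisson multiple-hit correction d = -ln(1 - p) for proteins;
* ``k2p`` — Kimura two-parameter distance for nucleotides,
  d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q), with P and Q the transition
  and transversion mismatch proportions over comparable sites.

Ambiguity codes (X for proteins, N for nucleotides) and gaps are treated as
missing and excluded pairwise, never by whole-column deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import SaturationError, UndefinedDistanceError
from .io import AlignmentSet, missing_chars

__all__ = [
    "DistanceMatrix",
    "p_distance",
    "poisson_distance",
    "k2p_distance",
    "distance_matrix",
]

# purines A,G -> 0,1; pyrimidines C,T -> 2,3; anything else is missing
_NT_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with identifiers.

    ``pairwise_sites`` counts the sites actually compared for each pair
    (pairwise deletion); ``undefined_pairs`` lists (id1, id2, reason) for
    pairs whose distance could not be computed — those entries hold NaN in
    ``values`` and are never silently zeroed.
    """

    ids: list[str]
    values: np.ndarray
    model: str = "p"
    pairwise_sites: np.ndarray | None = None
    undefined_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
            atol=1e-12,
        ):
            raise ValueError("matrix not symmetric within 1e-12")
        if not np.all(np.diag(self.values) == 0):
            raise ValueError("matrix diagonal must be zero")
        if np.any(self.values[finite] < 0):
            raise ValueError("distances must be nonnegative")

    def __len__(self) -> int:
        return len(self.ids)

    def pair(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def p_distance(a: str, b: str, alphabet: str = "protein") -> tuple[float, int]:
    """Uncorrected p-distance with pairwise deletion.

    Returns ``(p, sites)`` where *sites* counts positions at which neither
    sequence shows a gap or ambiguity character.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be equal length (aligned)")
    miss = missing_chars(alphabet)
    sites = 0
    mism = 0
    for x, y in zip(a, b):
        if x in miss or y in miss:
            continue
        sites += 1
        if x != y:
            mism += 1
    if sites == 0:
        raise UndefinedDistanceError("no comparable sites after pairwise deletion")
    return mism / sites, sites


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p) for a mismatch proportion."""
    if not 0.0 <= p < 1.0:
        raise UndefinedDistanceError(f"Poisson correction undefined for p = {p}")
    return -math.log1p(-p)


def k2p_distance(a: str, b: str) -> tuple[float, float, float]:
    """Kimura two-parameter distance between two aligned nucleotide strings.

    Returns ``(d, P, Q)``: the corrected distance plus the transition (P)
    and transversion (Q) mismatch proportions.  Raises
    :class:`SaturationError` when a log argument is non-positive.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be equal length (aligned)")
    sites = ti = tv = 0
    for x, y in zip(a, b):
        cx = _NT_CODE.get(x)
        cy = _NT_CODE.get(y)
        if cx is None or cy is None:
            continue
        sites += 1
        if cx == cy:
            continue
        if (cx < 2) == (cy < 2):  # both purine or both pyrimidine
            ti += 1
        else:
            tv += 1
    if sites == 0:
        raise UndefinedDistanceError("no comparable sites after pairwise deletion")
    P = ti / sites
    Q = tv / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P saturated: P={P:.4f}, Q={Q:.4f}")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return d, P, Q


def distance_matrix(aln: AlignmentSet, model: str = "p", strict: bool = False) -> DistanceMatrix:
    """All-pairs distances under ``model`` ('p', 'poisson' or 'k2p').

    Undefined pairs (saturated K2P, p = 1 under Poisson, no comparable
    sites) are recorded in ``undefined_pairs`` and hold NaN; under
    ``strict=True`` they raise instead, listing the offending pairs.
    """
    if model not in ("p", "poisson", "k2p"):
        raise ValueError(f"unknown distance model {model!r}")
    n = len(aln)
    if n < 2:
        raise ValueError("need at least two sequences")
    arr = aln.to_array()
    miss = missing_chars(aln.alphabet)
    ok = ~np.isin(arr, sorted(miss))
    if model == "k2p" and aln.alphabet != "nucleotide":
        raise ValueError("K2P requires nucleotide sequences")

    if model == "k2p":
        code = np.full(arr.shape, -1, dtype=np.int8)
        for base, c in _NT_CODE.items():
            code[arr == base] = c
        ok = code >= 0

    values = np.zeros((n, n))
    sites_mat = np.zeros((n, n), dtype=int)
    undefined: list[tuple[str, str, str]] = []
    ids = aln.ids
    for i in range(n):
        sites_mat[i, i] = int(ok[i].sum())
        for j in range(i + 1, n):
            valid = ok[i] & ok[j]
            sites = int(valid.sum())
            sites_mat[i, j] = sites_mat[j, i] = sites
            if sites == 0:
                values[i, j] = values[j, i] = np.nan
                undefined.append((ids[i], ids[j], "no comparable sites"))
                continue
            if model == "k2p":
                diff = valid & (code[i] != code[j])
                same_class = (code[i] < 2) == (code[j] < 2)
                P = float((diff & same_class).sum()) / sites
                Q = float((diff & ~same_class).sum()) / sites
                w1 = 1.0 - 2.0 * P - Q
                w2 = 1.0 - 2.0 * Q
                if w1 <= 0.0 or w2 <= 0.0:
                    values[i, j] = values[j, i] = np.nan
                    undefined.append((ids[i], ids[j], "K2P saturated"))
                    continue
                d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
            else:
                p = float((valid & (arr[i] != arr[j])).sum()) / sites
                if model == "p":
                    d = p
                else:  # poisson
                    if p >= 1.0:
                        values[i, j] = values[j, i] = np.nan
                        undefined.append((ids[i], ids[j], "p = 1, infinite distance"))
                        continue
                    d = -math.log1p(-p)
            values[i, j] = values[j, i] = d
    if strict and undefined:
        pairs = ", ".join(f"{a}~{b} ({r})" for a, b, r in undefined[:10])
        raise UndefinedDistanceError(f"{len(undefined)} undefined pair(s): {pairs}")
    return DistanceMatrix(
        ids=list(ids),
        values=values,
        model=model,
        pairwise_sites=sites_mat,
        undefined_pairs=undefined,
    )
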