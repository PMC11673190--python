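"""Synthetic retroelement generator with known ground truth.

Two generators share one :class:`SimulationConfig`:

* :func:`simulate_rt_families` emits aligned reverse-transcriptase (RT)
  protein families — ``n_groups`` superfamilies whose within-group
  divergence is far below the between-group divergence, the regime in which
  similarity-network clustering is meaningful;
* :func:`simulate_elements` emits nucleotide retroelements flanked by
  identical-orientation long terminal repeats (LTRs).  The two LTR copies of
  an element start identical and the 3' copy accumulates substitutions at a
  proportion drawn from a configurable mixture, emulating populations with
  recent (near-zero divergence) and older insertions.

Every stochastic choice flows from ``config.seed`` through one
``numpy.random.Generator``, so a fixed seed gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, FormatError
from .io import AlignmentSet

PROTEIN_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NT_RESIDUES = np.array(list("ACGT"))
# transition partner per base, and the two transversion alternatives
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

DEFAULT_MIXTURE = [(0.5, 0.0, 0.01), (0.3, 0.01, 0.08), (0.2, 0.08, 0.15)]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic retroelement generator.

    ``within_rate`` and ``between_rate`` are expected substitutions per site;
    ``between_rate`` must exceed ``within_rate`` for separable groups (group
    ancestors are drawn independently, i.e. at mutational saturation, so any
    ``between_rate`` well above ``within_rate`` describes the emitted data).
    ``ltr_divergence_mixture`` is a list of ``(weight, lower, upper)``
    uniform components for the 5'-3' LTR mismatch proportion.
    """

    n_groups: int = 5
    sizes: list[int] | None = None
    within_rate: float = 0.05
    between_rate: float = 0.8
    protein_length: int = 300
    element_length_range: tuple[int, int] = (5000, 6000)
    ltr_length_range: tuple[int, int] = (200, 500)
    ltr_divergence_mixture: list[tuple[float, float, float]] = field(
        default_factory=lambda: [tuple(c) for c in DEFAULT_MIXTURE]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sizes is None:
            self.sizes = [16] * self.n_groups
        self.validate()

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")
        if len(self.sizes) != self.n_groups:
            raise ConfigurationError(
                f"sizes has {len(self.sizes)} entries for {self.n_groups} groups"
            )
        if any(s < 1 for s in self.sizes):
            raise ConfigurationError("all group sizes must be >= 1")
        if self.within_rate < 0 or self.between_rate < 0:
            raise ConfigurationError("rates must be nonnegative")
        if self.between_rate <= self.within_rate:
            raise ConfigurationError(
                "between_rate must exceed within_rate for separable groups"
            )
        if self.protein_length < 1:
            raise ConfigurationError("protein_length must be >= 1")
        for name in ("element_length_range", "ltr_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigurationError(f"{name} lower must be in [1, upper]")
        if 2 * self.ltr_length_range[1] >= self.element_length_range[0]:
            raise ConfigurationError(
                "two LTRs at maximum length would not fit the shortest element"
            )
        wsum = sum(w for w, _, _ in self.ltr_divergence_mixture)
        if abs(wsum - 1.0) > 1e-9:
            raise ConfigurationError(f"mixture weights sum to {wsum}, not 1")
        for w, lo, hi in self.ltr_divergence_mixture:
            if w < 0 or lo < 0 or hi > 1 or lo > hi:
                raise ConfigurationError(
                    f"invalid mixture component ({w}, {lo}, {hi})"
                )

    def mixture_mean(self) -> float:
        """Expected LTR mismatch proportion under the configured mixture."""
        return sum(w * (lo + hi) / 2.0 for w, lo, hi in self.ltr_divergence_mixture)

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, default=list)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        data = json.loads(text)
        for key in ("element_length_range", "ltr_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "ltr_divergence_mixture" in data:
            data["ltr_divergence_mixture"] = [
                tuple(c) for c in data["ltr_divergence_mixture"]
            ]
        return cls(**data)


@dataclass
class GroundTruth:
    """What the generator knows: group labels, realized LTR divergences and
    true LTR coordinates (0-based half-open; the 5' interval precedes the 3')."""

    labels: dict[str, str] = field(default_factory=dict)
    true_ltr_divergences: dict[str, float] = field(default_factory=dict)
    true_ltr_coords: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)


def _mutate_protein(seq: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    """Apply ``n_sub`` substitutions at uniform sites; multiple hits allowed.

    Each hit resamples the site from the 19 alternative residues.
    """
    out = seq.copy()
    if n_sub == 0:
        return out
    sites = rng.integers(0, len(seq), size=n_sub)
    for s in sites:
        choices = PROTEIN_RESIDUES[PROTEIN_RESIDUES != out[s]]
        out[s] = rng.choice(choices)
    return out


def simulate_rt_families(config: SimulationConfig) -> tuple[AlignmentSet, GroundTruth]:
    """Generate aligned RT protein families with known group labels.

    Group ancestors are independent uniform-random sequences (saturated
    between-group divergence); each member then receives
    Poisson(within_rate x length) substitutions at uniform sites.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.protein_length
    records: list[tuple[str, str]] = []
    truth = GroundTruth()
    for g in range(config.n_groups):
        group = f"G{g + 1}"
        ancestor = rng.choice(PROTEIN_RESIDUES, size=L)
        for k in range(config.sizes[g]):
            ident = f"{group}_{k + 1:03d}"
            n_sub = rng.poisson(config.within_rate * L)
            member = _mutate_protein(ancestor, int(n_sub), rng)
            records.append((ident, "".join(member)))
            truth.labels[ident] = group
    return AlignmentSet(records, alphabet="protein"), truth


def _diverge_ltr(ltr: np.ndarray, proportion: float, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Copy an LTR and substitute a ``proportion`` of distinct sites.

    Sites are chosen without replacement so the realized mismatch proportion
    equals ``round(proportion * len) / len`` exactly.  Substitutions carry a
    2:1 transition:transversion bias.
    """
    out = ltr.copy()
    n_sub = int(round(proportion * len(ltr)))
    if n_sub == 0:
        return out, 0.0
    sites = rng.choice(len(ltr), size=n_sub, replace=False)
    for s in sites:
        base = out[s]
        if rng.random() < 2.0 / 3.0:
            out[s] = _TRANSITION[base]
        else:
            out[s] = rng.choice(list(_TRANSVERSIONS[base]))
    return out, n_sub / len(ltr)


def simulate_elements(config: SimulationConfig) -> tuple[AlignmentSet, GroundTruth]:
    """Generate LTR-flanked nucleotide elements with known coordinates.

    Each element is 5'-LTR + internal region + 3'-LTR; the 3' copy diverges
    from the 5' copy by a mismatch proportion drawn from
    ``ltr_divergence_mixture``.  Total length falls in
    ``element_length_range``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    weights = np.array([w for w, _, _ in config.ltr_divergence_mixture])
    weights = weights / weights.sum()
    records: list[tuple[str, str]] = []
    truth = GroundTruth()
    n_total = sum(config.sizes)
    group_of = []
    for g, size in enumerate(config.sizes):
        group_of.extend([f"G{g + 1}"] * size)
    for k in range(n_total):
        ident = f"elem_{k + 1:04d}"
        lo, hi = config.element_length_range
        total = int(rng.integers(lo, hi + 1))
        llo, lhi = config.ltr_length_range
        ltr_len = int(rng.integers(llo, lhi + 1))
        internal_len = total - 2 * ltr_len
        ltr5 = rng.choice(NT_RESIDUES, size=ltr_len)
        internal = rng.choice(NT_RESIDUES, size=internal_len)
        comp = int(rng.choice(len(weights), p=weights))
        _, dlo, dhi = config.ltr_divergence_mixture[comp]
        proportion = float(rng.uniform(dlo, dhi))
        ltr3, realized = _diverge_ltr(ltr5, proportion, rng)
        seq = "".join(ltr5) + "".join(internal) + "".join(ltr3)
        records.append((ident, seq))
        truth.labels[ident] = group_of[k]
        truth.true_ltr_divergences[ident] = realized
        truth.true_ltr_coords[ident] = (0, ltr_len, total - ltr_len, total)
    return AlignmentSet(records, alphabet="nucleotide"), truth


TRUTH_COLUMNS = [
    "id", "group", "ltr_divergence",
    "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end",
]


def write_truth(truth: GroundTruth, path) -> None:
    """TSV dump of the ground truth; round-trips losslessly via read_truth."""
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for ident in truth.labels:
            div = truth.true_ltr_divergences.get(ident)
            coords = truth.true_ltr_coords.get(ident)
            div_s = "NA" if div is None else repr(div)
            coord_s = ["NA"] * 4 if coords is None else [str(c) for c in coords]
            fh.write(
                "\t".join([ident, truth.labels[ident], div_s] + coord_s) + "\n"
            )


def read_truth(path) -> GroundTruth:
    truth = GroundTruth()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise FormatError(f"line 1: unexpected truth header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(TRUTH_COLUMNS):
                raise FormatError(f"line {lineno}: expected {len(TRUTH_COLUMNS)} columns")
            ident, group, div = parts[0], parts[1], parts[2]
            truth.labels[ident] = group
            if div != "NA":
                truth.true_ltr_divergences[ident] = float(div)
            if parts[3] != "NA":
                truth.true_ltr_coords[ident] = tuple(int(x) for x in parts[3:7])
    return truth
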