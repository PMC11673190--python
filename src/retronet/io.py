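"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based inclusive GFF3 convention happens only at the GFF3 boundary.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

from .exceptions import FormatError

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDE_ALPHABET = frozenset("ACGT")
#: characters treated as gap/ambiguity (missing) per alphabet
PROTEIN_MISSING = frozenset("-X")
NUCLEOTIDE_MISSING = frozenset("-NX")

GFF_SOURCE = "retronet"
LTR_FEATURE = "long_terminal_repeat"
ELEMENT_FEATURE = "mobile_genetic_element"


def missing_chars(alphabet: str) -> frozenset:
    return PROTEIN_MISSING if alphabet == "protein" else NUCLEOTIDE_MISSING


def _allowed_chars(alphabet: str) -> frozenset:
    if alphabet == "protein":
        return PROTEIN_ALPHABET | PROTEIN_MISSING
    if alphabet == "nucleotide":
        return NUCLEOTIDE_ALPHABET | NUCLEOTIDE_MISSING
    raise ValueError(f"unknown alphabet: {alphabet!r}")


@dataclass
class AlignmentSet:
    """An ordered collection of named, equal-length sequences.

    ``alphabet`` is ``"protein"`` or ``"nucleotide"``.  Equal length is only
    enforced when the set is used in an aligned context (``require_aligned``),
    so the same container also carries unaligned nucleotide elements.
    """

    records: list[tuple[str, str]]
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        seen = set()
        for ident, _seq in self.records:
            if not ident or any(c.isspace() for c in ident):
                raise FormatError(f"invalid identifier {ident!r}")
            if ident in seen:
                raise FormatError(f"duplicate identifier {ident!r}")
            seen.add(ident)

    @property
    def ids(self) -> list[str]:
        return [ident for ident, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, ident: str) -> str:
        for rid, seq in self.records:
            if rid == ident:
                return seq
        raise KeyError(ident)

    def require_aligned(self) -> int:
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise FormatError(f"sequences are not aligned: lengths {sorted(lengths)}")
        return lengths.pop() if lengths else 0

    def to_array(self) -> np.ndarray:
        """(n, L) array of single characters; requires alignment."""
        self.require_aligned()
        return np.array([list(s) for s in self.sequences], dtype="U1")


def read_fasta(path, alphabet: str = "protein") -> AlignmentSet:
    """Read a FASTA file with strict residue validation.

    Identifiers are the header up to the first whitespace, sequences are
    upper-cased, and ``.`` is normalized to ``-``.  Residues outside the
    alphabet (gaps and X/N ambiguity allowed) raise :class:`FormatError`
    naming the record.
    """
    allowed = _allowed_chars(alphabet)
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(".", "-")
        bad = set(seq) - allowed
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise FormatError(
                f"record {rec.id!r}: residue {seq[pos]!r} at position {pos} "
                f"is not valid for alphabet {alphabet!r}"
            )
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return AlignmentSet(records, alphabet)


def write_fasta(aln: AlignmentSet, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for ident, seq in aln.records:
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PHYLIP square distance matrix


def write_phylip_matrix(m, path) -> None:
    """Square PHYLIP distance matrix, 6 decimal places."""
    vals = np.asarray(m.values, dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-9):
        raise FormatError("matrix asymmetric beyond 1e-9")
    with open(path, "w") as fh:
        fh.write(f"{len(m.ids)}\n")
        for ident, row in zip(m.ids, vals):
            cells = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{ident}  {cells}\n")


def read_phylip_matrix(path, model: str = "p"):
    from .distances import DistanceMatrix

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"line 1: expected taxon count, got {lines[0]!r}") from exc
    if len(lines) != n + 1:
        raise FormatError(f"expected {n} rows, found {len(lines) - 1}")
    ids, rows = [], []
    for k, line in enumerate(lines[1:], start=2):
        parts = line.split()
        if len(parts) != n + 1:
            raise FormatError(f"line {k}: expected name + {n} values")
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    vals = np.array(rows)
    vals = (vals + vals.T) / 2.0  # symmetrize printed rounding
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(ids=ids, values=vals, model=model)


# ---------------------------------------------------------------------------
# TSV tables


def read_taxonomy(path) -> dict[str, str]:
    """TSV (id, group) -> mapping; duplicate ids are an error."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("taxonomy TSV needs at least 2 columns (id, group)")
    idc, grc = df.columns[:2]
    if df[idc].duplicated().any():
        dup = df[idc][df[idc].duplicated()].iloc[0]
        raise FormatError(f"identifier {dup!r} labeled more than once")
    return dict(zip(df[idc], df[grc]))


def write_taxonomy(labels: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"id": list(labels), "group": [labels[k] for k in labels]}
    ).to_csv(path, sep="\t", index=False)


def write_partition(partition, path) -> None:
    rows = sorted(partition.assignment.items())
    with open(path, "w") as fh:
        fh.write("id\tcluster\tmethod\n")
        for ident, lab in rows:
            fh.write(f"{ident}\t{lab}\t{partition.method}\n")


def read_partition(path):
    from .ssn import Partition

    df = pd.read_csv(path, sep="\t", dtype={"id": str, "cluster": int, "method": str})
    method = df["method"].iloc[0] if len(df) else "unknown"
    return Partition(dict(zip(df["id"], df["cluster"])), method=method)


def write_edge_list(g, path) -> None:
    """TSV edge list, one undirected edge once, smaller identifier first."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\tdistance\n")
        rows = []
        for u, v, data in g.edges(data=True):
            a, b = sorted((u, v))
            rows.append((a, b, data["weight"], data["distance"]))
        for a, b, w, d in sorted(rows):
            fh.write(f"{a}\t{b}\t{w:.6g}\t{d:.6g}\n")


# ---------------------------------------------------------------------------
# GFF3 (1-based inclusive at the file boundary)


def write_gff3(records: Iterable, path) -> None:
    """Write LTR pair records as GFF3.

    Each element contributes one ``mobile_genetic_element`` feature spanning
    the element and two ``long_terminal_repeat`` features.  Internal 0-based
    half-open ``(start, end)`` becomes GFF3 ``start+1, end``.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            eid = rec.element_id
            length = rec.element_length
            fh.write(
                f"{eid}\t{GFF_SOURCE}\t{ELEMENT_FEATURE}\t1\t{length}\t.\t+\t.\t"
                f"ID={eid}\n"
            )
            for tag, (s, e) in (("ltr5", rec.ltr5), ("ltr3", rec.ltr3)):
                fh.write(
                    f"{eid}\t{GFF_SOURCE}\t{LTR_FEATURE}\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={eid}_{tag};Parent={eid}\n"
                )


def read_gff3(path) -> pd.DataFrame:
    """Read GFF3 into a frame with internal 0-based half-open coordinates."""
    cols = [
        "seqid", "source", "type", "start", "end",
        "score", "strand", "phase", "attributes",
    ]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"line {lineno}: expected 9 columns, got {len(parts)}")
            try:
                parts[3] = int(parts[3]) - 1  # to 0-based half-open
                parts[4] = int(parts[4])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinates") from exc
            rows.append(parts)
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# newick


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def newick_string(tree: TreeNode) -> str:
    buf = _stdio.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
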