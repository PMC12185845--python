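"""Alignment-column conservation and gate typing across lipocalins.

Works on a multiple sequence alignment of the lipocalin family (OBPs,
VEGs, SALs, LCN9s, MUPs).  Conservation is reported as a plain residue
frequency — the percentage of sequences carrying a given residue (set)
at a column — with an explicit choice of denominator (all sequences or
non-gap sequences) and of family subset, because headline figures such
as the 82% conservation of the gate tyrosine depend on both.

Gate typing classifies the residue facing the gate tyrosine (S34 in
rOBP1) into {P, S, D/E, Other}: proline, serine, aspartate/glutamate,
or anything else.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Alignment",
    "ColumnProfile",
    "read_alignment",
    "read_family_labels",
    "map_reference_column",
    "column_profile",
    "conservation_at",
    "gate_typing",
    "logo_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
VALID_CHARS = set(AMINO_ACIDS) | {GAP, "X"}

FAMILIES = ("OBP", "VEG", "SAL", "LCN9", "MUP", "other")

GATE_CLASSES = ("P", "S", "D/E", "Other")


@dataclass
class Alignment:
    """A gapped protein alignment with optional family labels."""

    sequences: dict[str, str]                  # id -> aligned string
    family_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must share one length")
        for sid, seq in self.sequences.items():
            bad = set(seq.upper()) - VALID_CHARS
            if bad:
                raise ValueError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                )
        for sid, fam in self.family_labels.items():
            if sid not in self.sequences:
                raise ValueError(f"family label for unknown sequence {sid!r}")
            if fam not in FAMILIES:
                raise ValueError(
                    f"unknown family {fam!r} for {sid!r}; expected one of {FAMILIES}"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def subset_ids(self, subset: str | Iterable[str] | None) -> list[str]:
        """Sequence ids of a family subset ('all' / family name / id list)."""
        if subset is None or subset == "all":
            return list(self.sequences)
        if isinstance(subset, str):
            ids = [
                sid for sid in self.sequences
                if self.family_labels.get(sid) == subset
            ]
            if not ids:
                raise ValueError(f"no sequences labelled with family {subset!r}")
            return ids
        ids = list(subset)
        missing = [i for i in ids if i not in self.sequences]
        if missing:
            raise ValueError(f"unknown sequence ids: {missing[:5]}")
        if not ids:
            raise ValueError("empty sequence subset")
        return ids


@dataclass
class ColumnProfile:
    """Residue counts and frequencies of one alignment column."""

    column: int
    counts: dict[str, int]
    gap_count: int
    n_sequences: int

    @property
    def frequencies_all(self) -> dict[str, float]:
        return {r: c / self.n_sequences for r, c in self.counts.items()}

    @property
    def frequencies_nongap(self) -> dict[str, float]:
        nongap = self.n_sequences - self.gap_count
        if nongap == 0:
            return {}
        return {r: c / nongap for r, c in self.counts.items()}


def read_alignment(
    path: str | Path,
    fmt: str | None = None,
    family_labels: Mapping[str, str] | None = None,
) -> Alignment:
    """Read a FASTA or Clustal alignment via Biopython."""
    from Bio import AlignIO

    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal"} else "fasta"
    aln = AlignIO.read(str(path), fmt)
    sequences = {rec.id: str(rec.seq).upper() for rec in aln}
    return Alignment(
        sequences=sequences,
        family_labels=dict(family_labels) if family_labels else {},
    )


def read_family_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sequence id, family) of family labels."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{Path(path).name}:{lineno}: expected two tab-separated "
                    f"columns, got {line!r}"
                )
            labels[parts[0]] = parts[1]
    return labels


def map_reference_column(
    aln: Alignment, reference_id: str, residue_seq: int, seq_start: int = 1
) -> int:
    """Alignment column (0-based) of a residue in the reference sequence.

    ``residue_seq`` uses the author numbering of the reference construct;
    ``seq_start`` is the author number of its first residue.
    """
    if reference_id not in aln.sequences:
        raise KeyError(f"reference sequence {reference_id!r} not in alignment")
    target = residue_seq - seq_start + 1  # 1-based position in ungapped seq
    if target < 1:
        raise IndexError(
            f"residue {residue_seq} precedes the construct start {seq_start}"
        )
    seen = 0
    for col, ch in enumerate(aln.sequences[reference_id]):
        if ch != GAP:
            seen += 1
            if seen == target:
                return col
    raise IndexError(
        f"residue {residue_seq} beyond the reference sequence "
        f"({seen} residues)"
    )


def column_profile(
    aln: Alignment, column: int, subset: str | Iterable[str] | None = "all"
) -> ColumnProfile:
    """Residue counts of one column over a sequence subset."""
    if not 0 <= column < aln.length:
        raise IndexError(f"column {column} outside alignment of {aln.length}")
    ids = aln.subset_ids(subset)
    counter: Counter[str] = Counter()
    gaps = 0
    for sid in ids:
        ch = aln.sequences[sid][column]
        if ch == GAP:
            gaps += 1
        else:
            counter[ch] += 1
    return ColumnProfile(
        column=column, counts=dict(counter), gap_count=gaps, n_sequences=len(ids)
    )


def conservation_at(
    aln: Alignment,
    column: int,
    residue_set: Iterable[str],
    subset: str | Iterable[str] | None = "all",
    denominator: str = "nongap",
) -> float:
    """Percentage of sequences carrying one of ``residue_set`` at a column.

    ``denominator`` chooses between all subset sequences (``"all"``) and
    only those without a gap at the column (``"nongap"``).
    """
    residues = {r.upper() for r in residue_set}
    bad = residues - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)}")
    prof = column_profile(aln, column, subset)
    hits = sum(prof.counts.get(r, 0) for r in residues)
    if denominator == "all":
        denom = prof.n_sequences
    elif denominator == "nongap":
        denom = prof.n_sequences - prof.gap_count
    else:
        raise ValueError("denominator must be 'all' or 'nongap'")
    if denom == 0:
        raise ValueError("empty denominator (all sequences gapped?)")
    return 100.0 * hits / denom


def gate_typing(
    aln: Alignment,
    gate_column: int,
    subset: str | Iterable[str] | None = "all",
    per_family: bool = True,
) -> dict[str, dict[str, int]]:
    """Classify the gate-facing residue into {P, S, D/E, Other} per family.

    Gaps are counted under a separate ``gap`` key (and do not enter the
    four classes).  Returns ``{family: {class: count, "gap": count}}``;
    with ``per_family=False`` a single ``"all"`` entry is returned.
    """
    ids = aln.subset_ids(subset)
    if not 0 <= gate_column < aln.length:
        raise IndexError(f"column {gate_column} outside alignment")

    def classify(ch: str) -> str | None:
        if ch == GAP:
            return None
        if ch == "P":
            return "P"
        if ch == "S":
            return "S"
        if ch in ("D", "E"):
            return "D/E"
        return "Other"

    out: dict[str, dict[str, int]] = {}
    for sid in ids:
        fam = aln.family_labels.get(sid, "other") if per_family else "all"
        bucket = out.setdefault(
            fam, {c: 0 for c in GATE_CLASSES} | {"gap": 0}
        )
        cls = classify(aln.sequences[sid][gate_column])
        if cls is None:
            bucket["gap"] += 1
        else:
            bucket[cls] += 1
    return out


def logo_table(
    aln: Alignment, subset: str | Iterable[str] | None = "all"
) -> "np.ndarray":
    """Per-column non-gap residue frequency table (columns x 20).

    The rows are alignment columns, the columns the 20 amino acids in
    alphabetical order; each row sums to 1 (or 0 for all-gap columns).
    This is the numeric content of a sequence logo.
    """
    table = np.zeros((aln.length, len(AMINO_ACIDS)))
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for col in range(aln.length):
        prof = column_profile(aln, col, subset)
        nongap = prof.n_sequences - prof.gap_count
        if nongap == 0:
            continue
        for r, c in prof.counts.items():
            if r in aa_index:
                table[col, aa_index[r]] = c / nongap
    return table
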