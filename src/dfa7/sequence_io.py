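"""FASTA input, sequence normalization, and label / feature-table I/O.

Sequences are plain uppercase A/C/G/T strings; anything else must be
removed by :func:`normalize_sequence` before feature extraction.  Labels
follow the convention intronless -> +1, intron-containing -> -1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

#: Class-label convention.
INTRONLESS = 1
INTRON_CONTAINING = -1

_LABEL_NAMES = {"intronless": INTRONLESS, "intron_containing": INTRON_CONTAINING}
_LABEL_CODES = {v: k for k, v in _LABEL_NAMES.items()}

VALID_BASES = frozenset("ACGT")

FEATURE_COLUMNS = ["n1", "n2", "n3", "n4", "n5", "n6", "sigma"]


class SequenceError(ValueError):
    """Raised for malformed or rejected sequence input."""


@dataclass(frozen=True)
class GeneSequence:
    """A validated nucleotide sequence.

    Attributes
    ----------
    id : str
        Record identifier (first whitespace token of the FASTA header,
        e.g. a GenBank accession).
    bases : str
        Uppercase sequence over {A, C, G, T}.
    label : int | None
        +1 for intronless, -1 for intron-containing, ``None`` if unlabeled.
    """

    id: str
    bases: str
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise SequenceError(f"sequence {self.id!r} is empty")
        if not set(self.bases) <= VALID_BASES:
            bad = sorted(set(self.bases) - VALID_BASES)
            raise SequenceError(
                f"sequence {self.id!r} contains non-ACGT symbols {bad}; "
                "normalize it first"
            )
        if self.label is not None and self.label not in (INTRONLESS, INTRON_CONTAINING):
            raise SequenceError(f"label must be +1 or -1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class NormalizationReport:
    """What :func:`normalize_sequence` removed."""

    n_input: int
    n_removed: int

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


def normalize_sequence(
    raw: str,
    *,
    policy: str = "drop",
    max_removed_fraction: float = 0.05,
) -> tuple[str, NormalizationReport]:
    """Uppercase ``raw`` and remove non-ACGT symbols.

    Under the default ``"drop"`` policy every character outside {A,C,G,T}
    (ambiguity codes, gaps, whitespace) is deleted and counted.  A record
    losing more than ``max_removed_fraction`` of its characters is rejected:
    heavily ambiguous records would distort the positional statistics the
    downstream analysis relies on.

    Returns the cleaned base string and a removal report.
    """
    if policy != "drop":
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    if not raw:
        raise SequenceError("empty input sequence")
    upper = raw.upper()
    kept = [c for c in upper if c in VALID_BASES]
    n_removed = len(upper) - len(kept)
    report = NormalizationReport(n_input=len(upper), n_removed=n_removed)
    if report.removed_fraction > max_removed_fraction:
        raise SequenceError(
            f"rejected: {report.removed_fraction:.1%} of characters are non-ACGT "
            f"(threshold {max_removed_fraction:.1%})"
        )
    if not kept:
        raise SequenceError("empty sequence after removing non-ACGT characters")
    return "".join(kept), report


def read_fasta(
    path: str | Path,
    *,
    normalize: bool = True,
    max_removed_fraction: float = 0.05,
    labels: Mapping[str, int] | None = None,
) -> list[GeneSequence]:
    """Read a multi-record FASTA file into :class:`GeneSequence` objects.

    Record order is preserved; the id is the first whitespace-delimited
    token of the header.  Duplicate ids and empty files are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        bases = str(rec.seq)
        if normalize:
            bases, _ = normalize_sequence(
                bases, max_removed_fraction=max_removed_fraction
            )
        label = labels.get(rec.id) if labels else None
        records.append(GeneSequence(id=rec.id, bases=bases, label=label))
    if not records:
        raise SequenceError(f"no records in FASTA file {path}")
    return records


def write_fasta(seqs: Iterable[GeneSequence], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV ``id<TAB>{intronless|intron_containing}``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["id", "label"]:
        raise SequenceError(
            f"label file must have columns 'id' and 'label', got {list(df.columns)}"
        )
    out: dict[str, int] = {}
    for _, row in df.iterrows():
        name = row["label"].strip()
        if name not in _LABEL_NAMES:
            raise SequenceError(f"unknown label {name!r} for id {row['id']!r}")
        out[row["id"]] = _LABEL_NAMES[name]
    return out


def write_labels(labels: Mapping[str, int], path: str | Path) -> None:
    rows = [{"id": k, "label": _LABEL_CODES[v]} for k, v in labels.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_feature_table(
    records: Sequence[tuple[str, Sequence[float], int | None]],
    path: str | Path,
) -> None:
    """Write per-sequence feature vectors as TSV.

    Each record is ``(id, (n1..n6, sigma), label_or_None)``.  Floats are
    stored with ``repr`` precision so the table round-trips losslessly.
    """
    if not records:
        raise ValueError("cannot write an empty feature table")
    rows = []
    for rid, vec, label in records:
        if len(vec) != 7:
            raise ValueError(f"record {rid!r} has {len(vec)} features, expected 7")
        row: dict[str, object] = {"id": rid}
        row.update({c: float(v) for c, v in zip(FEATURE_COLUMNS, vec)})
        row["label"] = "" if label is None else _LABEL_CODES[label]
        rows.append(row)
    df = pd.DataFrame(rows, columns=["id", *FEATURE_COLUMNS, "label"])
    # repr gives the shortest digit string that parses back to the same float
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def read_feature_table(
    path: str | Path,
) -> list[tuple[str, tuple[float, ...], int | None]]:
    """Inverse of :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "label": str})
    missing = [c for c in ("id", *FEATURE_COLUMNS) if c not in df.columns]
    if missing:
        raise SequenceError(f"feature table missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        raw_label = row.get("label")
        if raw_label is None or (isinstance(raw_label, float) and math.isnan(raw_label)):
            label = None
        else:
            name = str(raw_label).strip()
            label = _LABEL_NAMES[name] if name else None
        vec = tuple(float(row[c]) for c in FEATURE_COLUMNS)
        out.append((str(row["id"]), vec, label))
    return out
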