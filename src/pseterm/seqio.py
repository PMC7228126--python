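"""Reading, writing and splitting labelled DNA sequence sets.

Sequences are plain A/C/G/T strings with a binary terminator /
non-terminator label.  Two on-disk formats are supported: multi-record
FASTA (labels carried in the description as ``label=positive``) and CSV
with columns ``id,sequence,label`` (the label column, and a trailing
``species`` column, are optional; a bare single-column sequence list is
also accepted, with ids generated from the row number).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "LABELS",
    "AlphabetError",
    "FormatError",
    "SequenceRecord",
    "Dataset",
    "read_sequences",
    "write_sequences",
    "split_dataset",
]

ALPHABET = frozenset("ACGT")
LABELS = ("positive", "negative", "unknown")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T}."""


class FormatError(ValueError):
    """A sequence file is empty or malformed."""


def reverse_complement(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


def _validate_bases(record_id: str, bases: str) -> str:
    bases = bases.upper()
    for pos, ch in enumerate(bases):
        if ch not in ALPHABET:
            raise AlphabetError(
                f"record {record_id!r}: invalid base {ch!r} at position {pos} "
                "(only A/C/G/T are supported; ambiguity codes are rejected)"
            )
    if not bases:
        raise AlphabetError(f"record {record_id!r}: empty sequence")
    return bases


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled DNA sequence."""

    id: str
    bases: str
    label: str = "unknown"
    species: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", _validate_bases(self.id, self.bases))
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Dataset:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate record id {dup!r} in dataset {self.name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def label_array(self) -> np.ndarray:
        """Binary label vector (positive=1, negative=0); errors on unknown."""
        out = np.empty(len(self), dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.label == "unknown":
                raise ValueError(f"record {r.id!r} has no label")
            out[i] = 1 if r.label == "positive" else 0
        return out

    def subset(self, indices: Sequence[int], name: str = "") -> "Dataset":
        return Dataset([self.records[i] for i in indices], name or self.name)

    def relabel(self, label: str) -> "Dataset":
        return Dataset([replace(r, label=label) for r in self.records], self.name)

    def max_length(self) -> int:
        return max(len(r) for r in self.records)


def concat(datasets: Iterable[Dataset], name: str = "") -> Dataset:
    records: list[SequenceRecord] = []
    for d in datasets:
        records.extend(d.records)
    return Dataset(records, name)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if suffix in {".csv", ".tsv", ".txt"}:
        return "csv"
    raise FormatError(f"cannot infer format from suffix of {path}")


def read_sequences(path: str | Path, format: str | None = None) -> Dataset:
    """Read a FASTA or CSV sequence file into a :class:`Dataset`.

    Labels come from a ``label`` CSV column or a ``label=...`` token in a
    FASTA description; records without one are ``unknown``.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "fasta":
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            label = "unknown"
            species = ""
            for token in rec.description.split():
                if token.startswith("label="):
                    label = token[len("label="):]
                elif token.startswith("species="):
                    species = token[len("species="):].replace("_", " ")
            records.append(SequenceRecord(rec.id, str(rec.seq), label, species))
    elif fmt == "csv":
        records = _read_csv(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if not records:
        raise FormatError(f"{path}: no sequence records found")
    return Dataset(records, name=path.stem)


def _read_csv(path: Path) -> list[SequenceRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh) if row and any(cell.strip() for cell in row)]
    if not rows:
        return []
    header = [c.strip().lower() for c in rows[0]]
    records: list[SequenceRecord] = []
    if "sequence" in header:
        idx_seq = header.index("sequence")
        idx_id = header.index("id") if "id" in header else None
        idx_label = header.index("label") if "label" in header else None
        idx_species = header.index("species") if "species" in header else None
        for n, row in enumerate(rows[1:]):
            rid = row[idx_id].strip() if idx_id is not None else f"seq{n + 1}"
            label = row[idx_label].strip().lower() if idx_label is not None and len(row) > idx_label and row[idx_label].strip() else "unknown"
            species = row[idx_species].strip() if idx_species is not None and len(row) > idx_species else ""
            records.append(SequenceRecord(rid, row[idx_seq].strip(), label, species))
    else:
        # headerless: 1 column of sequences, or (id, sequence[, label]) rows
        for n, row in enumerate(rows):
            cells = [c.strip() for c in row]
            if len(cells) == 1:
                records.append(SequenceRecord(f"seq{n + 1}", cells[0]))
            else:
                label = cells[2].lower() if len(cells) > 2 and cells[2] else "unknown"
                records.append(SequenceRecord(cells[0], cells[1], label))
    return records


def write_sequences(dataset: Dataset, path: str | Path, format: str | None = None) -> None:
    """Write a dataset to FASTA or CSV; round-trips ids, bases and labels."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "fasta":
        bio = []
        for r in dataset:
            desc = f"label={r.label}"
            if r.species:
                desc += f" species={r.species.replace(' ', '_')}"
            bio.append(SeqRecord(Seq(r.bases), id=r.id, description=desc))
        SeqIO.write(bio, str(path), "fasta")
    elif fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "sequence", "label"])
            for r in dataset:
                writer.writerow([r.id, r.bases, r.label])
    else:
        raise FormatError(f"unknown format {fmt!r}")


def _split_sizes(n: int, ratio: float) -> int:
    return int(round(n * ratio))


def split_dataset(
    dataset: Dataset,
    ratio: float,
    seed: int,
    stratified: bool = True,
) -> tuple[Dataset, Dataset]:
    """Randomly partition a dataset into two parts (e.g. benchmark 8 : 2 holdout).

    The first part receives ``round(n * ratio)`` records (per class when
    stratified); the same seed always yields the same partition.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must lie strictly between 0 and 1, got {ratio}")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    if stratified:
        classes: dict[str, list[int]] = {}
        for i, r in enumerate(dataset):
            classes.setdefault(r.label, []).append(i)
        for label, idx in classes.items():
            if len(idx) < 2:
                raise ValueError(
                    f"class {label!r} has {len(idx)} member(s); "
                    "stratified splitting needs at least 2 per class"
                )
        first_idx: list[int] = []
        second_idx: list[int] = []
        for label in sorted(classes):  # class order resolves rounding remainders
            idx = np.array(classes[label])
            rng.shuffle(idx)
            k = _split_sizes(len(idx), ratio)
            first_idx.extend(idx[:k].tolist())
            second_idx.extend(idx[k:].tolist())
        first_idx.sort()
        second_idx.sort()
    else:
        perm = rng.permutation(n)
        k = _split_sizes(n, ratio)
        first_idx = sorted(perm[:k].tolist())
        second_idx = sorted(perm[k:].tolist())
    return (
        dataset.subset(first_idx, f"{dataset.name}:train"),
        dataset.subset(second_idx, f"{dataset.name}:test"),
    )
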