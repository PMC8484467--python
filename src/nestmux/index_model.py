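"""Data model and I/O for index sets, sample sheets and the nested read layout.

In a nested metabarcoding library every molecule carries two index pairs: an
outer pair read by the instrument (plate ID, demultiplexed upstream by the
sequencing facility) and an inner pair that is sequenced as part of the read
itself — k nucleotides at each end of the merged read, immediately outside the
locus primers.  This module models the inner indexes: which sequences are in
play for each role (i5 / i7), which (i5, i7) combination maps to which sample,
and how the indexes and primers are laid out along a merged read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "IndexSequence",
    "IndexSet",
    "SampleSheetEntry",
    "SampleSheet",
    "ReadLayout",
    "load_sample_sheet",
    "write_sample_sheet",
    "load_index_fasta",
    "orient_indexes",
    "revcomp",
    "IUPAC",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide codes and their expansions.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a plain {A,C,G,T,N} DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_iupac(seq: str) -> str:
    """Reverse complement honouring IUPAC degeneracy codes."""
    return seq.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IndexSequence:
    """One named index oligo for a single role (e.g. ``N716`` for i7)."""

    name: str
    sequence: str
    role: str  # "i5" or "i7"

    def __post_init__(self) -> None:
        if self.role not in ("i5", "i7"):
            raise ValueError(f"role must be 'i5' or 'i7', got {self.role!r}")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq or set(seq) - set("ACGT"):
            raise ValueError(
                f"index {self.name!r}: sequence must be non-empty over A/C/G/T "
                f"(no ambiguity codes), got {self.sequence!r}"
            )


@dataclass(frozen=True)
class IndexSet:
    """The ordered collection of indexes used for one role in a run.

    All members share the index length ``k`` (8 nt for Nextera-style inner
    indexes); names and sequences must be unique.
    """

    role: str
    members: tuple[IndexSequence, ...]
    k: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise ValueError("IndexSet must be non-empty")
        names = [m.name for m in self.members]
        seqs = [m.sequence for m in self.members]
        if len(set(names)) != len(names):
            raise ValueError("duplicate index names in set")
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate index sequences in set")
        for m in self.members:
            if m.role != self.role:
                raise ValueError(f"member {m.name!r} has role {m.role}, set is {self.role}")
            if len(m.sequence) != self.k:
                raise ValueError(
                    f"member {m.name!r} has length {len(m.sequence)}, expected k={self.k}"
                )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.members)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(m.sequence for m in self.members)

    def by_name(self, name: str) -> IndexSequence:
        for m in self.members:
            if m.name == name:
                return m
        raise KeyError(f"unknown index name {name!r} in {self.role} set")

    @classmethod
    def from_sequences(cls, role: str, named: dict[str, str] | Sequence[tuple[str, str]],
                       k: int | None = None) -> "IndexSet":
        items = list(named.items()) if isinstance(named, dict) else list(named)
        if k is None:
            k = len(items[0][1]) if items else 8
        return cls(role=role,
                   members=tuple(IndexSequence(n, s, role) for n, s in items), k=k)


@dataclass(frozen=True)
class SampleSheetEntry:
    sample_id: str
    i5_name: str
    i7_name: str
    is_control: bool = False
    rfu: float | None = None
    plate_id: str | None = None
    lane_id: str | None = None


@dataclass(frozen=True)
class SampleSheet:
    """(i5, i7) pair -> sample mapping with control flags and optional RFU.

    Control entries mark index combinations that were prepared but never
    loaded on the sequencer: any reads demultiplexing to them measure index
    hopping, and they anchor the hopping threshold.
    """

    entries: tuple[SampleSheetEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if not self.entries:
            raise ValueError("sample sheet is empty")
        pairs = [(e.i5_name, e.i7_name) for e in self.entries]
        if len(set(pairs)) != len(pairs):
            dup = next(p for p in pairs if pairs.count(p) > 1)
            raise ValueError(f"duplicate index pair {dup}")
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def controls(self) -> tuple[SampleSheetEntry, ...]:
        return tuple(e for e in self.entries if e.is_control)

    @property
    def samples(self) -> tuple[SampleSheetEntry, ...]:
        return tuple(e for e in self.entries if not e.is_control)

    def pair_to_sample(self) -> dict[tuple[str, str], SampleSheetEntry]:
        return {(e.i5_name, e.i7_name): e for e in self.entries}

    def by_sample_id(self, sample_id: str) -> SampleSheetEntry:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e
        raise KeyError(sample_id)

    def validate_against(self, i5_set: IndexSet, i7_set: IndexSet) -> None:
        i5_names, i7_names = set(i5_set.names), set(i7_set.names)
        for e in self.entries:
            if e.i5_name not in i5_names:
                raise ValueError(f"unknown index name {e.i5_name!r} (i5) for sample {e.sample_id!r}")
            if e.i7_name not in i7_names:
                raise ValueError(f"unknown index name {e.i7_name!r} (i7) for sample {e.sample_id!r}")


@dataclass(frozen=True)
class ReadLayout:
    """Where each index role and primer sits along a merged read.

    With the default ``five_prime_index_role="i7"`` a merged read in read-1
    orientation is::

        [i7 index][5'-adjacent primer][insert][rc(3'-adjacent primer)][rc(i5 index)]

    The i7 index is read first (read 1 starts at the reverse-primer end of the
    amplicon) and the i5 index appears reverse-complemented at the 3' end.
    ``indexes_as_sequenced`` declares whether sheet/set sequences are already
    in this read orientation; instrument-dependent i5 orientation is a known
    pitfall, so the flag is explicit rather than guessed.
    """

    k: int = 8
    five_prime_index_role: str = "i7"
    forward_primer: str = "GGCACGYCTGYBTGG"
    reverse_primer: str = "CCCGHYTGAYYTGRGGTCDC"
    indexes_as_sequenced: bool = True

    def __post_init__(self) -> None:
        if self.five_prime_index_role not in ("i5", "i7"):
            raise ValueError("five_prime_index_role must be 'i5' or 'i7'")
        for label, p in (("forward", self.forward_primer), ("reverse", self.reverse_primer)):
            if not p or set(p.upper()) - set(IUPAC):
                raise ValueError(f"{label} primer is not a valid IUPAC DNA string: {p!r}")
        object.__setattr__(self, "forward_primer", self.forward_primer.upper())
        object.__setattr__(self, "reverse_primer", self.reverse_primer.upper())

    @property
    def three_prime_index_role(self) -> str:
        return "i5" if self.five_prime_index_role == "i7" else "i7"

    @property
    def five_prime_primer(self) -> str:
        """Primer adjacent to the 5' index in read orientation.

        The i7 index sits on the reverse locus primer, so with i7 at the 5'
        end the reverse primer opens the read.
        """
        return self.reverse_primer if self.five_prime_index_role == "i7" else self.forward_primer

    @property
    def three_prime_primer(self) -> str:
        """Primer whose reverse complement closes the read."""
        return self.forward_primer if self.five_prime_index_role == "i7" else self.reverse_primer


_SHEET_HEADER = ["sample_id", "i5_name", "i5_seq", "i7_name", "i7_seq",
                 "is_control", "rfu", "plate_id", "lane_id"]


def load_sample_sheet(path: str | Path, i5_set: IndexSet | None = None,
                      i7_set: IndexSet | None = None) -> SampleSheet:
    """Read and validate a sample sheet CSV.

    Expected header: ``sample_id,i5_name,i5_seq,i7_name,i7_seq,is_control,rfu,
    plate_id,lane_id``.  ``i5_seq``/``i7_seq`` are informative and, when
    present, are checked against the index sets.  Duplicate (i5, i7) pairs and
    index names absent from the sets are rejected.  Passing no index sets
    skips name validation (enough for report-only consumers).
    """
    path = Path(path)
    entries: list[SampleSheetEntry] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise ValueError(f"{path}: not a sample sheet CSV (missing header)")
        for lineno, row in enumerate(reader, start=2):
            try:
                rfu_raw = (row.get("rfu") or "").strip()
                entry = SampleSheetEntry(
                    sample_id=row["sample_id"].strip(),
                    i5_name=row["i5_name"].strip(),
                    i7_name=row["i7_name"].strip(),
                    is_control=_parse_bool(row.get("is_control", "")),
                    rfu=float(rfu_raw) if rfu_raw else None,
                    plate_id=(row.get("plate_id") or "").strip() or None,
                    lane_id=(row.get("lane_id") or "").strip() or None,
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: cannot parse row: {exc}") from exc
            for col, idx_set in (("i5_seq", i5_set), ("i7_seq", i7_set)):
                if idx_set is None:
                    continue
                declared = (row.get(col) or "").strip().upper()
                name = entry.i5_name if col == "i5_seq" else entry.i7_name
                if declared and name in idx_set.names and declared != idx_set.by_name(name).sequence:
                    raise ValueError(
                        f"{path}:{lineno}: {col} {declared} disagrees with index set for {name}"
                    )
            entries.append(entry)
    if not entries:
        raise ValueError(f"{path}: sample sheet has no entries")
    sheet = SampleSheet(tuple(entries))
    if i5_set is not None and i7_set is not None:
        sheet.validate_against(i5_set, i7_set)
    return sheet


def write_sample_sheet(sheet: SampleSheet, path: str | Path,
                       i5_set: IndexSet | None = None, i7_set: IndexSet | None = None) -> None:
    """Write a sheet back to CSV; inverse of :func:`load_sample_sheet`."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SHEET_HEADER)
        for e in sheet.entries:
            i5_seq = i5_set.by_name(e.i5_name).sequence if i5_set else ""
            i7_seq = i7_set.by_name(e.i7_name).sequence if i7_set else ""
            writer.writerow([
                e.sample_id, e.i5_name, i5_seq, e.i7_name, i7_seq,
                "1" if e.is_control else "0",
                "" if e.rfu is None else repr(e.rfu),
                e.plate_id or "", e.lane_id or "",
            ])


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in ("1", "true", "yes", "y"):
        return True
    if v in ("", "0", "false", "no", "n"):
        return False
    raise ValueError(f"cannot interpret {value!r} as a control flag")


def load_index_fasta(path: str | Path, role: str, k: int = 8) -> IndexSet:
    """Load an index set from FASTA (record id = index name)."""
    from Bio import SeqIO

    members = [IndexSequence(rec.id, str(rec.seq).upper(), role)
               for rec in SeqIO.parse(str(path), "fasta")]
    return IndexSet(role=role, members=tuple(members), k=k)


def orient_indexes(index_set: IndexSet, layout: ReadLayout) -> IndexSet:
    """Return the set in read orientation.

    If the layout declares sheet sequences as nominal (``indexes_as_sequenced
    = False``) every member is reverse-complemented; names are preserved.
    Applying the operation twice under that setting is the identity.
    """
    if layout.indexes_as_sequenced:
        return index_set
    members = tuple(replace(m, sequence=revcomp(m.sequence)) for m in index_set.members)
    return IndexSet(role=index_set.role, members=members, k=index_set.k)
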