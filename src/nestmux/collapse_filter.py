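"""Per-sample dereplication and the control-based index-hopping filter.

Trimmed reads are collapsed to unique sequences with copy counts (exact
string identity, the classic collapser behaviour).  Because control index
combinations were never loaded on the sequencer, any reads they receive must
stem from index hopping; the largest per-unique-sequence copy count observed
in any control therefore bounds how many reads hopping can pile onto a single
sequence, and every unique sequence at or below that count is removed from
every sample — controls and real samples alike.  By construction of the
maximum, all controls end up empty.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .index_model import SampleSheet

__all__ = ["UniqueSeqTable", "HoppingThreshold", "collapse_unique",
           "estimate_threshold", "apply_threshold"]


@dataclass(frozen=True)
class UniqueSeqTable:
    """Unique sequences of one sample with their copy counts."""

    sample_id: str
    records: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.records.values()):
            raise ValueError("copy counts must be >= 1")

    @property
    def total_reads(self) -> int:
        return sum(self.records.values())

    @property
    def n_unique(self) -> int:
        return len(self.records)

    @property
    def max_count(self) -> int:
        """Copy count of the most abundant unique sequence (0 if empty)."""
        return max(self.records.values(), default=0)

    def to_fasta(self, path: str | Path) -> None:
        """Write ``>{rank}-{count}`` records, most abundant first."""
        ranked = sorted(self.records.items(), key=lambda kv: (-kv[1], kv[0]))
        with Path(path).open("w") as fh:
            for rank, (seq, count) in enumerate(ranked, start=1):
                fh.write(f">{rank}-{count}\n{seq}\n")


@dataclass(frozen=True)
class HoppingThreshold:
    """The index-hopping read-count threshold T.

    ``value`` is the maximum, over all control samples, of each control's
    most abundant unique-sequence count; ``source_control`` names the control
    attaining it.  ``per_lane_values`` is filled in per-lane scope.
    """

    value: int
    source_control: str | None
    per_lane_values: dict[str, int] | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({
            "value": self.value,
            "source_control": self.source_control,
            "per_lane_values": self.per_lane_values,
        }, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def collapse_unique(reads: Iterable[str | tuple], sample_id: str = "") -> UniqueSeqTable:
    """Collapse reads to unique sequences with copy counts.

    ``reads`` may be plain sequences or ``(id, sequence[, quality])`` tuples
    (ids and qualities are ignored; identity is exact string equality of the
    sequence).  An empty input yields an empty table.
    """
    counts: Counter[str] = Counter()
    for read in reads:
        seq = read if isinstance(read, str) else read[1]
        counts[seq] += 1
    return UniqueSeqTable(sample_id=sample_id, records=dict(counts))


def table_from_fasta(path: str | Path, sample_id: str | None = None) -> UniqueSeqTable:
    """Rebuild a table from collapsed FASTA with ``>{rank}-{count}`` headers."""
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    records: dict[str, int] = {}
    header = None
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            header = line[1:].strip()
        elif line.strip():
            try:
                count = int(header.rsplit("-", 1)[1])
            except (AttributeError, IndexError, ValueError) as exc:
                raise ValueError(f"{path}: header {header!r} is not rank-count") from exc
            records[line.strip()] = records.get(line.strip(), 0) + count
    return UniqueSeqTable(sample_id=sample_id, records=records)


def estimate_threshold(
    tables: Mapping[str, UniqueSeqTable] | Iterable[UniqueSeqTable],
    sheet: SampleSheet,
    scope: str = "global",
) -> HoppingThreshold:
    """Derive T from the control samples' unique-sequence counts.

    T is the highest unique read count found in any control; controls without
    reads contribute 0.  With ``scope="per_lane"`` one T per lane is reported
    alongside the global maximum (which remains ``value``, matching the
    practice of applying a single run-wide threshold).
    """
    if scope not in ("global", "per_lane"):
        raise ValueError(f"scope must be 'global' or 'per_lane', got {scope!r}")
    by_id = (dict(tables) if isinstance(tables, Mapping)
             else {t.sample_id: t for t in tables})
    controls = sheet.controls
    if not controls:
        raise ValueError("no control samples in sheet: threshold cannot be estimated")

    best_value, best_control = 0, None
    per_lane: dict[str, int] = {}
    for entry in controls:
        table = by_id.get(entry.sample_id)
        peak = table.max_count if table is not None else 0
        if peak > best_value or best_control is None:
            best_value, best_control = peak, entry.sample_id
        if scope == "per_lane":
            lane = entry.lane_id or ""
            per_lane[lane] = max(per_lane.get(lane, 0), peak)
    return HoppingThreshold(
        value=best_value,
        source_control=best_control,
        per_lane_values=per_lane if scope == "per_lane" else None,
    )


def apply_threshold(
    tables: Mapping[str, UniqueSeqTable] | Iterable[UniqueSeqTable],
    threshold: HoppingThreshold | int,
) -> tuple[dict[str, UniqueSeqTable], pd.DataFrame]:
    """Remove every unique sequence with copy count <= T from every sample.

    The <= semantics (a sequence exactly at the control maximum is removed)
    is what guarantees that applying the estimated threshold empties all
    controls.  Samples left without sequences are listed in the drop report
    with zero counts rather than silently deleted.

    Returns the filtered tables and a drop report with columns
    ``sample_id, reads_before, reads_after, unique_before, unique_after,
    emptied``.
    """
    t = threshold.value if isinstance(threshold, HoppingThreshold) else int(threshold)
    if t < 0:
        raise ValueError("threshold must be >= 0")
    by_id = (dict(tables) if isinstance(tables, Mapping)
             else {tab.sample_id: tab for tab in tables})
    filtered: dict[str, UniqueSeqTable] = {}
    rows = []
    for sample_id, table in by_id.items():
        kept = {seq: c for seq, c in table.records.items() if c > t}
        new = UniqueSeqTable(sample_id=sample_id, records=kept)
        filtered[sample_id] = new
        rows.append({
            "sample_id": sample_id,
            "reads_before": table.total_reads,
            "reads_after": new.total_reads,
            "unique_before": table.n_unique,
            "unique_after": new.n_unique,
            "emptied": table.n_unique > 0 and new.n_unique == 0,
        })
    report = pd.DataFrame(rows, columns=["sample_id", "reads_before", "reads_after",
                                         "unique_before", "unique_after", "emptied"])
    return filtered, report
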