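"""Assign merged reads to samples via the inner index pair at the read ends.

The 5' terminal k-mer is decoded against the 5' role's index set and the 3'
terminal k-mer is reverse-complemented and decoded against the 3' role's set,
each under its precomputed :class:`~nestmux.decodability.DecoderRules`.  Index
bases are *not* removed here — primer trimming (the next stage) strips them
positionally.  Reads assigned to control samples are written like any other
sample, because the hopping threshold is estimated from them downstream.

Correction is deliberately conservative: a read is only ever assigned when
exactly one index can explain the observed k-mer under the rules.  Ties at
distance 1, and error patterns that two different tolerant regions resolve to
different indexes, are classed ambiguous rather than broken by list order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .decodability import DecoderRules, hamming
from .index_model import IndexSet, ReadLayout, SampleSheet, revcomp
from .io import FastqRecord, read_fastq, write_fastq

__all__ = ["DecodeResult", "Decoder", "decode_index", "demultiplex",
           "DemuxResult", "mismatch_profile"]

#: Decode outcome statuses.
EXACT = "exact"
CORRECTED_1MM = "corrected_1mm"
CORRECTED_REGION = "corrected_region"
AMBIGUOUS = "ambiguous"
NO_MATCH = "no_match"

#: Read-level assignment categories.
ASSIGNED = "assigned"
AMBIGUOUS_INDEX = "ambiguous_index"
UNKNOWN_INDEX = "unknown_index"
UNEXPECTED_COMBINATION = "unexpected_combination"

CATEGORIES = (ASSIGNED, AMBIGUOUS_INDEX, UNKNOWN_INDEX, UNEXPECTED_COMBINATION)


@dataclass(frozen=True)
class DecodeResult:
    """Outcome of decoding one observed index k-mer.

    ``n_mismatches`` is the Hamming distance to the decoded index when one was
    found, and the minimum distance over the set otherwise.
    ``mismatch_positions`` are 1-based.
    """

    status: str
    index_name: str | None
    n_mismatches: int
    mismatch_positions: tuple[int, ...] = ()


class Decoder:
    """Error-tolerant decoder for one index role, built from DecoderRules."""

    def __init__(self, index_set: IndexSet, rules: DecoderRules):
        if index_set.k != rules.k:
            raise ValueError(f"index set k={index_set.k} but rules k={rules.k}")
        if index_set.sequences != rules.member_sequences:
            raise ValueError("rules were computed for a different index set")
        self.index_set = index_set
        self.rules = rules
        self.k = rules.k
        self._exact = {m.sequence: m.name for m in index_set}
        # flank lookup tables: one dict per tolerant region, keyed by the
        # members' projection onto the flanking positions (0-based)
        self._regions: list[tuple[tuple[int, ...], dict[str, str]]] = []
        for region in rules.tolerant_regions:
            flank = tuple(p for p in range(self.k) if (p + 1) not in region)
            table = {"".join(m.sequence[p] for p in flank): m.name for m in index_set}
            self._regions.append((flank, table))
        self._cache: dict[str, DecodeResult] = {}

    def decode(self, observed: str) -> DecodeResult:
        if len(observed) != self.k:
            raise ValueError(f"observed k-mer has length {len(observed)}, expected {self.k}")
        hit = self._cache.get(observed)
        if hit is None:
            hit = self._decode_uncached(observed)
            if len(self._cache) < 1_000_000:
                self._cache[observed] = hit
        return hit

    def _decode_uncached(self, observed: str) -> DecodeResult:
        exact_name = self._exact.get(observed)
        if exact_name is not None:
            return DecodeResult(EXACT, exact_name, 0)

        seqs = self.rules.member_sequences
        dists = [hamming(observed, s) for s in seqs]
        dmin = min(dists)

        if self.rules.single_mismatch_safe and dmin == 1 and dists.count(1) == 1:
            i = dists.index(1)
            pos = _mismatch_positions(observed, seqs[i])
            return DecodeResult(CORRECTED_1MM, self.rules.member_names[i], 1, pos)

        # region correction: a flank match is unique within a region by
        # construction (injectivity); conflicts *across* regions mean two
        # indexes could explain the read, which is ambiguous.
        nominated: dict[str, None] = {}
        for flank, table in self._regions:
            key = "".join(observed[p] for p in flank)
            if "N" in key:
                continue  # N matches nothing: the flank cannot be verified
            name = table.get(key)
            if name is not None:
                nominated.setdefault(name, None)
        if len(nominated) == 1:
            name = next(iter(nominated))
            i = self.rules.member_names.index(name)
            pos = _mismatch_positions(observed, seqs[i])
            return DecodeResult(CORRECTED_REGION, name, dists[i], pos)
        if len(nominated) > 1:
            return DecodeResult(AMBIGUOUS, None, dmin)

        if dmin == 1:
            # unique nearest at distance 1 but unsafe set, or an exact tie
            if dists.count(1) > 1:
                return DecodeResult(AMBIGUOUS, None, 1)
            return DecodeResult(NO_MATCH, None, 1)
        return DecodeResult(NO_MATCH, None, dmin)


def _mismatch_positions(observed: str, member: str) -> tuple[int, ...]:
    return tuple(i + 1 for i, (x, y) in enumerate(zip(observed, member))
                 if x != y or x == "N")


def decode_index(observed: str, index_set: IndexSet, rules: DecoderRules) -> DecodeResult:
    """Decode one observed k-mer (convenience wrapper around :class:`Decoder`)."""
    return Decoder(index_set, rules).decode(observed)


@dataclass
class DemuxResult:
    """Assignment table plus summary statistics of one demultiplexing run."""

    assignments: pd.DataFrame
    per_sample_counts: dict[str, int]
    category_counts: dict[str, int]
    n_total: int
    too_short: int

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "category_counts": dict(self.category_counts),
            "too_short": self.too_short,
            "per_sample_counts": dict(self.per_sample_counts),
            "mismatch_profile": mismatch_profile(self.assignments),
        }


_ASSIGN_COLS = ["read_id", "i5_status", "i7_status", "i5_mm", "i7_mm",
                "sample_id", "category"]


def demultiplex(
    reads: Iterable[FastqRecord] | str | Path,
    layout: ReadLayout,
    sheet: SampleSheet,
    i5_rules: DecoderRules,
    i7_rules: DecoderRules,
    outdir: str | Path | None = None,
) -> DemuxResult:
    """Assign each merged read to a sample via its two terminal index k-mers.

    Parameters
    ----------
    reads
        FASTQ path (``.gz`` transparent) or an iterable of
        ``(title, sequence, quality)`` records.
    outdir
        When given, per-sample FASTQ files (``<sample_id>.fastq``) plus
        overflow files (``ambiguous_index.fastq``, ``unknown_index.fastq``,
        ``unexpected_combination.fastq``) and ``demux_summary.json`` /
        ``assignments.tsv`` are written there; nothing is dropped silently.

    Every read lands in exactly one category, so category counts always sum
    to the input read count.  Control samples get files like any other
    sample — their reads feed the hopping-threshold estimate.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)

    k = layout.k
    decoders = {
        "i5": Decoder(i5_rules.index_set(), i5_rules),
        "i7": Decoder(i7_rules.index_set(), i7_rules),
    }
    dec5 = decoders[layout.five_prime_index_role]
    dec3 = decoders[layout.three_prime_index_role]
    pair_map = {(e.i5_name, e.i7_name): e.sample_id for e in sheet}

    rows: list[tuple] = []
    per_sample: dict[str, int] = {e.sample_id: 0 for e in sheet}
    categories = {c: 0 for c in CATEGORIES}
    too_short = 0
    buckets: dict[str, list[FastqRecord]] | None = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        buckets = {}

    n_total = 0
    for title, seq, qual in reads:
        n_total += 1
        read_id = title.split()[0]
        seq = seq.upper()
        if len(seq) < 2 * k:
            too_short += 1
            categories[UNKNOWN_INDEX] += 1
            rows.append((read_id, "too_short", "too_short", -1, -1, "", UNKNOWN_INDEX))
            _bucket(buckets, UNKNOWN_INDEX, (title, seq, qual))
            continue

        res5 = dec5.decode(seq[:k])
        res3 = dec3.decode(revcomp(seq[-k:]))
        res_by_role = {dec5.rules.role: res5, dec3.rules.role: res3}
        r5, r7 = res_by_role["i5"], res_by_role["i7"]

        if r5.index_name is not None and r7.index_name is not None:
            sample_id = pair_map.get((r5.index_name, r7.index_name))
            if sample_id is None:
                category, sample_id = UNEXPECTED_COMBINATION, ""
            else:
                category = ASSIGNED
                per_sample[sample_id] += 1
        elif AMBIGUOUS in (r5.status, r7.status):
            category, sample_id = AMBIGUOUS_INDEX, ""
        else:
            category, sample_id = UNKNOWN_INDEX, ""

        categories[category] += 1
        rows.append((read_id, r5.status, r7.status, r5.n_mismatches, r7.n_mismatches,
                     sample_id, category))
        _bucket(buckets, sample_id if category == ASSIGNED else category,
                (title, seq, qual))

    assignments = pd.DataFrame(rows, columns=_ASSIGN_COLS)
    result = DemuxResult(
        assignments=assignments,
        per_sample_counts=per_sample,
        category_counts=categories,
        n_total=n_total,
        too_short=too_short,
    )

    if outdir is not None and buckets is not None:
        for name, records in sorted(buckets.items()):
            write_fastq(records, outdir / f"{name}.fastq")
        assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        (outdir / "demux_summary.json").write_text(
            json.dumps(result.summary(), indent=2, sort_keys=True) + "\n")
    return result


def _bucket(buckets: dict[str, list[FastqRecord]] | None, key: str,
            record: FastqRecord) -> None:
    if buckets is not None:
        buckets.setdefault(key, []).append(record)


def mismatch_profile(assignments: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-role proportions of reads with 0 / 1 / >1 index mismatches.

    ``original`` is an exact index match; ``one_mismatch`` is a single
    nucleotide difference that is either safely corrected or simply
    unmatched; ``multi_mismatch`` covers everything else — region-corrected,
    ambiguous, and unmatched reads at distance two or more.  Reads too short
    to carry both indexes are excluded from the denominator.
    """
    if len(assignments) == 0:
        raise ValueError("empty assignment table")
    usable = assignments[assignments["i5_mm"] >= 0]
    if len(usable) == 0:
        raise ValueError("no decodable-length reads in assignment table")
    profile: dict[str, dict[str, float]] = {}
    n = len(usable)
    for role in ("i5", "i7"):
        mm = usable[f"{role}_mm"]
        status = usable[f"{role}_status"]
        original = (status == EXACT).sum()
        one = ((mm == 1) & status.isin([CORRECTED_1MM, NO_MATCH])).sum()
        profile[role] = {
            "original": original / n,
            "one_mismatch": one / n,
            "multi_mismatch": (n - original - one) / n,
        }
    return profile
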