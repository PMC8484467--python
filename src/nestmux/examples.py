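"""Synthetic example index sets and sample sheets.

The index sequences here are **synthetic**: they are *not* the commercial
Nextera index oligos (those are licensed sequences distributed with the
kits), but they are designed to behave like a well-chosen inner index set —
minimum pairwise Hamming distance >= 3 (so every single mismatch is safely
correctable) and pairwise-distinct flanking positions ({1,2,7,8} for the
i5-style set, {1,2,6,7,8} for the i7-style set), so that multiple errors in
the central positions remain correctable from the flanks alone.  Names follow
the S5xx / N7xx convention of Nextera-style index kits.
"""

from __future__ import annotations

from .index_model import IndexSet, SampleSheet, SampleSheetEntry

__all__ = ["example_i5_set", "example_i7_set", "plate_sheet"]

_I5 = {
    "S513": "TTTCCTCA",
    "S515": "TGCAATTC",
    "S516": "AAAACCAT",
    "S517": "GTCCGTAA",
    "S518": "TGTAGGCG",
    "S520": "AAATAGTA",
    "S521": "AACCATTT",
    "S522": "TACGGAGG",
}

_I7 = {
    "N716": "GCTAAAGA",
    "N718": "CAATTACA",
    "N719": "TAACATAC",
    "N720": "ACGTCAGC",
    "N721": "ACGAAACT",
    "N722": "TGTTGGCC",
    "N723": "CAGTGTGA",
    "N724": "ATCGCTTA",
    "N726": "AGGGTTAA",
    "N727": "GTAAGTGT",
    "N728": "GATGCATA",
    "N729": "CGCCTTTA",
}


def example_i5_set() -> IndexSet:
    """Synthetic 8-member i5-style index set (one per plate row A-H)."""
    return IndexSet.from_sequences("i5", _I5, k=8)


def example_i7_set() -> IndexSet:
    """Synthetic 12-member i7-style index set (one per plate column 1-12)."""
    return IndexSet.from_sequences("i7", _I7, k=8)


def plate_sheet(
    n_controls: int = 6,
    plate_id: str = "plate1",
    lane_id: str = "lane1",
) -> SampleSheet:
    """A full 96-well plate sheet: 12 i7 columns x 8 i5 rows.

    ``n_controls`` wells are flagged as controls — index combinations
    prepared but never sequenced, which later anchor the hopping threshold.
    Control wells are scattered over distinct rows and columns (real plates
    scatter the non-amplifying wells rather than clustering them), so the
    controls sample the index-hopping flux of as many rows/columns as
    possible.  Supports up to 24 controls before well positions repeat.
    """
    i5_names = list(_I5)
    i7_names = list(_I7)
    if not 0 <= n_controls <= 24:
        raise ValueError("n_controls must be in [0, 24]")
    control_wells = {(i % len(i5_names), (1 + 2 * i) % len(i7_names))
                     for i in range(n_controls)}
    entries = []
    well = 0
    for ci, i7 in enumerate(i7_names):
        for ri, i5 in enumerate(i5_names):
            well += 1
            is_control = (ri, ci) in control_wells
            prefix = "ctrl" if is_control else "sample"
            entries.append(SampleSheetEntry(
                sample_id=f"{prefix}_{plate_id}_{well:02d}",
                i5_name=i5, i7_name=i7,
                is_control=is_control,
                rfu=None,
                plate_id=plate_id, lane_id=lane_id,
            ))
    return SampleSheet(tuple(entries))
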