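"""Linked-primer trimming of demultiplexed reads.

After demultiplexing, each read still carries its two index k-mers and the
two locus primers around the insert.  This stage strips the index bases
positionally (demultiplexing already validated them), then locates the
5'-end primer and the reverse complement of the 3'-end primer by IUPAC-aware
edit-distance alignment, each allowing at most ``floor(e * primer_length)``
errors (substitutions and indels), and extracts the insert between them.
Inserts shorter than the minimum length are rejected, as are reads missing a
required primer.

Primer degeneracy (Y, B, H, R, D ... positions in the plant ITS2 primers)
matches its expansion at zero cost, so a read never pays for degenerate
primer positions.  The alignment itself is delegated to edlib; each primer
is searched within a window of its own length plus 5 nt of slack from the
relevant read end, which accommodates small indels without letting the
primer match inside the insert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import edlib

from .index_model import IUPAC, ReadLayout, revcomp_iupac
from .io import FastqRecord, read_fastq, write_fastq

__all__ = ["TrimConfig", "TrimResult", "iupac_match", "trim_linked",
           "trim_stream", "error_rate_sweep"]

TRIMMED = "trimmed"
NO_FORWARD_PRIMER = "no_forward_primer"
NO_REVERSE_PRIMER = "no_reverse_primer"
TOO_SHORT = "too_short"

#: slack beyond the primer length when searching from a read end
_WINDOW_SLACK = 5

#: symmetric character equivalences handed to edlib so degenerate primer
#: positions match their expansions at zero cost.  N in the read matches
#: nothing (it is absent from every expansion pair), so it counts as an error.
_IUPAC_EQUALITIES: tuple[tuple[str, str], ...] = tuple(
    (code, base)
    for code, bases in IUPAC.items()
    if code not in "ACGT" and code != "N"
    for base in sorted(bases)
)
# edlib equalities are symmetric, so primer-side N cannot be given "match
# anything" semantics without also letting read-side Ns match for free; N in
# a primer therefore scores as an error here.  Per-base IUPAC semantics
# (including primer N) live in iupac_match.


def iupac_match(primer_base: str, read_base: str) -> bool:
    """True iff ``read_base`` is in the expansion of the IUPAC ``primer_base``.

    An N in the read matches nothing and therefore always counts as an error.
    """
    if primer_base not in IUPAC:
        raise ValueError(f"invalid IUPAC code {primer_base!r}")
    if read_base not in "ACGTN":
        raise ValueError(f"invalid read base {read_base!r}")
    if read_base == "N":
        return False
    return read_base in IUPAC[primer_base]


@dataclass(frozen=True)
class TrimConfig:
    """Settings for linked-primer trimming.

    ``forward_primer`` is the primer expected (5'->3') at the read's 5' end;
    ``reverse_primer`` is the primer whose reverse complement closes the 3'
    end.  ``max_error_rate`` is the fraction ``e`` of each primer's length
    allowed as edit errors — the effective budget is ``floor(e * L)`` per
    primer.  ``strip_index_bases`` leading and trailing bases (the inner
    indexes) are removed positionally before the primer search.
    """

    forward_primer: str
    reverse_primer: str
    max_error_rate: float = 0.3
    min_length: int = 50
    strip_index_bases: int = 8
    require_both_primers: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.max_error_rate < 1):
            raise ValueError("max_error_rate must be in [0, 1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.strip_index_bases < 0:
            raise ValueError("strip_index_bases must be >= 0")
        for label, p in (("forward", self.forward_primer), ("reverse", self.reverse_primer)):
            if not p or set(p.upper()) - set(IUPAC):
                raise ValueError(f"{label} primer is not valid IUPAC: {p!r}")
        object.__setattr__(self, "forward_primer", self.forward_primer.upper())
        object.__setattr__(self, "reverse_primer", self.reverse_primer.upper())

    @classmethod
    def from_layout(cls, layout: ReadLayout, **kwargs) -> "TrimConfig":
        """Build a config matching a read layout.

        The primer adjacent to the 5' index opens the read, so it becomes the
        config's forward (5') primer; the other primer is searched
        reverse-complemented at the 3' end.
        """
        kwargs.setdefault("strip_index_bases", layout.k)
        return cls(forward_primer=layout.five_prime_primer,
                   reverse_primer=layout.three_prime_primer, **kwargs)

    @property
    def fwd_budget(self) -> int:
        return int(self.max_error_rate * len(self.forward_primer))

    @property
    def rev_budget(self) -> int:
        return int(self.max_error_rate * len(self.reverse_primer))


@dataclass(frozen=True)
class TrimResult:
    """Outcome of trimming one read."""

    status: str
    insert: str | None = None
    insert_qual: str | None = None
    fwd_errors: int = -1
    rev_errors: int = -1


def _find_primer(pattern: str, window: str, budget: int) -> tuple[int, int, int] | None:
    """Locate ``pattern`` in ``window`` with <= budget edit errors.

    Returns (start, end_exclusive, n_errors) of the best hit, or None.
    """
    res = edlib.align(pattern, window, mode="HW", task="locations",
                      k=budget, additionalEqualities=list(_IUPAC_EQUALITIES))
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return start, end + 1, res["editDistance"]


def trim_linked(seq: str, qual: str, config: TrimConfig) -> TrimResult:
    """Trim one read: strip index bases, remove both primer spans, keep the insert.

    The forward primer is searched in a 5' window of its length + 5 nt; the
    reverse-complemented reverse primer in the mirror-image 3' window.  On
    success everything outside the two primer hits is discarded and the
    insert (bases and qualities untouched) is returned, provided it reaches
    ``min_length``.
    """
    seq = seq.upper()
    s = config.strip_index_bases
    if len(seq) < 2 * s:
        return TrimResult(TOO_SHORT)
    core = seq[s: len(seq) - s if s else len(seq)]
    core_qual = qual[s: len(qual) - s if s else len(qual)]

    fwd = config.forward_primer
    window5 = core[: len(fwd) + _WINDOW_SLACK]
    hit5 = _find_primer(fwd, window5, config.fwd_budget)
    if hit5 is None:
        if config.require_both_primers:
            return TrimResult(NO_FORWARD_PRIMER)
        ins_start, fwd_errors = 0, -1
    else:
        ins_start, fwd_errors = hit5[1], hit5[2]

    rev_rc = revcomp_iupac(config.reverse_primer)
    wlen = len(rev_rc) + _WINDOW_SLACK
    window3 = core[max(ins_start, len(core) - wlen):]
    hit3 = _find_primer(rev_rc, window3, config.rev_budget)
    if hit3 is None:
        if config.require_both_primers:
            return TrimResult(NO_REVERSE_PRIMER, fwd_errors=fwd_errors)
        ins_end, rev_errors = len(core), -1
    else:
        offset = max(ins_start, len(core) - wlen)
        ins_end, rev_errors = offset + hit3[0], hit3[2]

    insert = core[ins_start:ins_end]
    if len(insert) < config.min_length:
        return TrimResult(TOO_SHORT, fwd_errors=fwd_errors, rev_errors=rev_errors)
    return TrimResult(TRIMMED, insert, core_qual[ins_start:ins_end],
                      fwd_errors, rev_errors)


def trim_stream(
    reads: Iterable[FastqRecord] | str | Path,
    config: TrimConfig,
    out: str | Path | None = None,
) -> tuple[list[tuple[str, TrimResult]], dict[str, int]]:
    """Trim a FASTQ stream; returns per-read results and status counts.

    When ``out`` is given, retained reads are also written to that FASTQ
    path (ids preserved, qualities untouched).
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    results: list[tuple[str, TrimResult]] = []
    counts = {TRIMMED: 0, NO_FORWARD_PRIMER: 0, NO_REVERSE_PRIMER: 0, TOO_SHORT: 0}
    kept: list[FastqRecord] = []
    for title, seq, qual in reads:
        read_id = title.split()[0]
        res = trim_linked(seq, qual, config)
        results.append((read_id, res))
        counts[res.status] += 1
        if res.status == TRIMMED:
            kept.append((title, res.insert, res.insert_qual))
    if out is not None:
        write_fastq(kept, out)
    return results, counts


def error_rate_sweep(
    reads: Iterable[FastqRecord] | str | Path,
    config: TrimConfig,
    rates: Iterable[float],
) -> dict[float, int]:
    """Retained-read counts at each maximum error rate, on the same input.

    Reproduces the error-rate comparison a practitioner runs to pick ``e``:
    the same reads are trimmed at every rate and the retained counts are
    returned, suitable for a bar-chart comparison.
    """
    rates = list(rates)
    if not rates:
        raise ValueError("rates must be non-empty")
    records = list(read_fastq(reads)) if isinstance(reads, (str, Path)) else list(reads)
    from dataclasses import replace

    out: dict[float, int] = {}
    for e in rates:
        cfg = replace(config, max_error_rate=e)
        _, counts = trim_stream(records, cfg)
        out[e] = counts[TRIMMED]
    return out
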