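"""Synthetic merged-amplicon run generator with per-read ground truth.

Emulates the structure of a nested-metabarcoding HiSeq run so every pipeline
stage can be verified without real data: 8-nt inner indexes at both read
ends, a higher substitution rate on the 3' (i5) index than on the 5' (i7)
index, index hopping at a configurable rate that can land reads on unused
control combinations, and strongly variable per-sample depth.

Each merged read (read-1 orientation) is::

    [i7 index][reverse primer][insert][rc(forward primer)][rc(i5 index)]

with degenerate primer positions resolved uniformly at random per molecule
(a degenerate oligo pool contains all expansions), i.i.d. substitution
errors applied per region, and constant Q37 quality strings (no in-scope
stage consumes qualities).

Default per-base index error rates are derived by inverting
``P(>= 1 error) = 1 - (1 - e)^8`` against observed per-index error shares of
about 27% on the i5 end and about 3.1% on the i7 end:
``1 - (1 - 0.039)^8 = 0.273`` and ``1 - (1 - 0.0039)^8 = 0.031``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .index_model import IUPAC, IndexSet, ReadLayout, SampleSheet, revcomp
from .io import FastqRecord, write_fastq

__all__ = ["SimulationConfig", "SimulationResult", "simulate_run"]

_QUAL_CHAR = "F"  # Phred+33 Q37
_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic run.

    ``depth_mu``/``depth_sigma`` are the log-normal parameters of the
    per-sample depth weights (total read count is fixed at ``n_reads`` and
    split by a multinomial over the normalized weights).  The default
    ``sigma = 1.2`` reproduces a max/min depth spread of roughly 360x over
    ~90 samples (the expected z-range for 90 normal draws is about 4.9 SD
    and exp(1.2 * 4.9) is ~360), emulating the severe unevenness seen in
    signal-guided equimolar pooling.
    ``hopping_rate`` is the probability that exactly one of a read's two
    indexes (fair coin) is replaced by the corresponding index of another
    well in use.  ``rfu_rho`` sets the strength of the association between a
    sample's simulated pooling signal (RFU) and its depth weight; the default
    is deliberately weak.
    """

    seed: int = 0
    n_reads: int = 100_000
    insert_length_range: tuple[int, int] = (210, 250)
    depth_mu: float = 7.0
    depth_sigma: float = 1.2
    index_error_rate_5p: float = 0.0039
    index_error_rate_3p: float = 0.039
    body_error_rate: float = 0.001
    hopping_rate: float = 0.002
    rfu_rho: float = 0.3
    references: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("index_error_rate_5p", "index_error_rate_3p",
                     "body_error_rate", "hopping_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        lo, hi = self.insert_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid insert_length_range")
        if self.references is not None:
            object.__setattr__(self, "references", tuple(self.references))

    def to_json(self, path: str | Path | None = None) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SimulationConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        if "insert_length_range" in d:
            d["insert_length_range"] = tuple(d["insert_length_range"])
        if d.get("references") is not None:
            d["references"] = tuple(d["references"])
        return cls(**d)


@dataclass
class SimulationResult:
    """Reads, ground truth and per-sample metadata of one simulated run."""

    reads: list[FastqRecord]
    truth: pd.DataFrame
    depths: dict[str, int]
    rfu: dict[str, float]
    sheet: SampleSheet  # input sheet with RFU values filled in for samples

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fastq(self.reads, outdir / "reads.fastq.gz")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


_TRUTH_COLS = ["read_id", "true_sample_id", "hopped", "which_index_hopped",
               "n_index_errors_5p", "n_index_errors_3p"]


def _resolve_degenerate(primer: str, rng: np.random.Generator, n: int) -> list[str]:
    """n concrete expansions of a degenerate primer, one per molecule."""
    positions = [i for i, c in enumerate(primer) if c not in _BASES]
    if not positions:
        return [primer] * n
    choices = [sorted(IUPAC[primer[i]]) for i in positions]
    picks = [rng.integers(0, len(c), size=n) for c in choices]
    out = []
    template = list(primer)
    for r in range(n):
        for j, i in enumerate(positions):
            template[i] = choices[j][picks[j][r]]
        out.append("".join(template))
    return out


def _mutate(seq: str, n_errors: int, rng: np.random.Generator) -> str:
    """Substitute ``n_errors`` distinct positions with a different base."""
    if n_errors == 0:
        return seq
    positions = rng.choice(len(seq), size=n_errors, replace=False)
    chars = list(seq)
    for p in positions:
        current = chars[p]
        alternatives = [b for b in _BASES if b != current]
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def simulate_run(
    config: SimulationConfig,
    sheet: SampleSheet,
    layout: ReadLayout,
    i5_set: IndexSet,
    i7_set: IndexSet,
) -> SimulationResult:
    """Generate one synthetic merged-FASTQ run with a per-read truth table.

    Only non-control samples draw reads; control combinations receive reads
    exclusively through index hopping.  A fixed seed yields byte-identical
    output.  Raises if hopping is requested but the sheet has no controls
    (hopping cannot then be quantified downstream).
    """
    if config.hopping_rate > 0 and not sheet.controls:
        raise ValueError("hopping_rate > 0 requires control entries in the sheet")
    sheet.validate_against(i5_set, i7_set)

    rng = np.random.default_rng(config.seed)
    samples = list(sheet.samples)
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("sheet has no non-control samples")

    # --- per-sample depth, reference insert and RFU ---------------------
    log_w = rng.normal(config.depth_mu, config.depth_sigma, size=n_samples)
    weights = np.exp(log_w)
    depths = rng.multinomial(config.n_reads, weights / weights.sum())

    if config.references:
        refs = [config.references[i % len(config.references)] for i in range(n_samples)]
    else:
        lo, hi = config.insert_length_range
        lengths = rng.integers(lo, hi + 1, size=n_samples)
        refs = ["".join(rng.choice(list(_BASES), size=L)) for L in lengths]

    # weak positive association between pooling signal and depth weight
    z = (log_w - config.depth_mu) / config.depth_sigma
    noise = rng.normal(0.0, 1.0, size=n_samples)
    rfu_vals = np.round(np.clip(
        2.0 + config.rfu_rho * z + np.sqrt(1 - config.rfu_rho ** 2) * noise,
        0.1, 8.0), 3)
    rfu = {s.sample_id: float(v) for s, v in zip(samples, rfu_vals)}

    # --- per-read bookkeeping -------------------------------------------
    sample_of_read = np.repeat(np.arange(n_samples), depths)
    order = rng.permutation(len(sample_of_read))
    sample_of_read = sample_of_read[order]
    n = len(sample_of_read)

    i5_in_use = sorted({s.i5_name for s in samples})
    i7_in_use = sorted({s.i7_name for s in samples})

    hop_mask = rng.random(n) < config.hopping_rate
    hop_coin = rng.integers(0, 2, size=n)  # 0 -> i5 hops, 1 -> i7 hops
    k = layout.k
    n_err_5p = rng.binomial(k, config.index_error_rate_5p, size=n)
    n_err_3p = rng.binomial(k, config.index_error_rate_3p, size=n)

    primer5 = layout.five_prime_primer
    primer3 = layout.three_prime_primer
    primer5_pool = _resolve_degenerate(primer5, rng, n)
    primer3_pool = _resolve_degenerate(primer3, rng, n)

    five_role = layout.five_prime_index_role

    reads: list[FastqRecord] = []
    truth_rows: list[tuple] = []
    for r in range(n):
        entry = samples[sample_of_read[r]]
        i5_name, i7_name = entry.i5_name, entry.i7_name
        hopped = bool(hop_mask[r])
        which = ""
        if hopped:
            if hop_coin[r] == 0:
                pool = [x for x in i5_in_use if x != i5_name]
                i5_name = pool[rng.integers(0, len(pool))]
                which = "i5"
            else:
                pool = [x for x in i7_in_use if x != i7_name]
                i7_name = pool[rng.integers(0, len(pool))]
                which = "i7"

        i5_seq = i5_set.by_name(i5_name).sequence
        i7_seq = i7_set.by_name(i7_name).sequence
        idx5 = i7_seq if five_role == "i7" else i5_seq
        idx3 = i5_seq if five_role == "i7" else i7_seq

        insert = refs[sample_of_read[r]]
        body = primer5_pool[r] + insert + revcomp(primer3_pool[r])
        n_body_err = rng.binomial(len(body), config.body_error_rate)

        seq = (
            _mutate(idx5, int(n_err_5p[r]), rng)
            + _mutate(body, int(n_body_err), rng)
            + _mutate(revcomp(idx3), int(n_err_3p[r]), rng)
        )
        read_id = f"read{r + 1:07d}"
        reads.append((read_id, seq, _QUAL_CHAR * len(seq)))
        truth_rows.append((read_id, entry.sample_id, hopped, which,
                           int(n_err_5p[r]), int(n_err_3p[r])))

    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLS)
    new_entries = tuple(
        replace(e, rfu=rfu[e.sample_id]) if e.sample_id in rfu else e
        for e in sheet.entries
    )
    return SimulationResult(
        reads=reads,
        truth=truth,
        depths={s.sample_id: int(d) for s, d in zip(samples, depths)},
        rfu=rfu,
        sheet=SampleSheet(new_entries),
    )
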