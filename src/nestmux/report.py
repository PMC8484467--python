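"""Run-level QC summaries: retention per step, depth spread, RFU correlation.

These are the numbers a practitioner inspects after demultiplexing a nested
metabarcoding run: how many reads each plate/lane kept at each pipeline
step, how unevenly depth landed across samples despite signal-guided
pooling, and whether the pooling signal (RFU) actually predicted depth.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .index_model import SampleSheet

__all__ = ["StepCounts", "retention_stats", "depth_variability",
           "rfu_correlation", "render_retention_table"]

STEPS = ("demultiplexed", "trimmed", "collapsed_unique", "post_threshold")


class StepCounts:
    """Per-sample read counts at each pipeline step.

    Counts must be non-increasing along
    demultiplexed -> trimmed -> collapsed_unique -> post_threshold
    (each step only removes reads).
    """

    def __init__(self, counts: pd.DataFrame):
        missing = [c for c in ("sample_id",) + STEPS if c not in counts.columns]
        if missing:
            raise ValueError(f"StepCounts missing columns: {missing}")
        df = counts.loc[:, ["sample_id", *STEPS]].reset_index(drop=True)
        arr = df[list(STEPS)].to_numpy()
        if (np.diff(arr, axis=1) > 0).any():
            bad = df.loc[(np.diff(arr, axis=1) > 0).any(axis=1), "sample_id"].tolist()
            raise ValueError(f"counts increase across steps for samples: {bad[:5]}")
        self.frame = df

    @classmethod
    def from_dicts(cls, per_step: Mapping[str, Mapping[str, int]]) -> "StepCounts":
        """Build from ``{step: {sample_id: count}}`` mappings."""
        samples = sorted(set().union(*(per_step.get(s, {}) for s in STEPS)))
        rows = [{"sample_id": sid,
                 **{step: int(per_step.get(step, {}).get(sid, 0)) for step in STEPS}}
                for sid in samples]
        return cls(pd.DataFrame(rows))


def retention_stats(
    counts: StepCounts,
    sheet: SampleSheet,
    grouping: str = "plate_id",
    step: str = "trimmed",
) -> pd.DataFrame:
    """Read-weighted kept % and average per-sample loss % per group.

    For each group (plate or lane), ``kept_pct`` is
    ``100 * sum(kept) / sum(demultiplexed)`` over the group's samples
    (read-weighted, not a mean of per-sample percentages), and
    ``avg_loss_pct_per_sample`` spreads the group's total loss evenly over
    its samples: ``(100 - kept_pct) / n_samples``.  Groups with zero input
    reads get NaN, not 0.
    """
    if grouping not in ("plate_id", "lane_id"):
        raise ValueError("grouping must be 'plate_id' or 'lane_id'")
    if step not in STEPS:
        raise ValueError(f"step must be one of {STEPS}")
    if len(counts.frame) == 0:
        raise ValueError("empty step counts")

    group_of = {e.sample_id: getattr(e, grouping) or "" for e in sheet}
    df = counts.frame.copy()
    df["group"] = df["sample_id"].map(group_of)

    rows = []
    for group, sub in df.groupby("group", sort=True):
        total_in = int(sub["demultiplexed"].sum())
        total_kept = int(sub[step].sum())
        if total_in == 0:
            kept_pct = avg_loss = float("nan")
        else:
            kept_pct = 100.0 * total_kept / total_in
            avg_loss = (100.0 - kept_pct) / len(sub)
        rows.append({"group": group, "n_samples": len(sub),
                     "reads_in": total_in, "reads_kept": total_kept,
                     "kept_pct": kept_pct, "avg_loss_pct_per_sample": avg_loss})
    return pd.DataFrame(rows)


def render_retention_table(table: pd.DataFrame) -> str:
    """Plain-text render: kept % at one decimal, average loss at two."""
    lines = [f"{'group':<12} {'n':>4} {'reads in':>10} {'kept %':>7} {'avg loss %/sample':>18}"]
    for _, r in table.iterrows():
        kept = "undef" if pd.isna(r.kept_pct) else f"{r.kept_pct:.1f}"
        loss = "undef" if pd.isna(r.avg_loss_pct_per_sample) else f"{r.avg_loss_pct_per_sample:.2f}"
        lines.append(f"{r.group:<12} {r.n_samples:>4} {r.reads_in:>10} {kept:>7} {loss:>18}")
    return "\n".join(lines)


def depth_variability(counts: Mapping[str, int] | Sequence[int]) -> dict:
    """Min, max and max/min ratio of per-sample read counts.

    Zero-count samples cannot enter a ratio; they are excluded and reported
    under ``n_excluded_zero``.  Requires at least two positive-count samples.
    """
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    positive = [v for v in values if v > 0]
    n_zero = len(values) - len(positive)
    if len(positive) < 2:
        raise ValueError("need at least 2 samples with reads for a depth ratio")
    lo, hi = min(positive), max(positive)
    return {"min": lo, "max": hi, "ratio": hi / lo, "n_excluded_zero": n_zero}


def rfu_correlation(
    counts: Mapping[str, int],
    rfu: Mapping[str, float | None],
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between per-sample read counts and RFU.

    Computed on raw counts (no transform).  Samples lacking an RFU value are
    dropped pairwise; if more than half are missing a warning is issued and
    the computation proceeds pairwise-complete.  Constant RFU has no defined
    correlation and raises.
    """
    paired = [(counts[s], rfu[s]) for s in counts
              if s in rfu and rfu[s] is not None]
    n_missing = len(counts) - len(paired)
    if n_missing > len(counts) / 2:
        warnings.warn(
            f"RFU missing for {n_missing}/{len(counts)} samples; "
            "computing pairwise-complete correlation", stacklevel=2)
    if len(paired) < 3:
        raise ValueError("need >= 3 paired (count, RFU) observations")
    x = np.array([p[0] for p in paired], dtype=float)
    y = np.array([p[1] for p in paired], dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("correlation undefined: zero variance in counts or RFU")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
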