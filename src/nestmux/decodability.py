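"""Decodability analysis of an index set.

Before demultiplexing, each role's index set is analysed to determine which
sequencing-error patterns inside the k-nt index region can be corrected
without any risk of assigning a read to the wrong sample.  Two kinds of rule
come out of the analysis:

* **single-mismatch safety** — whether every k-mer one substitution away from
  some index has a unique nearest index, so that any single mismatch, at any
  position, can be tolerated;
* **error-tolerant regions** — maximal sets of positions ``E`` such that the
  indexes restricted to the flanking positions ``F = {1..k} \\ E`` are still
  pairwise distinct.  Arbitrarily many errors confined to ``E`` remain
  correctable because the flanks alone identify the index.

With k = 8 the full enumeration over all 2^8 position subsets is exact and
cheap; no pruning heuristics are used.  Positions are 1-based throughout so
reports read naturally ("positions 3-6").
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .index_model import IndexSet

__all__ = ["DecoderRules", "hamming_matrix", "analyze", "explain"]


@dataclass(frozen=True)
class DecoderRules:
    """Precomputed decodability of one index set.

    Attributes
    ----------
    role, k
        Index role and length the rules were computed for.
    distance_matrix
        Pairwise Hamming distances between members, in member order.
    d_min
        Minimum pairwise Hamming distance (k by convention for a
        single-member set).
    radius
        Guaranteed correction radius ``floor((d_min - 1) / 2)``.
    single_mismatch_safe
        True iff every k-mer at Hamming distance 1 from some member has a
        unique nearest member, so any single mismatch can be corrected.
    tolerant_regions
        Maximal position subsets (1-based, sorted tuples) whose complement
        projections are pairwise distinct.
    member_names, member_sequences
        The analysed set, embedded so serialized rules are self-contained.
    """

    role: str
    k: int
    distance_matrix: np.ndarray
    d_min: int
    radius: int
    single_mismatch_safe: bool
    tolerant_regions: tuple[tuple[int, ...], ...]
    member_names: tuple[str, ...]
    member_sequences: tuple[str, ...]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "role": self.role,
            "k": self.k,
            "distance_matrix": self.distance_matrix.tolist(),
            "d_min": self.d_min,
            "radius": self.radius,
            "single_mismatch_safe": self.single_mismatch_safe,
            "tolerant_regions": [list(r) for r in self.tolerant_regions],
            "member_names": list(self.member_names),
            "member_sequences": list(self.member_sequences),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DecoderRules":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            role=d["role"], k=d["k"],
            distance_matrix=np.asarray(d["distance_matrix"], dtype=int),
            d_min=d["d_min"], radius=d["radius"],
            single_mismatch_safe=d["single_mismatch_safe"],
            tolerant_regions=tuple(tuple(r) for r in d["tolerant_regions"]),
            member_names=tuple(d["member_names"]),
            member_sequences=tuple(d["member_sequences"]),
        )

    def index_set(self) -> IndexSet:
        return IndexSet.from_sequences(
            self.role, list(zip(self.member_names, self.member_sequences)), k=self.k
        )


def hamming(a: str, b: str) -> int:
    """Hamming distance; N (in reads) mismatches every base, including N."""
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def hamming_matrix(index_set: IndexSet) -> np.ndarray:
    """Symmetric matrix of pairwise Hamming distances between members."""
    seqs = index_set.sequences
    n = len(seqs)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(1 for x, y in zip(seqs[i], seqs[j]) if x != y)
            mat[i, j] = mat[j, i] = d
    return mat


def _single_mismatch_safe(seqs: tuple[str, ...], k: int) -> bool:
    # A single mismatch is tolerable only if every single-substitution
    # neighbour of every member decodes back to that member and no other:
    # the originating member must be the *unique* nearest member.  A
    # neighbour that coincides with, or ties with, a second member would be
    # mis-assigned, so such a set is unsafe.
    for i, seq in enumerate(seqs):
        for pos in range(k):
            for base in "ACGT":
                if base == seq[pos]:
                    continue
                neighbour = seq[:pos] + base + seq[pos + 1:]
                dists = [sum(1 for x, y in zip(neighbour, s) if x != y) for s in seqs]
                dmin = min(dists)
                if dists[i] != dmin or dists.count(dmin) > 1:
                    return False
    return True


def _injective_on(seqs: tuple[str, ...], flank: tuple[int, ...]) -> bool:
    """True iff projections onto 0-based positions `flank` are pairwise distinct."""
    proj = {"".join(s[p] for p in flank) for s in seqs}
    return len(proj) == len(seqs)


def _tolerant_regions(seqs: tuple[str, ...], k: int) -> tuple[tuple[int, ...], ...]:
    # Enumerate all 2^k candidate regions E; keep those whose complement
    # projection is injective, then discard non-maximal ones.
    positions = tuple(range(k))
    injective: list[frozenset[int]] = []
    for r in range(k + 1):
        for combo in itertools.combinations(positions, r):
            flank = tuple(p for p in positions if p not in combo)
            if _injective_on(seqs, flank):
                injective.append(frozenset(combo))
    maximal = [E for E in injective
               if E and not any(E < other for other in injective)]
    regions = sorted(
        (tuple(sorted(p + 1 for p in E)) for E in maximal),
        key=lambda r: (-len(r), r),
    )
    return tuple(regions)


def analyze(index_set: IndexSet) -> DecoderRules:
    """Compute the full decodability profile of an index set.

    Raises ``ValueError`` on duplicate sequences (the set invariant already
    forbids them, but rules can be requested for ad-hoc sets).  A
    single-member set gets ``d_min = k`` by convention.
    """
    seqs = index_set.sequences
    k = index_set.k
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate index sequences: injectivity impossible")

    mat = hamming_matrix(index_set)
    if len(seqs) == 1:
        d_min = k
    else:
        iu = np.triu_indices(len(seqs), 1)
        d_min = int(mat[iu].min())
    radius = (d_min - 1) // 2
    return DecoderRules(
        role=index_set.role,
        k=k,
        distance_matrix=mat,
        d_min=d_min,
        radius=radius,
        single_mismatch_safe=_single_mismatch_safe(seqs, k),
        tolerant_regions=_tolerant_regions(seqs, k),
        member_names=index_set.names,
        member_sequences=seqs,
    )


def _span(region: tuple[int, ...]) -> str:
    """Render a position set compactly, e.g. (3,4,5,6) -> 'positions 3-6'."""
    if not region:
        return "no positions"
    runs: list[str] = []
    start = prev = region[0]
    for p in region[1:]:
        if p == prev + 1:
            prev = p
            continue
        runs.append(f"{start}-{prev}" if prev > start else f"{start}")
        start = prev = p
    runs.append(f"{start}-{prev}" if prev > start else f"{start}")
    label = "position" if len(region) == 1 else "positions"
    return f"{label} {', '.join(runs)}"


def explain(rules: DecoderRules) -> str:
    """Human-readable report of what the decoder may correct and why."""
    lines = [
        f"Decodability report for the {rules.role} index set "
        f"({len(rules.member_names)} indexes, k = {rules.k})",
        f"  minimum pairwise Hamming distance: {rules.d_min}",
        f"  guaranteed correction radius: {rules.radius}",
    ]
    if rules.single_mismatch_safe:
        lines.append(
            "  single mismatches: any single mismatch, in any of the "
            f"{rules.k} positions of the index, can be tolerated"
        )
    else:
        lines.append("  single mismatches: NOT universally safe (nearest-index ties exist)")

    if len(rules.member_names) == 1:
        lines.append("  multi-error regions: trivial — a single index tolerates "
                     "errors at all positions (full-region tolerance)")
    elif not rules.tolerant_regions:
        lines.append("  multi-error regions: no multi-error region — flanking "
                     "positions never identify indexes uniquely")
    else:
        lines.append("  multi-error regions (errors here are correctable when the "
                     "flanking positions match):")
        for region in rules.tolerant_regions:
            flank = tuple(p for p in range(1, rules.k + 1) if p not in region)
            lines.append(f"    - {_span(region)} (flanking {_span(flank)})")
    return "\n".join(lines)
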