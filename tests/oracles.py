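"""Independent brute-force oracles for decoding and trimming.

Everything here is written from first principles — naive enumeration, no
imports from the package's decoding or alignment internals — so tests can
compare the implementation against an independent route.
"""

from __future__ import annotations

import itertools


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def brute_regions(seqs: list[str], k: int) -> list[tuple[int, ...]]:
    """All maximal error-tolerant regions (1-based), by testing every subset."""
    injective = []
    for r in range(1, k + 1):
        for E in itertools.combinations(range(k), r):
            flank = [p for p in range(k) if p not in E]
            projections = {"".join(s[p] for p in flank) for s in seqs}
            if len(projections) == len(seqs):
                injective.append(set(E))
    maximal = [E for E in injective
               if not any(E < other for other in injective)]
    return sorted(tuple(sorted(p + 1 for p in E)) for E in maximal)


def brute_single_mismatch_safe(seqs: list[str], k: int) -> bool:
    """Safe iff every 1-substitution neighbour of any member decodes
    uniquely back to that member by nearest-distance."""
    for i, seq in enumerate(seqs):
        for pos in range(k):
            for base in "ACGT":
                if base == seq[pos]:
                    continue
                o = seq[:pos] + base + seq[pos + 1:]
                dists = [hamming(o, s) for s in seqs]
                if dists[i] != min(dists) or dists.count(min(dists)) > 1:
                    return False
    return True


def brute_decode(observed: str, names: list[str], seqs: list[str], k: int,
                 regions: list[tuple[int, ...]] | None = None,
                 safe: bool | None = None) -> tuple[str, str | None]:
    """Reference decode: returns (status, index_name).

    Semantics: exact match; else a safely-corrected unique single mismatch;
    else flank-match against every maximal tolerant region, assigning only
    when all nominating regions agree on one member; a distance-1 tie is
    ambiguous; everything else is no_match.
    """
    if regions is None:
        regions = brute_regions(seqs, k)
    if safe is None:
        safe = brute_single_mismatch_safe(seqs, k)

    for name, s in zip(names, seqs):
        if observed == s:
            return "exact", name

    dists = [hamming(observed, s) for s in seqs]
    dmin = min(dists)
    if safe and dmin == 1 and dists.count(1) == 1:
        return "corrected_1mm", names[dists.index(1)]

    nominated = []
    for E in regions:
        flank = [p - 1 for p in range(1, k + 1) if p not in E]
        key = "".join(observed[p] for p in flank)
        if "N" in key:
            continue
        hits = [name for name, s in zip(names, seqs)
                if "".join(s[p] for p in flank) == key]
        for h in hits:
            if h not in nominated:
                nominated.append(h)
    if len(nominated) == 1:
        return "corrected_region", nominated[0]
    if len(nominated) > 1:
        return "ambiguous", None
    if dmin == 1:
        if dists.count(1) > 1:
            return "ambiguous", None
        return "no_match", None
    return "no_match", None


def iupac_edit_distance_infix(pattern: str, text: str, iupac: dict) -> int:
    """Semi-global (infix) edit distance of `pattern` inside `text`.

    Leading/trailing gaps in the text are free; substitutions and indels
    cost 1; a text base matching the IUPAC expansion of the pattern base
    costs 0; N in the text matches nothing.  Naive dynamic programming.
    """
    L, T = len(pattern), len(text)
    prev = [0] * (T + 1)
    for i in range(1, L + 1):
        cur = [i] + [0] * T
        for j in range(1, T + 1):
            match = text[j - 1] != "N" and text[j - 1] in iupac[pattern[i - 1]]
            cur[j] = min(prev[j - 1] + (0 if match else 1),
                         prev[j] + 1,
                         cur[j - 1] + 1)
        prev = cur
    return min(prev)


def best_substitution_errors(pattern: str, window: str, iupac: dict) -> int:
    """Minimum substitution-only error count of `pattern` at any offset
    inside `window` (IUPAC-aware); len(pattern) if it does not fit."""
    L = len(pattern)
    if len(window) < L:
        return L
    best = L
    for off in range(len(window) - L + 1):
        errs = sum(
            1 for pb, rb in zip(pattern, window[off:off + L])
            if rb == "N" or rb not in iupac[pb]
        )
        best = min(best, errs)
    return best
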