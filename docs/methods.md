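# Methods

This note documents the models, conventions and numerical choices behind
nestmux, and what the synthetic-data tests do and do not demonstrate.

## Read layout model

A merged read in read-1 orientation is modelled as

```
[5' index][5' primer][insert][rc(3' primer)][rc(3' index)]
```

with `k = 8` index bases at each end. By default the i7 index leads the
read: the i7 index sits on the reverse locus primer, which is the end read
first, and the i5 index appears reverse-complemented at the 3' end. Both
the role assignment and whether sheet sequences are already in read
orientation are declared explicitly in `ReadLayout` rather than guessed —
the i5 orientation differs between instrument families and silent guessing
is a classic source of silent demultiplexing failure. `orient_indexes`
reverse-complements a set when the sheet holds nominal sequences; applied
twice it is the identity.

## Decodability analysis

For one index role with members `m_1..m_n` of length `k`:

- the **Hamming distance matrix** and its minimum `d_min` give the
  guaranteed correction radius `floor((d_min-1)/2)`;
- **single-mismatch safety** holds iff every single-substitution neighbour
  of every member has that member as its *unique* nearest member. This is
  judged from the originating member's viewpoint: a neighbour of `m_i` that
  coincides with, or ties near, another member would be mis-assigned, so
  such sets are unsafe. (For substitution-only errors this criterion
  coincides with `d_min >= 3`; it is computed by enumeration, not inferred
  from `d_min`, so the reported flag is directly the decoding property.)
- **error-tolerant regions** are the maximal position subsets `E` such that
  the members restricted to the complement `F` are pairwise distinct;
  errors confined to `E` are correctable because the flanks alone identify
  the member. All `2^k` subsets are enumerated (256 for k = 8 — exactness
  is cheap at this scale, so no pruning heuristics are used) and
  non-maximal subsets discarded. Positions are reported 1-based.

Note that maximality produces *weak* regions as well as strong ones: any
pair of positions on which the members happen to be pairwise distinct
yields a region of size k-2. These are mathematically valid but carry
little evidence; the decode rules below handle the consequences.

## Decode semantics

For an observed k-mer (bases `ACGTN`; `N` mismatches everything including
the flank comparison):

1. exact member match → `exact`;
2. else, if the set is single-mismatch safe and exactly one member lies at
   distance 1 → `corrected_1mm`;
3. else, each tolerant region whose flank projection of the observed k-mer
   matches a member (necessarily unique within a region, by injectivity)
   nominates that member. One distinct nominee overall → `corrected_region`;
   two or more distinct nominees → `ambiguous`;
4. else, a distance-1 tie → `ambiguous`; anything else → `no_match`.

Two deliberate conservatisms: ties are never broken by list order, and
conflicting nominations across regions are refused rather than resolved.
The resulting guarantee, verified exhaustively over all 65,536 8-mers in
the acceptance tests, is *closest-match no-miscorrection*: an assigned
index is never contradicted by a different index that explains the
observed k-mer with the same or fewer errors. The stronger statement —
that no error pattern inside any tolerant region of any member can ever
decode elsewhere — is unattainable once single-mismatch correction is
allowed, because a multi-error region pattern of member A can land one
substitution away from member B; the decoder follows the
closest-matching-index rule and assigns B, which is overwhelmingly the
correct call under any realistic per-base error rate.

Demultiplexing decodes the 5' terminal k-mer directly and the
reverse-complemented 3' terminal k-mer, maps the (i5, i7) name pair through
the sample sheet, and buckets every read into exactly one of `assigned`,
`ambiguous_index`, `unknown_index` (including reads shorter than 2k) or
`unexpected_combination` (both indexes decoded, pair absent from the
sheet). Unassigned reads go to overflow FASTQs, never silently dropped;
category counts always sum to the input count. Index bases are *not*
removed at this stage — trimming strips them positionally, which avoids
penalizing index errors twice.

## Trimming

The 5'-end primer and the reverse complement of the 3'-end primer are
located by IUPAC-aware edit-distance alignment (edlib, infix mode), each
within a window of primer length + 5 nt of slack from its read end, after
positional removal of the k index bases. The error budget per primer is
`floor(e * L)` with `e` the configurable maximum error rate (default 0.3)
and `L` the primer length; substitutions and indels cost 1, degenerate
primer positions match their expansions free of charge. An `N` in the read
matches nothing. Both primers are required by default — the ~230-nt
amplicon is fully spanned by 2x250 merging, so a missing primer signals a
defective molecule rather than a short read — and the insert must reach 50
nt. The insert's bases and qualities are returned untouched (pure
substring extraction).

Edit-distance note: for damaged primers, the retained/rejected boundary
follows the *edit* distance, which can be smaller than the substitution
count when substitutions cluster or create repeats; the test fixtures pin
the intended error count with an independent dynamic-programming oracle.

`error_rate_sweep` re-trims the same input at several `e` values (default
0.1/0.2/0.3/0.4) to let users locate the retention plateau; on
substitution-only damage the retained count is non-decreasing in `e`.

## Dereplication and the hopping threshold

Collapsing is exact string identity of trimmed inserts within one sample;
counts conserve reads. Collapsed FASTA uses the classic `>{rank}-{count}`
header dialect.

The hopping threshold `T` is the maximum over control samples of each
control's most abundant unique-sequence count. The filter removes every
unique sequence with count `<= T` from *every* sample. The inclusive
comparison is essential: it is the only semantics under which the estimated
threshold empties all controls by construction. The default scope is one
global `T` per run (the conservative choice — the run's worst lane governs
both); a per-lane mode reports lane maxima alongside. The filter is applied
per sample: the same sequence may survive in a deep sample and be removed
from a shallow one, which is the intended behaviour since hopping flux is
per combination.

## The simulator

The generator emulates exactly the data features the pipeline must cope
with, with one knob per feature:

| parameter | default | meaning |
|---|---|---|
| `n_reads` | 100,000 | total reads, multinomially split across samples |
| `depth_mu`, `depth_sigma` | 7.0, 1.2 | log-normal per-sample depth weights; sigma = 1.2 yields a ~360x max/min spread over ~90 samples (expected z-range of 90 normal draws ~ 4.9 SD; exp(1.2 x 4.9) ~ 360) |
| `index_error_rate_5p` | 0.0039 | per-base substitution rate, 5' (i7) index; 1-(1-e)^8 ~ 3.1% of reads carry >= 1 error |
| `index_error_rate_3p` | 0.039 | per-base rate, 3' (i5) index; ~27% of reads carry >= 1 error |
| `body_error_rate` | 0.001 | per-base rate in primers + insert |
| `hopping_rate` | 0.002 | probability a read's index pair has exactly one index (fair coin) replaced by another in-use index of the same role |
| `insert_length_range` | 210-250 | per-sample reference insert length (uniform i.i.d. bases unless a FASTA is supplied) |
| `rfu_rho` | 0.3 | strength of the RFU-depth-weight association |

The per-end index error defaults are the inversion of `P(>=1 error) =
1-(1-e)^8` against per-index error shares of ~27% (i5 end) and ~3.1% (i7
end) — the asymmetry that makes error-aware decoding worthwhile; the
inversion is re-verified by a test. The hopping default sits at the low
end of the commonly reported 0.2-10% range; end-to-end fixtures raise it
to 2% so hop-derived contamination is abundant enough to measure. Hopping
is modelled as single-index replacement (not pair resampling) because
hopping arises per free adapter end; single swaps are what generate
unexpected combinations, including control wells. Example sheets scatter
control wells across distinct rows and columns, as real plates scatter
their non-amplifying wells; clustered controls would systematically
under-observe the hopping flux of distant wells. Degenerate primer
positions are resolved uniformly per molecule (a degenerate oligo pool
contains all expansions). Qualities are constant Q37 because no in-scope
stage consumes them. A fixed seed yields byte-identical FASTQ and truth
tables.

What the simulator does **not** model: PCR chimeras and polymerase bias,
quality-score structure, indels in reads (only the primers' aligner
tolerates indels), cluster-density artefacts, poly-G tails of two-channel
chemistry, and paired-end structure (only merged reads are emitted, since
merging is upstream of this toolkit). Passing tests therefore demonstrate
the pipeline's *logic* — decode correctness, threshold semantics, loss
accounting — under a realistic error budget; they do not certify recall on
chemistry-specific artefacts.

## Reports

Retention is read-weighted per group: `kept% = 100 * sum(kept) /
sum(input)` over a plate or lane, and the average per-sample loss spreads
the group's total loss evenly over its samples (`(100 - kept%) / n`), the
convention under which a plate keeping 94.2% of reads across 96 samples
loses 0.06% per sample. Zero-read groups report NaN (rendered `undef`),
not 0. Depth variability is the max/min ratio over positive-count samples
(zero-count samples are excluded and counted separately). The count-RFU
association is a plain Pearson correlation on raw counts — no transform,
matching common practice for this QC check — with a log-count option off
by default; missing RFUs are dropped pairwise with a warning past 50%,
and constant inputs raise rather than return a meaningless value.

## Problem sizes

The reference simulation used by the acceptance script and the deepest
end-to-end tests is one 96-well plate (90 samples + 6 controls) at 100,000
reads with 2% hopping — large enough that binomial checks have power
(3-SE bands) and that per-sample depth spans two orders of magnitude,
small enough to run in seconds. Exhaustive checks (all 65,536 observed
8-mers, all 2^8 position subsets) are complete, not sampled.

## Known limitations

- Index decoding is substitution-only; indels in the index region shift
  the frame and surface as multi-error reads. Levenshtein-tolerant index
  design/decoding is out of scope.
- The threshold model assumes controls see the same hopping flux as
  samples. With very few controls the max-statistic over controls is
  noisy; a sample pile can exceed `T` by chance, so a handful of
  hop-derived sequences (≲1% in the reference conditions) may survive.
- `estimate_threshold` with per-lane scope still applies the global max by
  default; genuinely independent lanes must be filtered separately.
- Plate-level (outer-index) demultiplexing, read merging, quality
  filtering and downstream taxonomy (BLAST) are upstream/downstream of
  this toolkit and deliberately excluded.
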