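# nestmux

Inner dual-index demultiplexing, primer trimming and index-hopping filtering
for **nested metabarcoding** amplicon runs.

## The problem

Nested metabarcoding tags every sample with *two* index pairs: an outer pair
read by the Illumina instrument (the plate ID, demultiplexed by the
sequencing facility) and an inner pair of 8-nt indexes that is sequenced as
part of the read itself — one index at each end of the merged amplicon,
immediately outside the locus primers. This multiplies the number of
individually taggable samples (e.g. 96 wells x 24 plates) at low cost, but
pushes two error sources onto the analyst:

1. **Sequencing errors in the inner index regions.** The read ends are the
   worst-quality part of the read, and the error burden is strongly
   asymmetric: the 3' (i5) index of a merged read accumulates many more
   substitutions than the 5' (i7) index. Discarding every read with an
   index mismatch wastes a large fraction of the run; correcting carelessly
   mis-assigns reads between samples.
2. **Index hopping.** Reads acquire index combinations that were never
   loaded on the flow cell. Index combinations that were *prepared but not
   sequenced* (control combinations) receive reads anyway, and those counts
   measure the hopping flux directly.

## The method

**Decodability analysis.** For each index role the toolkit computes, by
exhaustive enumeration over all 2^k position subsets, every maximal
*error-tolerant region* E: a set of positions such that the indexes
restricted to the flanking positions F = {1..k} \ E are still pairwise
distinct. Arbitrarily many errors confined to E stay correctable, because F
alone identifies the index. It also decides *single-mismatch safety*: every
k-mer one substitution away from an index must decode uniquely back to that
index. Decoding then proceeds conservatively — exact match, else a safely
corrected single mismatch, else a unique flank-match through a tolerant
region; ties and cross-region conflicts are left unassigned rather than
broken by list order, so a read is never assigned when two indexes explain
it equally well.

**Linked-primer trimming.** After index decoding, the k index bases are
stripped positionally and the two locus primers (degenerate IUPAC patterns,
e.g. `GGCACGYCTGYBTGG` / `CCCGHYTGAYYTGRGGTCDC`) are located by edit-distance
alignment, each allowing at most `floor(e * L)` errors for a configurable
maximum error rate `e` (default 0.3). Degenerate positions match their
expansions at zero cost. Inserts shorter than 50 nt are rejected.

**Dereplication and the hopping threshold.** Reads are collapsed per sample
to unique sequences with copy counts. The hopping threshold T is the
largest per-unique-sequence count observed in any control combination; every
unique sequence with count <= T is then removed from every sample. By
construction all controls end empty, and hop-derived contamination in real
samples — which experiences the same flux as the controls — is removed with
it.

**Run simulator.** Because the method is about error structure, the package
ships a generator for synthetic merged runs with per-read ground truth:
asymmetric index error rates (defaults 0.039 / 0.0039 per base, chosen so
that 1-(1-e)^8 reproduces per-index error shares of ~27% and ~3.1%),
single-index hopping at a configurable rate, unused control combinations,
log-normally varying per-sample depth (sigma = 1.2, ~360x max/min spread
over 90 samples) and a weak RFU-depth association. Every pipeline stage is
tested end-to-end against the generator's truth table.

## Worked example

```python
from nestmux import (ReadLayout, SimulationConfig, analyze, explain,
                     run_pipeline, simulate_run)
from nestmux.examples import example_i5_set, example_i7_set, plate_sheet

i5, i7 = example_i5_set(), example_i7_set()
print(explain(analyze(i7)))
```

```text
Decodability report for the i7 index set (12 indexes, k = 8)
  minimum pairwise Hamming distance: 4
  guaranteed correction radius: 1
  single mismatches: any single mismatch, in any of the 8 positions of the index, can be tolerated
  multi-error regions (errors here are correctable when the flanking positions match):
    - positions 1-2, 4, 6-8 (flanking positions 3, 5)
    ...
```

Any single mismatch is correctable for this set (minimum pairwise distance
4), and multiple errors are recoverable wherever the flanking positions
still identify the index uniquely.

```python
sheet = plate_sheet(n_controls=6)          # 90 samples + 6 control wells
layout = ReadLayout()                      # 8-nt indexes, i7 at the 5' end
config = SimulationConfig(seed=11, n_reads=50_000, hopping_rate=0.02)
sim = simulate_run(config, sheet, layout, i5, i7)
result = run_pipeline(sim.reads, layout, sim.sheet, i5, i7)
```

With this run the pipeline prints (see `result.demux.category_counts`,
`result.threshold`, `result.drop_report`):

```text
assigned: 48417  ambiguous: 1583  unknown: 0  unexpected: 0
hopping threshold T = 6 (source control: ctrl_plate1_09)
controls with sequences after filtering: 0 of 6
samples emptied by the filter: 6
depth spread across samples: 33-2754 reads (ratio 83x)
read count vs RFU: Pearson r = 0.37 (p = 0.00031)
```

96.8% of reads are assigned despite the heavy i5-end error load (the
unassigned remainder is multi-error reads the decoder refuses to guess at);
the threshold estimated from the six control wells empties exactly the
controls (the six "emptied" samples) and no real sample; and despite the
simulated signal-guided pooling, per-sample depth still spans nearly two
orders of magnitude with only a weak count-RFU correlation.

The same stages are available as a CLI:
`nestmux analyze-indexes`, `nestmux demux`, `nestmux trim`,
`nestmux trim-sweep`, `nestmux collapse`, `nestmux hop-threshold`,
`nestmux filter`, `nestmux simulate`, `nestmux report`.

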