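import math
import random

import pytest

from nestmux import (IndexSet, analyze, decode_index, demultiplex,
                     mismatch_profile)
from nestmux.demux import (AMBIGUOUS, ASSIGNED, CORRECTED_1MM,
                           CORRECTED_REGION, EXACT, NO_MATCH,
                           UNEXPECTED_COMBINATION, UNKNOWN_INDEX, Decoder)
from nestmux.index_model import revcomp

from oracles import brute_decode


class TestDecodeIndex:
    def test_exact(self, i5_set, i5_rules):
        for m in i5_set:
            res = decode_index(m.sequence, i5_set, i5_rules)
            assert (res.status, res.index_name, res.n_mismatches) == (EXACT, m.name, 0)

    def test_single_mismatch_corrected(self, i5_set, i5_rules):
        m = i5_set.members[0]
        observed = ("C" if m.sequence[3] != "C" else "G").join(
            [m.sequence[:3], m.sequence[4:]])
        res = decode_index(observed, i5_set, i5_rules)
        assert res.status == CORRECTED_1MM
        assert res.index_name == m.name
        assert res.n_mismatches == 1 and res.mismatch_positions == (4,)

    def test_constructed_tie_is_ambiguous(self):
        s = IndexSet.from_sequences("i7", {"X": "AAAAAAAA", "Y": "AAAAAACC"})
        res = decode_index("AAAAAAAC", s, analyze(s))
        assert res.status == AMBIGUOUS and res.index_name is None

    def test_region_correction(self):
        """Errors at positions 3-6 with matching flanks decode via the region."""
        s = IndexSet.from_sequences("i5", {
            "A": "ACAAAAGT", "B": "AGAAAACT", "C": "ATAAAATT"})
        rules = analyze(s)
        res = decode_index("ACGGGCGT", s, rules)
        assert res.status == CORRECTED_REGION and res.index_name == "A"
        assert set(res.mismatch_positions) == {3, 4, 5, 6}
        status, name = brute_decode("ACGGGCGT", list(s.names), list(s.sequences), 8)
        assert (status, name) == (res.status, "A")

    def test_n_counts_as_mismatch(self, i5_set, i5_rules):
        m = i5_set.members[0]
        observed = "N" + m.sequence[1:]
        res = decode_index(observed, i5_set, i5_rules)
        assert res.status == CORRECTED_1MM and res.index_name == m.name

    def test_length_mismatch_rejected(self, i5_set, i5_rules):
        with pytest.raises(ValueError, match="length"):
            decode_index("ACGT", i5_set, i5_rules)

    def test_rules_set_mismatch_rejected(self, i5_set, i7_rules):
        with pytest.raises(ValueError, match="different index set"):
            Decoder(i5_set, i7_rules)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_oracle_on_random_observations(self, seed, i7_set, i7_rules):
        from oracles import brute_regions, brute_single_mismatch_safe

        rng = random.Random(seed)
        dec = Decoder(i7_set, i7_rules)
        names, seqs = list(i7_set.names), list(i7_set.sequences)
        regions = brute_regions(seqs, 8)
        safe = brute_single_mismatch_safe(seqs, 8)
        for _ in range(400):
            observed = "".join(rng.choice("ACGT") for _ in range(8))
            got = dec.decode(observed)
            status, name = brute_decode(observed, names, seqs, 8,
                                        regions=regions, safe=safe)
            assert (got.status, got.index_name) == (status, name)

    def test_no_miscorrection_within_regions(self, i5_set, i5_rules):
        """Substituting bases inside any accepted region never reassigns the
        read to a different index (spot-checked exhaustively for small |E|)."""
        import itertools

        dec = Decoder(i5_set, i5_rules)
        regions = [E for E in i5_rules.tolerant_regions if len(E) <= 3]
        for E in regions or [i5_rules.tolerant_regions[0][:3]]:
            for m in i5_set:
                for sub in itertools.product("ACGT", repeat=len(E)):
                    o = list(m.sequence)
                    for p, b in zip(E, sub):
                        o[p - 1] = b
                    res = dec.decode("".join(o))
                    if res.index_name is not None:
                        assert res.index_name == m.name


def _reads_for(sheet, layout, i5_set, i7_set, entries, insert="A" * 60):
    """Construct error-free merged reads for the given sheet entries."""
    from nestmux.simulate import _resolve_degenerate
    import numpy as np

    rng = np.random.default_rng(0)
    fwd5 = _resolve_degenerate(layout.five_prime_primer, rng, 1)[0]
    rc3 = revcomp(_resolve_degenerate(layout.three_prime_primer, rng, 1)[0])
    reads = []
    for i, e in enumerate(entries):
        i5 = i5_set.by_name(e.i5_name).sequence
        i7 = i7_set.by_name(e.i7_name).sequence
        seq = i7 + fwd5 + insert + rc3 + revcomp(i5)
        reads.append((f"r{i}", seq, "F" * len(seq)))
    return reads


class TestDemultiplex:
    def test_exact_reads_assign_to_their_samples(self, sheet, layout, i5_set, i7_set,
                                                 i5_rules, i7_rules):
        entries = list(sheet.samples)[:3]
        reads = _reads_for(sheet, layout, i5_set, i7_set, entries)
        res = demultiplex(reads, layout, sheet, i5_rules, i7_rules)
        assert res.category_counts[ASSIGNED] == 3
        for e in entries:
            assert res.per_sample_counts[e.sample_id] == 1
        assert sum(res.category_counts.values()) == res.n_total == 3

    def test_unexpected_combination(self, sheet, layout, i5_set, i7_set,
                                    i5_rules, i7_rules, tmp_path):
        # build a sheet missing one pair, then send a read with that pair
        from nestmux import SampleSheet

        all_entries = list(sheet.entries)
        dropped = all_entries.pop()
        partial = SampleSheet(tuple(all_entries))
        reads = _reads_for(partial, layout, i5_set, i7_set, [dropped])
        res = demultiplex(reads, layout, partial, i5_rules, i7_rules,
                          outdir=tmp_path / "out")
        assert res.category_counts[UNEXPECTED_COMBINATION] == 1
        # unassigned reads are written to an overflow file, not dropped
        assert (tmp_path / "out" / "unexpected_combination.fastq").exists()

    def test_short_read_is_unknown(self, sheet, layout, i5_rules, i7_rules):
        res = demultiplex([("short", "ACGTACGTACGT", "F" * 12)],
                          layout, sheet, i5_rules, i7_rules)
        assert res.too_short == 1
        assert res.category_counts[UNKNOWN_INDEX] == 1

    def test_partition_conservation(self, small_run, sheet, layout,
                                    i5_rules, i7_rules):
        _, sim = small_run
        res = demultiplex(sim.reads, layout, sheet, i5_rules, i7_rules)
        assert sum(res.category_counts.values()) == len(sim.reads)
        assert len(res.assignments) == len(sim.reads)

    def test_noiseless_run_fully_assigned(self, clean_run, sheet, layout,
                                          i5_rules, i7_rules):
        _, sim = clean_run
        res = demultiplex(sim.reads, layout, sheet, i5_rules, i7_rules)
        assert res.category_counts[ASSIGNED] == len(sim.reads)
        truth = dict(zip(sim.truth["read_id"], sim.truth["true_sample_id"]))
        got = dict(zip(res.assignments["read_id"], res.assignments["sample_id"]))
        assert got == truth
        for e in sheet.controls:
            assert res.per_sample_counts[e.sample_id] == 0

    def test_determinism_byte_identical(self, small_run, sheet, layout,
                                        i5_rules, i7_rules, tmp_path):
        _, sim = small_run
        reads = sim.reads[:2000]
        out = []
        for d in ("a", "b"):
            res = demultiplex(reads, layout, sheet, i5_rules, i7_rules,
                              outdir=tmp_path / d)
            out.append((tmp_path / d / "assignments.tsv").read_bytes())
        assert out[0] == out[1]


class TestMismatchProfile:
    def test_arithmetic(self):
        import pandas as pd

        rows = ([("r%d" % i, EXACT, EXACT, 0, 0, "s", ASSIGNED) for i in range(95)]
                + [("c%d" % i, CORRECTED_1MM, EXACT, 1, 0, "s", ASSIGNED) for i in range(3)]
                + [("m%d" % i, NO_MATCH, EXACT, 3, 0, "", UNKNOWN_INDEX) for i in range(2)])
        df = pd.DataFrame(rows, columns=["read_id", "i5_status", "i7_status",
                                         "i5_mm", "i7_mm", "sample_id", "category"])
        prof = mismatch_profile(df)
        assert prof["i5"]["original"] == pytest.approx(0.95)
        assert prof["i5"]["one_mismatch"] == pytest.approx(0.03)
        assert prof["i5"]["multi_mismatch"] == pytest.approx(0.02)
        assert prof["i7"] == {"original": 1.0, "one_mismatch": 0.0, "multi_mismatch": 0.0}
        assert sum(prof["i5"].values()) == pytest.approx(1.0)

    def test_empty_table_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            mismatch_profile(pd.DataFrame(columns=["i5_mm"]))

    def test_binomial_expectation_on_simulated_run(self, small_run, sheet, layout,
                                                   i5_rules, i7_rules):
        """The 1-mismatch fraction on the error-prone (i5) end matches the
        binomial expectation 8 e (1-e)^7 within 3 standard errors."""
        config, sim = small_run
        res = demultiplex(sim.reads, layout, sheet, i5_rules, i7_rules)
        prof = mismatch_profile(res.assignments)
        e = config.index_error_rate_3p
        n = len(sim.reads)
        expected = 8 * e * (1 - e) ** 7
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(prof["i5"]["one_mismatch"] - expected) < 3 * se
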