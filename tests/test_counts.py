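"""Amplicon read merging, filtering, variant calling and count correction."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from folatedms import (
    CountTable,
    ReferenceMap,
    call_variant,
    correct_wt_hopping,
    merge_read_pair,
    quality_filter,
    tally_counts,
)
from folatedms.counts import AA_TO_CODONS, translate_codon
from folatedms.synthetic import random_reference


@pytest.fixture(scope="module")
def ref():
    return random_reference(n_codons=12, windows=((1, 6), (7, 12)), seed=0)


class TestReferenceMap:
    def test_default_windows_tile_159_codons(self):
        r = random_reference(n_codons=159, seed=1)
        assert r.windows == ((1, 40), (41, 80), (81, 120), (121, 159))
        assert r.n_codons == 159

    def test_overlapping_windows_rejected(self):
        seq = random_reference(n_codons=12, seed=0).wt_seq
        with pytest.raises(ValueError):
            ReferenceMap(seq, windows=((1, 7), (7, 12)))
        with pytest.raises(ValueError):
            ReferenceMap(seq, windows=((1, 5), (7, 12)))

    def test_non_codon_length_rejected(self):
        with pytest.raises(ValueError):
            ReferenceMap("ACGTA", windows=((1, 1),))


class TestMergeReadPair:
    def test_perfect_overlap_reconstructs_fragment(self):
        frag = "ACGTTGCAAGGTTACGGA"
        fwd, rev = frag[:14], str(Seq(frag[6:]).reverse_complement())
        merged = merge_read_pair(fwd, [30] * 14, rev, [30] * 12, min_overlap=5)
        assert merged is not None
        seq, qual = merged
        assert seq == frag
        assert len(qual) == len(frag)

    def test_non_overlapping_pair_rejected(self):
        assert (
            merge_read_pair("AAAAAAAAAA", [30] * 10, "CCCCCCCCCC", [30] * 10)
            is None
        )

    def test_higher_quality_base_wins_disagreement(self):
        frag = "ACGTTGCAAGGTTACGGATC"
        fwd = frag[:-1] + ("A" if frag[-1] != "A" else "G")  # error, low quality
        rev = str(Seq(frag[8:]).reverse_complement())
        merged = merge_read_pair(
            fwd, [40] * 19 + [2], rev, [40] * 12, min_overlap=4
        )
        assert merged is not None
        assert merged[0] == frag  # Q40 reverse call overrides the Q2 forward

    def test_empty_read_raises(self):
        with pytest.raises(ValueError):
            merge_read_pair("", [], "ACGT", [30] * 4)


class TestQualityFilter:
    def test_full_length_high_quality_passes(self):
        assert quality_filter("ACGT" * 5, [40] * 20, expected_length=20)

    def test_single_base_below_q20_fails(self):
        quals = [40] * 20
        quals[7] = 19
        assert not quality_filter("ACGT" * 5, quals, expected_length=20)

    def test_truncated_read_fails(self):
        assert not quality_filter("ACGT" * 4, [40] * 16, expected_length=20)


class TestCallVariant:
    def test_exact_reference_is_wt(self, ref):
        start, end = ref.window_nt_span(0)
        assert call_variant(ref.wt_seq[start:end], ref, 0) == "WT"

    def test_two_mutated_codons_rejected(self, ref):
        start, end = ref.window_nt_span(0)
        region = list(ref.wt_seq[start:end])
        for off in (0, 3):
            codon = region[off : off + 3]
            codon[0] = "A" if codon[0] != "A" else "G"
            region[off : off + 3] = codon
        mutated = "".join(region)
        if sum(
            mutated[3 * i : 3 * i + 3] != ref.wt_seq[start + 3 * i : start + 3 * i + 3]
            for i in range(2)
        ) == 2:
            assert call_variant(mutated, ref, 0) is None

    def test_length_mismatch_rejected(self, ref):
        start, end = ref.window_nt_span(0)
        assert call_variant(ref.wt_seq[start : end - 3], ref, 0) is None

    def test_mutation_outside_window_rejected(self, ref):
        # amplicon with one flanking codon on each side of window 2 (codons
        # 7..12 is the second window; flank reaches codon 6)
        start, end = ref.window_nt_span(1)
        region = list(ref.wt_seq[start - 3 : end])
        codon = list(region[0:3])
        codon[0] = "A" if codon[0] != "A" else "G"
        flank_codon = "".join(codon)
        if translate_codon(flank_codon) != ref.wt_protein[5]:
            region[0:3] = flank_codon
            assert call_variant("".join(region), ref, 1, flank_codons=1) is None

    def test_all_codon_substitutions_called_correctly(self, ref):
        """Brute force: replace codon 3 with all 64 codons and check the call."""
        start, end = ref.window_nt_span(0)
        wt_region = ref.wt_seq[start:end]
        pos = 3
        wt_aa = ref.wt_protein[pos - 1]
        bases = "ACGT"
        for b1 in bases:
            for b2 in bases:
                for b3 in bases:
                    codon = b1 + b2 + b3
                    read = wt_region[: 3 * (pos - 1)] + codon + wt_region[3 * pos :]
                    call = call_variant(read, ref, 0)
                    aa = translate_codon(codon)
                    if aa == wt_aa:
                        assert call == "WT"  # includes synonymous changes
                    else:
                        assert call == (pos, aa)


class TestTally:
    def test_empty_sample_gives_zero_wt_row(self, ref):
        table = tally_counts({(0.0, 1): []}, ref=ref)
        assert table.data["count"].sum() == 0
        assert "WT" in set(table.data["mutant"])

    def test_known_mixture(self, ref):
        table = tally_counts(
            {(0.0, 1): ["WT"] * 10 + [(2, "W")] * 5 + [None] * 3}, ref=ref
        )
        d = table.data.set_index("mutant")["count"]
        assert d["WT"] == 10
        assert d[ref.mutant_id(2, "W")] == 5

    def test_random_multiset_matches_brute_force(self, ref):
        rng = np.random.default_rng(0)
        pool = ["WT", (1, "K"), (2, "W"), (5, "*"), None]
        calls = [pool[i] for i in rng.integers(0, len(pool), 500)]
        table = tally_counts({(4.0, 2): calls}, ref=ref)
        d = table.data.set_index("mutant")["count"].to_dict()
        assert d["WT"] == calls.count("WT")
        for pos, aa in [(1, "K"), (2, "W"), (5, "*")]:
            assert d[ref.mutant_id(pos, aa)] == calls.count((pos, aa))
        assert table.data["count"].sum() == sum(c is not None for c in calls)

    def test_zero_rows_for_unobserved_mutants(self, ref):
        table = tally_counts(
            {(0.0, 1): ["WT"]}, all_mutants=[(1, "K"), (2, "W")], ref=ref
        )
        d = table.data.set_index("mutant")["count"]
        assert d[ref.mutant_id(1, "K")] == 0


class TestHoppingCorrection:
    def make_table(self, ref, counts):
        rows = []
        for (mut, pos, aa), c in counts.items():
            rows.append(
                {
                    "mutant": mut,
                    "position": pos,
                    "aa": aa,
                    "timepoint_h": 0.0,
                    "replicate": 1,
                    "count": c,
                }
            )
        return CountTable(pd.DataFrame(rows))

    def test_vanishing_error_rate_leaves_table_unchanged(self, ref):
        table = self.make_table(
            ref, {("WT", None, None): 1000, (ref.mutant_id(2, "W"), 2, "W"): 50}
        )
        out = correct_wt_hopping(table, ref, 1e-12)
        np.testing.assert_allclose(
            out.data["count"].to_numpy(float), table.data["count"].to_numpy(float),
            atol=1e-3,
        )

    def test_distance_three_hop_negligible(self, ref):
        # pick an amino acid whose every codon is 3 substitutions away
        wt_codon = ref.codon(1)
        far_aa = None
        for aa, codons in AA_TO_CODONS.items():
            if aa == "*":
                continue
            if all(sum(a != b for a, b in zip(c, wt_codon)) == 3 for c in codons):
                far_aa = aa
                break
        if far_aa is None:
            pytest.skip("no all-distance-3 amino acid for this codon")
        table = self.make_table(
            ref,
            {
                ("WT", None, None): 10**6,
                (ref.mutant_id(1, far_aa), 1, far_aa): 100,
            },
        )
        out = correct_wt_hopping(table, ref, 0.01)
        mut_row = out.data[out.data["mutant"] == ref.mutant_id(1, far_aa)]
        subtracted = 100 - float(mut_row["count"].iloc[0])
        assert 0 <= subtracted < 1  # (e/3)^3 * 1e6 * multiplicity << 1

    def test_counts_floored_at_zero_and_wt_untouched(self, ref):
        # a mutant one substitution from WT with fewer counts than the
        # expected hops must floor at zero
        wt_codon = ref.codon(1)
        near = None
        for aa, codons in AA_TO_CODONS.items():
            if aa in ("*", ref.wt_protein[0]):
                continue
            if any(sum(a != b for a, b in zip(c, wt_codon)) == 1 for c in codons):
                near = aa
                break
        table = self.make_table(
            ref,
            {("WT", None, None): 10**6, (ref.mutant_id(1, near), 1, near): 2},
        )
        out = correct_wt_hopping(table, ref, 0.01)
        d = out.data.set_index("mutant")["count"]
        assert d[ref.mutant_id(1, near)] == 0.0
        assert d["WT"] == 10**6

    def test_invalid_error_rate(self, ref):
        table = self.make_table(ref, {("WT", None, None): 10})
        with pytest.raises(ValueError):
            correct_wt_hopping(table, ref, 0.0)


class TestCountTable:
    def test_missing_wt_row_rejected(self):
        df = pd.DataFrame(
            [{"mutant": "A1K", "timepoint_h": 0.0, "replicate": 1, "count": 5}]
        )
        with pytest.raises(ValueError):
            CountTable(df)

    def test_negative_counts_rejected(self):
        df = pd.DataFrame(
            [{"mutant": "WT", "timepoint_h": 0.0, "replicate": 1, "count": -1}]
        )
        with pytest.raises(ValueError):
            CountTable(df)

    def test_csv_round_trip(self, ref, tmp_path):
        table = tally_counts({(0.0, 1): ["WT", (2, "W")]}, ref=ref)
        path = tmp_path / "counts.csv"
        table.to_csv(path)
        back = CountTable.from_csv(path)
        pd.testing.assert_frame_equal(
            back.data.sort_values("mutant").reset_index(drop=True)[
                ["mutant", "timepoint_h", "replicate", "count"]
            ],
            table.data.sort_values("mutant").reset_index(drop=True)[
                ["mutant", "timepoint_h", "replicate", "count"]
            ],
        )
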