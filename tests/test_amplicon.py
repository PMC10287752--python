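"""Amplicon pileups, repaired fraction, bystander and codon calls."""

import numpy as np
import pytest

from editaudit.amplicon import (
    codon_consequence,
    conditional_bystander,
    guide_frame_positions,
    indel_fraction,
    label_positions,
    pileup_and_fractions,
    repaired_fraction,
)
from editaudit.exceptions import ParameterError, PlacementError
from editaudit.homology import GuideSpec
from editaudit.simulate import simulate_amplicon_reads

WINDOW = "TTAGT" + "GTCACGTTAGCATCTGAACT" + "AGG" + "CAT"
GUIDE = GuideSpec("GTCACGTTAGCATCTGAACT", "NRN")
OFFSET = 5


class TestPositionLabels:
    def test_protospacer_base_label(self):
        labels = label_positions(GUIDE, WINDOW, OFFSET)
        # protospacer position 2 holds a T in this window
        assert labels[2] == "T_2"
        assert labels[1] == "G_1"

    def test_upstream_negative_label(self):
        labels = label_positions(GUIDE, WINDOW, OFFSET)
        assert labels[-2] == "G_-2"  # two bases 5' of position 1
        assert labels[-1] == "T_-1"

    def test_pam_positions_21_to_23(self):
        frame = guide_frame_positions(GUIDE, len(WINDOW), OFFSET)
        pam = [j for j, rel in enumerate(frame) if 21 <= rel <= 23]
        assert WINDOW[pam[0] : pam[-1] + 1] == "AGG"

    def test_no_position_zero(self):
        frame = guide_frame_positions(GUIDE, len(WINDOW), OFFSET)
        assert 0 not in frame

    def test_offset_outside_window_is_error(self):
        with pytest.raises(PlacementError):
            label_positions(GUIDE, WINDOW, 99)


class TestPileup:
    def test_all_reference_reads(self):
        pileup = pileup_and_fractions([WINDOW] * 5, WINDOW)
        frac = pileup.fractions()
        for j, base in enumerate(WINDOW):
            assert frac["ACGT-".index(base), j] == 1.0

    def test_replicates_summed_before_fractions(self):
        edited = WINDOW[:11] + "G" + WINDOW[12:]
        assert WINDOW[11] != "G"
        reps = [
            [edited] * 10 + [WINDOW] * 90,
            [edited] * 20 + [WINDOW] * 80,
            [edited] * 30 + [WINDOW] * 70,
        ]
        pileup = pileup_and_fractions(reps, WINDOW)
        assert pileup.n_reads == 300
        assert pileup.fractions()[2, 11] == pytest.approx(60 / 300)

    def test_fraction_rows_sum_to_one_without_insertions(self):
        reads = [WINDOW, WINDOW[:3] + "-" + WINDOW[4:]]
        frac = pileup_and_fractions(reads, WINDOW).fractions()
        assert np.allclose(frac.sum(axis=0), 1.0)

    def test_empty_reads_error(self):
        with pytest.raises(ParameterError):
            pileup_and_fractions([], WINDOW)

    def test_wrong_length_read_error(self):
        with pytest.raises(ParameterError):
            pileup_and_fractions(["ACGT"], WINDOW)


class TestRepairedFraction:
    def test_all_wild_type(self):
        assert repaired_fraction([WINDOW] * 4, WINDOW) == 1.0

    def test_count_ratio(self):
        other = WINDOW[:-1] + ("A" if WINDOW[-1] != "A" else "C")
        reads = [WINDOW] * 7 + [other] * 3
        assert repaired_fraction(reads, WINDOW) == pytest.approx(0.7)

    def test_bystander_read_not_repaired(self):
        # correct at the target but carrying a (synonymous) bystander
        bystander = WINDOW[:6] + "C" + WINDOW[7:]
        assert repaired_fraction([bystander], WINDOW) == 0.0

    def test_invariant_to_read_order(self, rng):
        other = "A" * len(WINDOW)
        reads = [WINDOW] * 5 + [other] * 5
        shuffled = list(rng.permutation(reads))
        assert repaired_fraction(reads, WINDOW) == repaired_fraction(
            shuffled, WINDOW)

    def test_indel_reads_counted_separately(self):
        gapped = WINDOW[:8] + "-" + WINDOW[9:]
        reads = [WINDOW, gapped]
        assert repaired_fraction(reads, WINDOW) == 0.5
        assert indel_fraction(reads) == 0.5


class TestCodonConsequence:
    @pytest.mark.parametrize("ref,alt,cat,aa", [
        ("TCT", "CCT", "missense", ("S", "P")),  # serine -> proline
        ("GCT", "GCC", "synonymous", ("A", "A")),
        ("TAC", "TAA", "nonsense", ("Y", "*")),
    ])
    def test_categories(self, ref, alt, cat, aa):
        category, aa_ref, aa_alt = codon_consequence(ref, alt)
        assert category == cat and (aa_ref, aa_alt) == aa

    def test_bad_codon_rejected(self):
        with pytest.raises(ParameterError):
            codon_consequence("AC", "ACG")


class TestConditionalBystander:
    def _simulate(self, conditional, seed=11, n=6000, error=0.0):
        return simulate_amplicon_reads(
            n_reads=n, window=WINDOW, guide=GUIDE, guide_offset=OFFSET,
            target_guide_pos=8, repair_fraction=0.6,
            bystander_spec={2: 0.08}, conditional_on_repair=conditional,
            indel_fraction=0.0, error_rate=error, seed=seed,
        )

    def test_conditional_mode_zero_among_unrepaired(self):
        reads, truth = self._simulate(conditional=True)
        amp = truth.amplicon
        wt_base = amp.wt_window[OFFSET + 7]
        result = conditional_bystander(
            reads, 8, [2], OFFSET, edited_base_at_target=wt_base,
            edited_base={2: "C"}, window_ref=WINDOW)
        among_repaired, among_unrepaired = result[2]
        assert among_unrepaired == 0.0
        assert among_repaired > 0.0

    def test_independent_mode_similar_frequencies(self):
        reads, _ = self._simulate(conditional=False, n=20000)
        wt_base = "C"  # the repaired T>C transition at position 8
        result = conditional_bystander(
            reads, 8, [2], OFFSET, edited_base_at_target=wt_base,
            edited_base={2: "C"}, window_ref=WINDOW)
        fr, fu = result[2]
        sigma = 3 * np.sqrt(0.08 * 0.92 / 6000)
        assert abs(fr - 0.08) < sigma and abs(fu - 0.08) < sigma

    def test_no_bystanders_zero_both(self):
        reads = [WINDOW] * 10
        result = conditional_bystander(
            reads, 8, [2], OFFSET, edited_base_at_target=WINDOW[OFFSET + 7],
            window_ref=WINDOW)
        assert result[2] == (0.0, None) or result[2][0] == 0.0

    def test_empty_partition_is_undefined_not_zero(self):
        reads, _ = self._simulate(conditional=True)
        # demand a base never present at the target -> empty "repaired" side
        result = conditional_bystander(
            reads, 8, [2], OFFSET, edited_base_at_target="-",
            edited_base={2: "C"}, window_ref=WINDOW)
        assert result[2][0] is None


class TestSummarizeEditing:
    def test_end_to_end_summary_on_conditional_simulation(self):
        reads, truth = simulate_amplicon_reads(
            n_reads=8000, window=WINDOW, guide=GUIDE, guide_offset=OFFSET,
            target_guide_pos=8, repair_fraction=0.7, bystander_spec={2: 0.05},
            conditional_on_repair=True, indel_fraction=0.01, error_rate=0.001,
            seed=909)
        from editaudit.amplicon import summarize_editing

        summary = summarize_editing(
            reads, WINDOW, truth.amplicon.wt_window, GUIDE,
            guide_offset=OFFSET, target_guide_pos=8, codon_frame=(OFFSET, 0),
            min_frequency=0.005)
        assert abs(summary.on_target_fraction - 0.7) < 0.02
        assert summary.repaired_fraction <= summary.on_target_fraction
        assert list(summary.bystander_table) == ["T_2"]
        entry = summary.bystander_table["T_2"]
        assert abs(entry["frequency"] - 0.7 * 0.05) < 0.01
        assert entry["consequence"] in ("synonymous", "missense", "nonsense")
        fr, fu = summary.conditional_bystander["T_2"]
        assert fr > 10 * (fu or 0.0)  # bystanders ride on repaired reads

    def test_noise_floor_masks_error_positions(self):
        reads, truth = simulate_amplicon_reads(
            n_reads=8000, window=WINDOW, guide=GUIDE, guide_offset=OFFSET,
            target_guide_pos=8, repair_fraction=0.7, bystander_spec=None,
            conditional_on_repair=False, indel_fraction=0.0, error_rate=0.002,
            seed=910)
        from editaudit.amplicon import summarize_editing

        raw = summarize_editing(reads, WINDOW, truth.amplicon.wt_window,
                                GUIDE, OFFSET, 8)
        masked = summarize_editing(reads, WINDOW, truth.amplicon.wt_window,
                                   GUIDE, OFFSET, 8, min_frequency=0.005)
        assert len(raw.bystander_table) > 0  # sequencing errors everywhere
        assert len(masked.bystander_table) == 0
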