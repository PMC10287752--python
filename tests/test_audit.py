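"""Normalization, merging, confidence filters, specificity, spectra."""

import numpy as np
import pytest

from _oracles import oracle_normalize
from editaudit.audit import (
    COLLAPSED_LABELS,
    ConsensusVariant,
    annotate_region,
    apply_confidence_filters,
    classify_tissue_specificity,
    conversion_spectrum,
    exclude_known,
    merge_callers,
    normalize_variant,
)
from editaudit.exceptions import ConfigError, ConsistencyError
from editaudit.io_formats import RegionAnnotation, VariantCall

TISSUES = ("heart", "liver", "tail")


def make_cv(afs, depths=None, callers=None, known=False, ref="A", alt="G"):
    cv = ConsensusVariant("chr1", 100, ref, alt)
    cv.known = known
    for i, t in enumerate(TISSUES):
        cv.allele_frequency[t] = afs[i]
        cv.depths[t] = None if depths is None else depths[i]
        cv.supporting_callers[t] = set() if callers is None else set(callers[i])
    return cv


class TestNormalizeVariant:
    REF = {"chr1": "GTAAAAC" + "ACGTACGTTTTTACGT"}

    def test_snv_is_fixed_point(self):
        call = VariantCall("MU", "chr1", 3, "A", "G")
        assert normalize_variant(call, self.REF) is call

    def test_deletion_left_aligned_through_homopolymer(self):
        # GTAAAAC: deleting one A is ambiguous; leftmost representation wins
        call = VariantCall("MU", "chr1", 5, "AA", "A")
        norm = normalize_variant(call, self.REF)
        assert (norm.pos, norm.ref, norm.alt) == (2, "TA", "T")

    def test_shared_leading_base_trimmed(self):
        # reference chr1[9:11] = "GT" (1-based 10..11)
        call = VariantCall("MU", "chr1", 10, "GT", "GA")
        norm = normalize_variant(call, self.REF)
        assert (norm.pos, norm.ref, norm.alt) == (11, "T", "A")

    def test_reference_mismatch_is_error(self):
        with pytest.raises(ConsistencyError):
            normalize_variant(VariantCall("MU", "chr1", 1, "T", "C"), self.REF)

    def test_idempotent_and_matches_enumeration_oracle(self, rng):
        """Randomized homopolymer/tandem contexts against the exhaustive
        enumeration of equivalent representations."""
        for _ in range(150):
            unit = "".join(rng.choice(list("ACGT"),
                                      size=int(rng.integers(1, 4))))
            contig = ("".join(rng.choice(list("ACGT"), size=6))
                      + unit * int(rng.integers(2, 6))
                      + "".join(rng.choice(list("ACGT"), size=6)))
            pos = int(rng.integers(2, len(contig) - 4))
            kind = rng.integers(3)
            if kind == 0:  # deletion written with an anchor base
                rlen = int(rng.integers(2, 4))
                ref = contig[pos - 1 : pos - 1 + rlen]
                alt = ref[0]
            elif kind == 1:  # insertion
                ref = contig[pos - 1]
                alt = ref + "".join(rng.choice(list("ACGT"),
                                               size=int(rng.integers(1, 3))))
            else:  # MNV with possibly shared context
                ref = contig[pos - 1 : pos + 1]
                alt = ref[0] + ("A" if ref[1] != "A" else "C")
            if ref == alt:
                continue
            call = VariantCall("MU", "c", pos, ref, alt)
            norm = normalize_variant(call, {"c": contig})
            again = normalize_variant(norm, {"c": contig})
            assert (again.pos, again.ref, again.alt) == (norm.pos, norm.ref, norm.alt)
            expect = oracle_normalize(contig, pos, ref, alt)
            assert (norm.pos, norm.ref, norm.alt) == expect


class TestMergeCallers:
    def test_priority_caller_depths_win(self):
        callsets = {
            ("MU", "heart"): [VariantCall("MU", "chr1", 100, "A", "G",
                                          ref_depth=10, alt_depth=5)],
            ("HC", "heart"): [VariantCall("HC", "chr1", 100, "A", "G",
                                          ref_depth=12, alt_depth=4)],
        }
        (cv,) = merge_callers(callsets, priority=["MU", "HC"])
        assert cv.depths["heart"] == (10, 5)
        assert cv.af("heart") == pytest.approx(5 / 15)
        assert cv.supporting_callers["heart"] == {"MU", "HC"}

    def test_fallback_to_next_priority(self):
        callsets = {
            ("MU", "heart"): [],
            ("HC", "heart"): [VariantCall("HC", "chr1", 100, "A", "G",
                                          ref_depth=12, alt_depth=4)],
        }
        (cv,) = merge_callers(callsets, priority=["MU", "HC"])
        assert cv.depths["heart"] == (12, 4)

    def test_zero_alt_record_measures_but_does_not_support(self):
        callsets = {
            ("MU", "heart"): [VariantCall("MU", "chr1", 100, "A", "G",
                                          ref_depth=30, alt_depth=0)],
        }
        (cv,) = merge_callers(callsets, priority=["MU"])
        assert cv.supporting_callers["heart"] == set()
        assert cv.af("heart") == 0.0

    def test_empty_input(self):
        assert merge_callers({("MU", "heart"): []}, ["MU"]) == []

    def test_unknown_caller_is_config_error(self):
        with pytest.raises(ConfigError):
            merge_callers({("XX", "heart"): []}, priority=["MU"])


class TestConfidenceFilters:
    def test_single_caller_removed(self):
        cv = make_cv([0.3, 0.0, 0.0], depths=[(7, 3), (6, 0), (7, 0)],
                     callers=[{"LF"}, set(), set()])
        assert apply_confidence_filters([cv]) == []

    def test_passing_variant_retained(self):
        cv = make_cv([0.3, 0.0, 0.0], depths=[(7, 3), (6, 0), (7, 0)],
                     callers=[{"MU", "HC"}, set(), set()])
        assert apply_confidence_filters([cv]) == [cv]

    def test_low_depth_tissue_removes(self):
        cv = make_cv([0.75, 0.0, 0.0], depths=[(1, 3), (6, 0), (7, 0)],
                     callers=[{"MU", "HC"}, set(), set()])
        assert apply_confidence_filters([cv]) == []

    def test_unmeasured_depth_fails_by_default(self):
        cv = make_cv([0.3, None, 0.0], depths=[(7, 3), None, (7, 0)],
                     callers=[{"MU", "HC"}, set(), set()])
        assert apply_confidence_filters([cv]) == []
        assert apply_confidence_filters(
            [cv], unmeasured_depth_passes=True) == [cv]

    def test_monotone_in_thresholds(self, rng):
        variants = []
        for _ in range(200):
            depths = [(int(rng.integers(0, 10)), int(rng.integers(0, 4)))
                      for _ in TISSUES]
            callers = [set(np.random.default_rng(rng.integers(1 << 16))
                           .choice(["MU", "HC", "LF"],
                                   size=rng.integers(0, 4), replace=False))
                       for _ in TISSUES]
            afs = [a / max(1, a + r) for r, a in depths]
            variants.append(make_cv(afs, depths=depths, callers=callers))
        prev = None
        for mc in (1, 2, 3):
            kept = {id(v) for v in apply_confidence_filters(
                variants, min_callers=mc)}
            if prev is not None:
                assert kept <= prev
            prev = kept
        prev = None
        for md in (3, 5, 7):
            kept = {id(v) for v in apply_confidence_filters(
                variants, min_depth_per_tissue=md)}
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestKnownAndSpecificity:
    def test_exclude_known_partition(self):
        a = make_cv([0.3, 0.0, 0.0])
        b = make_cv([0.3, 0.0, 0.0], ref="C", alt="T")
        novel, known = exclude_known([a, b], [{("chr1", 100, "A", "G")}])
        assert novel == [b] and known == [a] and a.known

    def test_empty_known_sets_all_novel(self):
        a = make_cv([0.3, 0.2, 0.1])
        novel, known = exclude_known([a], [])
        assert novel == [a] and known == []

    def test_heart_specific(self):
        v = make_cv([0.3, 0.0, 0.0])
        classify_tissue_specificity([v], TISSUES)
        assert v.specificity == "tissue-specific:heart"

    def test_common_variant(self):
        v = make_cv([0.3, 0.2, 0.1])
        classify_tissue_specificity([v], TISSUES)
        assert v.specificity == "common"

    def test_unmeasured_counts_as_clear(self):
        v = make_cv([0.3, None, 0.0])
        classify_tissue_specificity([v], TISSUES)
        assert v.specificity == "tissue-specific:heart"

    def test_known_variant_cannot_be_tissue_specific_but_can_be_common(self):
        v = make_cv([0.3, 0.0, 0.0], known=True)
        w = make_cv([0.3, 0.2, 0.1], known=True)
        classify_tissue_specificity([v, w], TISSUES)
        assert v.specificity == "other"
        assert w.specificity == "common"

    def test_labels_partition(self, rng):
        variants = []
        for _ in range(100):
            afs = [[0.0, 0.2, None][int(rng.integers(3))] for _ in TISSUES]
            v = make_cv(afs, known=bool(rng.random() < 0.3))
            variants.append(v)
        classify_tissue_specificity(variants, TISSUES)
        assert all(v.specificity is not None for v in variants)


class TestSpectrumAndRegions:
    def test_collapse(self):
        vs = [make_cv([0.1, 0, 0], ref=r, alt=a)
              for r, a in (("A", "G"), ("T", "C"), ("C", "T"))]
        spec = conversion_spectrum(vs)
        assert spec.counts_6["A>G/T>C"] == 2
        assert spec.counts_6["C>T/G>A"] == 1
        assert spec.total == 3

    def test_empty_spectrum(self):
        spec = conversion_spectrum([])
        assert spec.total == 0 and set(spec.counts_6) == set(COLLAPSED_LABELS)

    def test_indel_is_type_error(self):
        with pytest.raises(TypeError):
            conversion_spectrum([make_cv([0.1, 0, 0], ref="AT", alt="A")])

    def test_complement_symmetry(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        pairs = []
        for _ in range(60):
            r, a = rng.choice(list("ACGT"), size=2, replace=False)
            pairs.append((str(r), str(a)))
        direct = conversion_spectrum(
            [make_cv([0.1, 0, 0], ref=r, alt=a) for r, a in pairs])
        flipped = conversion_spectrum(
            [make_cv([0.1, 0, 0], ref=comp[r], alt=comp[a]) for r, a in pairs])
        assert direct.counts_6 == flipped.counts_6

    def test_region_annotation_and_rna_filter(self):
        ann = RegionAnnotation([("chr1", 90, 110, "exonic")])
        inside = make_cv([0.1, 0, 0])  # pos 100
        outside = make_cv([0.1, 0, 0])
        outside.pos = 500
        out = annotate_region([inside, outside], ann, rna_mode=False)
        assert inside.region_class == "exonic"
        assert outside.region_class == "other"
        assert len(out) == 2
        out = annotate_region([inside, outside], ann, rna_mode=True)
        assert out == [inside]
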