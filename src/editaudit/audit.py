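"""Multi-caller, multi-tissue variant auditing.

Per-caller call sets from three tissues of one individual are normalized,
merged on the (chrom, pos, ref, alt) key, passed through the confidence
filters (>= 2 callers, >= 5 reads per tissue, >= 2 alternative reads in
total), partitioned against known-variant sets, and classified as common
(allele frequency > 0 in every tissue, evaluated before known-variant
exclusion) or tissue-specific (AF > 0 in exactly one tissue and 0 or
unmeasured elsewhere, evaluated on the novel pool).

Depths and frequencies for a tissue come from the highest-priority caller
that reports them there (WGS priority MU > HC > LF/SC; RNA PL > HC > ST);
a tissue with no reported depth is "unmeasured", which is distinct from a
measured zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigError, ConsistencyError
from .io_formats import VariantCall

logger = logging.getLogger("editaudit")

WGS_CALLER_PRIORITY = ("MU", "HC", "LF", "SC")
RNA_CALLER_PRIORITY = ("PL", "HC", "ST")

#: the 12 ordered substitutions and their strand-collapsed 6 classes
ORDERED_SUBSTITUTIONS = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)
COLLAPSED_PAIRS = (
    ("A>G", "T>C"), ("A>C", "T>G"), ("A>T", "T>A"),
    ("C>T", "G>A"), ("C>G", "G>C"), ("C>A", "G>T"),
)
COLLAPSED_LABELS = tuple(f"{a}/{b}" for a, b in COLLAPSED_PAIRS)
_COLLAPSE = {sub: f"{a}/{b}" for a, b in COLLAPSED_PAIRS for sub in (a, b)}


@dataclass
class ConsensusVariant:
    """A normalized variant with per-tissue caller support and depths."""

    chrom: str
    pos: int
    ref: str
    alt: str
    supporting_callers: dict[str, set[str]] = field(default_factory=dict)
    depths: dict[str, tuple[int, int] | None] = field(default_factory=dict)
    allele_frequency: dict[str, float | None] = field(default_factory=dict)
    known: bool = False
    region_class: str | None = None
    specificity: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def af(self, tissue: str) -> float | None:
        """Allele frequency in a tissue, ``None`` when unmeasured."""
        return self.allele_frequency.get(tissue)

    def total_depth(self, tissue: str) -> int | None:
        d = self.depths.get(tissue)
        return None if d is None else d[0] + d[1]


# ---------------------------------------------------------------------------
# normalization (left-align + parsimony, re-implementing the usual
# bcftools/vt algorithm so the package has no external binary dependency)
# ---------------------------------------------------------------------------

def normalize_variant(call: VariantCall, reference: Mapping[str, str]) -> VariantCall:
    """Left-align and make parsimonious one variant against the reference.

    Shared trailing bases are trimmed (extending left through the
    reference when an allele empties), then shared leading bases are
    trimmed keeping a single anchor base.  SNVs are fixed points; the
    operation is idempotent.
    """
    contig = reference.get(call.chrom)
    if contig is None:
        raise ConsistencyError(f"unknown contig {call.chrom!r}")
    pos, ref, alt = call.pos, call.ref, call.alt
    if contig[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ConsistencyError(
            f"{call.chrom}:{pos} REF {ref!r} does not match reference "
            f"{contig[pos - 1 : pos - 1 + len(ref)]!r}"
        )
    # trailing trim, left-extending before an allele would empty; a
    # variant pinned at the contig start keeps its shared trailing base
    while ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        if len(ref) == 1 or len(alt) == 1:
            if pos == 1:
                break
            pos -= 1
            base = contig[pos - 1]
            ref, alt = base + ref, base + alt
        else:
            ref, alt = ref[:-1], alt[:-1]
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (pos, ref, alt) == (call.pos, call.ref, call.alt):
        return call
    return VariantCall(
        caller_id=call.caller_id, chrom=call.chrom, pos=pos, ref=ref, alt=alt,
        ref_depth=call.ref_depth, alt_depth=call.alt_depth,
        allele_frequency=call.allele_frequency,
    )


# ---------------------------------------------------------------------------
# merging and filtering
# ---------------------------------------------------------------------------

def merge_callers(
    callsets: Mapping[tuple[str, str], Sequence[VariantCall]],
    priority: Sequence[str],
) -> list[ConsensusVariant]:
    """Merge per-(caller, tissue) call sets into consensus variants.

    ``callsets`` maps (caller_id, tissue) to normalized calls.  For each
    variant key, per-tissue depths/frequencies come from the
    highest-priority caller reporting them in that tissue.  A caller
    *supports* a variant in a tissue when its record carries evidence for
    the alternative allele (alt depth > 0, AF > 0, or no measurements at
    all — a bare call); cohort-mode records with zero alternative reads
    contribute a measured AF of 0 but no support.
    """
    priority = list(priority)
    tissues: list[str] = []
    for caller, tissue in callsets:
        if caller not in priority:
            raise ConfigError(f"caller {caller!r} not in priority order {priority}")
        if tissue not in tissues:
            tissues.append(tissue)

    merged: dict[tuple[str, int, str, str], ConsensusVariant] = {}
    # records per key/tissue keyed by caller for the priority lookup
    records: dict[tuple, dict[str, dict[str, VariantCall]]] = {}
    order: list[tuple] = []
    for (caller, tissue), calls in callsets.items():
        for call in calls:
            key = call.key
            if key not in merged:
                merged[key] = ConsensusVariant(*key)
                records[key] = {}
                order.append(key)
            per_tissue = records[key].setdefault(tissue, {})
            per_tissue[caller] = call
            if _supports_alt(call):
                merged[key].supporting_callers.setdefault(tissue, set()).add(caller)

    for key in order:
        cv = merged[key]
        for tissue in tissues:
            cv.supporting_callers.setdefault(tissue, set())
            cv.depths[tissue] = None
            cv.allele_frequency[tissue] = None
            by_caller = records[key].get(tissue, {})
            for caller in priority:
                call = by_caller.get(caller)
                if call and call.ref_depth is not None and call.alt_depth is not None:
                    cv.depths[tissue] = (call.ref_depth, call.alt_depth)
                    total = call.ref_depth + call.alt_depth
                    cv.allele_frequency[tissue] = (
                        call.alt_depth / total if total > 0 else None
                    )
                    break
            if cv.depths[tissue] is None:
                # no depth source: fall back to a reported AF by priority
                for caller in priority:
                    call = by_caller.get(caller)
                    if call and call.allele_frequency is not None:
                        cv.allele_frequency[tissue] = call.allele_frequency
                        break
    out = [merged[k] for k in order]
    logger.info("merge_callers: %d calls -> %d consensus variants",
                sum(len(c) for c in callsets.values()), len(out))
    return out


def _supports_alt(call: VariantCall) -> bool:
    if call.alt_depth is not None:
        return call.alt_depth > 0
    if call.allele_frequency is not None:
        return call.allele_frequency > 0
    return True  # bare call: the caller asserted the allele exists


def apply_confidence_filters(
    variants: Sequence[ConsensusVariant],
    min_callers: int = 2,
    min_depth_per_tissue: int = 5,
    min_alt_total: int = 2,
    unmeasured_depth_passes: bool = False,
) -> list[ConsensusVariant]:
    """Keep variants meeting the three confidence rules.

    A variant is retained iff (1) at least ``min_callers`` callers support
    it in at least one tissue, (2) every tissue's total depth is at least
    ``min_depth_per_tissue`` (an unmeasured tissue fails unless
    ``unmeasured_depth_passes``), and (3) alternative-allele reads summed
    over all tissues reach ``min_alt_total``.
    """
    kept = []
    for v in variants:
        callers_ok = any(len(s) >= min_callers
                         for s in v.supporting_callers.values())
        depth_ok = True
        for tissue in v.depths:
            total = v.total_depth(tissue)
            if total is None:
                if not unmeasured_depth_passes:
                    depth_ok = False
                    break
            elif total < min_depth_per_tissue:
                depth_ok = False
                break
        alt_total = sum(d[1] for d in v.depths.values() if d is not None)
        if callers_ok and depth_ok and alt_total >= min_alt_total:
            kept.append(v)
    logger.info("confidence filters: %d in, %d out", len(variants), len(kept))
    return kept


def exclude_known(
    variants: Sequence[ConsensusVariant],
    known_sets: Iterable[Iterable[tuple[str, int, str, str]]],
) -> tuple[list[ConsensusVariant], list[ConsensusVariant]]:
    """Partition variants into (novel, known) against normalized key sets."""
    union: set[tuple[str, int, str, str]] = set()
    for ks in known_sets:
        union |= set(ks)
    novel, known = [], []
    for v in variants:
        v.known = v.key in union
        (known if v.known else novel).append(v)
    logger.info("known-variant exclusion: %d novel, %d known", len(novel), len(known))
    return novel, known


def classify_tissue_specificity(
    filtered: Sequence[ConsensusVariant],
    tissues: Sequence[str],
) -> list[ConsensusVariant]:
    """Label variants as common, tissue-specific:<tissue>, or other.

    Common variants (AF > 0 in every tissue) are identified on the whole
    quality-filtered set, before known-variant exclusion; tissue-specific
    variants are drawn from the novel pool only, requiring AF > 0 in the
    tissue in question and AF = 0 or unmeasured in every other tissue.
    Labels partition the input.
    """
    for v in filtered:
        afs = {t: v.af(t) for t in tissues}
        if all(af is not None and af > 0 for af in afs.values()):
            v.specificity = "common"
            continue
        v.specificity = "other"
        if v.known:
            continue
        carriers = [t for t, af in afs.items() if af is not None and af > 0]
        if len(carriers) == 1:
            rest_clear = all(af is None or af == 0
                             for t, af in afs.items() if t != carriers[0])
            if rest_clear:
                v.specificity = f"tissue-specific:{carriers[0]}"
    counts = pd.Series([v.specificity for v in filtered]).value_counts()
    logger.info("specificity labels: %s", counts.to_dict())
    return list(filtered)


# ---------------------------------------------------------------------------
# spectra, AF distributions, region annotation
# ---------------------------------------------------------------------------

@dataclass
class ConversionSpectrum:
    """Counts of single-nucleotide substitution classes.

    ``counts_12`` covers the 12 ordered substitutions; ``counts_6``
    collapses complementary pairs (A>G with T>C etc.).
    """

    counts_12: dict[str, int]
    counts_6: dict[str, int]
    total: int

    def fractions_6(self) -> dict[str, float]:
        if self.total == 0:
            return {k: 0.0 for k in COLLAPSED_LABELS}
        return {k: c / self.total for k, c in self.counts_6.items()}


def conversion_spectrum(variants: Sequence[ConsensusVariant]) -> ConversionSpectrum:
    """Substitution spectrum of a set of SNVs (indels are a type error)."""
    counts_12 = {s: 0 for s in ORDERED_SUBSTITUTIONS}
    for v in variants:
        if not v.is_snv:
            raise TypeError(f"conversion_spectrum expects SNVs, got {v.key}")
        counts_12[f"{v.ref}>{v.alt}"] += 1
    counts_6 = {label: 0 for label in COLLAPSED_LABELS}
    for sub, n in counts_12.items():
        counts_6[_COLLAPSE[sub]] += n
    return ConversionSpectrum(counts_12, counts_6, sum(counts_12.values()))


def annotate_region(
    variants: Sequence[ConsensusVariant],
    annotation,
    rna_mode: bool = False,
) -> list[ConsensusVariant]:
    """Set each variant's region class; in RNA mode drop unannotated ones."""
    out = []
    for v in variants:
        v.region_class = annotation.classify(v.chrom, v.pos) or "other"
        if rna_mode and v.region_class == "other":
            continue
        out.append(v)
    if rna_mode:
        logger.info("region filter (RNA mode): %d in, %d out", len(variants), len(out))
    return out


def af_distribution(
    variants: Sequence[ConsensusVariant], tissues: Sequence[str]
) -> pd.DataFrame:
    """Long-format per-tissue allele-frequency table for plotting."""
    rows = []
    for v in variants:
        for t in tissues:
            af = v.af(t)
            if af is not None and af > 0:
                rows.append({"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                             "alt": v.alt, "tissue": t, "af": af,
                             "specificity": v.specificity})
    return pd.DataFrame(rows)


def variants_to_table(
    variants: Sequence[ConsensusVariant], tissues: Sequence[str]
) -> pd.DataFrame:
    """Flat audited-variant table (one row per variant)."""
    rows = []
    for v in variants:
        row = {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
               "known": v.known, "region_class": v.region_class,
               "specificity": v.specificity}
        for t in tissues:
            d = v.depths.get(t)
            row[f"af_{t}"] = v.af(t)
            row[f"ref_depth_{t}"] = None if d is None else d[0]
            row[f"alt_depth_{t}"] = None if d is None else d[1]
            row[f"callers_{t}"] = ",".join(sorted(v.supporting_callers.get(t, ())))
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "ConsensusVariant", "ConversionSpectrum",
    "normalize_variant", "merge_callers", "apply_confidence_filters",
    "exclude_known", "classify_tissue_specificity", "conversion_spectrum",
    "annotate_region", "af_distribution", "variants_to_table",
    "WGS_CALLER_PRIORITY", "RNA_CALLER_PRIORITY",
    "ORDERED_SUBSTITUTIONS", "COLLAPSED_LABELS",
]
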