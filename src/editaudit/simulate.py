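"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is deterministic under a fixed seed and returns its data
together with a :class:`SimTruth` record; tests compare pipeline output
to the truth, never to hard-coded numbers.  The generators emulate:

* references with guide-homologous sites planted at a known edit
  distance (valid PAM, requested substitution count);
* per-(caller, tissue) variant call sets with germline, common-somatic
  and tissue-specific variants, caller sensitivity and false positives,
  Poisson depths and binomial allele counts (cohort-mode callers report
  depths in non-carrier tissues, single-sample callers do not);
* amplicon read populations with on-target repair, bystander edits
  (optionally conditional on repair), deletions and substitution-only
  sequencing error;
* junction-count splice tables whose events fall in known rescue
  categories with margins that survive replicate jitter;
* two-condition expression matrices with designated up/down genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError, PlacementError
from .homology import GuideSpec, IUPAC_SETS, reverse_complement
from .io_formats import EVENT_TYPES, SpliceTableRow, VariantCall

_TRANSITION = {"A": "G", "T": "C"}


@dataclass
class PlantedSite:
    contig: str
    pos: int  # 1-based start of the planted 23-mer on the forward strand
    strand: str
    edit_distance: int


@dataclass
class TrueVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str  # germline | common | specific:<tissue>
    conversion_class: str
    af: dict[str, float]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class AmpliconTruth:
    window: str
    wt_window: str
    guide_offset: int
    target_guide_pos: int
    repair_fraction: float
    bystander_spec: dict[int, float]
    conditional_on_repair: bool
    indel_fraction: float
    error_rate: float
    expected_exact_wt: float
    per_read: pd.DataFrame  # repaired, indel flags and per-read bystanders


@dataclass
class SpliceTruth:
    categories: dict[str, str]
    deltas: dict[str, tuple[float, float | None]]


@dataclass
class ExpressionTruth:
    up_genes: list[str]
    down_genes: list[str]
    effect_sd: float
    sd: float


@dataclass
class SimTruth:
    """Ground truth shared by the generators that produced the data."""

    seed: int
    reference: dict[str, str] = field(default_factory=dict)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    germline_variants: list[TrueVariant] = field(default_factory=list)
    common_variants: list[TrueVariant] = field(default_factory=list)
    tissue_variants: list[TrueVariant] = field(default_factory=list)
    known_keys: set[tuple[str, int, str, str]] = field(default_factory=set)
    amplicon: AmpliconTruth | None = None
    splice: SpliceTruth | None = None
    expression: ExpressionTruth | None = None

    @property
    def all_true_variants(self) -> list[TrueVariant]:
        return self.germline_variants + self.common_variants + self.tissue_variants


# ---------------------------------------------------------------------------
# reference with planted guide-homologous sites
# ---------------------------------------------------------------------------

def make_reference(
    seed: int,
    contig_lengths: Mapping[str, int],
    guide: GuideSpec | None = None,
    plant_requests: Sequence[tuple[str, int, str, int]] = (),
) -> tuple[dict[str, str], SimTruth]:
    """Uniform-random contigs with protospacer+PAM copies planted.

    Each request ``(contig, pos, strand, edit_distance)`` embeds, at
    forward positions ``pos..pos+22`` (1-based), a 23-mer that reads
    protospacer+PAM on the requested strand with exactly
    ``edit_distance`` substitutions in the protospacer and a PAM matching
    the guide's IUPAC pattern.  Planted 23-mers may not overlap.
    """
    rng = np.random.default_rng(seed)
    reference = {
        name: "".join(rng.choice(list("ACGT"), size=length))
        for name, length in contig_lengths.items()
    }
    truth = SimTruth(seed=seed, reference=reference)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for contig, pos, strand, k in plant_requests:
        if guide is None:
            raise ParameterError("plant_requests require a guide")
        if k > 6:
            raise ParameterError("requested edit distance must be <= 6")
        site_len = guide.length + len(guide.pam_pattern)
        end = pos + site_len - 1
        if pos < 1 or end > len(reference[contig]):
            raise PlacementError(f"planted site {contig}:{pos} outside contig")
        for s, e in occupied.get(contig, []):
            if pos <= e and end >= s:
                raise PlacementError(f"planted windows overlap at {contig}:{pos}")
        occupied.setdefault(contig, []).append((pos, end))

        proto = list(guide.protospacer)
        subs = rng.choice(guide.length, size=k, replace=False)
        for i in subs:
            proto[i] = rng.choice([b for b in "ACGT" if b != proto[i]])
        pam = "".join(
            rng.choice(sorted(IUPAC_SETS[c])) for c in guide.pam_pattern
        )
        site = "".join(proto) + pam
        if strand == "-":
            site = reverse_complement(site)
        seq = reference[contig]
        reference[contig] = seq[: pos - 1] + site + seq[end:]
        truth.planted_sites.append(PlantedSite(contig, pos, strand, k))
    truth.reference = reference
    return reference, truth


# ---------------------------------------------------------------------------
# variant truth and caller outputs
# ---------------------------------------------------------------------------

def simulate_variant_truth(
    truth: SimTruth,
    tissues: Sequence[str],
    n_specific: Mapping[str, int],
    n_common: int,
    n_germline: int,
    seed: int,
    spectrum: Mapping[str, float] | None = None,
    af_range: tuple[float, float] = (0.2, 0.5),
) -> SimTruth:
    """Plant germline, common-somatic and tissue-specific SNVs.

    Alternative alleles are drawn so that, under a uniform reference
    base composition and the default uniform 6-class collapsed spectrum,
    each collapsed conversion class is equally likely.  Germline keys
    are added to the known-variant set.
    """
    from .audit import COLLAPSED_LABELS, _COLLAPSE  # local to avoid a cycle

    rng = np.random.default_rng(seed)
    if spectrum is None:
        spectrum = {label: 1.0 for label in COLLAPSED_LABELS}
    contigs = list(truth.reference)
    taken: set[tuple[str, int]] = set()

    def draw_site() -> tuple[str, int, str, str, str]:
        while True:
            contig = contigs[rng.integers(len(contigs))]
            pos = int(rng.integers(2, len(truth.reference[contig])))
            if (contig, pos) in taken:
                continue
            taken.add((contig, pos))
            ref = truth.reference[contig][pos - 1]
            alts = [b for b in "ACGT" if b != ref]
            weights = np.array(
                [spectrum[_COLLAPSE[f"{ref}>{a}"]] for a in alts], dtype=float
            )
            alt = str(rng.choice(alts, p=weights / weights.sum()))
            return contig, pos, ref, alt, _COLLAPSE[f"{ref}>{alt}"]

    lo, hi = af_range
    for _ in range(n_germline):
        contig, pos, ref, alt, klass = draw_site()
        af = float(rng.choice([0.5, 1.0]))
        truth.germline_variants.append(
            TrueVariant(contig, pos, ref, alt, "germline", klass,
                        {t: af for t in tissues})
        )
    for _ in range(n_common):
        contig, pos, ref, alt, klass = draw_site()
        truth.common_variants.append(
            TrueVariant(contig, pos, ref, alt, "common", klass,
                        {t: float(rng.uniform(lo, hi)) for t in tissues})
        )
    for tissue in tissues:
        for _ in range(n_specific.get(tissue, 0)):
            contig, pos, ref, alt, klass = draw_site()
            afs = {t: 0.0 for t in tissues}
            afs[tissue] = float(rng.uniform(lo, hi))
            truth.tissue_variants.append(
                TrueVariant(contig, pos, ref, alt, f"specific:{tissue}",
                            klass, afs)
            )
    truth.known_keys |= {v.key for v in truth.germline_variants}
    return truth


@dataclass(frozen=True)
class CallerSpec:
    """One emulated variant caller."""

    caller_id: str
    sensitivity: float
    fp_per_mb: float = 0.0
    cohort: bool = False  # cohort mode reports depths in every tissue

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ParameterError("sensitivity must be in [0, 1]")


def simulate_caller_vcfs(
    truth: SimTruth,
    callers: Sequence[CallerSpec],
    tissues: Sequence[str],
    depth_mean: float,
    seed: int,
) -> dict[tuple[str, str], list[VariantCall]]:
    """Per-(caller, tissue) call sets over the truth's variants.

    Each caller detects a true variant with probability ``sensitivity``
    (one draw per variant for cohort callers, one per carrier tissue for
    single-sample callers).  Depths are Poisson(depth_mean) per tissue,
    alternative reads Binomial(depth, true AF).  Cohort callers emit a
    record in every tissue once detected anywhere, including AF = 0
    records in non-carrier tissues; single-sample callers only report
    carrier tissues.  False positives are uniform over the genome at
    ``fp_per_mb`` with Beta(1, 20) allele frequencies.
    """
    rng = np.random.default_rng(seed)
    callsets: dict[tuple[str, str], list[VariantCall]] = {
        (c.caller_id, t): [] for c in callers for t in tissues
    }
    genome_bp = sum(len(s) for s in truth.reference.values())
    contigs = list(truth.reference)

    def depths_for(af: float) -> tuple[int, int]:
        depth = int(rng.poisson(depth_mean))
        alt = int(rng.binomial(depth, af)) if depth > 0 else 0
        return depth - alt, alt

    for variant in truth.all_true_variants:
        for caller in callers:
            if caller.cohort:
                detected = (rng.random() < caller.sensitivity
                            and any(af > 0 for af in variant.af.values()))
                if not detected:
                    continue
                for tissue in tissues:
                    ref_d, alt_d = depths_for(variant.af[tissue])
                    callsets[(caller.caller_id, tissue)].append(
                        VariantCall(caller.caller_id, variant.chrom,
                                    variant.pos, variant.ref, variant.alt,
                                    ref_depth=ref_d, alt_depth=alt_d)
                    )
            else:
                for tissue in tissues:
                    if variant.af[tissue] <= 0:
                        continue
                    if rng.random() >= caller.sensitivity:
                        continue
                    ref_d, alt_d = depths_for(variant.af[tissue])
                    callsets[(caller.caller_id, tissue)].append(
                        VariantCall(caller.caller_id, variant.chrom,
                                    variant.pos, variant.ref, variant.alt,
                                    ref_depth=ref_d, alt_depth=alt_d)
                    )

    true_positions = {(v.chrom, v.pos) for v in truth.all_true_variants}
    for caller in callers:
        for tissue in tissues:
            n_fp = int(rng.poisson(caller.fp_per_mb * genome_bp / 1e6))
            for _ in range(n_fp):
                contig = contigs[int(rng.integers(len(contigs)))]
                pos = int(rng.integers(1, len(truth.reference[contig]) + 1))
                if (contig, pos) in true_positions:
                    continue
                ref = truth.reference[contig][pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                af = float(rng.beta(1, 20))
                depth = max(1, int(rng.poisson(depth_mean)))
                alt_d = max(1, int(rng.binomial(depth, af)))
                callsets[(caller.caller_id, tissue)].append(
                    VariantCall(caller.caller_id, contig, pos, ref, alt,
                                ref_depth=depth - alt_d, alt_depth=alt_d)
                )
    for calls in callsets.values():
        calls.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return callsets


# ---------------------------------------------------------------------------
# amplicon reads
# ---------------------------------------------------------------------------

def simulate_amplicon_reads(
    n_reads: int,
    window: str,
    guide: GuideSpec,
    guide_offset: int,
    target_guide_pos: int,
    repair_fraction: float,
    bystander_spec: Mapping[int, float] | None,
    conditional_on_repair: bool,
    indel_fraction: float,
    error_rate: float,
    seed: int,
) -> tuple[list[str], SimTruth]:
    """Aligned amplicon reads over a mutant window.

    ``window`` is the pre-repair (mutant) sequence in guide orientation;
    the base at ``target_guide_pos`` and every bystander position must be
    A or T and is converted by the A>G (T>C) transition when edited.
    Repaired reads carry the transition at the target; bystanders occur
    at their per-position fractions, on repaired reads only when
    ``conditional_on_repair``.  Deletion reads lose one base inside the
    protospacer span; sequencing errors are substitution-only.
    """
    from .amplicon import _window_index  # shared frame arithmetic

    rng = np.random.default_rng(seed)
    bystander_spec = dict(bystander_spec or {})
    jt = _window_index(target_guide_pos, guide_offset)
    if not (0 <= jt < len(window)):
        raise ParameterError("target position outside window")
    if window[jt] not in _TRANSITION:
        raise ParameterError("target base must be A or T (adenine editing)")
    bys_idx: dict[int, int] = {}
    for pos, frac in bystander_spec.items():
        j = _window_index(pos, guide_offset)
        if not (0 <= j < len(window)):
            raise ParameterError(f"bystander position {pos} outside window")
        if window[j] not in _TRANSITION:
            raise ParameterError(f"bystander base at {pos} must be A or T")
        if not (0.0 <= frac <= 1.0):
            raise ParameterError("bystander fractions must be in [0, 1]")
        bys_idx[pos] = j

    wt_window = window[:jt] + _TRANSITION[window[jt]] + window[jt + 1 :]
    reads: list[str] = []
    rows = []
    proto_span = range(guide_offset, min(guide_offset + guide.length, len(window)))
    for _ in range(n_reads):
        repaired = rng.random() < repair_fraction
        seq = list(wt_window if repaired else window)
        applied: list[int] = []
        for pos, frac in bystander_spec.items():
            if conditional_on_repair and not repaired:
                continue
            if rng.random() < frac:
                j = bys_idx[pos]
                seq[j] = _TRANSITION[window[j]]
                applied.append(pos)
        for j in range(len(seq)):
            if seq[j] != "-" and rng.random() < error_rate:
                seq[j] = str(rng.choice([b for b in "ACGT" if b != seq[j]]))
        has_indel = rng.random() < indel_fraction
        if has_indel:
            j = int(rng.choice(list(proto_span)))
            seq[j] = "-"
        reads.append("".join(seq))
        rows.append({"repaired": repaired, "indel": has_indel,
                     "bystanders": tuple(applied)})

    expected = (
        repair_fraction
        * (1.0 - indel_fraction)
        * float(np.prod([1.0 - f for f in bystander_spec.values()]))
        * (1.0 - error_rate) ** len(window)
    )
    truth = SimTruth(
        seed=seed,
        amplicon=AmpliconTruth(
            window=window, wt_window=wt_window, guide_offset=guide_offset,
            target_guide_pos=target_guide_pos,
            repair_fraction=repair_fraction,
            bystander_spec=bystander_spec,
            conditional_on_repair=conditional_on_repair,
            indel_fraction=indel_fraction, error_rate=error_rate,
            expected_exact_wt=expected,
            per_read=pd.DataFrame(rows),
        ),
    )
    return reads, truth


# ---------------------------------------------------------------------------
# splice tables
# ---------------------------------------------------------------------------

def simulate_splice_table(
    n_events: int,
    category_mix: Mapping[str, float],
    seed: int,
    n_replicates: int = 3,
) -> tuple[list[SpliceTableRow], list[SpliceTableRow], SimTruth]:
    """Two junction-count tables (treated vs WT, edited vs WT) with known
    rescue categories.

    ``category_mix`` weights the categories rescued, mis-spliced,
    unchanged and not-significant; weights must sum to 1.  Group-mean
    deltas are drawn with >= 0.03 margins from every classification
    boundary so that per-replicate jitter (+/- 0.01) cannot flip a
    label.
    """
    valid = {"rescued", "mis-spliced", "unchanged", "not-significant"}
    if set(category_mix) - valid:
        raise ParameterError(f"unknown categories {set(category_mix) - valid}")
    if abs(sum(category_mix.values()) - 1.0) > 1e-9:
        raise ParameterError("category mix must sum to 1")
    rng = np.random.default_rng(seed)
    cats = list(category_mix)
    probs = np.array([category_mix[c] for c in cats], dtype=float)

    original_rows: list[SpliceTableRow] = []
    edited_rows: list[SpliceTableRow] = []
    truth = SimTruth(seed=seed, splice=SpliceTruth(categories={}, deltas={}))

    for i in range(n_events):
        event_id = f"ev{i:05d}"
        etype = str(rng.choice(EVENT_TYPES))
        category = str(rng.choice(cats, p=probs))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        fdr = float(10.0 ** -rng.uniform(3, 6))
        if category == "rescued":
            o = sign * rng.uniform(0.28, 0.45)
            e = sign * rng.uniform(0.0, abs(o) - 0.15)
        elif category == "mis-spliced":
            o = sign * rng.uniform(0.15, 0.35)
            if rng.random() < 0.5:
                e = -sign * rng.uniform(0.25, 0.40)  # overshoot past the band
            else:
                e = sign * (abs(o) + rng.uniform(0.15, 0.25))  # worse than saline
        elif category == "unchanged":
            o = sign * rng.uniform(0.15, 0.45)
            e = o + rng.uniform(-0.05, 0.05)
        else:  # not-significant
            if rng.random() < 0.5:
                o = sign * rng.uniform(0.15, 0.45)
                fdr = float(rng.uniform(0.02, 0.9))
            else:
                o = sign * rng.uniform(0.0, 0.06)
            e = o + rng.uniform(-0.05, 0.05)
        lo = 0.03 - min(0.0, o, e)
        hi = 0.97 - max(0.0, o, e)
        psi_wt = float(rng.uniform(lo, hi))

        def reps(mean: float) -> list[float]:
            return [float(np.clip(mean + rng.uniform(-0.01, 0.01), 0.0, 1.0))
                    for _ in range(n_replicates)]

        gene = f"gene{i % max(1, n_events // 2):04d}"
        original_rows.append(SpliceTableRow(event_id, gene, etype,
                                            reps(psi_wt + o), reps(psi_wt), fdr))
        edited_rows.append(SpliceTableRow(event_id, gene, etype,
                                          reps(psi_wt + e), reps(psi_wt),
                                          float(10.0 ** -rng.uniform(1, 4))))
        truth.splice.categories[event_id] = category
        truth.splice.deltas[event_id] = (float(o), float(e))
    return original_rows, edited_rows, truth


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def simulate_expression_matrix(
    n_cells_per_condition: int,
    n_genes: int,
    n_up: int,
    n_down: int,
    effect: float,
    seed: int,
    conditions: tuple[str, str] = ("WT", "MUT"),
    sd: float = 0.5,
    cluster: str = "VCM",
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Two-genotype expression matrix with designated up/down genes.

    Baseline log-normalized expression per gene is Normal(mu_g, sd) with
    mu_g ~ Uniform(1, 3), clipped at 0.  In the second (mutant)
    condition the first ``n_up`` truth genes are shifted by
    ``+effect * sd`` and the next ``n_down`` by ``-effect * sd``
    (``effect`` is in units of the within-gene standard deviation).
    Returns (genes x cells matrix, cell metadata, truth).
    """
    if n_up + n_down > n_genes:
        raise ParameterError("n_up + n_down must not exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    cells = [f"{cond}_{i:05d}" for cond in conditions
             for i in range(n_cells_per_condition)]
    cond_labels = np.repeat(list(conditions), n_cells_per_condition)
    mu = rng.uniform(1.0, 3.0, size=n_genes)
    x = rng.normal(mu[:, None], sd, size=(n_genes, 2 * n_cells_per_condition))
    shift = effect * sd
    mutant = cond_labels == conditions[1]
    up = genes[:n_up]
    down = genes[n_up : n_up + n_down]
    x[:n_up, mutant] += shift
    x[n_up : n_up + n_down, mutant] -= shift
    x = np.clip(x, 0.0, None)
    matrix = pd.DataFrame(x, index=genes, columns=cells)
    metadata = pd.DataFrame(
        {"condition": cond_labels, "cluster": cluster}, index=pd.Index(cells, name="cell_id")
    )
    truth = SimTruth(seed=seed, expression=ExpressionTruth(
        up_genes=up, down_genes=down, effect_sd=effect, sd=sd))
    return matrix, metadata, truth


__all__ = [
    "SimTruth", "PlantedSite", "TrueVariant", "CallerSpec",
    "AmpliconTruth", "SpliceTruth", "ExpressionTruth",
    "make_reference", "simulate_variant_truth", "simulate_caller_vcfs",
    "simulate_amplicon_reads", "simulate_splice_table",
    "simulate_expression_matrix",
]
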