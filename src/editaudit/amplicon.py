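"""Editing outcomes from aligned amplicon reads over a target window.

Reads are consumed pre-aligned: every read is a string over {A,C,G,T,-}
of the window's length, where ``-`` marks a deleted base.  The module
computes per-position base fractions (replicates summed before dividing),
the "repaired" fraction (reads exactly matching the wild-type sequence
over the quantification span), bystander frequencies with guide-frame
labels and codon consequences, indel rates, and the
bystander-conditional-on-repair breakdown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .exceptions import ParameterError, PlacementError
from .homology import GuideSpec

logger = logging.getLogger("editaudit")

_ALPHABET = ("A", "C", "G", "T", "-")


# ---------------------------------------------------------------------------
# guide-frame position labels
# ---------------------------------------------------------------------------

def guide_frame_positions(guide: GuideSpec, window_len: int, guide_offset: int) -> list[int]:
    """Guide-frame index for every window position.

    ``guide_offset`` is the 0-based window index of protospacer position 1.
    Protospacer bases are 1..20, the PAM 21..23 (and beyond, counting on),
    upstream bases are negative with -1 immediately 5' of position 1
    (there is no position 0).
    """
    if not (0 <= guide_offset < window_len):
        raise PlacementError("guide_offset outside window")
    labels = []
    for j in range(window_len):
        rel = j - guide_offset
        labels.append(rel + 1 if rel >= 0 else rel)
    return labels


def label_positions(
    guide: GuideSpec, window_ref: str, guide_offset: int
) -> dict[int, str]:
    """Map guide-frame position -> label like ``A_2`` or ``T_-2``.

    The label's base is the window's reference base at that position;
    the index is the guide-frame position (PAM at 21..23).
    """
    frame = guide_frame_positions(guide, len(window_ref), guide_offset)
    return {rel: f"{window_ref[j]}_{rel}" for j, rel in enumerate(frame)}


def _window_index(guide_pos: int, guide_offset: int) -> int:
    """Window index of a guide-frame position (no position 0)."""
    if guide_pos == 0:
        raise ParameterError("guide-frame position 0 does not exist")
    rel = guide_pos - 1 if guide_pos > 0 else guide_pos
    return guide_offset + rel


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

@dataclass
class EditingPileup:
    """Per-position base counts over the amplicon window."""

    window_ref: str
    counts: np.ndarray  # shape (5, window_len) over A,C,G,T,deletion
    n_reads: int
    position_labels: dict[int, str] | None = None

    def fractions(self) -> np.ndarray:
        """Per-position fraction of each base among reads covering it."""
        cov = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(cov > 0, self.counts / cov, 0.0)
        return frac

    def base_fraction(self, guide_pos: int, base: str, guide_offset: int) -> float:
        j = _window_index(guide_pos, guide_offset)
        cov = self.counts[:, j].sum()
        return float(self.counts[_ALPHABET.index(base), j] / cov) if cov else 0.0


def pileup_and_fractions(
    read_groups: Sequence[Sequence[str]] | Sequence[str],
    window_ref: str,
    guide: GuideSpec | None = None,
    guide_offset: int | None = None,
) -> EditingPileup:
    """Sum replicate read groups into one pileup and per-position fractions.

    ``read_groups`` is either a flat list of aligned reads or a list of
    replicate lists; replicate counts are summed before any fraction is
    taken.  Every read must have the window's length (``-`` for deleted
    bases).
    """
    if read_groups and isinstance(read_groups[0], str):
        read_groups = [read_groups]  # type: ignore[list-item]
    n = len(window_ref)
    counts = np.zeros((5, n), dtype=np.int64)
    n_reads = 0
    for group in read_groups:
        for read in group:
            if len(read) != n:
                raise ParameterError(
                    f"read length {len(read)} != window length {n}; "
                    "reads must be pre-aligned"
                )
            n_reads += 1
            for j, base in enumerate(read):
                if base in _ALPHABET:
                    counts[_ALPHABET.index(base), j] += 1
    if n_reads == 0:
        raise ParameterError("empty read set")
    labels = None
    if guide is not None and guide_offset is not None:
        labels = label_positions(guide, window_ref, guide_offset)
    return EditingPileup(window_ref=window_ref, counts=counts, n_reads=n_reads,
                         position_labels=labels)


# ---------------------------------------------------------------------------
# summary metrics
# ---------------------------------------------------------------------------

def repaired_fraction(
    reads: Sequence[str], wt_window: str, span: tuple[int, int] | None = None
) -> float:
    """Fraction of reads exactly wild-type over the quantification span.

    ``span`` is a 0-based half-open window slice; default is the full
    window.  Any bystander, residual mutation or indel inside the span
    disqualifies a read.
    """
    if span is None:
        span = (0, len(wt_window))
    s, e = span
    target = wt_window[s:e]
    hits = sum(1 for r in reads if r[s:e] == target)
    return hits / len(reads) if reads else 0.0


def indel_fraction(reads: Sequence[str]) -> float:
    """Fraction of reads carrying at least one deleted base."""
    return sum(1 for r in reads if "-" in r) / len(reads) if reads else 0.0


def codon_consequence(ref_codon: str, alt_codon: str) -> tuple[str, str, str]:
    """Classify a codon change: (category, ref amino acid, alt amino acid).

    Categories: synonymous, missense, nonsense (gain of stop).
    Translation uses the standard genetic code.
    """
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or set(codon) - set("ACGT"):
            raise ParameterError(f"{codon!r} is not a DNA codon")
    aa_ref = _translate_codon(ref_codon)
    aa_alt = _translate_codon(alt_codon)
    if aa_alt == aa_ref:
        category = "synonymous"
    elif aa_alt == "*":
        category = "nonsense"
    else:
        category = "missense"
    return category, aa_ref, aa_alt


def _translate_codon(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return "*"
    return str(Seq(codon).translate())


@dataclass
class EditingSummary:
    """Headline editing metrics for one amplicon experiment."""

    repaired_fraction: float
    on_target_fraction: float
    bystander_table: dict[str, dict]
    indel_fraction: float
    conditional_bystander: dict[str, tuple[float | None, float | None]]


def conditional_bystander(
    reads: Sequence[str],
    target_guide_pos: int,
    bystander_guide_positions: Sequence[int],
    guide_offset: int,
    edited_base_at_target: str,
    edited_base: Mapping[int, str] | None = None,
    window_ref: str | None = None,
) -> dict[int, tuple[float | None, float | None]]:
    """Bystander frequency among repaired-at-target vs unrepaired reads.

    A read is repaired-at-target when it carries ``edited_base_at_target``
    at the target position; a bystander at position p is observed when
    the read base there differs from the window reference (or equals the
    expected edited base if ``edited_base`` supplies one).  Frequencies of
    an empty partition are ``None`` (undefined), not 0.
    """
    jt = _window_index(target_guide_pos, guide_offset)
    repaired = [r for r in reads if r[jt] == edited_base_at_target]
    unrepaired = [r for r in reads if r[jt] != edited_base_at_target]
    out: dict[int, tuple[float | None, float | None]] = {}
    for p in bystander_guide_positions:
        j = _window_index(p, guide_offset)

        def freq(group: list[str]) -> float | None:
            if not group:
                return None
            if edited_base and p in edited_base:
                n = sum(1 for r in group if r[j] == edited_base[p])
            else:
                if window_ref is None:
                    raise ParameterError(
                        "window_ref required when no edited_base map is given"
                    )
                n = sum(1 for r in group if r[j] not in ("-", window_ref[j]))
            return n / len(group)

        out[p] = (freq(repaired), freq(unrepaired))
    return out


def summarize_editing(
    reads: Sequence[str],
    window_ref: str,
    wt_window: str,
    guide: GuideSpec,
    guide_offset: int,
    target_guide_pos: int,
    codon_frame: tuple[int, int] | None = None,
    span: tuple[int, int] | None = None,
    min_frequency: float = 0.0,
) -> EditingSummary:
    """End-to-end editing summary for one read population.

    ``window_ref`` is the pre-editing (mutant) reference over the window,
    ``wt_window`` the wild-type sequence the repair should restore.
    Bystanders are counted at non-PAM positions where reads differ from
    both the mutant reference and the wild-type expectation only at that
    position; labels follow the guide frame.  ``codon_frame`` gives
    (window index of a codon start, strand is always the guide strand)
    for consequence calls.  ``min_frequency`` masks positions whose
    edited-read fraction is at or below a noise floor (default 0: the
    raw metric).
    """
    if len(window_ref) != len(wt_window):
        raise ParameterError("window_ref and wt_window lengths differ")
    jt = _window_index(target_guide_pos, guide_offset)
    wt_base = wt_window[jt]
    repaired = repaired_fraction(reads, wt_window, span=span)
    on_target = sum(1 for r in reads if r[jt] == wt_base) / len(reads)
    indels = indel_fraction(reads)

    labels = label_positions(guide, window_ref, guide_offset)
    frame = guide_frame_positions(guide, len(window_ref), guide_offset)
    bystanders: dict[str, dict] = {}
    n_reads = len(reads)
    for j, rel in enumerate(frame):
        if j == jt or 21 <= rel <= 20 + len(guide.pam_pattern):
            continue  # PAM positions excluded from bystander counting
        n_edited = sum(1 for r in reads if r[j] not in ("-", wt_window[j]))
        if n_edited == 0 or n_edited / n_reads <= min_frequency:
            continue  # below the configured noise floor
        entry: dict = {"label": labels[rel], "frequency": n_edited / n_reads}
        if codon_frame is not None:
            c0, _ = codon_frame
            codon_start = c0 + 3 * ((j - c0) // 3)
            if 0 <= codon_start and codon_start + 3 <= len(window_ref):
                alt_counts: dict[str, int] = {}
                for r in reads:
                    if r[j] not in ("-", wt_window[j]):
                        alt_counts[r[j]] = alt_counts.get(r[j], 0) + 1
                alt = max(alt_counts, key=alt_counts.get)
                ref_codon = wt_window[codon_start : codon_start + 3]
                alt_codon = (ref_codon[: j - codon_start] + alt
                             + ref_codon[j - codon_start + 1 :])
                cat, aa_ref, aa_alt = codon_consequence(ref_codon, alt_codon)
                entry.update(consequence=cat, aa_ref=aa_ref, aa_alt=aa_alt)
        bystanders[labels[rel]] = entry

    cond_positions = [rel for j, rel in enumerate(frame)
                      if labels[rel] in bystanders]
    cond = conditional_bystander(
        reads, target_guide_pos, cond_positions, guide_offset,
        edited_base_at_target=wt_base, window_ref=wt_window,
    )
    cond_by_label = {labels[p]: v for p, v in cond.items()}
    return EditingSummary(
        repaired_fraction=repaired,
        on_target_fraction=on_target,
        bystander_table=bystanders,
        indel_fraction=indels,
        conditional_bystander=cond_by_label,
    )


__all__ = [
    "EditingPileup", "EditingSummary",
    "guide_frame_positions", "label_positions", "pileup_and_fractions",
    "repaired_fraction", "indel_fraction", "codon_consequence",
    "conditional_bystander", "summarize_editing",
]
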