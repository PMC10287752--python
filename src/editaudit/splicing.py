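"""Percent-spliced-in (PSI) rescue classification.

Alternative-splicing events come from two pairwise junction-count
comparisons against wild-type: mutant+saline vs WT ("original") and
mutant+base-editor vs WT ("edited").  Group-mean PSI differences relative
to WT give dPSI_original (o) and dPSI_edited (e); events passing the
significance gate (FDR < 0.01 and |o| > 0.1 on the original comparison)
are classified:

* unchanged   if |o - e| < 0.1 (the ddPSI band);
* otherwise, for o > 0: rescued if 0 <= e < o, or -0.2 <= e <= 0.2 and
  e < o; mis-spliced if e >= 0 and e > o, or e < -0.2 (overshoot);
* the o < 0 case is the mirror image.

At the exact overshoot boundary (e = -0.2 for o > 0, e = 0.2 for o < 0)
the inclusive band takes precedence, so the three categories partition
the (o, e) plane wherever |o| > the ddPSI band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_formats import SpliceTableRow

logger = logging.getLogger("editaudit")

CATEGORIES = ("rescued", "mis-spliced", "unchanged", "not-significant")


@dataclass
class SpliceEventRecord:
    """One splicing event with deltas relative to WT and its category."""

    event_id: str
    gene: str
    event_type: str
    psi_wt: float
    psi_original: float
    psi_edited: float | None
    fdr: float
    significant: bool = False
    category: str | None = None

    @property
    def delta_psi_original(self) -> float:
        return self.psi_original - self.psi_wt

    @property
    def delta_psi_edited(self) -> float | None:
        return None if self.psi_edited is None else self.psi_edited - self.psi_wt

    @property
    def delta_delta_psi(self) -> float | None:
        e = self.delta_psi_edited
        return None if e is None else abs(self.delta_psi_original - e)


def compute_deltas(
    original_vs_wt: Sequence[SpliceTableRow],
    edited_vs_wt: Sequence[SpliceTableRow] | None = None,
) -> list[SpliceEventRecord]:
    """Build event records from the two pairwise comparisons.

    In each table group 1 is the treatment (saline- or editor-treated
    mutant) and group 2 is WT; events are matched across tables by
    (event_id, event_type).  Group means use the non-missing replicate
    PSI values.  The FDR and the WT baseline come from the original
    comparison; events absent from the edited table carry no edited
    delta.
    """
    edited_map = {}
    if edited_vs_wt:
        edited_map = {(r.event_id, r.event_type): r for r in edited_vs_wt}
    records = []
    for row in original_vs_wt:
        psi_wt = row.mean_psi(2)
        psi_orig = row.mean_psi(1)
        edited = edited_map.get((row.event_id, row.event_type))
        records.append(
            SpliceEventRecord(
                event_id=row.event_id,
                gene=row.gene,
                event_type=row.event_type,
                psi_wt=psi_wt,
                psi_original=psi_orig,
                psi_edited=edited.mean_psi(1) if edited else None,
                fdr=row.fdr,
            )
        )
    logger.info("compute_deltas: %d events (%d with edited deltas)",
                len(records), sum(r.psi_edited is not None for r in records))
    return records


def significance_gate(
    records: Sequence[SpliceEventRecord],
    fdr_max: float = 0.01,
    min_abs_delta: float = 0.1,
) -> list[SpliceEventRecord]:
    """Flag events with FDR < fdr_max and |dPSI_original| > min_abs_delta."""
    for r in records:
        r.significant = (r.fdr < fdr_max
                         and abs(r.delta_psi_original) > min_abs_delta)
    n_sig = sum(r.significant for r in records)
    logger.info("significance gate: %d of %d events significant",
                n_sig, len(records))
    return list(records)


def classify_category(
    o: float, e: float, unchanged_band: float = 0.1, overshoot_band: float = 0.2
) -> str:
    """Category of one significant event from its two deltas."""
    if abs(o - e) < unchanged_band:
        return "unchanged"
    if o > 0:
        if (0 <= e < o) or (-overshoot_band <= e <= overshoot_band and e < o):
            return "rescued"
        return "mis-spliced"
    if (o < e <= 0) or (-overshoot_band <= e <= overshoot_band and e > o):
        return "rescued"
    return "mis-spliced"


def classify_rescue(
    records: Sequence[SpliceEventRecord],
    unchanged_band: float = 0.1,
    overshoot_band: float = 0.2,
) -> list[SpliceEventRecord]:
    """Assign rescued/mis-spliced/unchanged to every significant event.

    Non-significant events get ``not-significant``; significant events
    without an edited delta keep ``category=None`` with a warning.
    """
    n_missing = 0
    for r in records:
        if not r.significant:
            r.category = "not-significant"
            continue
        e = r.delta_psi_edited
        if e is None:
            r.category = None
            n_missing += 1
            continue
        r.category = classify_category(r.delta_psi_original, e,
                                       unchanged_band, overshoot_band)
    if n_missing:
        logger.warning("%d significant events lack an edited delta; "
                       "category left unset", n_missing)
    return list(records)


def intersect_events(
    *comparisons: Sequence[SpliceEventRecord],
) -> pd.DataFrame:
    """Events significant in every comparison, with each comparison's delta.

    Event identity is (event_id, event_type); multiple events per gene
    are preserved.
    """
    if len(comparisons) < 2:
        raise ValueError("need at least two comparisons")
    keysets = []
    maps = []
    for comp in comparisons:
        m = {(r.event_id, r.event_type): r for r in comp if r.significant}
        maps.append(m)
        keysets.append(set(m))
    shared = set.intersection(*keysets)
    rows = []
    for key in sorted(shared):
        base = maps[0][key]
        row = {"event_id": key[0], "event_type": key[1], "gene": base.gene}
        for i, m in enumerate(maps, 1):
            row[f"delta_psi_{i}"] = m[key].delta_psi_original
        rows.append(row)
    return pd.DataFrame(rows)


def category_counts(records: Sequence[SpliceEventRecord]) -> pd.DataFrame:
    """Category x event-type count table (the per-genotype summary)."""
    df = pd.DataFrame(
        [{"category": r.category, "event_type": r.event_type}
         for r in records if r.category and r.category != "not-significant"]
    )
    if df.empty:
        return pd.DataFrame()
    return df.value_counts().unstack(fill_value=0)


def records_to_table(records: Sequence[SpliceEventRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "event_id": r.event_id, "gene": r.gene, "event_type": r.event_type,
            "psi_wt": r.psi_wt, "psi_original": r.psi_original,
            "psi_edited": r.psi_edited,
            "delta_psi_original": r.delta_psi_original,
            "delta_psi_edited": r.delta_psi_edited,
            "delta_delta_psi": r.delta_delta_psi,
            "fdr": r.fdr, "significant": r.significant, "category": r.category,
        } for r in records]
    )


__all__ = [
    "SpliceEventRecord", "CATEGORIES",
    "compute_deltas", "significance_gate", "classify_category",
    "classify_rescue", "intersect_events", "category_counts",
    "records_to_table",
]
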