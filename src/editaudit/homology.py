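"""Constrained guide-homology scanning around variant positions.

For each variant, a window of +/-30 bases around its start site is scanned
on both strands for the best alignment of the guide protospacer followed
immediately by its PAM.  The score is an edit distance: substitutions plus
single-base gap events (at most two events per alignment).  In ``strict``
mode placements whose PAM does not match the IUPAC pattern are
inadmissible; in ``lenient`` mode PAM mismatches are counted into the
distance instead.  Gaps are never allowed inside the PAM.

The admissible alignment set is defined precisely as:

* the protospacer is aligned gap-to-gap against a window segment whose
  3' end abuts the PAM placement;
* a gap event is a single unaligned base in either sequence; events in
  the same sequence may not be adjacent (no multi-base gaps);
* at most ``max_gap_events`` (default 2) events per alignment;
* window-side gap events (bulges) must fall strictly inside the
  protospacer span; protospacer-side events may include terminal bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from scipy import stats

from .exceptions import CoordinateError, ParameterError

logger = logging.getLogger("editaudit")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC code -> set of concrete bases it matches (N matches everything).
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideSpec:
    """A guide RNA target: 20-nt protospacer plus 3' PAM pattern.

    Position numbering follows the guide frame: protospacer bases are
    1..20 (5'->3'), the PAM occupies 21..23, and bases upstream of
    position 1 carry negative indices (-1 is immediately 5' of 1; there
    is no position 0).  ``seed_length`` counts PAM-proximal protospacer
    bases (the seed region is positions 20-seed_length+1 .. 20).
    """

    protospacer: str
    pam_pattern: str = "NGG"
    seed_length: int = 12

    def __post_init__(self) -> None:
        if set(self.protospacer) - set("ACGT"):
            raise ValueError("protospacer must be plain ACGT")
        if not self.protospacer:
            raise ValueError("empty protospacer")
        for code in self.pam_pattern:
            if code not in IUPAC_SETS:
                raise ValueError(f"{code!r} is not an IUPAC DNA code")
        if not (1 <= self.seed_length <= len(self.protospacer)):
            raise ValueError("seed_length must be in 1..len(protospacer)")

    @property
    def length(self) -> int:
        return len(self.protospacer)

    @property
    def seed_positions(self) -> range:
        """Guide-frame positions (1-based) of the seed region."""
        return range(self.length - self.seed_length + 1, self.length + 1)

    def pam_matches(self, seq: str) -> bool:
        return len(seq) == len(self.pam_pattern) and all(
            b in IUPAC_SETS[c] for b, c in zip(seq, self.pam_pattern)
        )

    def pam_mismatches(self, seq: str) -> int:
        return sum(b not in IUPAC_SETS[c] for b, c in zip(seq, self.pam_pattern))


@dataclass(frozen=True)
class Window:
    """A reference window with its 1-based inclusive genomic span."""

    chrom: str
    start: int
    end: int
    seq: str


def extract_window(
    reference: Mapping[str, str], chrom: str, pos: int, flank: int = 30
) -> Window:
    """Clip ``[pos-flank, pos+flank]`` (1-based inclusive) to contig bounds."""
    if chrom not in reference:
        raise CoordinateError(f"unknown contig {chrom!r}")
    contig = reference[chrom]
    if not (1 <= pos <= len(contig)):
        raise CoordinateError(f"{chrom}:{pos} outside contig of length {len(contig)}")
    start = max(1, pos - flank)
    end = min(len(contig), pos + flank)
    return Window(chrom=chrom, start=start, end=end, seq=contig[start - 1 : end])


@dataclass
class HomologyResult:
    """Best admissible protospacer+PAM alignment within one window."""

    variant_key: tuple | None
    window: Window | None
    best_strand: str | None
    best_offset: int | None
    edit_distance: int | None
    mismatches: int | None
    gaps: int | None
    alignment: tuple[str, str] | None
    mode: str = "strict"
    seed_edits: int | None = None

    @property
    def alignable(self) -> bool:
        return self.edit_distance is not None


# ---------------------------------------------------------------------------
# scanner core
# ---------------------------------------------------------------------------

def _mismatch_prefix(proto: str, seq: str) -> np.ndarray:
    """Pre[k, o] = substitutions when the first k protospacer bases sit at
    scanned-sequence offset o (position i maps to seq index i + o)."""
    lp, n = len(proto), len(seq)
    pad = lp + 2
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    parr = np.frombuffer(proto.encode(), dtype=np.uint8)
    big = np.full((lp, n + 2 * pad), 1000, dtype=np.int64)
    for i in range(lp):
        # entry at column (o + pad) compares proto[i] with seq[i + o];
        # valid offsets satisfy 0 <= i + o <= n - 1
        seg = (arr != parr[i]).astype(np.int64)
        big[i, -i + pad : n - i + pad] = seg
    pre = np.zeros((lp + 1, n + 2 * pad), dtype=np.int64)
    np.cumsum(big, axis=0, out=pre[1:])
    return pre  # index as pre[k, o + pad]; pad == lp + 2


def _pam_costs(guide: GuideSpec, seq: str) -> np.ndarray:
    """PAM mismatch count for every placement p (PAM at seq[p:p+len])."""
    lm = len(guide.pam_pattern)
    n = len(seq)
    costs = np.full(n + 1, 1000, dtype=np.int64)
    for p in range(0, n - lm + 1):
        costs[p] = guide.pam_mismatches(seq[p : p + lm])
    return costs


def _gap_configs(lp: int, max_gap_events: int, seed_start: int | None):
    """Enumerate admissible gap configurations.

    Yields ``(n_gaps, dels, inss)`` where ``dels`` are 0-based protospacer
    indices left unaligned and ``inss`` are bulge slots (a window base
    inserted between protospacer positions m-1 and m, 1 <= m <= lp-1).
    ``seed_start`` (0-based) forbids gaps at/after that index when the
    seed-gap restriction is on.
    """

    def del_ok(k: int) -> bool:
        return seed_start is None or k < seed_start

    def ins_ok(m: int) -> bool:
        # bulge between m-1 and m touches the seed once m > seed_start
        return seed_start is None or m <= seed_start

    yield (0, (), ())
    if max_gap_events < 1:
        return
    for k in range(lp):
        if del_ok(k):
            yield (1, (k,), ())
    for m in range(1, lp):
        if ins_ok(m):
            yield (1, (), (m,))
    if max_gap_events < 2:
        return
    for k1 in range(lp):
        for k2 in range(k1 + 2, lp):  # adjacent deletions form a 2-base gap
            if del_ok(k1) and del_ok(k2):
                yield (2, (k1, k2), ())
    for m1 in range(1, lp):
        for m2 in range(m1 + 1, lp):
            if ins_ok(m1) and ins_ok(m2):
                yield (2, (), (m1, m2))
    for k in range(lp):
        for m in range(1, lp):
            if del_ok(k) and ins_ok(m):
                yield (2, (k,), (m,))


def _config_cost_vector(pre: np.ndarray, pad: int, lp: int, n: int,
                        dels: tuple, inss: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Substitution counts for one gap configuration at every start offset.

    Returns (offsets a, costs) where ``a`` is the scanned-sequence index of
    the alignment's first column; the alignment ends at
    ``p = a + lp - len(dels) + len(inss)``.
    """
    seg_len = lp - len(dels) + len(inss)
    a = np.arange(0, n - seg_len + 1, dtype=np.int64)
    if a.size == 0:
        return a, a
    # protospacer position i maps to offset a + (#ins slots <= i) - (#dels < i)
    cost = np.zeros_like(a)
    for piece_start, piece_end, shift in _pieces(lp, dels, inss):
        if piece_end > piece_start:
            cost += (pre[piece_end, a + shift + pad]
                     - pre[piece_start, a + shift + pad])
    return a, cost


def _pieces(lp: int, dels: tuple, inss: tuple):
    """Contiguous protospacer runs with a constant window offset shift."""
    boundaries = sorted(set([0, lp] + [k for k in dels] + [k + 1 for k in dels]
                            + list(inss)))
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        if s in dels:
            continue  # the deleted base itself
        shift = sum(1 for m in inss if m <= s) - sum(1 for k in dels if k < s)
        yield s, e, shift


def _align_strings(proto: str, seq: str, a: int, dels: tuple, inss: tuple,
                   pam_pattern: str) -> tuple[str, str]:
    top = []  # protospacer + PAM row
    bottom = []  # window row
    j = a
    for i in range(len(proto)):
        # emit the bulge column sitting just before protospacer base i
        if i in inss:
            top.append("-")
            bottom.append(seq[j])
            j += 1
        if i in dels:
            top.append(proto[i])
            bottom.append("-")
        else:
            top.append(proto[i])
            bottom.append(seq[j])
            j += 1
    # PAM columns: the IUPAC pattern (lowercase) over the window bases
    top.append(pam_pattern.lower())
    bottom.append(seq[j : j + len(pam_pattern)])
    return "".join(top), "".join(bottom)


def _scan_strand(seq: str, guide: GuideSpec, mode: str, max_gap_events: int,
                 forbid_seed_gaps: bool):
    """Best (cost, gaps, offset, dels, inss) on one scanned sequence."""
    lp, n = guide.length, len(seq)
    lm = len(guide.pam_pattern)
    if n < lp - min(2, max_gap_events) + lm:
        return None
    pre = _mismatch_prefix(guide.protospacer, seq)
    pad = lp + 2
    pam = _pam_costs(guide, seq)
    seed_start = lp - guide.seed_length if forbid_seed_gaps else None
    best = None
    for n_gaps, dels, inss in _gap_configs(lp, max_gap_events, seed_start):
        a, cost = _config_cost_vector(pre, pad, lp, n, dels, inss)
        if a.size == 0:
            continue
        seg_len = lp - len(dels) + len(inss)
        p = a + seg_len
        total = cost + n_gaps
        pam_cost = pam[p]
        if mode == "strict":
            admissible = pam_cost == 0
        else:
            admissible = pam_cost < 1000
            total = total + pam_cost
        if not admissible.any():
            continue
        total = np.where(admissible, total, 10_000)
        idx = int(np.argmin(total))  # smallest offset wins ties within config
        cand = (int(total[idx]), n_gaps, int(a[idx]), dels, inss)
        if cand[0] >= 10_000:
            continue
        if best is None or cand[:3] < best[:3]:
            best = cand
    return best


def min_edit_distance(
    window: Window | str,
    guide: GuideSpec,
    mode: str = "strict",
    max_gap_len: int = 1,
    max_gap_events: int = 2,
    forbid_seed_gaps: bool = False,
    variant_key: tuple | None = None,
) -> HomologyResult:
    """Minimum constrained edit distance of protospacer+PAM to a window.

    Both strands are scanned; the minus strand is represented by scanning
    the reverse complement of the window, and ``best_offset`` is the
    0-based protospacer start within the scanned (possibly
    reverse-complemented) sequence.  Ties break by fewest gap events,
    then smallest offset, then the plus strand.
    """
    if mode not in ("strict", "lenient"):
        raise ParameterError(f"unknown mode {mode!r}")
    if max_gap_len != 1:
        raise ParameterError("only single-base gap events are supported "
                             "(max_gap_len must be 1)")
    win = window if isinstance(window, Window) else Window("", 1, len(window), window)
    seq = win.seq.upper()
    candidates = []
    for strand, scanned in (("+", seq), ("-", reverse_complement(seq))):
        hit = _scan_strand(scanned, guide, mode, max_gap_events, forbid_seed_gaps)
        if hit is not None:
            cost, n_gaps, offset, dels, inss = hit
            candidates.append((cost, n_gaps, offset, 0 if strand == "+" else 1,
                               strand, dels, inss, scanned))
    if not candidates:
        return HomologyResult(variant_key, win, None, None, None, None, None,
                              None, mode=mode)
    cost, n_gaps, offset, _, strand, dels, inss, scanned = min(
        candidates, key=lambda c: c[:4]
    )
    top, bottom = _align_strings(guide.protospacer, scanned, offset, dels, inss,
                                 guide.pam_pattern)
    mismatches = cost - n_gaps
    seed_edits = _count_seed_edits(guide, top, bottom)
    return HomologyResult(
        variant_key=variant_key,
        window=win,
        best_strand=strand,
        best_offset=offset,
        edit_distance=cost,
        mismatches=mismatches,
        gaps=n_gaps,
        alignment=(top, bottom),
        mode=mode,
        seed_edits=seed_edits,
    )


def _count_seed_edits(guide: GuideSpec, top: str, bottom: str) -> int:
    """Edits (substitutions + gaps) at seed-region protospacer positions."""
    seed = set(guide.seed_positions)
    edits = 0
    pos = 0  # protospacer position consumed so far
    for t, b in zip(top, bottom):
        if t.islower():
            break  # PAM columns
        if t == "-":
            if pos + 1 in seed or pos in seed:
                edits += 1
            continue
        pos += 1
        if pos > guide.length:
            break
        if b == "-" or t != b:
            if pos in seed:
                edits += 1
    return edits


def scan_variants(
    variants: Sequence, reference: Mapping[str, str], guide: GuideSpec,
    flank: int = 30, mode: str = "strict", **kwargs
) -> list[HomologyResult]:
    """Scan the +/-flank window of each variant's start site."""
    results = []
    for v in variants:
        chrom, pos = v.key[0], v.key[1]
        win = extract_window(reference, chrom, pos, flank=flank)
        results.append(min_edit_distance(win, guide, mode=mode,
                                         variant_key=v.key, **kwargs))
    return results


def summarize_mismatch_profile(
    results: Sequence[HomologyResult], group_labels: Sequence[str]
) -> pd.DataFrame:
    """Per-group mean and standard error of the minimum edit distance.

    Non-alignable results are excluded; empty groups are flagged with a
    logged warning and omitted.
    """
    if len(results) != len(group_labels):
        raise ParameterError("results and group_labels lengths differ")
    per_group: dict[str, list[int]] = {}
    for res, label in zip(results, group_labels):
        per_group.setdefault(label, [])
        if res.alignable:
            per_group[label].append(res.edit_distance)
    rows = []
    for label, dists in sorted(per_group.items()):
        if not dists:
            logger.warning("group %r has no alignable results; omitted", label)
            continue
        arr = np.asarray(dists, dtype=float)
        rows.append({
            "group": label,
            "n": len(dists),
            "mean_edit_distance": float(arr.mean()),
            "sem": float(stats.sem(arr)) if len(dists) > 1 else 0.0,
            "distribution": dict(zip(*np.unique(arr.astype(int),
                                                return_counts=True))),
        })
    return pd.DataFrame(rows)


__all__ = [
    "GuideSpec", "Window", "HomologyResult", "extract_window",
    "min_edit_distance", "scan_variants", "summarize_mismatch_profile",
    "reverse_complement", "IUPAC_SETS",
]
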