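"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through different algorithms than
the package (explicit-state dynamic programming, exhaustive enumeration)
so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _pam_mismatches(pam_seq: str, pattern: str, iupac: dict) -> int:
    return sum(b not in iupac[c] for b, c in zip(pam_seq, pattern))


def oracle_strand_ends(seq: str, proto: str, max_gap_events: int = 2):
    """Explicit-state DP: min (cost, gaps) of aligning the full protospacer
    to a segment of ``seq`` ending at each position.

    States are (protospacer bases consumed, seq bases consumed, gap events
    used, last move).  Moves: match/mismatch; deletion of a protospacer
    base (not after another deletion); insertion of a seq base strictly
    inside the protospacer (not after another insertion).  Returns
    ``ends[p] = [(cost, gaps), ...]`` minima per end position p.
    """
    lp, n = len(proto), len(seq)
    G = max_gap_events + 1
    INF = 10**9
    # cost[i][j][g][last], last: 0=match, 1=del(proto), 2=ins(seq)
    cost = np.full((lp + 1, n + 1, G, 3), INF, dtype=np.int64)
    cost[0, :, 0, 0] = 0  # free start anywhere, no gaps yet
    for i in range(lp + 1):
        for j in range(n + 1):
            for g in range(G):
                for last in range(3):
                    c = cost[i, j, g, last]
                    if c >= INF:
                        continue
                    if i < lp and j < n:
                        nc = c + (proto[i] != seq[j])
                        if nc < cost[i + 1, j + 1, g, 0]:
                            cost[i + 1, j + 1, g, 0] = nc
                    if i < lp and last != 1 and g + 1 < G:
                        if c + 1 < cost[i + 1, j, g + 1, 1]:
                            cost[i + 1, j, g + 1, 1] = c + 1
                    if j < n and 0 < i < lp and last != 2 and g + 1 < G:
                        if c + 1 < cost[i, j + 1, g + 1, 2]:
                            cost[i, j + 1, g + 1, 2] = c + 1
    ends: dict[int, list[tuple[int, int]]] = {}
    for p in range(n + 1):
        opts = []
        for g in range(G):
            best = int(cost[lp, p, g, :].min())
            if best < INF:
                opts.append((best, g))  # gap cost already included in best
        if opts:
            ends[p] = opts
    return ends


def oracle_min_edit_distance(window: str, guide, mode: str = "strict",
                             max_gap_events: int = 2):
    """Minimum constrained edit distance by exhaustive DP, both strands.

    Returns the distance only (None when no admissible placement).
    """
    from editaudit.homology import IUPAC_SETS

    proto = guide.protospacer
    pattern = guide.pam_pattern
    lm = len(pattern)
    best = None
    for seq in (window.upper(), _revcomp(window.upper())):
        n = len(seq)
        ends = oracle_strand_ends(seq, proto, max_gap_events)
        for p, opts in ends.items():
            if p + lm > n:
                continue
            pam_cost = _pam_mismatches(seq[p : p + lm], pattern, IUPAC_SETS)
            for cost, _g in opts:
                if mode == "strict":
                    if pam_cost > 0:
                        continue
                    total = cost
                else:
                    total = cost + pam_cost
                if best is None or total < best:
                    best = total
    return best


def oracle_normalize(chrom_seq: str, pos: int, ref: str, alt: str,
                     max_len: int = 8):
    """Canonical variant representation by exhaustive enumeration.

    Enumerates every equivalent (pos', ref', alt') representation (same
    edited haplotype), discards non-parsimonious ones (shared trailing
    base, or shared leading base with both alleles longer than 1), and
    returns the leftmost, then shortest, survivor.
    """
    n = len(chrom_seq)
    edited = chrom_seq[: pos - 1] + alt + chrom_seq[pos - 1 + len(ref) :]
    reps = []
    for p in range(1, n + 1):
        pre = chrom_seq[: p - 1]
        if not edited.startswith(pre):
            continue
        for rlen in range(1, max_len + 1):
            if p - 1 + rlen > n:
                break
            suf = chrom_seq[p - 1 + rlen :]
            alen = len(edited) - len(pre) - len(suf)
            if alen < 1:
                continue
            if suf and not edited.endswith(suf):
                continue
            r = chrom_seq[p - 1 : p - 1 + rlen]
            a = edited[p - 1 : p - 1 + alen]
            if r == a:
                continue
            if r[-1] == a[-1]:
                continue  # shared trailing base: trimmable
            if r[0] == a[0] and len(r) > 1 and len(a) > 1:
                continue  # shared leading base beyond the anchor
            reps.append((p, r, a))
    if not reps:
        # indel pinned at the contig start: no representation can shed the
        # shared trailing base; take the leftmost, shortest one instead
        for p in range(1, n + 1):
            pre = chrom_seq[: p - 1]
            if not edited.startswith(pre):
                continue
            for rlen in range(1, max_len + 1):
                if p - 1 + rlen > n:
                    break
                suf = chrom_seq[p - 1 + rlen :]
                alen = len(edited) - len(pre) - len(suf)
                if alen < 1 or (suf and not edited.endswith(suf)):
                    continue
                r = chrom_seq[p - 1 : p - 1 + rlen]
                a = edited[p - 1 : p - 1 + alen]
                if r != a:
                    reps.append((p, r, a))
    reps.sort(key=lambda t: (t[0], len(t[1]), len(t[2])))
    return reps[0]


def oracle_splice_category(o: float, e: float) -> str:
    """Direct transcription of the printed rescue criteria.

    Unchanged when the absolute delta-delta is under 0.1; otherwise the
    rescued clauses (same-direction partial correction, or landing in the
    [-0.2, 0.2] band closer to zero than the saline arm) are evaluated
    before the mis-spliced clauses, which resolves the shared boundary at
    |e| = 0.2 in favour of rescued.
    """
    if abs(o - e) < 0.1:
        return "unchanged"
    rescued = (
        (o > 0 and ((e >= 0) or (-0.2 <= e <= 0.2)) and o > e)
        or (o < 0 and ((e <= 0) or (-0.2 <= e <= 0.2)) and o < e)
    )
    if rescued:
        return "rescued"
    mis = (
        (o > 0 and e >= 0 and o < e)
        or (o < 0 and e <= 0 and o > e)
        or (o < 0 and e >= 0.2)
        or (o > 0 and e <= -0.2)
    )
    if mis:
        return "mis-spliced"
    raise AssertionError(f"no category fires for o={o}, e={e}")


def oracle_activity_scores(expression) -> dict:
    """Mean-of-min-max scores via plain Python loops (genes x cells frame)."""
    genes = list(expression.index)
    cells = list(expression.columns)
    mins = {g: min(expression.loc[g]) for g in genes}
    maxs = {g: max(expression.loc[g]) for g in genes}
    usable = [g for g in genes if maxs[g] > mins[g]]
    out = {}
    for c in cells:
        vals = [
            (expression.loc[g, c] - mins[g]) / (maxs[g] - mins[g])
            for g in usable
        ]
        out[c] = sum(vals) / len(vals)
    return out
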