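"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's own code paths: per-base boolean
coverage arrays instead of interval sweeps, an explicit truth table
instead of the classifier cascade, and rank-then-Pearson arithmetic
instead of the packaged Spearman routine.
"""

import numpy as np


def perbase_consensus(rep1, rep2, chrom_len):
    """Per-base both-replicates voting oracle for consensus regions.

    *rep1*/*rep2* are iterables of objects with ``.interval`` and
    ``.signal`` on one chromosome. A base is consensus-supported iff it is
    covered in both replicates; each supported run is then expanded to the
    span of every region sharing a base with it (iterated to a fixpoint),
    and overlapping spans are merged. Returns a list of
    ``(start, end, signal)`` with the signal the length-weighted mean of
    all member regions.
    """
    cov1 = np.zeros(chrom_len, dtype=bool)
    cov2 = np.zeros(chrom_len, dtype=bool)
    regions = []
    for rep, cov in ((rep1, cov1), (rep2, cov2)):
        for r in rep:
            cov[r.interval.start:r.interval.end] = True
            regions.append((r.interval.start, r.interval.end, r.signal))
    both = cov1 & cov2
    # runs of both-covered bases
    edges = np.flatnonzero(np.diff(np.concatenate(([0], both.view(np.int8), [0]))))
    spans = [[int(edges[i]), int(edges[i + 1])] for i in range(0, len(edges), 2)]
    # expand each run over regions sharing >= 1 base, to a fixpoint
    expanded = []
    for span in spans:
        changed = True
        while changed:
            changed = False
            for s, e, _ in regions:
                if s < span[1] and e > span[0] and (s < span[0] or e > span[1]):
                    span[0], span[1] = min(span[0], s), max(span[1], e)
                    changed = True
        expanded.append(span)
    # merge spans sharing a base
    expanded.sort()
    merged = []
    for span in expanded:
        if merged and span[0] < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], span[1])
        else:
            merged.append(span)
    out = []
    for lo, hi in merged:
        members = [(s, e, v) for s, e, v in regions if s < hi and e > lo]
        w = sum(e - s for s, e, _ in members)
        sig = sum((e - s) * v for s, e, v in members) / w
        out.append((lo, hi, sig))
    return out


def truth_table_state(k4, k27, tss, halfwidth=500):
    """Explicit truth table for the joint mark configuration of one gene.

    *k4*/*k27* are ``(start, end)`` tuples or None. Matches the documented
    decision rules: containment with the inner peak's midpoint within
    ``tss +- halfwidth`` gives H (K27 outer) or E (K4 outer), checked in
    that order; otherwise the longer-spanning mark names the partial label
    with K27 winning span ties.
    """
    if k4 is None and k27 is None:
        return "Unmarked"
    if k27 is None:
        return "K4_only"
    if k4 is None:
        return "K27_only"
    s4, e4 = k4
    s27, e27 = k27
    if min(e4, e27) - max(s4, s27) < 1:
        return "Non"
    if s27 <= s4 and e4 <= e27 and abs((s4 + e4) / 2.0 - tss) <= halfwidth:
        return "H"
    if s4 <= s27 and e27 <= e4 and abs((s27 + e27) / 2.0 - tss) <= halfwidth:
        return "E"
    return "K4_gt_K27" if (e4 - s4) > (e27 - s27) else "K27_gt_K4"


def rank_then_pearson(x, y):
    """Spearman rho as the Pearson correlation of explicit mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def midranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
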