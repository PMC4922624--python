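"""Independent oracle implementations used only by the tests.

These deliberately use naive per-base / textbook algorithms so they share
no code path with the package implementations they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_cnvrs(calls, genome, recurrence: float):
    """Per-base CNVR compilation oracle for small (<=100 kb) genomes.

    Returns a sorted list of (chrom, start, end, type) tuples.
    """
    trimmed = []  # (chrom, start, end, type)
    for rtype, keep in (("loss", lambda c: c.cn < 2), ("gain", lambda c: c.cn > 2)):
        for chrom, clen in genome.chromosomes:
            cov = np.zeros(clen, dtype=int)
            sub = [c for c in calls if c.chrom == chrom and keep(c)]
            for c in sub:
                cov[c.start : c.end] += 1
            covered = cov > 0
            # clusters = maximal covered runs (equivalent to transitive overlap)
            for cs, ce in _runs(covered):
                n = sum(1 for c in sub if c.start < ce and c.end > cs)
                ok = cov[cs:ce] / n >= recurrence if recurrence > 0 else cov[cs:ce] > 0
                for rs, re_ in _runs(ok):
                    trimmed.append((chrom, cs + rs, cs + re_, rtype))
    # transitive merge of overlapping regions into "both"
    merged = [list(t) for t in trimmed]
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                a, b = merged[i], merged[j]
                if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                    a[1], a[2] = min(a[1], b[1]), max(a[2], b[2])
                    a[3] = a[3] if a[3] == b[3] else "both"
                    del merged[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((c, s, e, t) for c, s, e, t in merged)


def _runs(mask: np.ndarray):
    """Maximal runs of True as (start, end) half-open pairs."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def bh_stepup(p):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * p[i] / rank)
        adj[i] = running_min
    return adj


def brute_force_overlaps(query, target, min_bp=1):
    """All-pairs scan returning {(qname, tname): overlap_bp}."""
    out = {}
    for qi, q in enumerate(query.intervals):
        for ti, t in enumerate(target.intervals):
            if q.chrom != t.chrom:
                continue
            ov = min(q.end, t.end) - max(q.start, t.start)
            if ov >= min_bp:
                qn = q.name if q.name != "." else f"q{qi}"
                tn = t.name if t.name != "." else f"t{ti}"
                out[(qn, tn)] = ov
    return out


def random_call_set(rng, genome, n_calls, samples):
    """Random small CNV calls on a toy genome for oracle comparisons."""
    from cnvmap.core import CNVCall

    calls = []
    names = genome.names
    for _ in range(n_calls):
        chrom = names[int(rng.integers(0, len(names)))]
        clen = genome.lengths[chrom]
        length = int(rng.integers(5, max(6, clen // 3)))
        start = int(rng.integers(0, clen - length))
        cn = int(rng.choice([0, 1, 3, 4]))
        sid = samples[int(rng.integers(0, len(samples)))]
        calls.append(CNVCall(sid, chrom, start, start + length, cn=cn))
    return calls
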