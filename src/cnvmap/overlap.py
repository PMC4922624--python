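"""Region-set overlap statistics.

Provides pairwise overlap detection with type classification, the mutual
(reciprocal) overlap rule used when matching region sets across studies,
and a permutation test against size- and chromosome-matched random
regions with two robustness measures: the number of query regions hitting
a target region, and the total genomic size in bp overlapped.

Empirical p-values use the add-one estimator ``(k + 1) / (N + 1)``; with
N = 1000 permutations and no null value as extreme as the observed one,
this reports p < 0.001 and never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import AnnotationTrack, CnvmapError, GenomeBuild, Interval

REGION_COUNT, TOTAL_BP = "region_count", "total_bp"


@dataclass(frozen=True)
class OverlapRecord:
    query_id: str
    target_id: str
    overlap_bp: int
    query_fraction: float
    target_fraction: float
    overlap_type: str  # query_within_target | target_within_query | identical | partial


def _classify(q: Interval, t: Interval) -> str:
    if q.start == t.start and q.end == t.end:
        return "identical"
    if q.start >= t.start and q.end <= t.end:
        return "query_within_target"
    if t.start >= q.start and t.end <= q.end:
        return "target_within_query"
    return "partial"


def _trees(track: AnnotationTrack) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(track.intervals):
        if iv.length > 0:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def find_overlaps(
    query: AnnotationTrack, target: AnnotationTrack, min_bp: int = 1
) -> list[OverlapRecord]:
    """All query/target interval pairs sharing at least ``min_bp`` bases."""
    trees = _trees(target)
    records: list[OverlapRecord] = []
    for qi, q in enumerate(query.intervals):
        tree = trees.get(q.chrom)
        if tree is None or q.length == 0:
            continue
        for hit in sorted(tree.overlap(q.start, q.end), key=lambda h: (h.begin, h.end)):
            t = target.intervals[hit.data]
            ov = min(q.end, t.end) - max(q.start, t.start)
            if ov < min_bp:
                continue
            records.append(
                OverlapRecord(
                    query_id=q.name if q.name != "." else f"q{qi}",
                    target_id=t.name if t.name != "." else f"t{hit.data}",
                    overlap_bp=ov,
                    query_fraction=ov / q.length,
                    target_fraction=ov / t.length,
                    overlap_type=_classify(q, t),
                )
            )
    return records


def mutual_overlap_match(
    set_a: AnnotationTrack, set_b: AnnotationTrack, threshold: float = 0.7
) -> list[tuple[Interval, Interval]]:
    """Pairs considered the same event across two studies.

    A pair matches only if the shared bases exceed ``threshold`` of *each*
    interval's own length (reciprocal overlap), so a small interval inside
    a much larger one does not count as detected by both.
    """
    trees = _trees(set_b)
    pairs: list[tuple[Interval, Interval]] = []
    for a in set_a.intervals:
        tree = trees.get(a.chrom)
        if tree is None or a.length == 0:
            continue
        for hit in sorted(tree.overlap(a.start, a.end), key=lambda h: (h.begin, h.end)):
            b = set_b.intervals[hit.data]
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov / a.length > threshold and ov / b.length > threshold:
                pairs.append((a, b))
    return pairs


def randomize_regions(
    regions: list[Interval],
    genome: GenomeBuild,
    rng: np.random.Generator,
    same_chromosome: bool = True,
    max_len_bp: int = 1_000_000,
    allow_overlap: bool = True,
    max_retries: int = 1000,
) -> list[Interval]:
    """Replace each region by a uniformly placed same-length interval.

    Regions longer than ``max_len_bp`` are dropped first (extreme
    outliers would dominate both measures). Placement is uniform over all
    valid starts; by default sampled regions may overlap one another
    (``allow_overlap=False`` rejection-samples disjoint placements).
    With ``same_chromosome`` the chromosome assignment is preserved,
    matching the chromosomal distribution of the input set.
    """
    lengths = genome.lengths
    placed: dict[str, list[tuple[int, int]]] = {}
    out: list[Interval] = []
    for iv in regions:
        if iv.length > max_len_bp:
            continue
        for attempt in range(max_retries):
            if same_chromosome:
                chrom = iv.chrom
                space = lengths[chrom] - iv.length
                if space < 0:
                    raise CnvmapError(
                        f"region of {iv.length} bp exceeds chromosome {chrom}"
                    )
            else:
                fits = [
                    (n, lengths[n] - iv.length)
                    for n in genome.names
                    if lengths[n] >= iv.length
                ]
                if not fits:
                    raise CnvmapError(f"region of {iv.length} bp exceeds every chromosome")
                weights = np.array([s + 1 for _, s in fits], dtype=float)
                idx = rng.choice(len(fits), p=weights / weights.sum())
                chrom, space = fits[idx]
            start = int(rng.integers(0, space + 1))
            end = start + iv.length
            if allow_overlap or not any(
                start < e and end > s for s, e in placed.get(chrom, [])
            ):
                break
        else:
            raise CnvmapError("could not place non-overlapping random regions")
        if not allow_overlap:
            placed.setdefault(chrom, []).append((start, end))
        out.append(Interval(chrom, start, end, iv.name))
    return out


def _merge_sorted(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _union_by_chrom(intervals: list[Interval]) -> dict[str, list[tuple[int, int]]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        if iv.length > 0:
            by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: _merge_sorted(vs) for c, vs in by.items()}


def _intersection_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total, i, j = 0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


class _TargetIndex:
    """Merged, per-chromosome target intervals with binary-search lookup."""

    def __init__(self, intervals: list[Interval]):
        self._by: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, merged in _union_by_chrom(intervals).items():
            starts = np.fromiter((s for s, _ in merged), dtype=np.int64)
            ends = np.fromiter((e for _, e in merged), dtype=np.int64)
            self._by[chrom] = (starts, ends)

    def count_overlapping(self, query: list[Interval]) -> int:
        n = 0
        for iv in query:
            entry = self._by.get(iv.chrom)
            if entry is None or iv.length == 0:
                continue
            starts, ends = entry
            # merged intervals are disjoint and sorted, so only the last
            # one starting before the query end can overlap it
            i = int(np.searchsorted(starts, iv.end, side="left")) - 1
            if i >= 0 and ends[i] > iv.start:
                n += 1
        return n

    def intersect_bp(self, query: list[Interval]) -> int:
        total = 0
        for chrom, merged in _union_by_chrom(query).items():
            entry = self._by.get(chrom)
            if entry is None:
                continue
            target = list(zip(entry[0].tolist(), entry[1].tolist()))
            total += _intersection_bp(merged, target)
        return total

    def evaluate(self, query: list[Interval], measure: str) -> int:
        if measure == REGION_COUNT:
            return self.count_overlapping(query)
        if measure == TOTAL_BP:
            return self.intersect_bp(query)
        raise CnvmapError(f"unknown measure {measure!r}")


def overlap_measure(
    query: list[Interval], target: list[Interval], measure: str
) -> int:
    """Evaluate one overlap measure.

    ``region_count`` is the number of query intervals sharing >= 1 base
    with any target interval (not symmetric in query/target);
    ``total_bp`` is the size of the intersection of the two sets' base
    unions (symmetric).
    """
    return _TargetIndex(target).evaluate(query, measure)


@dataclass(frozen=True)
class PermutationResult:
    measure: str
    observed: float
    null_mean: float
    null_sd: float
    n_perm: int
    alternative: str  # less | greater
    p_value: float
    seed: int

    def to_row(self) -> dict:
        return {
            "measure": self.measure,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_perm": self.n_perm,
            "alternative": self.alternative,
            "p_value": self.p_value,
            "seed": self.seed,
        }


def permutation_overlap_test(
    query: AnnotationTrack,
    target: AnnotationTrack,
    genome: GenomeBuild,
    n_perm: int = 1000,
    measure: str = REGION_COUNT,
    alternative: str = "auto",
    rng_seed: int = 0,
    max_len_bp: int = 1_000_000,
    same_chromosome: bool = True,
) -> PermutationResult:
    """Permutation test of query/target overlap against random placement.

    Each permutation re-places every retained query region uniformly on
    its chromosome and recomputes the measure. The >1 Mb exclusion is
    applied to the observed measure and the randomizations alike so the
    two are comparable. One-sided p = (k + 1)/(N + 1) with ties counting
    toward k; ``alternative="auto"`` picks the side from the sign of
    observed - null mean.
    """
    if n_perm < 1:
        raise CnvmapError("n_perm must be >= 1")
    if len(query) == 0:
        raise CnvmapError("empty query track")
    retained = [iv for iv in query.intervals if iv.length <= max_len_bp]
    if not retained:
        raise CnvmapError(f"no query region <= {max_len_bp} bp")
    index = _TargetIndex(target.intervals)
    observed = index.evaluate(retained, measure)

    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_perm, dtype=float)
    for b in range(n_perm):
        rand = randomize_regions(
            retained, genome, rng, same_chromosome=same_chromosome, max_len_bp=max_len_bp
        )
        null[b] = index.evaluate(rand, measure)

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    if alternative == "auto":
        alternative = "less" if observed < null_mean else "greater"
    if alternative == "less":
        k = int(np.sum(null <= observed))
    elif alternative == "greater":
        k = int(np.sum(null >= observed))
    else:
        raise CnvmapError(f"unknown alternative {alternative!r}")
    return PermutationResult(
        measure=measure,
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        n_perm=n_perm,
        alternative=alternative,
        p_value=(k + 1) / (n_perm + 1),
        seed=rng_seed,
    )


def permutation_batch(
    query: AnnotationTrack,
    targets: dict[str, AnnotationTrack],
    genome: GenomeBuild,
    **kwargs,
) -> pd.DataFrame:
    """Run the permutation test against several target tracks.

    Returns one row per target (trait, observed, null mean, sd, p), the
    table shape used for per-trait QTL overlap reports.
    """
    rows = []
    for label, target in targets.items():
        res = permutation_overlap_test(query, target, genome, **kwargs)
        rows.append({"target": label, **res.to_row()})
    return pd.DataFrame(rows)
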