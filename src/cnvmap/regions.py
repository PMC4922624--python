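"""Compilation of per-sample CNV calls into population CNV regions (CNVRs).

The pipeline mirrors the CNVRuler-style "Gain/Loss separated regions"
procedure with recurrence trimming:

1. partition calls into losses (cn < 2) and gains (cn > 2);
2. within each partition and chromosome, cluster transitively overlapping
   calls (>= 1 shared base);
3. per cluster, trim bases where the coverage density — member calls
   covering the base divided by calls in the cluster — falls below the
   recurrence threshold; each maximal surviving run becomes a region
   (a cluster may split);
4. merge overlapping gain and loss regions (transitively) into single
   regions of type "both" spanning their union;
5. attach member calls, count distinct carrier samples and compute the
   population frequency;
6. number regions by (chromosome order, start).

Density is defined relative to the transitive cluster's call count, which
reproduces the intended trimming of thinly-supported region tails without
requiring per-sample weights. The trimming is computed on interval
breakpoints, not per-base arrays, so it is exact at any genome size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import AnnotationTrack, CNVCall, CnvmapError, GenomeBuild, Interval

LOSS, GAIN, BOTH = "loss", "gain", "both"


@dataclass
class CNVRegion:
    """A population-level CNV region."""

    region_id: str
    chrom: str
    start: int
    end: int
    type: str
    member_calls: list[CNVCall] = field(default_factory=list)
    n_samples: int = 0
    frequency: float = 0.0
    polymorphic: bool = False
    fixed_state_flag: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def member_call_ids(self) -> list[str]:
        return [
            f"{c.sample_id}:{c.chrom}:{c.start}-{c.end}:cn{c.cn}" for c in self.member_calls
        ]


def _clusters(calls: list[CNVCall]) -> list[list[CNVCall]]:
    """Group calls on one chromosome into transitive-overlap clusters."""
    out: list[list[CNVCall]] = []
    cur: list[CNVCall] = []
    cur_end = -1
    for c in sorted(calls, key=lambda c: (c.start, c.end)):
        if cur and c.start < cur_end:
            cur.append(c)
            cur_end = max(cur_end, c.end)
        else:
            if cur:
                out.append(cur)
            cur = [c]
            cur_end = c.end
    if cur:
        out.append(cur)
    return out


def _trim_cluster(cluster: list[CNVCall], recurrence: float) -> list[tuple[int, int]]:
    """Return maximal runs of bases where coverage/len(cluster) >= recurrence."""
    n = len(cluster)
    if recurrence == 0:
        return [(min(c.start for c in cluster), max(c.end for c in cluster))]
    # breakpoint sweep: +1 at starts, -1 at ends
    points = sorted({p for c in cluster for p in (c.start, c.end)})
    delta = dict.fromkeys(points, 0)
    for c in cluster:
        delta[c.start] += 1
        delta[c.end] -= 1
    runs: list[tuple[int, int]] = []
    depth = 0
    run_start: int | None = None
    for p in points:
        depth += delta[p]
        keep = depth / n >= recurrence
        if keep and run_start is None:
            run_start = p
        elif not keep and run_start is not None:
            runs.append((run_start, p))
            run_start = None
    # depth is 0 after the last point, so any open run was closed above
    return runs


def compile_cnvrs(
    calls: list[CNVCall],
    genome: GenomeBuild,
    population_size: int,
    recurrence: float = 0.1,
    separate_gain_loss: bool = True,
) -> list[CNVRegion]:
    """Concatenate filtered CNV calls into CNV regions.

    ``population_size`` is the number of animals the frequencies refer to
    (it may exceed the number of samples contributing calls).
    """
    if not 0 <= recurrence < 1:
        raise CnvmapError(f"recurrence must be in [0, 1), got {recurrence}")
    n_obs = len({c.sample_id for c in calls})
    if population_size < n_obs:
        raise CnvmapError(
            f"population_size {population_size} < {n_obs} distinct samples observed"
        )

    chrom_order = {name: i for i, name in enumerate(genome.names)}
    partitions: dict[str, list[CNVCall]]
    if separate_gain_loss:
        partitions = {
            LOSS: [c for c in calls if c.is_loss],
            GAIN: [c for c in calls if c.is_gain],
        }
    else:
        partitions = {BOTH: list(calls)}

    # raw (untyped-merge) regions per chromosome
    raw: dict[str, list[tuple[int, int, str]]] = {}
    for rtype, part in partitions.items():
        by_chrom: dict[str, list[CNVCall]] = {}
        for c in part:
            by_chrom.setdefault(c.chrom, []).append(c)
        for chrom, chrom_calls in by_chrom.items():
            for cluster in _clusters(chrom_calls):
                for s, e in _trim_cluster(cluster, recurrence):
                    raw.setdefault(chrom, []).append((s, e, rtype))

    # merge overlapping gain/loss regions (transitive chains) into "both"
    merged: list[CNVRegion] = []
    for chrom, regs in raw.items():
        regs.sort()
        group: list[tuple[int, int, str]] = []
        group_end = -1
        for reg in regs + [(math.inf, math.inf, "")]:  # sentinel flushes last group
            s, e, t = reg
            if group and s < group_end:
                group.append(reg)
                group_end = max(group_end, e)
            else:
                if group:
                    types = {t_ for _, _, t_ in group}
                    rtype = types.pop() if len(types) == 1 else BOTH
                    merged.append(
                        CNVRegion(
                            region_id="",
                            chrom=chrom,
                            start=min(s_ for s_, _, _ in group),
                            end=max(e_ for _, e_, _ in group),
                            type=rtype,
                        )
                    )
                if s is math.inf:
                    break
                group = [reg]
                group_end = e

    merged.sort(key=lambda r: (chrom_order[r.chrom], r.start, r.end))
    for i, region in enumerate(merged, start=1):
        region.region_id = f"CNVR_{i}"

    _assign_members(merged, calls, population_size)
    return merged


def _assign_members(
    regions: list[CNVRegion], calls: list[CNVCall], population_size: int
) -> None:
    """Attach each call to the one overlapping region with maximal overlap.

    Unique assignment (leftmost region on ties) keeps membership a
    partition of the assignable calls even when a long call spans a
    trimmed gap between two surviving runs.
    """
    by_chrom: dict[str, list[CNVRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for regs in by_chrom.values():
        regs.sort(key=lambda r: r.start)

    for call in calls:
        best: CNVRegion | None = None
        best_ov = 0
        for r in by_chrom.get(call.chrom, []):
            if r.start >= call.end:
                break
            ov = min(call.end, r.end) - max(call.start, r.start)
            if ov > best_ov:
                best, best_ov = r, ov
        if best is not None:
            best.member_calls.append(call)

    for r in regions:
        r.n_samples = len({c.sample_id for c in r.member_calls})
        r.frequency = r.n_samples / population_size


def classify_polymorphic(
    regions: list[CNVRegion], threshold: float = 0.01
) -> list[CNVRegion]:
    """Flag regions carried by strictly more than ``threshold`` of the population."""
    for r in regions:
        r.polymorphic = r.frequency > threshold
    return regions


def flag_fixed_state(
    regions: list[CNVRegion],
    freq_threshold: float = 0.75,
    state_fraction: float = 0.95,
) -> list[CNVRegion]:
    """Flag high-frequency regions whose member calls are nearly one CN state.

    A region carried by more than ``freq_threshold`` of the population in
    which a single copy-number state accounts for more than
    ``state_fraction`` of the member calls is suspicious: it suggests a
    fixed difference against the reference assembly (a mapping artifact)
    rather than segregating variation within the population.
    """
    for r in regions:
        r.fixed_state_flag = False
        if r.frequency > freq_threshold and r.member_calls:
            counts: dict[int, int] = {}
            for c in r.member_calls:
                counts[c.cn] = counts.get(c.cn, 0) + 1
            r.fixed_state_flag = max(counts.values()) / len(r.member_calls) > state_fraction
    return regions


DEFAULT_LENGTH_EDGES = (5_000, 50_000, 100_000, 250_000, 500_000, 1_000_000, math.inf)


@dataclass
class LengthHistogram:
    edges: tuple[float, ...]
    counts: np.ndarray
    fractions: np.ndarray

    def to_tsv(self) -> str:
        lines = ["bin_start\tbin_end\tcount\tfraction"]
        for i in range(len(self.counts)):
            hi = self.edges[i + 1]
            hi_s = "inf" if math.isinf(hi) else str(int(hi))
            lines.append(
                f"{int(self.edges[i])}\t{hi_s}\t{self.counts[i]}\t{self.fractions[i]:.6g}"
            )
        return "\n".join(lines) + "\n"


def length_histogram(
    regions: list[CNVRegion], edges=DEFAULT_LENGTH_EDGES
) -> LengthHistogram:
    """Bin region lengths into half-open bins ``[e_i, e_{i+1})``."""
    edges = tuple(float(e) for e in edges)
    if list(edges) != sorted(edges) or len(set(edges)) != len(edges):
        raise CnvmapError("histogram edges must be strictly increasing")
    lengths = np.array([r.length for r in regions], dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for i in range(len(edges) - 1):
        counts[i] = int(np.sum((lengths >= edges[i]) & (lengths < edges[i + 1])))
    total = counts.sum()
    if total == 0:
        import logging

        logging.getLogger(__name__).warning("empty input to length_histogram")
        fractions = np.zeros_like(counts, dtype=float)
    else:
        fractions = counts / total
    return LengthHistogram(edges=edges, counts=counts, fractions=fractions)


@dataclass
class RegionSummary:
    n_regions: int
    n_loss: int
    n_gain: int
    n_both: int
    total_bp: int
    genome_fraction: float
    mean_length: float
    min_length: int
    max_length: int
    per_chrom_fraction: dict[str, float]

    def to_tsv(self) -> str:
        lines = ["metric\tvalue"]
        for k in (
            "n_regions n_loss n_gain n_both total_bp genome_fraction "
            "mean_length min_length max_length".split()
        ):
            lines.append(f"{k}\t{getattr(self, k):.6g}" if isinstance(getattr(self, k), float) else f"{k}\t{getattr(self, k)}")
        for chrom, frac in self.per_chrom_fraction.items():
            lines.append(f"coverage:{chrom}\t{frac:.6g}")
        return "\n".join(lines) + "\n"


def summarize_regions(regions: list[CNVRegion], genome: GenomeBuild) -> RegionSummary:
    """Totals, type counts and genome coverage for a region set."""
    lengths = [r.length for r in regions]
    total = sum(lengths)
    per_chrom: dict[str, float] = {}
    chrom_len = genome.lengths
    for name in genome.names:
        covered = sum(r.length for r in regions if r.chrom == name)
        per_chrom[name] = covered / chrom_len[name]
    auto_len = genome.autosome_length
    return RegionSummary(
        n_regions=len(regions),
        n_loss=sum(r.type == LOSS for r in regions),
        n_gain=sum(r.type == GAIN for r in regions),
        n_both=sum(r.type == BOTH for r in regions),
        total_bp=total,
        genome_fraction=total / auto_len if auto_len else 0.0,
        mean_length=float(np.mean(lengths)) if lengths else 0.0,
        min_length=min(lengths) if lengths else 0,
        max_length=max(lengths) if lengths else 0,
        per_chrom_fraction=per_chrom,
    )


def regions_to_track(regions: list[CNVRegion], label: str = "cnvr") -> AnnotationTrack:
    """Project regions onto a generic annotation track (BED6+-shaped)."""
    ivs = [
        Interval(
            r.chrom,
            r.start,
            r.end,
            r.region_id,
            (
                ("score", str(r.n_samples)),
                ("strand", "."),
                ("type", r.type),
                ("frequency", f"{r.frequency:.6g}"),
                ("polymorphic", str(int(r.polymorphic))),
                ("fixed_state", str(int(r.fixed_state_flag))),
            ),
        )
        for r in regions
    ]
    return AnnotationTrack(label=label, intervals=ivs)
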