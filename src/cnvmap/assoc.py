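"""Genome-wide association of copy-number state with a quantitative trait.

The scan proceeds in six steps:

1. every probe in every sample is assigned the integer copy number of the
   call covering it (2 where no call does), giving a probes x samples CN
   matrix;
2. probes deviating from 2n in at least ``min_dev`` (default 5%) of the
   population are selected — rarer polymorphisms carry too little dosage
   information at SNP-array scale;
3. each selected probe's CN (0..4, used as an integer covariate) is
   regressed on the phenotype by OLS, with a two-sided t test on the
   slope;
4. consecutive selected probes on one chromosome whose genotypes agree in
   at least ``identity_frac`` (default 95%) of samples are chained into
   CNV segments — such probes measure the same underlying event and are
   identical by state;
5. each segment is represented by its most significant member probe
   (leftmost on ties);
6. segment p-values are adjusted by the Benjamini-Hochberg step-up
   procedure controlling the FDR.

A statsmodels-style front-end (:class:`CNVStateGWAS` / fit ->
:class:`CNVStateGWASResults` with ``summary()``) wraps the functional
steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AnnotationTrack, CnvmapError, Interval, PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class ProbeCNMatrix:
    """Probes x samples integer copy-number matrix (0..4; 2 = diploid)."""

    probe_map: pd.DataFrame  # columns probe_id, chrom, pos; sorted
    samples: list[str]
    cn: np.ndarray  # shape (n_probes, n_samples), int8

    @property
    def deviation_fraction(self) -> np.ndarray:
        """Per-probe fraction of samples deviating from the 2n state."""
        return (self.cn != 2).mean(axis=1)


def assign_probe_cn(
    calls, probe_map: pd.DataFrame, samples: list[str]
) -> ProbeCNMatrix:
    """Build the probe CN matrix from per-sample calls.

    Calls from one sample must not overlap each other (a probe covered by
    two calls of the same animal has no well-defined copy number and
    indicates invalid upstream calling).
    """
    sample_idx = {s: i for i, s in enumerate(samples)}
    n_probes = len(probe_map)
    cn = np.full((n_probes, len(samples)), 2, dtype=np.int8)

    pos_by_chrom: dict[str, np.ndarray] = {}
    base_by_chrom: dict[str, int] = {}
    for chrom, grp in probe_map.groupby("chrom", sort=False):
        pos_by_chrom[chrom] = grp["pos"].to_numpy()
        base_by_chrom[chrom] = int(grp.index[0])

    by_sample: dict[str, list] = {}
    for c in calls:
        if c.sample_id in sample_idx:
            by_sample.setdefault(c.sample_id, []).append(c)

    for sid, sample_calls in by_sample.items():
        sample_calls.sort(key=lambda c: (c.chrom, c.start))
        for prev, cur in zip(sample_calls, sample_calls[1:]):
            if prev.chrom == cur.chrom and cur.start < prev.end:
                pos = pos_by_chrom.get(cur.chrom)
                probe = "<no probe in overlap>"
                if pos is not None:
                    lo = np.searchsorted(pos, max(prev.start, cur.start), side="left")
                    hi = np.searchsorted(pos, min(prev.end, cur.end), side="left")
                    if hi > lo:
                        probe = probe_map["probe_id"].iloc[base_by_chrom[cur.chrom] + lo]
                raise CnvmapError(
                    f"sample {sid}: overlapping calls on chromosome {cur.chrom} "
                    f"(at probe {probe}); per-sample calls must be disjoint"
                )
        j = sample_idx[sid]
        for c in sample_calls:
            pos = pos_by_chrom.get(c.chrom)
            if pos is None:
                continue
            lo = np.searchsorted(pos, c.start, side="left")
            hi = np.searchsorted(pos, c.end, side="left")  # pos < end (half-open)
            base = base_by_chrom[c.chrom]
            cn[base + lo : base + hi, j] = c.cn
    return ProbeCNMatrix(probe_map=probe_map, samples=list(samples), cn=cn)


def select_variable_probes(matrix: ProbeCNMatrix, min_dev: float = 0.05) -> np.ndarray:
    """Indices of probes deviating from 2n in >= ``min_dev`` of samples."""
    return np.flatnonzero(matrix.deviation_fraction >= min_dev)


@dataclass(frozen=True)
class ProbeAssoc:
    probe_id: str
    beta: float
    se: float
    t_stat: float
    p_value: float
    n_used: int
    degenerate: bool = False


def probe_association(
    cn_row: np.ndarray,
    phenotype: np.ndarray,
    probe_id: str = "",
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> ProbeAssoc:
    """OLS of phenotype on copy number at one probe, t test on the slope.

    Samples with missing phenotype (NaN) are dropped pairwise. A constant
    CN row (or fewer than 3 usable samples) gives a flagged degenerate
    result with beta 0 and p 1. With ``n_perm > 0`` the analytic p-value
    is replaced by an empirical one from phenotype permutations,
    (#{|beta*| >= |beta|} + 1)/(n_perm + 1).
    """
    mask = np.isfinite(phenotype)
    x = cn_row[mask].astype(float)
    y = phenotype[mask]
    n = len(y)
    if n < 3 or np.all(x == x[0]):
        return ProbeAssoc(probe_id, 0.0, np.nan, np.nan, 1.0, n, degenerate=True)
    fit = stats.linregress(x, y)
    p_value = float(fit.pvalue)
    if n_perm > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        xc = x - x.mean()
        denom = float(np.sum(xc**2))
        k = 0
        y_perm = y.copy()
        for _ in range(n_perm):
            rng.shuffle(y_perm)
            beta_perm = float(xc @ y_perm) / denom
            k += abs(beta_perm) >= abs(fit.slope)
        p_value = (k + 1) / (n_perm + 1)
    return ProbeAssoc(
        probe_id=probe_id,
        beta=float(fit.slope),
        se=float(fit.stderr),
        t_stat=float(fit.slope / fit.stderr) if fit.stderr > 0 else np.inf,
        p_value=p_value,
        n_used=n,
    )


@dataclass
class CNVSegment:
    """A run of adjacent high-identity probes treated as one CNV event."""

    segment_id: str
    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    probe_indices: list[int]
    representative_probe: str = ""
    p_value: float = np.nan
    fdr_q: float = np.nan
    state_counts: dict[int, int] = field(default_factory=dict)
    neighbor_genes: list[tuple[Interval, int]] = field(default_factory=list)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def build_segments(
    selected: np.ndarray, matrix: ProbeCNMatrix, identity_frac: float = 0.95
) -> list[CNVSegment]:
    """Chain consecutive selected probes with near-identical genotypes.

    Greedy left-to-right: probe j joins the open segment iff it sits on
    the same chromosome as the previous selected probe and the fraction
    of samples with identical CN at the two probes is >= ``identity_frac``.
    Intervening invariant (non-selected) probes do not break a segment.
    """
    segments: list[CNVSegment] = []
    chroms = matrix.probe_map["chrom"].to_numpy()
    poss = matrix.probe_map["pos"].to_numpy()
    pids = matrix.probe_map["probe_id"].to_numpy()

    cur: list[int] = []
    for idx in selected:
        idx = int(idx)
        if cur:
            prev = cur[-1]
            same_chrom = chroms[prev] == chroms[idx]
            if same_chrom:
                identity = float(np.mean(matrix.cn[idx] == matrix.cn[prev]))
            if same_chrom and identity >= identity_frac:
                cur.append(idx)
                continue
            segments.append(cur)
        cur = [idx]
    if cur:
        segments.append(cur)

    out = []
    for i, members in enumerate(segments, start=1):
        out.append(
            CNVSegment(
                segment_id=f"SEG_{i}",
                chrom=str(chroms[members[0]]),
                start=int(poss[members[0]]),
                end=int(poss[members[-1]]) + 1,
                probe_ids=[str(pids[m]) for m in members],
                probe_indices=members,
            )
        )
    return out


def score_segments(
    segments: list[CNVSegment],
    probe_assocs: dict[str, ProbeAssoc],
    matrix: ProbeCNMatrix,
    phenotype: np.ndarray | None = None,
) -> list[CNVSegment]:
    """Pick each segment's representative probe and per-state counts.

    The representative is the member probe with the smallest association
    p-value (leftmost on ties); the segment inherits its p-value, and the
    per-state animal counts are taken at that probe (over phenotyped
    samples when a phenotype vector is supplied).
    """
    for seg in segments:
        ps = [probe_assocs[pid].p_value for pid in seg.probe_ids]
        best = int(np.argmin(ps))  # argmin takes the first minimum -> leftmost
        seg.representative_probe = seg.probe_ids[best]
        seg.p_value = ps[best]
        row = matrix.cn[seg.probe_indices[best]]
        if phenotype is not None:
            row = row[np.isfinite(phenotype)]
        states, counts = np.unique(row, return_counts=True)
        seg.state_counts = {int(s): int(c) for s, c in zip(states, counts)}
    return segments


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise CnvmapError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotate_neighbors(
    segments: list[CNVSegment],
    gene_track: AnnotationTrack,
    window_bp: int = 450_000,
) -> list[CNVSegment]:
    """Attach genes within ``window_bp`` up/downstream of each segment.

    Gene expression can be affected by copy-number changes hundreds of kb
    away, so the window defaults to 450 kb on each side. Neighbors are
    ordered by gap distance to the segment (0 for overlapping genes).
    """
    by_chrom: dict[str, list[Interval]] = {}
    for iv in gene_track.intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for seg in segments:
        lo = max(0, seg.start - window_bp)
        hi = seg.end + window_bp
        found: list[tuple[Interval, int]] = []
        for g in by_chrom.get(seg.chrom, []):
            if g.end > lo and g.start < hi:
                if g.end <= seg.start:
                    dist = seg.start - g.end + 1
                elif g.start >= seg.end:
                    dist = g.start - seg.end + 1
                else:
                    dist = 0
                found.append((g, dist))
        found.sort(key=lambda t: (t[1], t[0].start))
        seg.neighbor_genes = found
    return segments


def run_cnv_gwas(
    calls,
    probe_map: pd.DataFrame,
    phenotypes: PhenotypeTable,
    gene_track: AnnotationTrack | None = None,
    samples: list[str] | None = None,
    min_dev: float = 0.05,
    identity_frac: float = 0.95,
    window_bp: int = 450_000,
) -> pd.DataFrame:
    """Run the full six-step scan; one output row per CNV segment."""
    model = CNVStateGWAS(
        calls,
        probe_map,
        phenotypes,
        gene_track=gene_track,
        samples=samples,
        min_dev=min_dev,
        identity_frac=identity_frac,
        window_bp=window_bp,
    )
    return model.fit().table


class CNVStateGWAS:
    """Model object for the copy-number-state association scan.

    Parameters
    ----------
    calls
        Filtered per-sample CNV calls.
    probe_map
        Sorted (probe_id, chrom, pos) table (see ``io.read_probe_map``).
    phenotypes
        Sample -> quantitative phenotype. Samples absent from the table
        are excluded from the regression but still count toward the
        deviation and identity fractions (the population is larger than
        the phenotyped subset).
    """

    def __init__(
        self,
        calls,
        probe_map: pd.DataFrame,
        phenotypes: PhenotypeTable,
        gene_track: AnnotationTrack | None = None,
        samples: list[str] | None = None,
        min_dev: float = 0.05,
        identity_frac: float = 0.95,
        window_bp: int = 450_000,
    ) -> None:
        self.calls = list(calls)
        self.probe_map = probe_map
        self.phenotypes = phenotypes
        self.gene_track = gene_track
        if samples is None:
            samples = sorted(
                {c.sample_id for c in self.calls} | set(phenotypes.values)
            )
        self.samples = list(samples)
        self.min_dev = min_dev
        self.identity_frac = identity_frac
        self.window_bp = window_bp

    def fit(self) -> "CNVStateGWASResults":
        matrix = assign_probe_cn(self.calls, self.probe_map, self.samples)
        selected = select_variable_probes(matrix, self.min_dev)
        pheno = np.array(
            [self.phenotypes.values.get(s, np.nan) for s in self.samples], dtype=float
        )
        assocs: dict[str, ProbeAssoc] = {}
        pids = matrix.probe_map["probe_id"].to_numpy()
        for idx in selected:
            pid = str(pids[idx])
            assocs[pid] = probe_association(matrix.cn[idx], pheno, probe_id=pid)
        segments = build_segments(selected, matrix, self.identity_frac)
        segments = score_segments(segments, assocs, matrix, phenotype=pheno)
        if segments:
            qs = fdr_adjust([s.p_value for s in segments])
            for seg, q in zip(segments, qs):
                seg.fdr_q = float(q)
        else:
            logger.warning("no variable probe at min_dev=%.3g; empty scan", self.min_dev)
        if self.gene_track is not None:
            annotate_neighbors(segments, self.gene_track, self.window_bp)
        return CNVStateGWASResults(self, matrix, selected, assocs, segments)


class CNVStateGWASResults:
    """Fitted scan: segments with statistics, diagnostics and a summary."""

    def __init__(self, model, matrix, selected, probe_assocs, segments):
        self.model = model
        self.matrix = matrix
        self.selected_probes = selected
        self.probe_assocs = probe_assocs
        self.segments = segments

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for seg in self.segments:
            rows.append(
                {
                    "segment_id": seg.segment_id,
                    "chrom": seg.chrom,
                    "start": seg.start,
                    "end": seg.end,
                    "n_probes": seg.n_probes,
                    "probe_ids": ",".join(seg.probe_ids),
                    "representative_probe": seg.representative_probe,
                    "beta": self.probe_assocs[seg.representative_probe].beta,
                    "p_value": seg.p_value,
                    "fdr_q": seg.fdr_q,
                    **{f"n_cn{s}": seg.state_counts.get(s, 0) for s in range(5)},
                    "neighbor_genes": ",".join(g.name for g, _ in seg.neighbor_genes),
                }
            )
        cols = [
            "segment_id", "chrom", "start", "end", "n_probes", "probe_ids",
            "representative_probe", "beta", "p_value", "fdr_q",
            "n_cn0", "n_cn1", "n_cn2", "n_cn3", "n_cn4", "neighbor_genes",
        ]
        return pd.DataFrame(rows, columns=cols)

    def manhattan_table(self) -> pd.DataFrame:
        """(chrom, pos, -log10 q) per segment, ready for plotting."""
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.segments],
                "pos": [(s.start + s.end) // 2 for s in self.segments],
                "neg_log10_q": [-np.log10(s.fdr_q) for s in self.segments],
            }
        )

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        t = self.table
        return t[t["fdr_q"] < q_threshold].reset_index(drop=True)

    def summary(self) -> str:
        n_pheno = int(
            np.sum([s in self.model.phenotypes for s in self.model.samples])
        )
        lines = [
            "Copy-number state association scan",
            "==================================",
            f"samples:            {len(self.model.samples)} ({n_pheno} phenotyped)",
            f"probes:             {len(self.matrix.probe_map)} "
            f"({len(self.selected_probes)} variable at >={self.model.min_dev:.0%})",
            f"segments:           {len(self.segments)} "
            f"(identity >= {self.model.identity_frac:.0%})",
            f"q < 0.05:           {len(self.significant(0.05))}",
            f"q < 0.10:           {len(self.significant(0.10))}",
            "",
        ]
        top = self.table.sort_values("fdr_q").head(10)
        if len(top):
            lines.append(
                top[
                    ["segment_id", "chrom", "start", "end", "n_probes",
                     "representative_probe", "beta", "p_value", "fdr_q"]
                ].to_string(index=False)
            )
        return "\n".join(lines)
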