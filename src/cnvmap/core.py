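"""Domain types and call-level quality control.

All coordinates are held internally as 0-based half-open intervals
``[start, end)``; conversion from/to 1-based inclusive (PennCNV rawcnv)
and 0-based half-open (BED) conventions happens only at I/O boundaries
(see :mod:`cnvmap.io`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field


class CnvmapError(Exception):
    """Base class for all package errors."""


class ParseError(CnvmapError):
    """A malformed input record (carries file context where available)."""


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with lengths, plus the autosome subset.

    Chromosome names are stored normalized (no ``chr`` prefix). Sex
    chromosomes and unplaced scaffolds may be present but are excluded
    from analysis when ``autosomes_only`` filters are applied.
    """

    chromosomes: tuple[tuple[str, int], ...]
    autosome_names: frozenset[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise CnvmapError("duplicate chromosome names in genome build")
        if any(length <= 0 for _, length in self.chromosomes):
            raise CnvmapError("chromosome lengths must be positive")
        if self.autosome_names is None:
            auto = frozenset(n for n in names if n not in _SEX_CHROM_NAMES)
            object.__setattr__(self, "autosome_names", auto)
        else:
            object.__setattr__(self, "autosome_names", frozenset(self.autosome_names))
            if not self.autosome_names <= set(names):
                raise CnvmapError("autosome_names must be a subset of chromosome names")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def chrom_order(self, chrom: str) -> int:
        return self.names.index(chrom)

    def is_autosome(self, chrom: str) -> bool:
        return chrom in self.autosome_names

    @property
    def autosome_length(self) -> int:
        return sum(l for n, l in self.chromosomes if n in self.autosome_names)


_SEX_CHROM_NAMES = {"X", "Y", "W", "Z", "M", "MT"}


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix; comparison is case-sensitive afterwards."""
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True)
class CNVCall:
    """One per-sample called copy-number event (a deviation from 2n).

    ``start``/``end`` are 0-based half-open; ``cn`` is the integer copy
    number in 0..4 and never 2.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    cn: int
    num_snps: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CnvmapError(
                f"empty call interval [{self.start}, {self.end}) for {self.sample_id}"
            )
        if self.cn == 2:
            raise CnvmapError(f"cn=2 is not a CNV (sample {self.sample_id})")
        if not 0 <= self.cn <= 4:
            raise CnvmapError(f"cn={self.cn} outside the supported 0..4 states")
        if self.num_snps < 1:
            raise CnvmapError("num_snps must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_gain(self) -> bool:
        return self.cn > 2

    @property
    def is_loss(self) -> bool:
        return self.cn < 2


@dataclass(frozen=True)
class Interval:
    """A generic named genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CnvmapError(f"interval start > end: {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationTrack:
    """A labelled collection of intervals (genes, QTLs, known CNVRs, ...)."""

    label: str
    intervals: list[Interval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)


@dataclass
class QCReport:
    """Tally of the call-level QC filters.

    Each removed call is attributed to exactly one primary reason with
    precedence sample-level > chromosome > length.
    """

    n_input_calls: int = 0
    n_removed_short: int = 0
    n_removed_sex_chrom: int = 0
    removed_samples: dict[str, int] = field(default_factory=dict)
    n_output_calls: int = 0

    @property
    def n_removed_sample_qc(self) -> int:
        return sum(self.removed_samples.values())

    def validate(self) -> None:
        removed = self.n_removed_short + self.n_removed_sex_chrom + self.n_removed_sample_qc
        if self.n_output_calls != self.n_input_calls - removed:
            raise CnvmapError("QC report tallies are inconsistent")

    def to_tsv(self) -> str:
        lines = [
            "metric\tvalue",
            f"n_input_calls\t{self.n_input_calls}",
            f"n_removed_sample_qc\t{self.n_removed_sample_qc}",
            f"n_removed_sex_chrom\t{self.n_removed_sex_chrom}",
            f"n_removed_short\t{self.n_removed_short}",
            f"n_output_calls\t{self.n_output_calls}",
            f"n_removed_samples\t{len(self.removed_samples)}",
        ]
        for sid in sorted(self.removed_samples):
            lines.append(f"removed_sample:{sid}\t{self.removed_samples[sid]}")
        return "\n".join(lines) + "\n"


def filter_calls(
    calls: list[CNVCall],
    genome: GenomeBuild,
    min_len_bp: int = 5000,
    max_calls_per_sample: int = 150,
    autosomes_only: bool = True,
) -> tuple[list[CNVCall], QCReport]:
    """Apply the standard post-calling QC filters.

    Samples whose *pre-filter* call count exceeds ``max_calls_per_sample``
    are dropped entirely (low-quality arrays inflate region length through
    concatenation of false positives). Remaining calls shorter than
    ``min_len_bp`` or on non-autosomes are removed. A call of exactly
    ``min_len_bp`` is retained — only strictly shorter calls go.
    """
    report = QCReport(n_input_calls=len(calls))
    per_sample = Counter(c.sample_id for c in calls)
    bad_samples = {s for s, n in per_sample.items() if n > max_calls_per_sample}
    report.removed_samples = {s: per_sample[s] for s in sorted(bad_samples)}

    kept: list[CNVCall] = []
    for call in calls:
        if call.sample_id in bad_samples:
            continue
        if autosomes_only and not genome.is_autosome(call.chrom):
            report.n_removed_sex_chrom += 1
            continue
        if call.length < min_len_bp:
            report.n_removed_short += 1
            continue
        kept.append(call)
    report.n_output_calls = len(kept)
    report.validate()
    return kept, report


@dataclass
class PhenotypeTable:
    """Maps sample id to a continuous phenotype value (e.g. a breeding value)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        import math

        for sid, v in self.values.items():
            if not math.isfinite(v):
                raise CnvmapError(f"non-finite phenotype for sample {sid}")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, sample_id: str) -> float:
        return self.values[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.values
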