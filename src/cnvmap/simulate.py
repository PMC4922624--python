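"""Synthetic SNP-array CNV data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a diploid population segregating non-overlapping autosomal CNV
loci at configurable frequencies, per-animal calls with probe-grid
boundary jitter and Poisson false positives, a regular probe grid at
HD-chip density, dosage-effect phenotypes (y = mu + sum beta_l * (CN - 2)
+ noise), annotation tracks with controllable enrichment or depletion
relative to the true loci, and triplicate qPCR plates.

All randomness flows from one root seed through per-component child
streams (loci, carriers, calls, phenotype, qPCR), so changing one
sub-configuration does not perturb the others and every output is
byte-stable under a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnnotationTrack, CNVCall, CnvmapError, GenomeBuild, Interval, PhenotypeTable
from . import io as _io


@dataclass(frozen=True)
class QPCRConfig:
    base_ct: float = 25.0
    efficiency: float = 1.9
    ct_noise_sd: float = 0.1
    n_replicates: int = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Desk-scale defaults: 100 animals, 5 x 10 Mb chromosomes, probes
    every 3.2 kb (the density of a ~770k-probe chip on a 2.5 Gb genome),
    40 CNV loci of which 3 affect the phenotype."""

    seed: int = 0
    n_animals: int = 100
    n_chromosomes: int = 5
    chrom_length_bp: int = 10_000_000
    probe_spacing_bp: int = 3_200
    n_cnv_loci: int = 40
    locus_frequency_range: tuple[float, float] = (0.01, 0.6)
    locus_length_range: tuple[int, int] = (5_000, 500_000)
    gain_fraction: float = 0.4
    boundary_jitter_sd_bp: float = 3_200.0
    false_positive_rate: float = 2.0
    causal_loci: tuple[tuple[int, float], ...] = ((0, 0.8), (1, -0.6), (2, 0.5))
    phenotype_mu: float = 0.0
    phenotype_noise_sd: float = 1.0
    plant_overlap_pair: bool = False
    qpcr: QPCRConfig = field(default_factory=QPCRConfig)

    def __post_init__(self) -> None:
        if min(self.n_animals, self.n_chromosomes, self.n_cnv_loci) <= 0:
            raise CnvmapError("counts must be positive")
        lo, hi = self.locus_frequency_range
        if not (0 < lo <= hi < 1):
            raise CnvmapError("locus frequencies must lie in (0, 1)")
        for idx, _ in self.causal_loci:
            if not 0 <= idx < self.n_cnv_loci:
                raise CnvmapError(f"causal locus index {idx} out of range")


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    type: str  # loss | gain
    frequency: float
    beta: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    loci: list[Locus]
    cn: np.ndarray  # animals x loci, true integer CN (2 = non-carrier)
    animals: list[str]
    genetic_values: np.ndarray | None = None

    def carriers(self, locus_idx: int) -> np.ndarray:
        return np.flatnonzero(self.cn[:, locus_idx] != 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [l.chrom for l in self.loci],
                "start": [l.start for l in self.loci],
                "end": [l.end for l in self.loci],
                "type": [l.type for l in self.loci],
                "frequency": [l.frequency for l in self.loci],
                "beta": [l.beta for l in self.loci],
                "n_carriers": [len(self.carriers(i)) for i in range(len(self.loci))],
            }
        )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeBuild
    probe_map: pd.DataFrame
    truth: GroundTruth
    calls: list[CNVCall]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every core_io-readable file; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "calls": outdir / "calls.rawcnv",
            "chrom_sizes": outdir / "genome.chrom.sizes",
            "probe_map": outdir / "probes.tsv",
            "ground_truth": outdir / "ground_truth.tsv",
        }
        _io.write_penncnv_calls(self.calls, paths["calls"])
        _io.write_chrom_sizes(self.genome, paths["chrom_sizes"])
        _io.write_probe_map(self.probe_map, paths["probe_map"])
        self.truth.to_frame().to_csv(paths["ground_truth"], sep="\t", index=False)
        return paths


def _streams(seed: int, n: int = 6) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _make_genome(config: SimulationConfig) -> GenomeBuild:
    return GenomeBuild(
        chromosomes=tuple(
            (str(i + 1), config.chrom_length_bp) for i in range(config.n_chromosomes)
        )
    )


def _make_probe_map(config: SimulationConfig, genome: GenomeBuild) -> pd.DataFrame:
    rows = []
    k = 0
    for chrom, length in genome.chromosomes:
        for pos in range(config.probe_spacing_bp, length, config.probe_spacing_bp):
            rows.append((f"p{k:06d}", chrom, pos))
            k += 1
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])


def _snap(x: float, spacing: int) -> int:
    return int(round(x / spacing)) * spacing


def _place_loci(config: SimulationConfig, genome: GenomeBuild, rng) -> list[Locus]:
    """Place non-overlapping loci, boundaries snapped to the probe grid."""
    spacing = config.probe_spacing_bp
    lo_f, hi_f = config.locus_frequency_range
    lo_l, hi_l = config.locus_length_range
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in genome.names}
    loci: list[Locus] = []
    budget = 1000 * config.n_cnv_loci
    while len(loci) < config.n_cnv_loci:
        if budget <= 0:
            raise CnvmapError(
                "could not place loci without overlap; use fewer or shorter loci"
            )
        budget -= 1
        length = max(
            spacing, _snap(np.exp(rng.uniform(np.log(lo_l), np.log(hi_l))), spacing)
        )
        chrom = genome.names[int(rng.integers(0, len(genome.names)))]
        chrom_len = genome.lengths[chrom]
        if chrom_len - length - 2 * spacing <= spacing:
            continue
        start = _snap(rng.uniform(spacing, chrom_len - length - spacing), spacing)
        end = start + length + 1  # cover the probe at start+length
        # keep one probe spacing clear between loci so jittered calls stay apart
        if any(start < e + spacing and end + spacing > s for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        loci.append(
            Locus(
                chrom=chrom,
                start=start,
                end=end,
                type="gain" if rng.random() < config.gain_fraction else "loss",
                frequency=float(rng.uniform(lo_f, hi_f)),
            )
        )
    loci.sort(key=lambda l: (int(l.chrom), l.start))
    if config.plant_overlap_pair:
        loci.extend(_plant_overlap_pair(config, genome, placed, rng))
    for idx, beta in config.causal_loci:
        loci[idx].beta = beta
    return loci


def _plant_overlap_pair(config, genome, placed, rng) -> list[Locus]:
    """One gain and one loss locus with partial overlap (a 'both' region)."""
    spacing = config.probe_spacing_bp
    span = 20 * spacing
    for chrom in genome.names:
        chrom_len = genome.lengths[chrom]
        for _ in range(1000):
            start = _snap(rng.uniform(spacing, chrom_len - 2 * span - spacing), spacing)
            end = start + 2 * span
            if not any(start < e + spacing and end + spacing > s for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                half = span
                return [
                    Locus(chrom, start, start + half + span // 2 + 1, "loss", 0.2),
                    Locus(chrom, start + half, end + 1, "gain", 0.2),
                ]
    raise CnvmapError("no room to plant the overlapping gain/loss pair")


def _draw_carriers(config: SimulationConfig, loci: list[Locus], rng) -> np.ndarray:
    cn = np.full((config.n_animals, len(loci)), 2, dtype=np.int8)
    for j, locus in enumerate(loci):
        carriers = rng.random(config.n_animals) < locus.frequency
        if locus.type == "loss":
            states = np.where(rng.random(config.n_animals) < 0.1, 0, 1)
        else:
            states = np.where(rng.random(config.n_animals) < 0.1, 4, 3)
        cn[carriers, j] = states[carriers]
    return cn


def _num_snps(probe_pos: np.ndarray, start: int, end: int) -> int:
    return int(
        np.searchsorted(probe_pos, end, "left") - np.searchsorted(probe_pos, start, "left")
    )


def simulate_population(config: SimulationConfig) -> SimulatedDataset:
    """Generate the genome, probe grid, ground truth and rawcnv-style calls."""
    rng_loci, rng_carriers, rng_calls, _, _, _ = _streams(config.seed)
    genome = _make_genome(config)
    probe_map = _make_probe_map(config, genome)
    probe_pos = {
        chrom: grp["pos"].to_numpy() for chrom, grp in probe_map.groupby("chrom")
    }
    loci = _place_loci(config, genome, rng_loci)
    cn = _draw_carriers(config, loci, rng_carriers)
    animals = [f"A{i:04d}" for i in range(config.n_animals)]
    truth = GroundTruth(loci=loci, cn=cn, animals=animals)

    spacing = config.probe_spacing_bp
    calls: list[CNVCall] = []
    for i, animal in enumerate(animals):
        candidates: list[tuple[str, int, int, int]] = []
        for j, locus in enumerate(loci):
            state = int(cn[i, j])
            if state == 2:
                continue
            if config.boundary_jitter_sd_bp > 0:
                ds = _snap(rng_calls.normal(0, config.boundary_jitter_sd_bp), spacing)
                de = _snap(rng_calls.normal(0, config.boundary_jitter_sd_bp), spacing)
            else:
                ds = de = 0
            start = max(spacing, locus.start + ds)
            end = min(genome.lengths[locus.chrom] - 1, locus.end + de)
            if end - start < spacing:  # jittered away; event unobserved
                continue
            candidates.append((locus.chrom, start, end, state))
        # a caller emits disjoint events per sample: clip any jitter-induced
        # overlap between calls at neighbouring loci
        candidates.sort()
        animal_calls: list[CNVCall] = []
        prev_chrom, prev_end = "", 0
        for chrom, start, end, state in candidates:
            if chrom == prev_chrom:
                start = max(start, prev_end)
            if end - start < spacing:
                continue
            nsnp = _num_snps(probe_pos[chrom], start, end)
            if nsnp >= 1:
                animal_calls.append(
                    CNVCall(animal, chrom, start, end, cn=state, num_snps=nsnp)
                )
                prev_chrom, prev_end = chrom, end
        n_fp = rng_calls.poisson(config.false_positive_rate)
        for _ in range(n_fp):
            for _attempt in range(100):
                chrom = genome.names[int(rng_calls.integers(0, len(genome.names)))]
                length = max(
                    spacing,
                    _snap(np.exp(rng_calls.uniform(np.log(5_000), np.log(50_000))), spacing),
                )
                start = _snap(
                    rng_calls.uniform(spacing, genome.lengths[chrom] - length - spacing),
                    spacing,
                )
                end = start + length + 1
                if any(
                    c.chrom == chrom and c.start < end and c.end > start
                    for c in animal_calls
                ):
                    continue  # same-sample calls must stay disjoint
                state = 1 if rng_calls.random() < 0.5 else 3
                nsnp = _num_snps(probe_pos[chrom], start, end)
                if nsnp >= 1:
                    animal_calls.append(
                        CNVCall(animal, chrom, start, end, cn=state, num_snps=nsnp)
                    )
                break
        calls.extend(animal_calls)
    return SimulatedDataset(
        config=config, genome=genome, probe_map=probe_map, truth=truth, calls=calls
    )


def simulate_phenotype(truth: GroundTruth, config: SimulationConfig) -> PhenotypeTable:
    """Dosage-effect phenotype: y = mu + sum_l beta_l (CN_l - 2) + noise."""
    rng = _streams(config.seed)[3]
    betas = np.array([l.beta for l in truth.loci])
    genetic = (truth.cn.astype(float) - 2.0) @ betas
    noise = (
        rng.normal(0, config.phenotype_noise_sd, len(truth.animals))
        if config.phenotype_noise_sd > 0
        else np.zeros(len(truth.animals))
    )
    y = config.phenotype_mu + genetic + noise
    truth.genetic_values = genetic
    return PhenotypeTable(values=dict(zip(truth.animals, map(float, y))))


def simulate_annotation(
    genome: GenomeBuild,
    truth: GroundTruth,
    n_intervals: int,
    placement_bias: str = "uniform",
    seed: int = 0,
    length_range: tuple[int, int] = (2_000, 50_000),
    label: str = "genes",
    max_retries: int = 200_000,
) -> AnnotationTrack:
    """An annotation track placed uniformly, avoiding, or inside true loci.

    ``avoid_loci`` rejection-samples intervals sharing no base with any
    true CNV locus (a depleted annotation); ``inside_loci`` forces every
    interval to overlap a locus (an enriched one).
    """
    rng = np.random.default_rng(seed)
    loci_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for l in truth.loci:
        loci_by_chrom.setdefault(l.chrom, []).append((l.start, l.end))
    intervals: list[Interval] = []
    retries = max_retries
    while len(intervals) < n_intervals:
        if retries <= 0:
            raise CnvmapError(
                f"annotation placement exceeded the retry budget ({placement_bias})"
            )
        retries -= 1
        length = int(np.exp(rng.uniform(np.log(length_range[0]), np.log(length_range[1]))))
        if placement_bias == "inside_loci":
            locus = truth.loci[int(rng.integers(0, len(truth.loci)))]
            start = int(rng.integers(max(0, locus.start - length + 1), locus.end))
            chrom = locus.chrom
        else:
            chrom = genome.names[int(rng.integers(0, len(genome.names)))]
            start = int(rng.integers(0, genome.lengths[chrom] - length))
        end = start + length
        if placement_bias == "avoid_loci" and any(
            start < e and end > s for s, e in loci_by_chrom.get(chrom, [])
        ):
            continue
        intervals.append(Interval(chrom, start, end, f"{label}_{len(intervals)}"))
    return AnnotationTrack(label=label, intervals=intervals)


def simulate_qpcr(
    truth: GroundTruth,
    locus_idx: int,
    samples: list[str],
    config: SimulationConfig,
    region_id: str | None = None,
    primer_id: str | None = None,
) -> pd.DataFrame:
    """Triplicate qPCR plate rows for one locus over the given samples.

    Generative model per replicate (on the efficiency-corrected scale):
    target Ct = base_ct - log2(CN/2) + noise, control Ct = base_ct +
    noise; raw on-disk Ct values are de-corrected by log2(efficiency) so
    the analysis pipeline recovers CN exactly at zero noise. CN = 0 does
    not amplify.
    """
    rng = _streams(config.seed)[5]
    q = config.qpcr
    scale = float(np.log2(q.efficiency))
    locus = truth.loci[locus_idx]
    region_id = region_id or f"locus_{locus_idx}"
    primer_id = primer_id or f"primer_{locus_idx}"
    animal_index = {a: i for i, a in enumerate(truth.animals)}
    rows = []
    for sid in samples:
        state = int(truth.cn[animal_index[sid], locus_idx])
        amplified = state > 0
        target = []
        control = []
        for _ in range(q.n_replicates):
            noise_t = rng.normal(0, q.ct_noise_sd) if q.ct_noise_sd > 0 else 0.0
            noise_c = rng.normal(0, q.ct_noise_sd) if q.ct_noise_sd > 0 else 0.0
            if amplified:
                target.append((q.base_ct - np.log2(state / 2.0) + noise_t) / scale)
            else:
                target.append(np.nan)
            control.append((q.base_ct + noise_c) / scale)
        rows.append(
            {
                "sample_id": sid,
                "primer_id": primer_id,
                "region_id": region_id,
                "target_ct1": target[0],
                "target_ct2": target[1],
                "target_ct3": target[2],
                "control_ct1": control[0],
                "control_ct2": control[1],
                "control_ct3": control[2],
                "efficiency": q.efficiency,
                "amplified": amplified,
            }
        )
    return pd.DataFrame(rows)
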