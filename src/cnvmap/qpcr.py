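"""qPCR copy-number estimation and validation against array-derived calls.

Relative quantification follows the efficiency-corrected ddCt scheme with
a diploid reference: cycle thresholds are scaled by log2 of the primer
efficiency (so a perfectly doubling primer, E = 2, is unchanged), dCt is
the corrected target Ct minus the corrected control-gene Ct, ddCt
subtracts the mean dCt of the array-diploid (2n) animals for the same
primer, and the normalized ratio

    NR = 2 * 2**(-ddCt)

estimates the copy number directly (NR = 2 for a diploid sample). States
are assigned by geometric-mean boundaries between adjacent integers:
category n covers sqrt(n*(n-1)) < NR <= sqrt(n*(n+1)), with NR above
sqrt(20) called 5n (gain of more than two copies) and lack of
amplification called 0n (complete deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CnvmapError

PLATE_COLUMNS = [
    "sample_id", "primer_id", "region_id",
    "target_ct1", "target_ct2", "target_ct3",
    "control_ct1", "control_ct2", "control_ct3",
    "efficiency", "amplified",
]


def efficiency_correct(ct: float, efficiency: float) -> float:
    """Scale a cycle threshold by log2 of the amplification efficiency.

    ``efficiency`` is the per-cycle amplification factor in (1, 2]; the
    corrected value is ``ct * log2(efficiency)``, i.e. the number of
    perfect doublings equivalent to the observed cycles.
    """
    if not 1.0 < efficiency <= 2.0:
        raise CnvmapError(f"efficiency must be in (1, 2], got {efficiency}")
    return ct * math.log2(efficiency)


def normalized_ratio(ddct: float) -> float:
    """NR = 2 * 2**(-ddCt); equals the copy number under ideal conditions."""
    return 2.0 * 2.0 ** (-ddct)


# upper bound of category n is sqrt(n*(n+1)); ties go to the lower state
_CATEGORY_UPPER = [(n, math.sqrt(n * (n + 1))) for n in range(1, 5)]


def categorize_cn(nr: float, amplified: bool = True) -> int:
    """Assign the integer CN category 0..5 from a normalized ratio."""
    if not amplified:
        return 0
    if nr <= 0:
        raise CnvmapError(f"NR must be positive for an amplified assay, got {nr}")
    for n, upper in _CATEGORY_UPPER:
        if nr <= upper:
            return n
    return 5


@dataclass
class QPCRRecord:
    """One sample x primer measurement with its derived quantities."""

    sample_id: str
    primer_id: str
    region_id: str
    target_ct: tuple[float, ...]
    control_ct: tuple[float, ...]
    efficiency: float
    amplified: bool = True
    dct: float = np.nan
    ddct: float = np.nan
    nr: float = np.nan
    cn_category: int = -1

    def mean_corrected(self, which: str, drop_outlier: bool = False) -> float:
        vals = np.array(self.target_ct if which == "target" else self.control_ct, float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise CnvmapError(
                f"no finite {which} Ct for {self.sample_id}/{self.primer_id}"
            )
        if drop_outlier and vals.size >= 3:
            med = np.median(vals)
            dev = np.abs(vals - med)
            if dev.max() > 1.0:
                vals = np.delete(vals, int(np.argmax(dev)))
        return float(np.mean([efficiency_correct(v, self.efficiency) for v in vals]))


def delta_ct(record: QPCRRecord, drop_outlier: bool = False) -> float:
    """Corrected mean target Ct minus corrected mean control Ct."""
    return record.mean_corrected("target", drop_outlier) - record.mean_corrected(
        "control", drop_outlier
    )


def delta_delta_ct(record: QPCRRecord, reference_dct: float) -> QPCRRecord:
    """Fill in dCt and ddCt relative to the diploid reference dCt."""
    record.dct = delta_ct(record)
    record.ddct = record.dct - reference_dct
    return record


def reference_dct(records: list[QPCRRecord], two_n_samples: set[str]) -> float:
    """Mean dCt over array-diploid samples; the 2n anchor for one primer."""
    vals = [delta_ct(r) for r in records if r.sample_id in two_n_samples and r.amplified]
    if not vals:
        raise CnvmapError("no array-2n sample available to anchor the ddCt reference")
    return float(np.mean(vals))


def analyze_records(
    records: list[QPCRRecord], two_n_samples: dict[str, set[str]]
) -> list[QPCRRecord]:
    """Derive dCt, ddCt, NR and CN category for every record.

    ``two_n_samples`` maps primer id to the samples the array considers
    diploid for that primer's region (the ddCt reference panel).
    """
    by_primer: dict[str, list[QPCRRecord]] = {}
    for r in records:
        by_primer.setdefault(r.primer_id, []).append(r)
    for primer, recs in by_primer.items():
        ref = reference_dct(recs, two_n_samples.get(primer, set()))
        for r in recs:
            if not r.amplified:
                r.cn_category = 0
                continue
            delta_delta_ct(r, ref)
            r.nr = normalized_ratio(r.ddct)
            r.cn_category = categorize_cn(r.nr, amplified=True)
    return records


def read_qpcr_plate(path) -> pd.DataFrame:
    """Read a TSV plate table (see ``PLATE_COLUMNS`` for the layout)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise CnvmapError(f"plate file {path} lacks columns: {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["amplified"] = df["amplified"].astype(bool)
    return df


def records_from_plate(plate: pd.DataFrame) -> list[QPCRRecord]:
    records = []
    for row in plate.itertuples(index=False):
        records.append(
            QPCRRecord(
                sample_id=str(row.sample_id),
                primer_id=str(row.primer_id),
                region_id=str(row.region_id),
                target_ct=(row.target_ct1, row.target_ct2, row.target_ct3),
                control_ct=(row.control_ct1, row.control_ct2, row.control_ct3),
                efficiency=float(row.efficiency),
                amplified=bool(row.amplified),
            )
        )
    return records


def records_to_frame(records: list[QPCRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "primer_id": [r.primer_id for r in records],
            "region_id": [r.region_id for r in records],
            "dct": [r.dct for r in records],
            "ddct": [r.ddct for r in records],
            "nr": [r.nr for r in records],
            "cn_category": [r.cn_category for r in records],
        }
    )


@dataclass
class ConcordanceReport:
    """Per-region agreement between array calls and qPCR categories."""

    region_id: str
    tested_samples: int
    concordant_samples: int  # includes normal/normal agreement
    concordant_non_normal: int  # shared loss or gain type only
    validated: bool

    @property
    def concordance_pct(self) -> float:
        return self.concordant_samples / self.tested_samples

    @property
    def concordance_pct_non_normal(self) -> float:
        return self.concordant_non_normal / self.tested_samples


def _cn_type(cn: int) -> str:
    return "loss" if cn < 2 else "gain" if cn > 2 else "normal"


def concordance(
    region_id: str,
    array_calls_per_sample: dict[str, list[int]],
    qpcr_records_per_sample: dict[str, list[QPCRRecord]],
) -> ConcordanceReport:
    """Compare array CN type and qPCR CN type sample by sample.

    A sample is concordant when the array reports at least one call of a
    CNV type (loss or gain) over the region and at least one qPCR assay
    agrees on that type. Samples diploid on both platforms count toward
    the concordance percentage but not toward validation: a region is
    validated only by >= 1 sample concordant in a non-normal type.
    """
    tested = sorted(qpcr_records_per_sample)
    if not tested:
        raise CnvmapError(f"region {region_id}: no tested sample")
    n_conc = 0
    n_conc_nn = 0
    for sid in tested:
        array_types = {_cn_type(cn) for cn in array_calls_per_sample.get(sid, [])}
        qpcr_types = {_cn_type(r.cn_category) for r in qpcr_records_per_sample[sid]}
        shared = (array_types & qpcr_types) - {"normal"}
        if shared:
            n_conc += 1
            n_conc_nn += 1
        elif not (array_types - {"normal"}) and qpcr_types == {"normal"}:
            n_conc += 1
    return ConcordanceReport(
        region_id=region_id,
        tested_samples=len(tested),
        concordant_samples=n_conc,
        concordant_non_normal=n_conc_nn,
        validated=n_conc_nn >= 1,
    )


def validate_regions(
    plate: pd.DataFrame,
    calls,
    regions,
) -> tuple[pd.DataFrame, list[ConcordanceReport]]:
    """Run the full validation: ddCt analysis plus per-region concordance.

    For each primer, the ddCt reference panel is the set of plate samples
    with no array call overlapping the primer's region (array-2n).
    """
    region_by_id = {r.region_id: r for r in regions}
    records = records_from_plate(plate)

    def _array_cns(sid: str, region) -> list[int]:
        return [
            c.cn
            for c in calls
            if c.sample_id == sid
            and c.chrom == region.chrom
            and c.start < region.end
            and c.end > region.start
        ]

    two_n: dict[str, set[str]] = {}
    for r in records:
        region = region_by_id[r.region_id]
        if not _array_cns(r.sample_id, region):
            two_n.setdefault(r.primer_id, set()).add(r.sample_id)
    analyze_records(records, two_n)

    reports = []
    for region_id in sorted({r.region_id for r in records}):
        region = region_by_id[region_id]
        per_sample: dict[str, list[QPCRRecord]] = {}
        for r in records:
            if r.region_id == region_id:
                per_sample.setdefault(r.sample_id, []).append(r)
        array_calls = {sid: _array_cns(sid, region) for sid in per_sample}
        reports.append(concordance(region_id, array_calls, per_sample))
    return records_to_frame(records), reports


def reports_to_frame(reports: list[ConcordanceReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in reports],
            "tested_samples": [r.tested_samples for r in reports],
            "concordant_samples": [r.concordant_samples for r in reports],
            "concordant_non_normal": [r.concordant_non_normal for r in reports],
            "concordance_pct": [100 * r.concordance_pct for r in reports],
            "concordance_pct_non_normal": [
                100 * r.concordance_pct_non_normal for r in reports
            ],
            "validated": [r.validated for r in reports],
        }
    )
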