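"""Readers and writers for the text formats the pipeline touches.

Conventions at the boundary:

* PennCNV ``rawcnv`` call files are 1-based inclusive; converted to the
  internal 0-based half-open representation on read.
* BED files are natively 0-based half-open and pass through unchanged.
* chrom.sizes, probe-map, phenotype and qPCR plate files are plain TSV.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

from .core import (
    AnnotationTrack,
    CNVCall,
    CnvmapError,
    GenomeBuild,
    Interval,
    ParseError,
    PhenotypeTable,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

_RAWCNV_RE = re.compile(
    r"^(?:chr)?(?P<chrom>\S+):(?P<start>\d+)-(?P<end>[\d,]+)"
    r"\s+numsnp=(?P<numsnp>[\d,]+)"
    r"\s+length=(?P<length>[\d,]+)"
    r"\s+state(?P<state>\d+),cn=(?P<cn>\d+)"
    r"(?:\s+(?P<sample>\S+))?"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?"
    r"(?:\s+endsnp=(?P<endsnp>\S+))?"
    r"\s*$"
)


def _strip_thousands(s: str) -> int:
    return int(s.replace(",", ""))


def read_penncnv_calls(path: str | Path) -> list[CNVCall]:
    """Parse a PennCNV ``rawcnv`` file into a list of :class:`CNVCall`.

    One call per non-empty line; a line looks like::

        chr3:22796624-22815905 numsnp=10 length=19,282 state5,cn=3 SAMPLE startsnp=p1 endsnp=p10

    Coordinates are 1-based inclusive in the file. The ``length=`` field is
    cross-checked against ``end - start + 1``; on disagreement by more than
    1 bp a warning is logged and the coordinates win. If the sample field is
    absent the file stem is used as the sample id.
    """
    path = Path(path)
    calls: list[CNVCall] = []
    default_sample = path.stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = _RAWCNV_RE.match(line)
            if m is None:
                raise ParseError(f"{path}:{lineno}: malformed rawcnv line: {line!r}")
            start1 = _strip_thousands(m.group("start"))
            end1 = _strip_thousands(m.group("end"))
            cn = int(m.group("cn"))
            if cn == 2:
                raise ParseError(f"{path}:{lineno}: cn=2 record is not a CNV call")
            if not 0 <= cn <= 4:
                raise ParseError(f"{path}:{lineno}: cn={cn} outside supported states 0..4")
            stated_len = _strip_thousands(m.group("length"))
            true_len = end1 - start1 + 1
            if abs(stated_len - true_len) > 1:
                logger.warning(
                    "%s:%d: length field %d disagrees with coordinates (%d); "
                    "coordinates win",
                    path,
                    lineno,
                    stated_len,
                    true_len,
                )
            try:
                calls.append(
                    CNVCall(
                        sample_id=m.group("sample") or default_sample,
                        chrom=normalize_chrom(m.group("chrom")),
                        start=start1 - 1,
                        end=end1,
                        cn=cn,
                        num_snps=_strip_thousands(m.group("numsnp")),
                    )
                )
            except CnvmapError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return calls


_PENNCNV_STATE = {0: 1, 1: 2, 3: 5, 4: 6}  # cn -> HMM state label


def write_penncnv_calls(calls: list[CNVCall], path: str | Path) -> None:
    """Write calls in the rawcnv dialect (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"chr{c.chrom}:{c.start + 1}-{c.end} numsnp={c.num_snps} "
                f"length={c.length} state{_PENNCNV_STATE[c.cn]},cn={c.cn} "
                f"{c.sample_id}\n"
            )


def read_bed_track(
    path: str | Path,
    label: str,
    genome: GenomeBuild | None = None,
    on_unknown_chrom: str = "warn",
) -> AnnotationTrack:
    """Read a BED3+ file into an :class:`AnnotationTrack`.

    Column 4 (if present) is the interval name; columns 5+ are stored as
    attributes (``key=value`` tokens keep their key, bare tokens get
    positional keys ``col5``, ``col6``...). When a genome is supplied,
    intervals on unknown chromosomes or extending beyond a chromosome end
    are skipped with a warning (``on_unknown_chrom="error"`` raises).
    """
    intervals: list[Interval] = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has <3 columns")
            chrom = normalize_chrom(fields[0])
            start, end = int(fields[1]), int(fields[2])
            if start > end:
                raise ParseError(f"{path}:{lineno}: start > end")
            name = fields[3] if len(fields) > 3 else "."
            attrs = []
            for i, tok in enumerate(fields[4:], start=5):
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    attrs.append((k, v))
                else:
                    attrs.append((f"col{i}", tok))
            if genome is not None:
                bad = chrom not in genome.lengths or end > genome.lengths[chrom]
                if bad:
                    msg = f"{path}:{lineno}: interval outside genome bounds ({chrom}:{start}-{end})"
                    if on_unknown_chrom == "error":
                        raise ParseError(msg)
                    logger.warning("%s; skipped", msg)
                    continue
            intervals.append(Interval(chrom, start, end, name, tuple(attrs)))
    return AnnotationTrack(label=label, intervals=intervals)


def write_bed_track(track: AnnotationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in track.intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name]
            cols += [f"{k}={v}" for k, v in iv.attributes]
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path: str | Path) -> GenomeBuild:
    """Read a two-column ``chrom<TAB>length`` table into a GenomeBuild."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype=str)
    chroms = tuple(
        (normalize_chrom(r.chrom), int(r.length)) for r in df.itertuples(index=False)
    )
    return GenomeBuild(chromosomes=chroms)


def write_chrom_sizes(genome: GenomeBuild, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a two-column ``sample<TAB>value`` phenotype table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "value"], comment="#")
    df["sample"] = df["sample"].astype(str)
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r} in phenotype table")
    return PhenotypeTable(values=dict(zip(df["sample"], df["value"].astype(float))))


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, val in table.values.items():
            fh.write(f"{sid}\t{val:.6g}\n")


def read_probe_map(path: str | Path, genome: GenomeBuild | None = None) -> pd.DataFrame:
    """Read a ``probe_id<TAB>chrom<TAB>pos`` probe map.

    Returns a DataFrame with columns (probe_id, chrom, pos), sorted stably
    by (chromosome order, position, probe_id). Positions are 0-based.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["probe_id", "chrom", "pos"], comment="#"
    )
    df["probe_id"] = df["probe_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)
    df["pos"] = df["pos"].astype(int)
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ParseError(f"{path}: duplicate probe id {dup!r}")
    if genome is not None:
        order = {name: i for i, name in enumerate(genome.names)}
        df["_ord"] = df["chrom"].map(order)
        if df["_ord"].isna().any():
            bad = df.loc[df["_ord"].isna(), "chrom"].iloc[0]
            raise ParseError(f"{path}: probe on unknown chromosome {bad!r}")
    else:
        cats = sorted(df["chrom"].unique(), key=_chrom_sort_key)
        df["_ord"] = df["chrom"].map({c: i for i, c in enumerate(cats)})
    df = df.sort_values(["_ord", "pos", "probe_id"], kind="stable").drop(columns="_ord")
    return df.reset_index(drop=True)


def write_probe_map(probe_map: pd.DataFrame, path: str | Path) -> None:
    probe_map[["probe_id", "chrom", "pos"]].to_csv(path, sep="\t", header=False, index=False)


def _chrom_sort_key(name: str):
    return (0, int(name)) if name.isdigit() else (1, name)
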