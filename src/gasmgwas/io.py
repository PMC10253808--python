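"""Readers, writers and eco-trait derivation.

Input formats are deliberately plain: VCF v4.x (GT fields only) for SNP
genotypes of inbred lines, GFF3 or BED for gene intervals, headered TSV for
phenotype observations, daily weather and accession metadata.

The two derived eco-traits are the accumulative day-length (ADL, d*h) and
the accumulative active temperature (AAT, d*degC) over a growth period:
ADL sums daily day-lengths, AAT sums daily mean temperatures but only over
days whose mean (t_max + t_min)/2 is at least 10 degC.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel code for a missing genotype call.
MISSING: int = -1

GEO_GROUPS = ("O", "A", "B", "C", "D")
MG_SETS = ("E", "P", "L")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SnpMatrix:
    """Biallelic SNP calls for a panel of inbred accessions.

    ``calls`` is an ``n_accessions x n_snps`` int8 array with codes
    0 (reference homozygote), 1 (alternate homozygote) and -1 (missing).
    ``snps`` is a DataFrame with columns ``snp_id, chrom, pos`` (1-based bp),
    position-sorted within each chromosome.
    """

    accession_ids: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("duplicate accession ids")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.accession_ids), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.snps)} snps"
            )
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1 or MISSING (-1)")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicate snp ids")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            # ties allowed only for split multi-allelic records at one site
            if not np.all(np.diff(pos) >= 0):
                raise ValueError(f"positions not sorted on {chrom}")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic interval, 1-based inclusive on both ends."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end {self.end} < start {self.start}")


@dataclass
class PhenotypeTable:
    """Plot-level phenotype records: accession x environment x block x trait."""

    records: pd.DataFrame  # columns: accession, environment, block, trait, value

    COLUMNS = ("accession", "environment", "block", "trait", "value")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        key = ["accession", "environment", "block", "trait"]
        if self.records.duplicated(subset=key).any():
            dup = self.records[self.records.duplicated(subset=key, keep=False)]
            raise ValueError(f"duplicate phenotype keys, e.g. {dup.iloc[0][key].tolist()}")
        if not np.isfinite(self.records["value"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite phenotype values")

    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())

    def environments(self) -> list[str]:
        return sorted(self.records["environment"].astype(str).unique())

    def accession_means(self, trait: str) -> pd.Series:
        """Per-accession mean over environments and blocks (main-effect scale)."""
        sub = self.records[self.records["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present")
        return sub.groupby("accession")["value"].mean()

    def environment_means(self, trait: str) -> pd.DataFrame:
        """Accession x environment means (one row per accession-environment)."""
        sub = self.records[self.records["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present")
        return (
            sub.groupby(["accession", "environment"], as_index=False)["value"].mean()
        )


@dataclass
class DailyWeather:
    """Daily weather series: date, day_length (h), t_max, t_min (degC)."""

    records: pd.DataFrame  # columns: date (datetime.date), day_length, t_max, t_min

    def __post_init__(self) -> None:
        df = self.records
        for col in ("date", "day_length", "t_max", "t_min"):
            if col not in df.columns:
                raise ValueError(f"weather table missing column {col!r}")
        if df["date"].duplicated().any():
            raise ValueError("duplicate weather dates")
        df = df.sort_values("date").reset_index(drop=True)
        dl = df["day_length"].to_numpy(dtype=float)
        if ((dl < 0) | (dl > 24)).any():
            raise ValueError("day_length outside [0, 24]")
        dates = pd.to_datetime(df["date"]).dt.date.to_numpy()
        gaps = [
            (dates[i], dates[i + 1])
            for i in range(len(dates) - 1)
            if (dates[i + 1] - dates[i]).days != 1
        ]
        if gaps:
            raise ValueError(f"weather series has date gaps, first gap after {gaps[0][0]}")
        self.records = df

    def daily_mean(self) -> pd.Series:
        df = self.records
        return pd.Series(
            (df["t_max"].to_numpy() + df["t_min"].to_numpy()) / 2.0,
            index=pd.to_datetime(df["date"]).dt.date,
        )


@dataclass
class AccessionMetadata:
    """Geographic-group and maturity-group-set labels per accession.

    geo_group is one of O (center of origin), A, B, C, D (dissemination
    routes); mg_set is E (MG 000-0), P (MG I-VII) or L (MG VIII-X).
    """

    records: pd.DataFrame  # columns: accession, geo_group, mg_set

    def __post_init__(self) -> None:
        df = self.records
        for col in ("accession", "geo_group", "mg_set"):
            if col not in df.columns:
                raise ValueError(f"metadata missing column {col!r}")
        if df["accession"].duplicated().any():
            raise ValueError("duplicate accessions in metadata")
        bad_geo = set(df["geo_group"]) - set(GEO_GROUPS)
        if bad_geo:
            raise ValueError(f"unknown geo_group labels {sorted(bad_geo)}")
        bad_mg = set(df["mg_set"]) - set(MG_SETS)
        if bad_mg:
            raise ValueError(f"unknown mg_set labels {sorted(bad_mg)}")
        self.records = df.reset_index(drop=True)

    def group_members(self, column: str, groups: str | Sequence[str]) -> list[str]:
        """Accessions whose label in ``column`` is in ``groups`` (str or list)."""
        if isinstance(groups, str):
            groups = [groups]
        mask = self.records[column].isin(list(groups))
        return self.records.loc[mask, "accession"].tolist()


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, split_multiallelic: bool = False) -> SnpMatrix:
    """Read a VCF of inbred lines into a :class:`SnpMatrix`.

    Homozygous GTs map 0/0 -> 0 and 1/1 -> 1; heterozygous or missing GTs
    become MISSING (the panel is assumed inbred, so heterozygotes are treated
    as call errors).  Multi-allelic sites are rejected unless
    ``split_multiallelic`` is set, in which case each ALT becomes its own
    biallelic record (carrying that ALT -> 1, any other allele -> 0).
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no samples")
    rows = []
    cols: list[np.ndarray] = []
    for i, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            if not split_multiallelic:
                raise FormatError(
                    f"{path}: multi-allelic site {var.CHROM}:{var.POS} "
                    f"(record {i}); pass split_multiallelic=True to split"
                )
            alts = list(range(1, len(var.ALT) + 1))
        else:
            alts = [1]
        gts = var.genotypes  # [[a0, a1, phased], ...]
        for alt_idx in alts:
            codes = np.full(len(samples), MISSING, dtype=np.int8)
            for s, gt in enumerate(gts):
                a0, a1 = gt[0], gt[1]
                if len(gt) > 3:
                    raise FormatError(f"{path}: ploidy > 2 at record {i}")
                if a0 < 0 or a1 < 0 or a0 != a1:
                    continue  # missing or heterozygous
                codes[s] = 1 if a0 == alt_idx else 0
            snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
            if len(alts) > 1:
                snp_id = f"{snp_id}_alt{alt_idx}"
            rows.append((snp_id, var.CHROM, var.POS))
            cols.append(codes)
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])
    calls = np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=np.int8)
    order = snps.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    snps = snps.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    return SnpMatrix(samples, snps, calls)


def write_vcf(matrix: SnpMatrix, path: str | Path) -> None:
    """Write a :class:`SnpMatrix` as a minimal VCF v4.2 (GT only, A/T alleles)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = matrix.snps["chrom"].unique()
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.accession_ids) + "\n")
        code_to_gt = {0: "0/0", 1: "1/1", MISSING: "./."}
        for j in range(matrix.n_snps):
            snp = matrix.snps.iloc[j]
            gts = "\t".join(code_to_gt[int(c)] for c in matrix.calls[:, j])
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_gene_intervals(path: str | Path, dialect: str | None = None) -> list[GeneInterval]:
    """Read gene intervals from GFF3 (rows of type ``gene``) or BED.

    BED's 0-based half-open coordinates are converted to 1-based inclusive.
    ``dialect`` is inferred from the file extension when omitted.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {"": "bed", ".bed": "bed", ".gff": "gff3", ".gff3": "gff3"}.get(suffix)
        if dialect is None:
            raise FormatError(f"cannot infer dialect from extension {suffix!r}")
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    intervals: list[GeneInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "gff3":
                if len(fields) < 9:
                    raise FormatError(f"{path}:{lineno}: GFF3 row has {len(fields)} fields")
                if fields[2] != "gene":
                    continue
                chrom, start, end = fields[0], int(fields[3]), int(fields[4])
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID") or attrs.get("Name")
                if gene_id is None:
                    raise FormatError(f"{path}:{lineno}: gene row lacks ID attribute")
            else:
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: BED row has {len(fields)} fields")
                chrom = fields[0]
                start0, end0 = int(fields[1]), int(fields[2])
                if end0 <= start0:
                    raise FormatError(f"{path}:{lineno}: BED end {end0} <= start {start0}")
                start, end = start0 + 1, end0
                gene_id = fields[3] if len(fields) > 3 else f"{chrom}_{start}_{end}"
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id}")
            seen.add(gene_id)
            intervals.append(GeneInterval(gene_id, chrom, start, end))
    return intervals


def write_gene_intervals(intervals: Sequence[GeneInterval], path: str | Path,
                         dialect: str = "gff3") -> None:
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for g in intervals:
                fh.write(
                    f"{g.chromosome}\tgasmgwas\tgene\t{g.start}\t{g.end}\t.\t+\t.\tID={g.gene_id}\n"
                )
        elif dialect == "bed":
            for g in intervals:
                fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read the plot-level phenotype TSV (accession, environment, block, trait, value).

    Rows whose value is NA are dropped with a logged count; any other
    non-numeric value is a format error naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    expected = list(PhenotypeTable.COLUMNS)
    if list(df.columns[: len(expected)]) != expected:
        raise FormatError(
            f"{path}: expected header {expected}, got {list(df.columns)}"
        )
    na_mask = df["value"].isin(["NA", "NaN", ""]) | df["value"].isna()
    n_na = int(na_mask.sum())
    if n_na:
        logger.info("dropped %d NA phenotype rows from %s", n_na, path)
        df = df[~na_mask]
    try:
        values = df["value"].astype(float)
    except ValueError:
        bad = df[pd.to_numeric(df["value"], errors="coerce").isna()]
        raise FormatError(
            f"{path}: non-numeric value {bad.iloc[0]['value']!r} at data row "
            f"{bad.index[0] + 2}"
        ) from None
    out = df[["accession", "environment", "block", "trait"]].copy()
    out["value"] = values.to_numpy()
    return PhenotypeTable(out.reset_index(drop=True))


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def _parse_clock(text: str) -> float:
    """'HH:MM[:SS]' -> hours as a float."""
    parts = text.split(":")
    if len(parts) not in (2, 3):
        raise FormatError(f"bad clock time {text!r}")
    h, m = int(parts[0]), int(parts[1])
    s = int(parts[2]) if len(parts) == 3 else 0
    return h + m / 60.0 + s / 3600.0


def read_weather(path: str | Path) -> DailyWeather:
    """Read the daily weather TSV.

    Accepts either an explicit ``day_length`` column (hours) or
    ``sunrise``/``sunset`` clock-time columns, in which case
    day_length = sunset - sunrise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "date" not in df.columns:
        raise FormatError(f"{path}: weather table needs a date column")
    if "day_length" in df.columns:
        day_length = df["day_length"].astype(float)
    elif {"sunrise", "sunset"} <= set(df.columns):
        day_length = df["sunset"].map(_parse_clock) - df["sunrise"].map(_parse_clock)
    else:
        raise FormatError(f"{path}: need day_length or sunrise+sunset columns")
    out = pd.DataFrame(
        {
            "date": pd.to_datetime(df["date"]).dt.date,
            "day_length": day_length.to_numpy(dtype=float),
            "t_max": df["t_max"].astype(float).to_numpy(),
            "t_min": df["t_min"].astype(float).to_numpy(),
        }
    )
    return DailyWeather(out)


def write_weather(weather: DailyWeather, path: str | Path) -> None:
    weather.records.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> AccessionMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return AccessionMetadata(df)


def write_metadata(meta: AccessionMetadata, path: str | Path) -> None:
    meta.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Eco-trait derivation
# ---------------------------------------------------------------------------

def derive_adl_aat(
    weather: DailyWeather,
    period_start: _dt.date | str,
    period_end: _dt.date | str,
) -> tuple[float, float]:
    """Accumulative day-length and active temperature over [start, end).

    The half-open convention makes a D-day growth period sum exactly D daily
    terms.  ADL sums the day-lengths; AAT sums daily mean temperatures
    (t_max + t_min)/2 over days whose mean is at least 10 degC (active
    temperature threshold).
    """
    start = pd.to_datetime(period_start).date()
    end = pd.to_datetime(period_end).date()
    if end <= start:
        raise ValueError(f"empty period [{start}, {end})")
    df = weather.records
    dates = pd.to_datetime(df["date"]).dt.date
    mask = (dates >= start) & (dates < end)
    n_days = (end - start).days
    if int(mask.sum()) != n_days:
        raise ValueError(
            f"weather covers {int(mask.sum())} of {n_days} days in [{start}, {end})"
        )
    sub = df[mask]
    adl = float(sub["day_length"].sum())
    daily_mean = (sub["t_max"].to_numpy() + sub["t_min"].to_numpy()) / 2.0
    aat = float(daily_mean[daily_mean >= 10.0].sum())
    return adl, aat
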