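"""Readers and writers for the external formats the pipeline touches.

Formats handled here:

* pooled-array intensity TSV (project-defined dialect; Illumina raw exports
  are proprietary, so a plain-text dialect keeps runs reproducible),
* gene annotation in BED4+ (converted to 1-based inclusive coordinates at
  the boundary),
* pathway gene sets in GMT,
* per-subject genotype TSV and platelet-series TSV,
* full-precision results TSV.

All readers accept plain or gzip-compressed files.
"""

from __future__ import annotations

import gzip
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(str(i) for i in range(1, 23))
SEX_CHROMOSOMES = ("X", "Y", "MT")
VALID_CHROMOSOMES = AUTOSOMES + SEX_CHROMOSOMES
POOL_LABELS = ("case", "control")

INTENSITY_COLUMNS = ["snp_id", "chrom", "pos", "pool", "replicate", "green", "red"]
GENOTYPE_META_COLUMNS = ["subject", "group"]


class FormatError(ValueError):
    """Input file does not conform to the expected dialect."""


class DuplicateKeyError(ValueError):
    """A key that must be unique appears more than once."""


def _normalize_chrom(label: str) -> str:
    """Map 'chr22'/'22'/'chrM' style labels onto 1-22, X, Y, MT."""
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper()
    if c in ("M", "MT"):
        return "MT"
    return c


@contextmanager
def _open_text(source, mode: str = "rt"):
    """Open a path (optionally .gz), or pass a stream through without closing it."""
    if hasattr(source, "read") or hasattr(source, "write"):
        yield source
        return
    path = Path(source)
    fh = gzip.open(path, mode) if path.suffix == ".gz" else open(path, mode)
    try:
        yield fh
    finally:
        fh.close()


# ---------------------------------------------------------------------------
# Pooled intensity table
# ---------------------------------------------------------------------------

@dataclass
class PooledIntensityTable:
    """Two-channel raw intensities per SNP x pool x replicate.

    ``data`` columns: snp_id, chrom, pos, pool, replicate, green_raw,
    red_raw, failed.  A row is *failed* when both channels read zero
    (hybridization failure); failed rows are retained here and dropped by QC.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.data["snp_id"].unique()

    def __len__(self) -> int:
        return len(self.data)


def read_pool_intensities(source) -> PooledIntensityTable:
    """Read the intensity TSV dialect.

    Header ``snp_id chrom pos pool replicate green red``; '.' marks a
    missing intensity.  Raises :class:`FormatError` for a missing column,
    ``ValueError`` (with line numbers) for negative intensities or bad
    labels, and :class:`DuplicateKeyError` for a repeated
    (snp_id, pool, replicate) key.
    """
    with _open_text(source) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, na_values=["."], keep_default_na=False)

    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"intensity TSV is missing column(s): {', '.join(missing)}")

    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"].astype(str),
            "chrom": df["chrom"].map(_normalize_chrom),
            "pos": pd.to_numeric(df["pos"]).astype(np.int64),
            "pool": df["pool"].astype(str),
            "replicate": pd.to_numeric(df["replicate"]).astype(np.int64),
            "green_raw": pd.to_numeric(df["green"]).astype(float),
            "red_raw": pd.to_numeric(df["red"]).astype(float),
        }
    )

    bad_pool = ~out["pool"].isin(POOL_LABELS)
    if bad_pool.any():
        lines = (out.index[bad_pool] + 2).tolist()
        raise ValueError(f"pool label must be one of {POOL_LABELS}; bad lines: {lines}")
    bad_chrom = ~out["chrom"].isin(VALID_CHROMOSOMES)
    if bad_chrom.any():
        lines = (out.index[bad_chrom] + 2).tolist()
        raise ValueError(f"unrecognized chromosome label; bad lines: {lines}")
    if (out["pos"] < 1).any():
        lines = (out.index[out["pos"] < 1] + 2).tolist()
        raise ValueError(f"pos must be >= 1; bad lines: {lines}")
    if (out["replicate"] < 1).any():
        lines = (out.index[out["replicate"] < 1] + 2).tolist()
        raise ValueError(f"replicate must be >= 1; bad lines: {lines}")
    neg = (out["green_raw"] < 0) | (out["red_raw"] < 0)
    if neg.any():
        lines = (out.index[neg] + 2).tolist()
        raise ValueError(f"negative intensity; bad lines: {lines}")

    dup = out.duplicated(subset=["snp_id", "pool", "replicate"], keep=False)
    if dup.any():
        key = out.loc[dup, ["snp_id", "pool", "replicate"]].iloc[0]
        raise DuplicateKeyError(
            "duplicate (snp_id, pool, replicate) key: "
            f"({key['snp_id']}, {key['pool']}, {key['replicate']})"
        )

    # missing channel values (written as '.') count as zero signal
    out["green_raw"] = out["green_raw"].fillna(0.0)
    out["red_raw"] = out["red_raw"].fillna(0.0)
    out["failed"] = (out["green_raw"] == 0.0) & (out["red_raw"] == 0.0)
    n_failed = int(out["failed"].sum())
    if n_failed:
        logger.info("read_pool_intensities: %d row(s) flagged as failed hybridizations", n_failed)
    return PooledIntensityTable(out)


def write_pool_intensities(table: PooledIntensityTable, target) -> None:
    df = table.data
    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"],
            "chrom": df["chrom"],
            "pos": df["pos"],
            "pool": df["pool"],
            "replicate": df["replicate"],
            "green": df["green_raw"],
            "red": df["red_raw"],
        }
    )
    with _open_text(target, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Gene annotation (BED)
# ---------------------------------------------------------------------------

def read_gene_annotation(source) -> pd.DataFrame:
    """Read gene spans from BED4+ into 1-based inclusive coordinates.

    BED uses 0-based half-open intervals, so ``start = chromStart + 1`` and
    ``end = chromEnd``.  Strand (column 6) is carried if present, 'unknown'
    otherwise.  Output is sorted by (chrom, start).
    """
    rows = []
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"BED line {lineno}: expected >= 4 fields, got {len(parts)}")
            chrom = _normalize_chrom(parts[0])
            chrom_start, chrom_end = int(parts[1]), int(parts[2])
            if chrom_start >= chrom_end:
                raise ValueError(
                    f"BED line {lineno}: zero/negative-length interval "
                    f"({chrom_start}, {chrom_end})"
                )
            name = parts[3].strip()
            if not name:
                raise ValueError(f"BED line {lineno}: empty gene symbol")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "unknown"
            rows.append((name, chrom, chrom_start + 1, chrom_end, strand))
    ann = pd.DataFrame(rows, columns=["gene_symbol", "chrom", "start", "end", "strand"])
    return ann.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_gene_annotation(annotation: pd.DataFrame, target) -> None:
    """Write 1-based inclusive gene spans back out as BED4/BED6."""
    with _open_text(target, "wt") as fh:
        for rec in annotation.itertuples(index=False):
            fields = [rec.chrom, str(rec.start - 1), str(rec.end), rec.gene_symbol]
            if rec.strand in ("+", "-"):
                fields += ["0", rec.strand]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Pathway gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class PathwayDB:
    """Named gene-symbol sets plus the size of the reference universe."""

    pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    reference_size: int = 0

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[str]:
        return iter(self.pathways)


def read_gmt(source, reference_size: int | None = None) -> PathwayDB:
    """Read GMT (name, description, gene symbols...).

    Duplicate genes within a set are deduplicated; a pathway name listed
    twice keeps the last definition (with a warning).  ``reference_size``
    defaults to the size of the union of all sets.
    """
    pathways: dict[str, frozenset[str]] = {}
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: expected >= 3 fields, got {len(parts)}")
            name = parts[0]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"GMT line {lineno}: pathway '{name}' has no genes")
            if name in pathways:
                logger.warning("GMT: pathway '%s' defined twice; keeping the last definition", name)
            pathways[name] = genes
    if reference_size is None:
        union: set[str] = set()
        for genes in pathways.values():
            union |= genes
        reference_size = len(union)
    max_set = max((len(g) for g in pathways.values()), default=0)
    if reference_size < max_set:
        raise ValueError(
            f"reference_size {reference_size} smaller than the largest set ({max_set})"
        )
    return PathwayDB(pathways=pathways, reference_size=reference_size)


def write_gmt(db: PathwayDB, target) -> None:
    with _open_text(target, "wt") as fh:
        for name, genes in db.pathways.items():
            fh.write("\t".join([name, "na"] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Genotype cohort
# ---------------------------------------------------------------------------

@dataclass
class GenotypeCohort:
    """Per-subject minor-allele dosages with group labels.

    ``genotypes`` is indexed by subject id with one nullable-integer column
    per SNP (dosage 0/1/2, NA for missing).  ``group`` holds case/control or
    response/nonresponse labels.  Optional treatment-outcome attributes are
    attached by the response simulator or the platelet-series reader:
    ``baseline_plt`` and ``plt`` (subjects x days, columns ``day_<d>``,
    units 1e9 platelets per litre).
    """

    genotypes: pd.DataFrame
    group: pd.Series
    baseline_plt: pd.Series | None = None
    plt: pd.DataFrame | None = None
    response: pd.Series | None = None

    @property
    def subjects(self) -> pd.Index:
        return self.genotypes.index

    @property
    def snp_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    def __len__(self) -> int:
        return len(self.genotypes)


def read_genotypes(source) -> GenotypeCohort:
    """Read the genotype TSV dialect ``subject group snp1 snp2 ...``.

    Dosages are 0/1/2 minor-allele copies or NA; anything else raises
    ``ValueError``.
    """
    with _open_text(source) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    missing = [c for c in GENOTYPE_META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"genotype TSV is missing column(s): {', '.join(missing)}")
    snp_cols = [c for c in df.columns if c not in GENOTYPE_META_COLUMNS]
    if df["subject"].duplicated().any():
        dup = df.loc[df["subject"].duplicated(), "subject"].iloc[0]
        raise DuplicateKeyError(f"duplicate subject id: {dup}")
    geno = df[snp_cols].apply(pd.to_numeric).astype("Int64")
    bad = ~(geno.isin([0, 1, 2]) | geno.isna())
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        raise ValueError(f"dosage outside {{0,1,2,NA}} in column '{col}'")
    geno.index = pd.Index(df["subject"], name="subject")
    group = pd.Series(df["group"].values, index=geno.index, name="group")
    return GenotypeCohort(genotypes=geno, group=group)


def write_genotypes(cohort: GenotypeCohort, target) -> None:
    out = cohort.genotypes.astype("Int64").astype(object).where(
        cohort.genotypes.notna(), "NA"
    )
    out.insert(0, "group", cohort.group)
    out = out.reset_index()
    with _open_text(target, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


def read_platelet_series(source) -> tuple[pd.Series, pd.DataFrame]:
    """Read ``subject baseline day_1 day_3 ...`` platelet counts (1e9/L)."""
    with _open_text(source) as fh:
        df = pd.read_csv(fh, sep="\t")
    if "subject" not in df.columns or "baseline" not in df.columns:
        raise FormatError("platelet TSV needs 'subject' and 'baseline' columns")
    df = df.set_index("subject")
    day_cols = [c for c in df.columns if c.startswith("day_")]
    if (df[["baseline"] + day_cols] < 0).any().any():
        raise ValueError("platelet counts must be >= 0")
    return df["baseline"].astype(float), df[day_cols].astype(float)


def write_platelet_series(baseline: pd.Series, plt: pd.DataFrame, target) -> None:
    out = plt.copy()
    out.insert(0, "baseline", baseline)
    out = out.reset_index().rename(columns={"index": "subject"})
    with _open_text(target, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Generic results TSV
# ---------------------------------------------------------------------------

def write_results(results: pd.DataFrame, target, columns: list[str] | None = None) -> None:
    """Write a results table with fixed column order and full-precision floats."""
    df = results if columns is None else results[columns]
    with _open_text(target, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_results(source) -> pd.DataFrame:
    with _open_text(source) as fh:
        return pd.read_csv(fh, sep="\t")
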