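"""Table readers/writers and schema validation.

CSV and Parquet are dispatched on file extension.  Genotypes can come
from a long-format table (participant_id, snv_id, allele1, allele2) or
a VCF 4.2 with GT fields; a minimal GT-only VCF writer is provided for
round-tripping synthetic genotypes.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("hrphase")

__all__ = [
    "read_table",
    "write_table",
    "read_hr",
    "read_cohort",
    "read_genotypes",
    "read_ontology",
    "read_labs",
    "write_vcf",
    "read_vcf",
    "SchemaError",
]


class SchemaError(ValueError):
    """Raised when an input table is missing required columns."""


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        return pd.read_parquet(path)
    if path.suffix == ".tsv":
        return pd.read_csv(path, sep="\t")
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".parquet", ".pq"):
        df.to_parquet(path, index=False)
    elif path.suffix == ".tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        df.to_csv(path, index=False)


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what}: missing columns {missing}; found {list(df.columns)}")


def read_hr(path: str | Path) -> pd.DataFrame:
    """Raw heart-rate samples; malformed rows are dropped and counted."""
    df = read_table(path)
    _require(df, ["participant_id", "timestamp", "bpm"], "hr table")
    bpm = pd.to_numeric(df["bpm"], errors="coerce")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = bpm.isna() | ts.isna() | (bpm <= 0)
    if bad.any():
        for i in np.flatnonzero(bad.to_numpy())[:20]:
            logger.warning("hr table: rejected row %d: %s", i, df.iloc[i].to_dict())
        logger.warning("hr table: rejected %d malformed rows", int(bad.sum()))
    out = df.loc[~bad].copy()
    out["bpm"] = bpm[~bad]
    out["timestamp"] = ts[~bad]
    return out.reset_index(drop=True)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    _require(df, ["participant_id", "phi"], "cohort table")
    return df


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Long-format genotypes from CSV/Parquet, or VCF by extension."""
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return read_vcf(path)
    df = read_table(path)
    _require(df, ["participant_id", "snv_id", "allele1", "allele2"], "genotype table")
    return df


def read_ontology(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    _require(df, ["parent_id", "child_id"], "ontology edge list")
    return df


def read_labs(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    _require(df, ["participant_id", "date", "hba1c_pct"], "lab table")
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_vcf(genotypes: pd.DataFrame, snv_meta: pd.DataFrame,
              path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields.

    ``snv_meta`` needs columns snv_id, ref_allele and alt alleles
    observed; positions are synthetic (1-based order).
    """
    pids = sorted(genotypes["participant_id"].unique())
    sample_names = [f"S{p}" for p in pids]
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(sample_names)]
    by_snv = {s: g.set_index("participant_id") for s, g in genotypes.groupby("snv_id")}
    for pos, (_, meta) in enumerate(snv_meta.iterrows(), start=1):
        snv = meta["snv_id"]
        g = by_snv[snv]
        ref = meta["ref_allele"]
        alts = sorted({a for col in ("allele1", "allele2") for a in g[col].unique()
                       if a != ref})
        code = {ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
        calls = []
        for p in pids:
            if p in g.index:
                row = g.loc[p]
                calls.append(f"{code[row['allele1']]}/{code[row['allele2']]}")
            else:
                calls.append("./.")
        lines.append("\t".join(
            ["1", str(pos), str(snv), ref, ",".join(alts) or ".", ".", "PASS",
             ".", "GT"] + calls))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read VCF genotypes (GT field) into long format.

    Uses cyvcf2 when available, otherwise a plain-text fallback
    sufficient for uncompressed GT-only files.  Sample names of the
    form ``S<id>`` map back to integer participant ids.
    """
    try:
        from cyvcf2 import VCF  # noqa: PLC0415
    except ImportError:
        return _read_vcf_text(path)
    rows = []
    vcf = VCF(str(path))
    samples = vcf.samples
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        for s, gt in zip(samples, var.genotypes):
            a1 = alleles[gt[0]] if gt[0] >= 0 else None
            a2 = alleles[gt[1]] if gt[1] >= 0 else None
            if a1 is None or a2 is None:
                continue
            rows.append((_sample_to_pid(s), var.ID, a1, a2))
    return pd.DataFrame(rows, columns=["participant_id", "snv_id",
                                       "allele1", "allele2"])


def _sample_to_pid(sample: str):
    if sample.startswith("S") and sample[1:].isdigit():
        return int(sample[1:])
    return sample


def _read_vcf_text(path: str | Path) -> pd.DataFrame:
    rows = []
    samples: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("##") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if line.startswith("#CHROM"):
            samples = fields[9:]
            continue
        alleles = [fields[3]] + (fields[4].split(",") if fields[4] != "." else [])
        fmt = fields[8].split(":")
        gt_idx = fmt.index("GT")
        for s, call in zip(samples, fields[9:]):
            gt = call.split(":")[gt_idx].replace("|", "/")
            parts = gt.split("/")
            if len(parts) != 2 or "." in parts:
                continue
            a1, a2 = alleles[int(parts[0])], alleles[int(parts[1])]
            rows.append((_sample_to_pid(s), fields[2], a1, a2))
    return pd.DataFrame(rows, columns=["participant_id", "snv_id",
                                       "allele1", "allele2"])
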