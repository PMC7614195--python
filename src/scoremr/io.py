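"""Readers and writers for the package's tab-separated file dialects.

All tables are plain TSV with an optional commented provenance header
(lines starting with ``#``).  Summary statistics use a GWAS-SSF-like dialect
with a fixed column set; missing values are encoded ``NA``.  Writers produce
canonical files for which ``write(read(f)) == f`` byte-for-byte.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import pandas as pd

from .cohort import SUMMARY_COLUMNS
from .derive import InstrumentVariant

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_instruments",
    "write_instruments",
    "read_dosages",
    "write_dosages",
    "read_keyed_table",
    "write_keyed_table",
]

INSTRUMENT_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "weight",
    "is_cis",
    "pleiotropy_flags",
    "clump_members",
    "standard_error",
    "p_value",
    "n",
]


class SummaryStatFormatError(ValueError):
    """Malformed summary-statistics file (message carries line numbers)."""


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        return repr(x)
    return str(x)


def _provenance_lines(provenance: Mapping[str, str] | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {k}: {v}" for k, v in provenance.items()]


def _write_rows(path, header: list[str], rows: Iterable[list[str]], provenance=None) -> None:
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_summary_stats(records: pd.DataFrame, path, provenance=None) -> None:
    """Write summary statistics in the canonical dialect (columns in fixed
    order, NaN as ``NA``, floats in shortest round-trip form)."""
    df = records[SUMMARY_COLUMNS]
    rows = []
    for t in df.itertuples(index=False):
        rows.append(
            [
                str(t.chromosome),
                str(int(t.base_pair_location)),
                str(t.rsid),
                str(t.effect_allele),
                str(t.other_allele),
                _fmt(float(t.effect_allele_frequency)),
                _fmt(float(t.beta)),
                _fmt(float(t.standard_error)),
                _fmt(float(t.p_value)),
                str(int(t.n)),
            ]
        )
    _write_rows(path, SUMMARY_COLUMNS, rows, provenance)


def read_summary_stats(path) -> pd.DataFrame:
    """Read and validate a summary-statistics TSV.

    The header must match the dialect exactly; malformed rows (non-numeric
    beta/SE, se <= 0, p outside [0,1], eaf outside (0,1)) are rejected with
    their 1-based line numbers.  ``NA`` markers are allowed in the numeric
    effect columns (undefined-effect records, excluded downstream).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    while body_start < len(lines) and lines[body_start].startswith("#"):
        body_start += 1
    if body_start >= len(lines):
        raise SummaryStatFormatError("file has no header line")
    header = lines[body_start].split("\t")
    if header != SUMMARY_COLUMNS:
        unknown = [c for c in header if c not in SUMMARY_COLUMNS]
        raise SummaryStatFormatError(
            f"header mismatch: unknown/misplaced columns {unknown or header}"
        )
    records = []
    errors = []
    for lineno, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(SUMMARY_COLUMNS):
            errors.append(f"line {lineno}: expected {len(SUMMARY_COLUMNS)} fields, got {len(parts)}")
            continue
        rec = dict(zip(SUMMARY_COLUMNS, parts))
        try:
            rec["base_pair_location"] = int(rec["base_pair_location"])
            rec["n"] = int(rec["n"])
            for col in ("effect_allele_frequency", "beta", "standard_error", "p_value"):
                rec[col] = float("nan") if rec[col] == "NA" else float(rec[col])
        except ValueError:
            errors.append(f"line {lineno}: non-numeric value in numeric column")
            continue
        se, p, eaf = rec["standard_error"], rec["p_value"], rec["effect_allele_frequency"]
        if not math.isnan(se) and se <= 0:
            errors.append(f"line {lineno}: standard_error must be > 0")
            continue
        if not math.isnan(p) and not 0.0 <= p <= 1.0:
            errors.append(f"line {lineno}: p_value outside [0,1]")
            continue
        if not math.isnan(eaf) and not 0.0 < eaf < 1.0:
            errors.append(f"line {lineno}: effect_allele_frequency outside (0,1)")
            continue
        records.append(rec)
    if errors:
        raise SummaryStatFormatError("; ".join(errors))
    if not records:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    return pd.DataFrame.from_records(records)[SUMMARY_COLUMNS]


def write_instruments(instruments: list[InstrumentVariant], path, provenance=None) -> None:
    rows = []
    for v in instruments:
        rows.append(
            [
                v.rsid,
                str(v.chrom),
                str(v.pos),
                v.effect_allele,
                v.other_allele,
                _fmt(float(v.eaf)),
                _fmt(float(v.weight)),
                "1" if v.is_cis else "0",
                ";".join(v.pleiotropy_flags),
                ";".join(v.clump_members),
                _fmt(float(v.se)),
                _fmt(float(v.p)),
                str(int(v.n)),
            ]
        )
    _write_rows(path, INSTRUMENT_COLUMNS, rows, provenance)


def read_instruments(path) -> list[InstrumentVariant]:
    """Read an instrument TSV (the trailing standard_error/p_value/n columns
    are optional; absent values default to NaN/0)."""
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    required = INSTRUMENT_COLUMNS[:10]
    if header[: len(required)] != required:
        raise ValueError(f"instrument header mismatch: {header}")
    out = []
    for line in lines[1:]:
        d = dict(zip(header, line.split("\t")))
        out.append(
            InstrumentVariant(
                rsid=d["rsid"],
                chrom=d["chrom"],
                pos=int(d["pos"]),
                effect_allele=d["effect_allele"],
                other_allele=d["other_allele"],
                eaf=float(d["eaf"]),
                beta=float(d["weight"]),
                se=float(d.get("standard_error", "nan") or "nan"),
                p=float(d.get("p_value", "nan") or "nan"),
                n=int(d.get("n", "0") or "0"),
                weight=float(d["weight"]),
                is_cis=d["is_cis"] == "1",
                pleiotropy_flags=[f for f in d["pleiotropy_flags"].split(";") if f],
                clump_members=[m for m in d["clump_members"].split(";") if m],
            )
        )
    return out


def write_dosages(dosages: pd.DataFrame, path, provenance=None) -> None:
    """Dosage matrix TSV: header row of rsids, first column individual IDs."""
    header = ["iid"] + list(dosages.columns)
    rows = (
        [str(iid)] + [_fmt(float(x)) for x in row]
        for iid, row in zip(dosages.index, dosages.to_numpy())
    )
    _write_rows(path, header, rows, provenance)


def read_dosages(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="iid")
    bad = [(c, float(df[c].min()), float(df[c].max())) for c in df.columns
           if df[c].min() < 0 or df[c].max() > 2]
    if bad:
        raise ValueError(f"dosages outside [0,2]: {bad[:3]}")
    return df


def write_keyed_table(df: pd.DataFrame, path, provenance=None) -> None:
    """Covariate/outcome/phenotype table keyed by individual ID."""
    header = ["iid"] + list(df.columns)
    rows = (
        [str(iid)] + [_fmt(x) if isinstance(x, float) else str(x) for x in row]
        for iid, row in zip(df.index, df.itertuples(index=False))
    )
    _write_rows(path, header, rows, provenance)


def read_keyed_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="iid")


def write_table(df: pd.DataFrame, path, provenance=None) -> None:
    """Generic TSV writer with provenance header (for report tables)."""
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
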