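"""On-disk formats, configuration and run logging.

All tabular artifacts are plain text: tab-separated matrices (first column the
feature id, header row the sample ids), a comma-separated sample sheet, a
tab-separated dosage table (snp_id, chrom, pos, then one column per subject)
with an optional minimal VCF dialect behind the same contract, and result
tables with a fixed leading column order.  The missing-value token is "NA".
Genomic coordinates are 1-based inclusive everywhere inside the package;
conversion to BED (0-based half-open) happens only at the export boundary.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, FormatError

log = logging.getLogger(__name__)

NA_TOKEN = "NA"
TIMEPOINTS = ("T0", "T14", "T90")
SAMPLE_SHEET_COLUMNS = [
    "sample_id", "subject_id", "timepoint", "age", "sex", "plate",
    "collection_date", "bmi", "smoking",
]
RESULT_COLUMNS = ["feature", "estimate", "se", "stat", "p", "q"]


def _check_rectangular(path: Path, sep: str) -> None:
    """Reject silently truncated files: every row must have the header width."""
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise FormatError(f"{path}: empty file")
        width = header.rstrip("\n").count(sep)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if line.rstrip("\n").count(sep) != width:
                raise FormatError(f"{path}: row length mismatch at line {lineno}")


def _check_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    """Coerce to float, naming the first offending cell on failure."""
    bad_cols = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    for col in bad_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at "
                f"row {row!r}, column {col!r}"
            )
        df[col] = coerced
    return df.astype(float)


def read_matrix(path, index_name: str = "probe_id") -> pd.DataFrame:
    """Read a features x samples TSV matrix (NA token preserved as NaN)."""
    path = Path(path)
    _check_rectangular(path, "\t")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = {h for h in header if header.count(h) > 1}
    if dup:
        raise FormatError(f"{path}: duplicated sample column {sorted(dup)[0]!r}")
    df = pd.read_csv(path, sep="\t", index_col=0,
                     na_values=[NA_TOKEN], keep_default_na=False)
    df.index.name = index_name
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated {index_name} {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicated sample column {dup!r}")
    return _check_numeric(df, path)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a features x samples matrix as TSV; round-trips to full precision."""
    matrix.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the per-sample covariate sheet (CSV)."""
    path = Path(path)
    _check_rectangular(path, ",")
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
    if bad_tp.any():
        raise FormatError(
            f"{path}: invalid timepoint {df.loc[bad_tp, 'timepoint'].iloc[0]!r}"
        )
    if df.duplicated(subset=["subject_id", "timepoint"]).any():
        raise FormatError(f"{path}: duplicated (subject_id, timepoint) pair")
    df["collection_date"] = pd.to_datetime(df["collection_date"])
    for col in ("age", "bmi"):
        df[col] = pd.to_numeric(df[col])
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    out = sheet.copy()
    out["collection_date"] = pd.to_datetime(out["collection_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep=NA_TOKEN)


def read_probe_annotation(path) -> pd.DataFrame:
    """Read probe annotation TSV: probe_id, chromosome, position, nearest_gene."""
    path = Path(path)
    _check_rectangular(path, "\t")
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    for col in ("probe_id", "chromosome", "position"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotation missing column {col!r}")
    if df["probe_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated probe_id")
    df["position"] = pd.to_numeric(df["position"], downcast=None).astype(int)
    if (df["position"] < 1).any():
        raise FormatError(f"{path}: positions must be >= 1 (coordinates are 1-based)")
    if "nearest_gene" not in df.columns:
        df["nearest_gene"] = ""
    df["nearest_gene"] = df["nearest_gene"].fillna("")
    return df.set_index("probe_id", drop=False)


def write_probe_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.reset_index(drop=True).to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def annotation_to_bed(annotation: pd.DataFrame, path) -> None:
    """Export probe positions as BED (0-based half-open; conversion happens here)."""
    bed = pd.DataFrame({
        "chrom": annotation["chromosome"],
        "start": annotation["position"] - 1,
        "end": annotation["position"],
        "name": annotation["probe_id"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_dosages(path) -> pd.DataFrame:
    """Read a SNP dosage TSV: snp_id, chrom, pos, then per-subject dosages.

    Dosages must lie in [0, 2]; out-of-range values are an error, never a
    silent clip.  Returns a DataFrame indexed by snp_id with ``chrom`` and
    ``pos`` columns followed by subject columns.
    """
    path = Path(path)
    _check_rectangular(path, "\t")
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    for col in ("snp_id", "chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"{path}: dosage table missing column {col!r}")
    if df["snp_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated snp_id")
    df = df.set_index("snp_id", drop=True)
    df["pos"] = df["pos"].astype(int)
    df["chrom"] = df["chrom"].astype(str)
    subj_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    dos = _check_numeric(df[subj_cols].copy(), path)
    with np.errstate(invalid="ignore"):
        bad = (dos.to_numpy() < 0) | (dos.to_numpy() > 2)
    if np.nansum(bad):
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: dosage {dos.iat[i, j]} outside [0, 2] for SNP "
            f"{dos.index[i]!r}, subject {dos.columns[j]!r}"
        )
    out = pd.concat([df[["chrom", "pos"]], dos], axis=1)
    return out


def write_dosages(dosages: pd.DataFrame, path) -> None:
    dosages.to_csv(path, sep="\t", index=True, index_label="snp_id", na_rep=NA_TOKEN)


def read_vcf_dosages(path) -> pd.DataFrame:
    """Read genotypes from a minimal VCF (CHROM, POS, ID, GT) as dosages.

    GT alleles are summed into an alternate-allele dosage ("0/1" -> 1.0);
    missing genotypes ("./.") become NaN.  Output matches :func:`read_dosages`.
    """
    from cyvcf2 import VCF  # optional dialect; imported lazily

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        meta.append((snp_id, str(var.CHROM), int(var.POS)))
        gts = var.genotypes  # [allele_a, allele_b, phased]
        dos = []
        for g in gts:
            alleles = [a for a in g[:-1] if a >= 0]
            dos.append(float(sum(alleles)) if len(alleles) == len(g) - 1 else np.nan)
        rows.append(dos)
    vcf.close()
    idx = pd.Index([m[0] for m in meta], name="snp_id")
    out = pd.DataFrame(rows, index=idx, columns=subjects, dtype=float)
    out.insert(0, "chrom", [m[1] for m in meta])
    out.insert(1, "pos", [m[2] for m in meta])
    return out


def write_results(results: pd.DataFrame, path) -> None:
    """Write a result table with the fixed leading column order.

    Leading columns: feature, estimate, se, stat, p, q; any extra columns
    (n_used, model, reason, ...) follow in their existing order.
    """
    df = results.copy()
    if "feature" not in df.columns and df.index.name is not None:
        df = df.reset_index().rename(columns={df.index.name: "feature"})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"results missing required columns {missing}")
    extra = [c for c in df.columns if c not in RESULT_COLUMNS]
    df = df[RESULT_COLUMNS + extra]
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_results(path) -> pd.DataFrame:
    path = Path(path)
    _check_rectangular(path, "\t")
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)


# ---------------------------------------------------------------------------
# configuration


def load_config(path, config_cls):
    """Load a YAML configuration file into ``config_cls`` (a dataclass).

    Unknown keys are rejected with a closest-match suggestion; omitted keys
    take the dataclass defaults; the resulting object is validated.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    known = {f.name for f in dataclasses.fields(config_cls)}
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigurationError(f"{path}: unknown key {key!r}{suffix}")
    cfg = config_cls(**raw)
    validate = getattr(cfg, "validate", None)
    if validate is not None:
        validate()
    return cfg


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunLog:
    """Append-only JSON-lines log of analysis runs (seed, version, inputs)."""

    def __init__(self, path):
        self.path = Path(path)

    def record(self, event: str, *, seed=None, inputs=(), **fields) -> dict:
        from . import __version__

        entry = {
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "event": event,
            "version": __version__,
        }
        if seed is not None:
            entry["seed"] = int(seed)
        if inputs:
            entry["inputs"] = {str(p): file_sha256(p) for p in inputs}
        entry.update(fields)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
        return entry
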