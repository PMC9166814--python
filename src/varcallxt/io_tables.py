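"""Delimited-text I/O for assay, evidence and report tables.

All tables are plain TSV/CSV with a header line.  The assay schema is
replicate-level (one row per measurement); :func:`average_within_batch`
collapses it to the within-batch mean table that the hierarchical model
analyzes.  Variant identifiers are opaque strings — no coordinate or HGVS
semantics are imposed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical label vocabulary
BENIGN = "benign_control"
PATHOGENIC = "pathogenic_control"
UNLABELED = "unlabeled"
LABELS = (BENIGN, PATHOGENIC, UNLABELED)

#: default alias map covering IARC-class vocabularies seen in curation practice
DEFAULT_LABEL_ALIASES = {
    "benign_control": BENIGN,
    "pathogenic_control": PATHOGENIC,
    "unlabeled": UNLABELED,
    "benign": BENIGN,
    "pathogenic": PATHOGENIC,
    "vus": UNLABELED,
    "iarc1": BENIGN,
    "iarc2": BENIGN,
    "iarc3": UNLABELED,
    "iarc4": PATHOGENIC,
    "iarc5": PATHOGENIC,
    "0": BENIGN,
    "1": PATHOGENIC,
}

ASSAY_COLUMNS = ["variant_id", "batch_id", "replicate_id", "log_ratio", "label"]
EVIDENCE_FIXED_COLUMNS = [
    "variant_id",
    "family_log_bf",
    "agvgd_prob",
    "agvgd_lo",
    "agvgd_hi",
    "label",
]


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ValidationError(ValueError):
    """Row-level content violates a table invariant."""


def _sep_for(path: str | Path, dialect: str | None = None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    return "," if str(path).endswith(".csv") else "\t"


def normalize_label(raw, aliases: dict[str, str] | None = None) -> str:
    """Map a raw label string to the canonical vocabulary.

    Missing / empty cells map to ``unlabeled``.  Unknown labels raise a
    :class:`ValidationError`.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return UNLABELED
    key = str(raw).strip().lower()
    if key in ("", "na", "nan"):
        return UNLABELED
    table = dict(DEFAULT_LABEL_ALIASES)
    if aliases:
        table.update({k.strip().lower(): v for k, v in aliases.items()})
    if key not in table:
        raise ValidationError(f"unknown label {raw!r}")
    value = table[key]
    if value not in LABELS:
        raise ValidationError(f"alias {raw!r} maps to unknown label {value!r}")
    return value


def _check_label_consistency(df: pd.DataFrame) -> None:
    per_variant = df.groupby("variant_id")["label"].nunique()
    bad = per_variant[per_variant > 1]
    if len(bad):
        raise ValidationError(
            "inconsistent label within variant(s): " + ", ".join(bad.index[:5])
        )


def read_assay_table(
    path: str | Path,
    dialect: str | None = None,
    label_aliases: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a replicate-level assay table.

    Expected columns: ``variant_id, batch_id, [replicate_id,] log_ratio, label``.
    Returns a validated DataFrame with normalized labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str,
                     keep_default_na=False)
    required = {"variant_id", "batch_id", "log_ratio", "label"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"assay table missing column(s): {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError("assay table has no rows")

    log_ratio = pd.to_numeric(
        df["log_ratio"].mask(df["log_ratio"].str.strip().isin(["", "NA"])),
        errors="coerce")
    bad = np.flatnonzero(~np.isfinite(log_ratio.to_numpy(dtype=float)))
    if len(bad):
        # +2: header line and 1-based numbering
        raise SchemaError(
            f"non-numeric or non-finite log_ratio at file row(s) {[int(i) + 2 for i in bad[:5]]}"
        )
    out = pd.DataFrame(
        {
            "variant_id": df["variant_id"].astype(str),
            "batch_id": df["batch_id"].astype(str),
            "replicate_id": (
                df["replicate_id"].astype(str)
                if "replicate_id" in df.columns
                else [str(i) for i in range(len(df))]
            ),
            "log_ratio": log_ratio.astype(float),
            "label": [normalize_label(x, label_aliases) for x in df["label"]],
        }
    )
    dup = out.duplicated(subset=["variant_id", "batch_id", "replicate_id"])
    if dup.any():
        raise ValidationError(
            f"duplicate (variant, batch, replicate) rows: {int(dup.sum())}"
        )
    _check_label_consistency(out)
    return out


def write_assay_table(df: pd.DataFrame, path: str | Path,
                      dialect: str | None = None) -> None:
    path = Path(path)
    cols = [c for c in ASSAY_COLUMNS if c in df.columns]
    df.to_csv(path, sep=_sep_for(path, dialect), index=False, columns=cols,
              na_rep="", float_format="%.6g")


def average_within_batch(measurements: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate rows to one row per (variant, batch).

    ``mean_log_ratio`` is the plain arithmetic mean of the group's replicate
    log-ratios and ``n_replicates`` the group size; labels are carried through.
    """
    if measurements is None or len(measurements) == 0:
        raise ValidationError("cannot average an empty measurement table")
    grouped = measurements.groupby(["variant_id", "batch_id"], sort=True)
    out = grouped.agg(
        mean_log_ratio=("log_ratio", "mean"),
        n_replicates=("log_ratio", "size"),
        label=("label", "first"),
    ).reset_index()
    out["n_replicates"] = out["n_replicates"].astype(int)
    return out


def _parse_optional_float(series: pd.Series) -> pd.Series:
    cleaned = series.astype(str).str.strip()
    return pd.to_numeric(cleaned.mask(cleaned.isin(["", "NA", "nan"])),
                         errors="raise")


def read_evidence_table(
    path: str | Path,
    dialect: str | None = None,
    label_aliases: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read the per-variant evidence table.

    Columns: ``variant_id, pc_1..pc_K, family_log_bf, agvgd_prob, agvgd_lo,
    agvgd_hi, label``; every column except ``variant_id`` may be absent or
    sparse.  Empty / ``NA`` cells become NaN (the explicit "absent" encoding).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str,
                     keep_default_na=False)
    if "variant_id" not in df.columns:
        raise SchemaError("evidence table missing column(s): ['variant_id']")
    if df["variant_id"].duplicated().any():
        raise ValidationError("duplicate variant_id rows in evidence table")

    pc_cols = sorted(
        (c for c in df.columns if c.startswith("pc_")),
        key=lambda c: int(c.split("_", 1)[1]),
    )
    out = pd.DataFrame({"variant_id": df["variant_id"].astype(str)})
    for c in pc_cols:
        out[c] = _parse_optional_float(df[c])
    if pc_cols:
        pc = out[pc_cols].to_numpy(dtype=float)
        partial = np.isnan(pc).any(axis=1) & ~np.isnan(pc).all(axis=1)
        if partial.any():
            raise ValidationError(
                "pc vector length mismatch (partially missing PC scores) for "
                + ", ".join(out.loc[partial, "variant_id"][:5])
            )
    for c in ("family_log_bf", "agvgd_prob", "agvgd_lo", "agvgd_hi"):
        out[c] = _parse_optional_float(df[c]) if c in df.columns else np.nan
    for c in ("agvgd_prob", "agvgd_lo", "agvgd_hi"):
        vals = out[c].to_numpy(dtype=float)
        bad = np.flatnonzero((vals < 0) | (vals > 1))
        if len(bad):
            raise ValidationError(
                f"{c} outside [0, 1] for variant(s) "
                + ", ".join(out["variant_id"].iloc[bad[:5]])
            )
    raw_label = df["label"] if "label" in df.columns else [""] * len(df)
    out["label"] = [normalize_label(x, label_aliases) for x in raw_label]
    return out


def write_evidence_table(df: pd.DataFrame, path: str | Path,
                         dialect: str | None = None) -> None:
    path = Path(path)
    pc_cols = sorted(
        (c for c in df.columns if c.startswith("pc_")),
        key=lambda c: int(c.split("_", 1)[1]),
    )
    cols = ["variant_id", *pc_cols, *EVIDENCE_FIXED_COLUMNS[1:]]
    cols = [c for c in cols if c in df.columns]
    df.to_csv(path, sep=_sep_for(path, dialect), index=False, columns=cols,
              na_rep="", float_format="%.6g")


def write_posterior_table(df: pd.DataFrame, path: str | Path,
                          dialect: str | None = None) -> None:
    """Write a per-variant posterior summary (prob, log-odds, call, theta)."""
    cols = [
        "variant_id", "prob_pathogenic", "log_odds", "call",
        "theta_mean", "theta_sd", "label",
    ]
    cols = [c for c in cols if c in df.columns]
    df.to_csv(Path(path), sep=_sep_for(path, dialect), index=False,
              columns=cols, na_rep="", float_format="%.6g")


def read_posterior_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    if "variant_id" not in df.columns:
        raise SchemaError("posterior table missing column(s): ['variant_id']")
    df["variant_id"] = df["variant_id"].astype(str)
    return df
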