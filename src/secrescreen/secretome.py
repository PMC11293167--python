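"""Secretome definition from signal-peptide predictions and LC-MS detection.

The secretome is the union of (i) proteins whose SignalP Sec/SPI probability
exceeds a threshold (strictly; default 0.5) and (ii) proteins detected in
culture supernatant in any cultivation phase. Members are classified into
three disjoint sets — predicted_and_detected, predicted_only, detected_only.
Relative abundance is the log10 of the total area under the curve summed over
replicate cultivations, and cross-phase similarity is summarized by the
Pearson correlation of those log10 abundances over proteins detected in both
phases.
"""

from __future__ import annotations

import logging
import math
import operator
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, FormatError

log = logging.getLogger(__name__)

SP_COLUMN = "SP(Sec/SPI)"
PHASES = ("outgrowth", "production")
CLASSES = ("predicted_and_detected", "predicted_only", "detected_only")


def parse_signalp(path) -> pd.DataFrame:
    """Parse a SignalP 5 short-format prediction table.

    The dialect: '#'-prefixed comment lines (the last of which names the
    columns), tab-separated data rows with the protein id in column 1 and a
    ``SP(Sec/SPI)`` probability column. A headerless two-column
    ``id<TAB>probability`` file is accepted as a fallback. Malformed data
    rows are skipped and reported with their line numbers.

    Returns a DataFrame with columns ``protein_id, sp_prob``.
    """
    prob_col: int | None = None
    rows: list[tuple[str, float]] = []
    bad: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                fields = line.lstrip("# ").split("\t")
                if SP_COLUMN in fields:
                    prob_col = fields.index(SP_COLUMN)
                continue
            parts = line.split("\t")
            col = prob_col
            if col is None:
                if len(parts) == 2:  # two-column fallback
                    col = 1
                else:
                    raise FormatError(
                        f"{path}: no '{SP_COLUMN}' header column and not a "
                        "two-column id/probability file"
                    )
            try:
                prob = float(parts[col])
            except (IndexError, ValueError):
                bad.append(lineno)
                continue
            if not 0.0 <= prob <= 1.0:
                bad.append(lineno)
                continue
            rows.append((parts[0], prob))
    if bad:
        log.warning("%s: skipped %d malformed row(s) at line(s) %s", path, len(bad), bad)
    df = pd.DataFrame(rows, columns=["protein_id", "sp_prob"])
    if df["protein_id"].duplicated().any():
        dups = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()
        raise FormatError(f"{path}: duplicate protein ids {dups[:5]}")
    return df


def write_signalp(df: pd.DataFrame, path) -> None:
    """Write predictions in the short-format dialect ``parse_signalp`` reads."""
    with open(path, "w") as fh:
        fh.write("# secrescreen signal peptide predictions\n")
        fh.write(f"# ID\tPrediction\t{SP_COLUMN}\tOTHER\n")
        for row in df.itertuples():
            pred = "SP(Sec/SPI)" if row.sp_prob > 0.5 else "OTHER"
            fh.write(
                f"{row.protein_id}\t{pred}\t{row.sp_prob:.6f}\t{1 - row.sp_prob:.6f}\n"
            )


def predict_secreted(predictions: pd.DataFrame, threshold: float = 0.5) -> set[str]:
    """Ids with signal-peptide probability strictly greater than *threshold*.

    The comparison is strict: a protein at exactly the threshold is excluded.
    """
    mask = predictions["sp_prob"] > threshold
    return set(predictions.loc[mask, "protein_id"])


_OPS = {
    ">": operator.gt,
    ">=": operator.ge,
    "<": operator.lt,
    "<=": operator.le,
    "==": operator.eq,
}


def filter_rows(df: pd.DataFrame, column: str, op: str, cutoff: float) -> pd.DataFrame:
    """Generic numeric row filter (column, operator, cutoff).

    Stands in for upstream spectral-quality filters (e.g. search-engine score
    or isolation-interference cutoffs) when the input table still carries the
    relevant column.
    """
    if op not in _OPS:
        raise DataError(f"unknown operator {op!r}; use one of {sorted(_OPS)}")
    if column not in df.columns:
        raise DataError(f"no column {column!r} in table")
    return df[_OPS[op](df[column], cutoff)].copy()


def load_abundance(path_or_df) -> pd.DataFrame:
    """Load a per-protein, per-phase replicate AUC table and summarize it.

    Input: TSV (or DataFrame) with columns ``protein_id, phase`` and one or
    more replicate AUC columns. Relative abundance is computed as
    log10(sum of replicate AUCs); rows whose replicate sum is zero are
    dropped with a warning (no detection), negative AUCs are an error.

    Returns columns ``protein_id, phase, rel_abundance``.
    """
    df = (
        pd.read_csv(path_or_df, sep="\t")
        if not isinstance(path_or_df, pd.DataFrame)
        else path_or_df.copy()
    )
    required = {"protein_id", "phase"}
    if not required.issubset(df.columns):
        raise FormatError(f"abundance table needs columns {sorted(required)}")
    auc_cols = [c for c in df.columns if c not in required]
    if not auc_cols:
        raise FormatError("abundance table needs at least one replicate AUC column")
    auc = df[auc_cols].to_numpy(float)
    if (auc < 0).any():
        raise DataError("negative AUC values in abundance table")
    total = auc.sum(axis=1)
    zero = total == 0
    if zero.any():
        log.warning(
            "dropping %d abundance row(s) with zero total AUC: %s",
            int(zero.sum()),
            df.loc[zero, "protein_id"].tolist()[:5],
        )
    out = df.loc[~zero, ["protein_id", "phase"]].copy()
    out["rel_abundance"] = np.log10(total[~zero])
    return out.reset_index(drop=True)


def define_secretome(
    predicted: set[str],
    detected: set[str] | dict[str, set[str]],
    sp_probs: pd.DataFrame | None = None,
    abundance: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Union of predicted and detected proteins, classified three ways.

    *detected* may be a flat id set or a mapping phase -> id set (a protein
    detected in any phase counts as detected). Optional *sp_probs*
    (``protein_id, sp_prob``) and long-format *abundance*
    (``protein_id, phase, rel_abundance``) fill the annotation columns.

    Output columns: ``protein_id, sp_prob, detected_<phase>,
    rel_abundance_<phase>, secretome_class``; proteins detected in only one
    phase carry a missing (not zero) abundance in the other.
    """
    if isinstance(detected, dict):
        per_phase = {ph: set(ids) for ph, ids in detected.items()}
    else:
        per_phase = {ph: set(detected) for ph in PHASES}
    detected_any = set().union(*per_phase.values()) if per_phase else set()
    members = sorted(predicted | detected_any)

    def classify(pid: str) -> str:
        if pid in predicted and pid in detected_any:
            return "predicted_and_detected"
        return "predicted_only" if pid in predicted else "detected_only"

    out = pd.DataFrame({"protein_id": members})
    probs = (
        dict(zip(sp_probs["protein_id"], sp_probs["sp_prob"]))
        if sp_probs is not None
        else {}
    )
    out["sp_prob"] = out["protein_id"].map(probs)
    rel: dict[str, dict[str, float]] = {}
    if abundance is not None:
        for row in abundance.itertuples():
            rel.setdefault(row.phase, {})[row.protein_id] = row.rel_abundance
    for ph in per_phase:
        out[f"detected_{ph}"] = out["protein_id"].isin(per_phase[ph])
        out[f"rel_abundance_{ph}"] = out["protein_id"].map(rel.get(ph, {}))
    out["secretome_class"] = out["protein_id"].map(classify)
    return out


def class_counts(secretome: pd.DataFrame) -> dict[str, int]:
    """Cardinalities of the three classes plus the total."""
    counts = secretome["secretome_class"].value_counts().to_dict()
    return {
        "total": len(secretome),
        **{c: int(counts.get(c, 0)) for c in CLASSES},
    }


def abundance_correlation(
    abundance: pd.DataFrame, phase_a: str = PHASES[0], phase_b: str = PHASES[1]
) -> float:
    """Pearson R of log10 abundances across the two phases.

    Computed over the proteins detected in both phases; fewer than two shared
    proteins is an error. Accepts the long format from :func:`load_abundance`
    or a wide table with one column per phase.
    """
    if {"phase", "rel_abundance"}.issubset(abundance.columns):
        wide = abundance.pivot_table(
            index="protein_id", columns="phase", values="rel_abundance"
        )
    else:
        wide = abundance.set_index("protein_id")
    for ph in (phase_a, phase_b):
        if ph not in wide.columns:
            raise DataError(f"phase {ph!r} absent from abundance table")
    pair = wide[[phase_a, phase_b]].dropna()
    if len(pair) < 2:
        raise DataError("fewer than 2 proteins detected in both phases")
    x, y = pair[phase_a].to_numpy(), pair[phase_b].to_numpy()
    if np.allclose(x - x.mean(), 0) or np.allclose(y - y.mean(), 0):
        raise DataError("zero variance in one phase; correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(r)
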