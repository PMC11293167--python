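"""Knockout target selection.

Candidates are secretome members experimentally detected in supernatant (any
phase) whose essentiality score is strictly below the threshold; a curated
exclusion list (e.g. methanol-metabolism genes whose loss would compromise
induced production) is then subtracted to give the final target list handed
to vector packing. Genes with missing scores are never candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Candidates, exclusions applied (with reasons), and final targets.

    ``final == [c for c in candidates if c not in excluded]``; candidate
    order is deterministic (score ascending, ties by id).
    """

    candidates: list[str]
    excluded: dict[str, str]
    final: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g,
                "stage": "excluded" if g in self.excluded else "target",
                "reason": self.excluded.get(g, ""),
            }
            for g in self.candidates
        ]
        return pd.DataFrame(rows, columns=["gene_id", "stage", "reason"])


def load_exclusions(path_or_df) -> dict[str, str]:
    """Read a two-column ``gene_id, reason`` TSV into a mapping."""
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df, sep="\t")
    )
    if "gene_id" not in df.columns:
        raise DataError("exclusion list needs a gene_id column")
    reasons = df["reason"] if "reason" in df.columns else [""] * len(df)
    return dict(zip(df["gene_id"], reasons))


def select_targets(
    secretome: pd.DataFrame,
    scores: pd.DataFrame,
    exclusion: dict[str, str] | None = None,
    score_threshold: float = 0.5,
) -> SelectionResult:
    """Select non-essential, supernatant-detected knockout targets.

    candidates = detected in any phase AND score < threshold (strict; a
    score of exactly the threshold is neither called essential nor
    selected). final = candidates minus exclusion-list keys. Exclusion ids
    that are not candidates are warned about, not errors.
    """
    exclusion = exclusion or {}
    det_cols = [c for c in secretome.columns if c.startswith("detected_")]
    if not det_cols:
        raise DataError("secretome table has no detected_<phase> columns")
    detected = set(
        secretome.loc[secretome[det_cols].any(axis=1), "protein_id"]
    )
    score_by_gene = dict(zip(scores["gene_id"], scores["score"]))
    missing = set(secretome["protein_id"]) - set(score_by_gene)
    if missing:
        log.info("%d secretome members have no essentiality score", len(missing))

    def is_candidate(g: str) -> bool:
        s = score_by_gene.get(g)
        return (
            g in detected and s is not None and not pd.isna(s) and s < score_threshold
        )

    cand = [g for g in secretome["protein_id"] if is_candidate(g)]
    cand.sort(key=lambda g: (score_by_gene[g], g))
    stray = sorted(set(exclusion) - set(cand))
    if stray:
        log.warning("exclusion ids not among candidates (ignored): %s", stray[:10])
    excluded = {g: exclusion[g] for g in cand if g in exclusion}
    final = [g for g in cand if g not in excluded]
    return SelectionResult(candidates=cand, excluded=excluded, final=final)
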