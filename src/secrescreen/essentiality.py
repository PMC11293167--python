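"""Gene essentiality from guide depletion, and gene-set enrichment.

Essentiality of a gene is scored by a one-sided two-sample
Kolmogorov-Smirnov test comparing the gene's guide log2 fold changes to the
background of all other guides: D = sup_x [ECDF_gene(x) - ECDF_bg(x)] is
large when the gene's guides are stochastically more depleted. The score is
1 - p with p the one-sided asymptotic tail bound exp(-2 m D^2),
m = n_g * n_b / (n_g + n_b); genes scoring > 0.5 are called likely
essential. An exact label-permutation p-value is available for small guide
counts. The score is rank-based: any strictly increasing transformation of
all LFCs leaves it unchanged.

Weighted gene-set enrichment follows the classic running-sum statistic over
the score-ranked gene list: hits increment by |score|^w (normalized), misses
decrement by 1/(N - |set|); the enrichment score is the signed maximal
deviation, and significance comes from gene-label permutations with
sign-stratified normalization and Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

RESULT_COLUMNS = ["gene_id", "n_guides", "ks_stat", "p_value", "score", "essential_call"]


def _check_sample(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DataError(f"{name} needs at least 2 values, got {x.size}")
    if not np.isfinite(x).all():
        raise DataError(f"non-finite values in {name}")
    return x


def _one_sided_D(gene: np.ndarray, background: np.ndarray) -> float:
    """sup_x [ECDF_gene(x) - ECDF_bg(x)] evaluated at pooled points.

    Both ECDFs are right-continuous and evaluated at every pooled sorted
    unique point, which handles ties; the sup of the difference is attained
    at one of these points.
    """
    pooled = np.unique(np.concatenate([gene, background]))
    fg = np.searchsorted(np.sort(gene), pooled, side="right") / gene.size
    fb = np.searchsorted(np.sort(background), pooled, side="right") / background.size
    return float(np.max(fg - fb))


def ks_depletion_test(
    gene_lfcs, background_lfcs, method: str = "asymptotic",
    n_perm: int = 1000, seed: int | None = None,
) -> tuple[float, float]:
    """One-sided two-sample KS test in the depletion direction.

    Returns ``(D, p)``. With ``method="asymptotic"`` (default),
    p = exp(-2 m D^2) with m the harmonic sample-size factor — a valid
    (conservative) tail bound at any sample size. ``method="permutation"``
    computes p by label permutation with the +1 correction, preferable for
    very small guide counts.
    """
    g = _check_sample(gene_lfcs, "gene_lfcs")
    b = _check_sample(background_lfcs, "background_lfcs")
    d = _one_sided_D(g, b)
    m = g.size * b.size / (g.size + b.size)
    if method == "asymptotic":
        p = min(1.0, math.exp(-2.0 * m * d * d))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([g, b])
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if _one_sided_D(pooled[: g.size], pooled[g.size :]) >= d:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
    else:
        raise DataError(f"unknown p-value method {method!r}")
    return d, p


def essentiality_scores(
    lfc_table: pd.DataFrame,
    min_guides: int = 2,
    threshold: float = 0.5,
    method: str = "asymptotic",
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score every gene against the leave-one-gene-out background.

    For each gene with at least *min_guides* guides, the background is the
    LFCs of all guides from other genes (excluding the focal gene avoids
    self-contamination). Genes below *min_guides* are reported with missing
    statistics and no essentiality call. Output is sorted by score
    descending (ties by gene id) with columns
    ``gene_id, n_guides, ks_stat, p_value, score, essential_call``.
    """
    if "gene_id" not in lfc_table.columns or "lfc" not in lfc_table.columns:
        raise DataError("lfc table needs gene_id and lfc columns")
    lfcs = lfc_table["lfc"].to_numpy(float)
    if not np.isfinite(lfcs).all():
        raise DataError("non-finite LFC values")
    genes = lfc_table["gene_id"].to_numpy()
    order = np.argsort(genes, kind="stable")
    genes_sorted, lfcs_sorted = genes[order], lfcs[order]
    uniq, starts = np.unique(genes_sorted, return_index=True)
    bounds = np.append(starts, len(genes_sorted))
    rows = []
    any_scored = False
    for i, gene in enumerate(uniq):
        sl = slice(bounds[i], bounds[i + 1])
        g = lfcs_sorted[sl]
        if g.size < min_guides or len(lfcs_sorted) - g.size < 2:
            rows.append(
                {
                    "gene_id": gene, "n_guides": int(g.size),
                    "ks_stat": np.nan, "p_value": np.nan,
                    "score": np.nan, "essential_call": pd.NA,
                }
            )
            continue
        bg = np.concatenate([lfcs_sorted[: bounds[i]], lfcs_sorted[bounds[i + 1] :]])
        d, p = ks_depletion_test(
            g, bg, method=method, n_perm=n_perm,
            seed=None if seed is None else seed + i,
        )
        score = 1.0 - p
        any_scored = True
        rows.append(
            {
                "gene_id": gene, "n_guides": int(g.size),
                "ks_stat": d, "p_value": p,
                "score": score, "essential_call": bool(score > threshold),
            }
        )
    if not any_scored:
        raise DataError(f"no gene has >= {min_guides} guides")
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out = out.sort_values(
        ["score", "gene_id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return out


def classify_essential(
    results: pd.DataFrame, threshold: float = 0.5
) -> dict[str, list[str]]:
    """Partition genes by the strict score threshold.

    score > threshold -> essential; score <= threshold -> non_essential;
    missing score -> unclassified. A score of exactly the threshold is
    non-essential.
    """
    score = results["score"]
    essential = results.loc[score > threshold, "gene_id"].tolist()
    non_essential = results.loc[score <= threshold, "gene_id"].tolist()
    unclassified = results.loc[score.isna(), "gene_id"].tolist()
    return {
        "essential": essential,
        "non_essential": non_essential,
        "unclassified": unclassified,
    }


# ---------------------------------------------------------------------------
# weighted GSEA


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <TAB> description <TAB> members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"GMT line {lineno}: need name, description, members")
            sets[parts[0]] = set(parts[2:])
    return sets


def _es_from_steps(weights: np.ndarray, hit_mask: np.ndarray) -> float:
    """Signed maximal deviation of the running sum for one set."""
    n = weights.size
    k = int(hit_mask.sum())
    hit_w = np.where(hit_mask, weights, 0.0)
    total = hit_w.sum()
    if k == n:  # no misses: running sum climbs monotonically to 1
        return 1.0
    steps = np.where(hit_mask, hit_w / total if total > 0 else 0.0, -1.0 / (n - k))
    run = np.cumsum(steps)
    imax = int(np.argmax(np.abs(run)))
    return float(run[imax])


def weighted_gsea(
    scores: pd.Series | dict,
    gene_sets: dict[str, set[str]],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """Weighted running-sum enrichment of gene sets on a score ranking.

    Genes are ranked by score descending (ties broken by gene id). For each
    set, hits increment the running sum by |score|^weight_exponent
    (normalized so hits sum to 1) and misses decrement by 1/(N - |set|);
    ES is the signed maximal deviation. The null permutes gene labels
    (equivalently, draws random member positions), NES divides by the mean
    |null ES| of the same sign, the permutation p carries the +1
    correction, and FDR is Benjamini-Hochberg across sets.

    Returns columns ``set, size, es, nes, p_perm, fdr`` sorted by nes
    descending.
    """
    if isinstance(scores, dict):
        scores = pd.Series(scores)
    if scores.empty:
        raise DataError("empty score universe")
    ranked = scores.reset_index()
    ranked.columns = ["gene_id", "score"]
    ranked = ranked.sort_values(
        ["score", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    gene_order = ranked["gene_id"].to_numpy()
    weights = np.abs(ranked["score"].to_numpy(float)) ** weight_exponent
    n = len(gene_order)
    pos_of = {g: i for i, g in enumerate(gene_order)}

    qualifying = {}
    for name, members in gene_sets.items():
        inside = sorted(members & set(gene_order))
        if min_set_size <= len(inside) <= n:
            qualifying[name] = inside
    if not qualifying:
        raise DataError(f"no gene set with >= {min_set_size} members in universe")

    rng = np.random.default_rng(seed)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, inside in sorted(qualifying.items()):
        k = len(inside)
        mask = np.zeros(n, dtype=bool)
        mask[[pos_of[g] for g in inside]] = True
        es = _es_from_steps(weights, mask)
        if k not in null_cache:
            null = np.empty(n_perm)
            for j in range(n_perm):
                pm = np.zeros(n, dtype=bool)
                pm[rng.choice(n, size=k, replace=False)] = True
                null[j] = _es_from_steps(weights, pm)
            null_cache[k] = null
        null = null_cache[k]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        denom = np.abs(same_sign).mean() if same_sign.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        extreme = int((np.abs(same_sign) >= abs(es)).sum())
        p = (1 + extreme) / (1 + same_sign.size)
        rows.append({"set": name, "size": k, "es": es, "nes": nes, "p_perm": p})
    out = pd.DataFrame(rows)
    out["fdr"] = stats.false_discovery_control(out["p_perm"].to_numpy(), method="bh")
    return out.sort_values("nes", ascending=False).reset_index(drop=True)
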