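"""Amplicon FASTQ -> guide counts -> normalized counts -> log2 fold changes.

Guides are counted by locating a constant anchor (the invariant cassette
flank preceding the spacer in the amplicon) and matching the following
``spacer_len`` nucleotides against the library spacer dictionary — either
exactly, or with at most one mismatch via a precomputed mismatch
neighborhood (slower to build, same lookup cost). Counts are normalized to
counts-per-million with a pseudocount, which keeps log fold changes finite
and avoids the mostly-unchanged assumption of median-ratio methods that a
heavily depleted screen violates.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import DataError

ALPHABET = "ACGT"


@dataclass
class CountStats:
    """Per-sample accounting; mapped + unmapped = reads processed."""

    reads: int = 0
    mapped: int = 0
    unmapped: int = 0


def _open_maybe_gz(path):
    return gzip.open(path, "rt") if str(path).endswith(".gz") else open(path)


def _mismatch_neighborhood(spacers: dict[str, str]) -> dict[str, str]:
    """Map every 1-mismatch variant to its guide; ambiguous variants dropped.

    A variant within distance 1 of two different spacers cannot be assigned
    and is removed, so such reads count as unmapped rather than guessed.
    """
    table: dict[str, str | None] = {}
    for spacer, gid in spacers.items():
        for i, base in enumerate(spacer):
            for b in ALPHABET:
                if b == base:
                    continue
                variant = spacer[:i] + b + spacer[i + 1 :]
                if variant in table and table[variant] != gid:
                    table[variant] = None
                else:
                    table.setdefault(variant, gid)
    return {v: g for v, g in table.items() if g is not None}


def count_guides(
    fastq_paths: dict[str, str | list],
    library: pd.DataFrame,
    anchor: str,
    max_mismatches: int = 0,
) -> tuple[pd.DataFrame, dict[str, CountStats]]:
    """Count guide spacers in amplicon FASTQ files, one entry per sample.

    *fastq_paths* maps sample name -> FASTQ path (or list of paths;
    ``.gz`` accepted). For each read the first occurrence of *anchor* is
    located and the following ``spacer_len`` nt are looked up in the spacer
    dictionary. Reads lacking the anchor, too short to contain a full
    spacer after it, or without a dictionary hit are unmapped.

    Returns ``(counts, stats)``: counts has columns
    ``guide_id, gene_id, <sample>...``; stats maps sample ->
    :class:`CountStats`.
    """
    if not anchor:
        raise DataError("anchor sequence must be non-empty")
    if library["spacer"].duplicated().any():
        dups = library.loc[library["spacer"].duplicated(), "spacer"].tolist()
        raise DataError(f"duplicate spacers in library (ambiguous): {dups[:3]}")
    if max_mismatches not in (0, 1):
        raise DataError("max_mismatches must be 0 or 1")
    spacer_lens = library["spacer"].str.len().unique()
    if len(spacer_lens) != 1:
        raise DataError("library spacers must share one length")
    slen = int(spacer_lens[0])
    exact = dict(zip(library["spacer"], library["guide_id"]))
    lookup = dict(exact)
    if max_mismatches == 1:
        for variant, gid in _mismatch_neighborhood(exact).items():
            lookup.setdefault(variant, gid)

    guide_ids = library["guide_id"].tolist()
    index = {g: i for i, g in enumerate(guide_ids)}
    counts = library[["guide_id", "gene_id"]].copy()
    stats: dict[str, CountStats] = {}
    for sample, paths in fastq_paths.items():
        if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
            paths = [paths]
        vec = np.zeros(len(guide_ids), dtype=np.int64)
        st = CountStats()
        for path in paths:
            with _open_maybe_gz(path) as fh:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    st.reads += 1
                    pos = seq.find(anchor)
                    if pos == -1:
                        st.unmapped += 1
                        continue
                    start = pos + len(anchor)
                    candidate = seq[start : start + slen]
                    if len(candidate) < slen:
                        st.unmapped += 1
                        continue
                    gid = lookup.get(candidate)
                    if gid is None:
                        st.unmapped += 1
                    else:
                        vec[index[gid]] += 1
                        st.mapped += 1
        counts[sample] = vec
        stats[sample] = st
    return counts, stats


def normalize(
    counts: pd.DataFrame,
    samples: list[str] | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Counts-per-million with a pseudocount.

    ``norm = (count + pc) / (total_mapped + pc * n_guides) * 1e6`` so each
    sample column sums to exactly one million. A sample with zero mapped
    reads is an error.
    """
    if samples is None:
        samples = [c for c in counts.columns if c not in ("guide_id", "gene_id")]
    out = counts[["guide_id", "gene_id"]].copy()
    n = len(counts)
    for s in samples:
        col = counts[s].to_numpy(float)
        total = col.sum()
        if total <= 0:
            raise DataError(f"sample {s!r} has zero mapped reads")
        out[s] = (col + pseudocount) / (total + pseudocount * n) * 1e6
    return out


def compute_lfc(
    normalized: pd.DataFrame, pre: str = "pre", post: str = "post"
) -> pd.DataFrame:
    """Guide-level log2 fold change of normalized counts, post vs pre.

    Both samples must cover the same guide universe (the table carries one
    row per guide, so this holds by construction when both columns exist).
    Returns columns ``guide_id, gene_id, pre_norm, post_norm, lfc``.
    """
    for s in (pre, post):
        if s not in normalized.columns:
            raise DataError(f"sample {s!r} not in normalized table")
    out = normalized[["guide_id", "gene_id"]].copy()
    out["pre_norm"] = normalized[pre].to_numpy(float)
    out["post_norm"] = normalized[post].to_numpy(float)
    if (out["pre_norm"] <= 0).any() or (out["post_norm"] <= 0).any():
        raise DataError("normalized counts must be positive (pseudocount missing?)")
    out["lfc"] = np.log2(out["post_norm"]) - np.log2(out["pre_norm"])
    return out
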