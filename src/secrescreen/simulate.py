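"""Synthetic data generation for the screen pipeline.

Everything the pipeline consumes can be generated here: a small genome with
annotated CDSs, paired cross-phase protein abundance tables, pre/post
selection guide counts with negative-binomial noise and gene-level depletion
for a known-essential subset, amplicon FASTQ emission, and a fixed reference
fixture whose marginal counts match the published secretome/selection
arithmetic (361 proteins = 257 predicted + 134 detected − 30 overlap;
61 non-essential detected candidates of which 7 are excluded).

All randomness flows through ``numpy.random.default_rng`` seeded from the
configuration, so a fixed seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

BASES = np.array(list("ACGT"))

#: Constant 5' flank placed before the spacer in emitted amplicon reads.
#: Stands in for the invariant cassette sequence immediately upstream of the
#: retargetable region; configurable everywhere it is consumed.
DEFAULT_ANCHOR = "GACGAAACACCG"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the packaged simulation.

    Defaults define the acceptance simulation: a 361-gene secretome-sized
    library, 6 guides per gene, 10% essential genes depleted 8-fold, NB
    counts with mean 500 and dispersion 0.1 (variance = mu + 0.1 mu^2),
    cross-phase abundance correlation 0.93, four replicate cultivations.
    """

    n_genes: int = 361
    cds_len_range: tuple[int, int] = (300, 1500)
    gc_content: float = 0.45
    intergenic_len: int = 200
    guides_per_gene: int = 6
    frac_essential: float = 0.10
    depletion_factor: float = 8.0
    nb_mean: float = 500.0
    nb_dispersion: float = 0.1
    #: sigma of the per-guide lognormal baseline on the log2 scale; pooled
    #: libraries are never uniform and this mimics typical synthesis skew.
    library_skew_sigma: float = 0.5
    abundance_rho: float = 0.93
    n_replicates: int = 4
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        lo, hi = self.cds_len_range
        if not (24 <= lo <= hi):
            raise ConfigError(
                "cds_len_range must satisfy 24 <= lo <= hi (spacer+PAM must fit)"
            )
        if not 0.0 <= self.gc_content <= 1.0:
            raise ConfigError("gc_content must be in [0, 1]")
        if not 0.0 <= self.frac_essential <= 1.0:
            raise ConfigError("frac_essential must be in [0, 1]")
        if self.depletion_factor < 1.0:
            raise ConfigError("depletion_factor must be >= 1")
        if self.nb_mean <= 0:
            raise ConfigError("nb_mean must be > 0")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if not -1.0 <= self.abundance_rho <= 1.0:
            raise ConfigError("abundance_rho must be in [-1, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Known truth behind one simulation, for evaluating recovery."""

    essential_gene_ids: frozenset[str]
    #: per-gene expected post/pre ratio of guide counts (1 for neutral genes)
    fitness: dict[str, float]
    #: per-protein true secretion class, one of predicted_and_detected /
    #: predicted_only / detected_only / none
    secretion_class: dict[str, str]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=length, p=probs))


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate a single-contig genome with non-overlapping CDS features.

    Returns ``(genome, features)`` where *genome* maps contig name to
    sequence and *features* has columns ``gene_id, seqid, start, end,
    strand`` with 0-based half-open coordinates (converted to GFF3 1-based
    inclusive only at the I/O boundary). CDS lengths are multiples of 3;
    strands are assigned randomly.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cds_len_range
    chunks: list[str] = [_random_seq(rng, config.intergenic_len, config.gc_content)]
    pos = config.intergenic_len
    rows = []
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        length -= length % 3
        strand = "+" if rng.random() < 0.5 else "-"
        chunks.append(_random_seq(rng, length, config.gc_content))
        rows.append(
            {
                "gene_id": f"G{i + 1:04d}",
                "seqid": "chr1",
                "start": pos,
                "end": pos + length,
                "strand": strand,
            }
        )
        pos += length
        chunks.append(_random_seq(rng, config.intergenic_len, config.gc_content))
        pos += config.intergenic_len
    genome = {"chr1": "".join(chunks)}
    features = pd.DataFrame(
        rows, columns=["gene_id", "seqid", "start", "end", "strand"]
    )
    return genome, features


def write_genome(
    genome: dict[str, str], features: pd.DataFrame, fasta_path, gff_path
) -> None:
    """Write FASTA + GFF3 (1-based inclusive CDS features, ID = gene id)."""
    with open(fasta_path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples():
            fh.write(
                f"{row.seqid}\tsecrescreen\tCDS\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t0\tID={row.gene_id}\n"
            )


def simulate_abundance(
    n: int,
    rho: float,
    seed: int,
    mean: float = 7.0,
    sd: float = 1.0,
    phases: tuple[str, str] = ("outgrowth", "production"),
) -> pd.DataFrame:
    """Draw paired per-protein log10 abundances from a bivariate normal.

    Emulates the cross-phase (glycerol outgrowth vs methanol production)
    supernatant abundance comparison: the two log10 abundances of each
    protein share correlation *rho*. Returns a DataFrame with columns
    ``protein_id`` and one log10-abundance column per phase.
    """
    if n < 2:
        raise DataError("need n >= 2 proteins (correlation undefined otherwise)")
    if not -1.0 <= rho <= 1.0:
        raise ConfigError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    if abs(rho) == 1.0:
        # degenerate covariance: exactly collinear pairs
        x = rng.normal(mean, sd, size=n)
        draws = np.column_stack([x, mean + rho * (x - mean)])
    else:
        cov = sd * sd * np.array([[1.0, rho], [rho, 1.0]])
        draws = rng.multivariate_normal([mean, mean], cov, size=n, method="cholesky")
    return pd.DataFrame(
        {
            "protein_id": [f"P{i + 1:04d}" for i in range(n)],
            phases[0]: draws[:, 0],
            phases[1]: draws[:, 1],
        }
    )


# secretion-class mixture used when inventing truth; proportions follow the
# published 30/227/104 split of a 361-member secretome
_CLASS_PROPS = {
    "predicted_and_detected": 30 / 361,
    "predicted_only": 227 / 361,
    "detected_only": 104 / 361,
}


def make_ground_truth(
    config: SimConfig, gene_ids: list[str] | None = None
) -> GroundTruth:
    """Assign essentiality and secretion classes to the simulated genes."""
    rng = np.random.default_rng(config.seed + 1)
    if gene_ids is None:
        gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    n_ess = round(config.frac_essential * len(gene_ids))
    essential = frozenset(
        rng.choice(np.array(gene_ids), size=n_ess, replace=False).tolist()
    )
    fitness = {
        g: (1.0 / config.depletion_factor if g in essential else 1.0)
        for g in gene_ids
    }
    names = list(_CLASS_PROPS)
    classes = rng.choice(
        names, size=len(gene_ids), p=[_CLASS_PROPS[k] for k in names]
    )
    return GroundTruth(
        essential_gene_ids=essential,
        fitness=fitness,
        secretion_class=dict(zip(gene_ids, classes)),
    )


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB with variance mu + dispersion*mu^2; Poisson when dispersion = 0."""
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_screen_counts(
    library: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
    n_post_samples: int = 1,
) -> pd.DataFrame:
    """Simulate pre/post selection guide counts for a designed library.

    Per-guide baseline means are lognormal around ``nb_mean`` (log2 sigma
    ``library_skew_sigma``); counts are negative binomial with the
    configured dispersion. Essential-gene guides have their post-selection
    mean divided by ``depletion_factor`` (applied cumulatively across
    *n_post_samples* passages when > 1).

    Returns columns ``guide_id, gene_id, pre, post[, post2, ...]``.
    """
    if len(library) == 0:
        raise DataError("empty guide library")
    unknown = sorted(set(library["gene_id"]) - set(truth.fitness))
    if unknown:
        raise DataError(f"guides map to genes absent from truth: {unknown[:5]}")
    rng = np.random.default_rng(config.seed + 2)
    mu = config.nb_mean * 2.0 ** rng.normal(
        0.0, config.library_skew_sigma, size=len(library)
    )
    f = library["gene_id"].map(truth.fitness).to_numpy(float)
    out = library[["guide_id", "gene_id"]].copy()
    out["pre"] = _nb_draw(rng, mu, config.nb_dispersion)
    for k in range(1, n_post_samples + 1):
        name = "post" if k == 1 else f"post{k}"
        out[name] = _nb_draw(rng, mu * f**k, config.nb_dispersion)
    return out


def write_screen_fastq(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    sample: str,
    path,
    seed: int,
    anchor: str = DEFAULT_ANCHOR,
    read_len: int = 50,
    error_rate: float = 0.0,
) -> int:
    """Emit one amplicon FASTQ for *sample*: each guide's spacer appears
    ``counts[sample]`` times after the constant anchor, padded to *read_len*.

    Optional uniform substitution noise at *error_rate* per base; reads are
    shuffled. Returns the number of reads written. ``.gz`` suffix gzips.
    """
    rng = np.random.default_rng(seed)
    spacers = dict(zip(library["guide_id"], library["spacer"]))
    reads: list[str] = []
    for row in counts.itertuples():
        seq = anchor + spacers[row.guide_id]
        if len(seq) < read_len:
            seq = seq + "T" * (read_len - len(seq))
        reads.extend([seq] * int(getattr(row, sample)))
    order = rng.permutation(len(reads))
    if str(path).endswith(".gz"):
        # fileobj form omits the filename from the header and mtime=0 fixes
        # the timestamp, so reruns are byte-identical
        fh_ctx = io.TextIOWrapper(
            gzip.GzipFile(
                filename="", fileobj=open(path, "wb"), mode="wb", mtime=0
            )
        )
    else:
        fh_ctx = open(path, "w")
    with fh_ctx as fh:
        for i, idx in enumerate(order):
            seq = reads[idx]
            if error_rate > 0:
                arr = np.array(list(seq))
                hit = rng.random(len(arr)) < error_rate
                arr[hit] = rng.choice(BASES, size=int(hit.sum()))
                seq = "".join(arr)
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return len(reads)


def marginals_fixture() -> dict[str, pd.DataFrame]:
    """Fixed reference tables reproducing the published selection arithmetic.

    361 proteins total: 30 predicted-and-detected, 227 predicted-only,
    104 detected-only (so 257 signal-peptide predictions and 134 detections).
    Essentiality scores are set so exactly 61 detected proteins score < 0.5,
    and exactly 7 of those carry a methanol-metabolism exclusion flag.
    Gene/protein ids are synthetic; all values are deterministic.

    Returns ``{"secretome": ..., "scores": ..., "exclusions": ...}`` in the
    same schemas the pipeline stages emit.
    """
    n = 361
    ids = [f"SYN{i + 1:04d}" for i in range(n)]
    cls = (
        ["predicted_and_detected"] * 30
        + ["predicted_only"] * 227
        + ["detected_only"] * 104
    )
    sp_prob = [0.9] * 30 + [0.8] * 227 + [0.2] * 104
    detected = [c != "predicted_only" for c in cls]

    det_idx = [i for i in range(n) if detected[i]]  # 134 rows
    scores = np.empty(n)
    # non-detected proteins: varied scores, irrelevant to selection
    for i in range(n):
        scores[i] = 0.30 + 0.45 * ((i * 37) % 100) / 100.0
    # first 61 detected proteins are non-essential candidates (< 0.5 strict),
    # the remaining 73 score above threshold
    for j, i in enumerate(det_idx[:61]):
        scores[i] = 0.05 + 0.40 * j / 60.0
    for j, i in enumerate(det_idx[61:]):
        scores[i] = 0.55 + 0.44 * j / 72.0

    rel = np.where(detected, 5.0 + 0.02 * np.arange(n), np.nan)
    secretome = pd.DataFrame(
        {
            "protein_id": ids,
            "sp_prob": sp_prob,
            "detected_outgrowth": detected,
            "detected_production": detected,
            "rel_abundance_outgrowth": rel,
            "rel_abundance_production": rel,
            "secretome_class": cls,
        }
    )

    n_g, n_b = 6, 2160
    m = n_g * n_b / (n_g + n_b)
    p = 1.0 - scores
    scores_df = pd.DataFrame(
        {
            "gene_id": ids,
            "n_guides": n_g,
            "ks_stat": np.sqrt(-np.log(p) / (2 * m)),
            "p_value": p,
            "score": scores,
            "essential_call": scores > 0.5,
        }
    )

    excl_ids = [ids[i] for i in det_idx[:7]]
    exclusions = pd.DataFrame(
        {"gene_id": excl_ids, "reason": ["methanol metabolism"] * 7}
    )
    return {"secretome": secretome, "scores": scores_df, "exclusions": exclusions}


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cds_len_range"] = list(d["cds_len_range"])
    return d


def config_from_dict(d: dict) -> SimConfig:
    known = {f.name for f in dataclasses.fields(SimConfig)}
    extra = set(d) - known
    if extra:
        raise ConfigError(f"unknown SimConfig keys: {sorted(extra)}")
    d = dict(d)
    if "cds_len_range" in d:
        d["cds_len_range"] = tuple(d["cds_len_range"])
    return SimConfig(**d)
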