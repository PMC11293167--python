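"""sgRNA library design, oligo emission, and multiplexed vector packing.

Spacers are designed against annotated CDSs: every SpCas9 protospacer
(20-nt spacer + NGG PAM, either orientation) whose spacer lies within the
5' portion of the CDS is a candidate; candidates are filtered on GC content,
homopolymer runs, and genome-wide uniqueness of the exact spacer+PAM string,
then ranked 5'-most first by cut position. Early cuts maximize the chance a
repair-induced frameshift truncates the protein.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the I/O boundary only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .errors import ConfigError, DataError

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Neutral cassette template for emitted oligos: constant flanks around the
#: retargetable spacer. Real cassettes (e.g. tRNA-flanked designs) are passed
#: in by the user.
DEFAULT_TEMPLATE = "GACGAAACACCG{SPACER}GTTTTAGAGCTAGAA"

SPACER_PLACEHOLDER = "{SPACER}"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _pam_regex(pam: str) -> re.Pattern:
    try:
        pattern = "".join(
            b if len(_IUPAC[b]) == 1 else f"[{_IUPAC[b]}]" for b in pam.upper()
        )
    except KeyError as e:
        raise ConfigError(f"invalid IUPAC code in PAM pattern: {e}") from None
    return re.compile(f"(?=({pattern}))")


@dataclass(frozen=True)
class DesignParams:
    """Tunable sgRNA design parameters.

    ``cds_window_frac`` restricts spacers to the first fraction of the CDS;
    ``gc_min``/``gc_max`` bound spacer GC content; ``forbid_homopolymer``
    rejects spacers containing the given run (TTTT also terminates pol III
    transcription); uniqueness demands the exact spacer+PAM string occur once
    in the genome (either strand).
    """

    spacer_len: int = 20
    pam: str = "NGG"
    cds_window_frac: float = 0.5
    gc_min: float = 0.2
    gc_max: float = 0.8
    forbid_homopolymer: str = "TTTT"
    guides_per_gene: int = 4
    uniqueness: str = "spacer_pam_exact"

    def __post_init__(self) -> None:
        if self.spacer_len < 1:
            raise ConfigError("spacer_len must be >= 1")
        if not 0.0 < self.cds_window_frac <= 1.0:
            raise ConfigError("cds_window_frac must be in (0, 1]")
        if not self.gc_min < self.gc_max:
            raise ConfigError("gc_min must be < gc_max")
        if self.uniqueness != "spacer_pam_exact":
            raise ConfigError("uniqueness mode must be 'spacer_pam_exact'")
        _pam_regex(self.pam)


@dataclass
class DesignResult:
    """Designed guides plus the genes for which nothing passed the filters."""

    guides: pd.DataFrame
    genes_without_guides: list[str] = field(default_factory=list)


GUIDE_COLUMNS = ["guide_id", "gene_id", "spacer", "pam", "strand", "cut_offset"]


def load_genome(fasta_path) -> dict[str, str]:
    """Read a FASTA into an in-memory contig -> uppercase sequence map."""
    fa = Fasta(str(fasta_path), rebuild=False, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def load_cds_features(gff_path) -> pd.DataFrame:
    """Read CDS features (ID attribute = gene id) from a GFF3 file.

    Returns columns ``gene_id, seqid, start, end, strand`` with coordinates
    converted to 0-based half-open.
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="error", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("CDS"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "seqid": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "seqid", "start", "end", "strand"])


def _count_occurrences(haystacks: list[str], needle: str, stop_at: int = 2) -> int:
    """Overlapping occurrence count of *needle* across contigs, both strands."""
    total = 0
    rc = revcomp(needle)
    for seq in haystacks:
        for probe in {needle, rc}:  # set collapses palindromes
            start = 0
            while (pos := seq.find(probe, start)) != -1:
                total += 1
                if total >= stop_at:
                    return total
                start = pos + 1
    return total


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _candidates(cds: str, params: DesignParams, window_len: int):
    """Yield (cut_offset, spacer, pam, strand) protospacer candidates.

    *cds* is the sense-orientation CDS. Both orientations are scanned; the
    spacer interval, expressed in sense-CDS coordinates, must lie within
    ``[0, window_len]``. ``cut_offset`` is the nt distance from the CDS
    start to the blunt cut (3 nt 5' of the PAM).
    """
    pam_re = _pam_regex(params.pam)
    slen = params.spacer_len
    plen = len(params.pam)
    L = len(cds)
    for strand, seq in (("+", cds), ("-", revcomp(cds))):
        for m in pam_re.finditer(seq):
            p = m.start()
            if p < slen or p + plen > len(seq):
                continue
            spacer = seq[p - slen : p]
            if strand == "+":
                lo, cut = p - slen, p - 3
            else:
                lo, cut = L - p, L - p + 3
            if lo < 0 or lo + slen > window_len:
                continue
            yield cut, spacer, m.group(1), strand


def design_guides(
    genome: dict[str, str],
    features: pd.DataFrame,
    gene_ids: list[str] | None = None,
    params: DesignParams | None = None,
) -> DesignResult:
    """Design up to ``guides_per_gene`` spacers per gene.

    *genome* maps contig -> sequence; *features* is the CDS table from
    :func:`load_cds_features` (or the simulator). Candidates are ranked by
    ``cut_offset`` ascending (5'-most cut first; ties broken by strand then
    spacer for determinism). Genes whose id is missing from the annotation
    raise; genes where no candidate passes the filters are reported in
    ``genes_without_guides``.
    """
    params = params or DesignParams()
    feat_by_gene = {row.gene_id: row for row in features.itertuples()}
    if gene_ids is None:
        gene_ids = list(feat_by_gene)
    missing = [g for g in gene_ids if g not in feat_by_gene]
    if missing:
        raise DataError(f"gene ids absent from annotation: {missing[:10]}")
    haystacks = list(genome.values())
    records: list[dict] = []
    failed: list[str] = []
    for gene in gene_ids:
        row = feat_by_gene[gene]
        if row.seqid not in genome:
            raise DataError(f"contig {row.seqid!r} for gene {gene} not in genome")
        region = genome[row.seqid][row.start : row.end]
        cds = region if row.strand == "+" else revcomp(region)
        wlen = int(len(cds) * params.cds_window_frac)
        candidates = []
        for cut, spacer, pam_seq, strand in _candidates(cds, params, wlen):
            if not params.gc_min <= _gc(spacer) <= params.gc_max:
                continue
            if params.forbid_homopolymer and params.forbid_homopolymer in spacer:
                continue
            candidates.append((cut, 0 if strand == "+" else 1, spacer, pam_seq, strand))
        candidates.sort()
        kept = 0
        seen_spacers = set()
        for cut, _, spacer, pam_seq, strand in candidates:
            if kept >= params.guides_per_gene:
                break
            if spacer in seen_spacers:
                continue
            if _count_occurrences(haystacks, spacer + pam_seq) != 1:
                continue
            seen_spacers.add(spacer)
            kept += 1
            records.append(
                {
                    "guide_id": f"{gene}_g{kept}",
                    "gene_id": gene,
                    "spacer": spacer,
                    "pam": pam_seq,
                    "strand": strand,
                    "cut_offset": cut,
                }
            )
        if kept == 0:
            failed.append(gene)
    guides = pd.DataFrame(records, columns=GUIDE_COLUMNS)
    return DesignResult(guides=guides, genes_without_guides=failed)


def emit_oligos(
    guides: pd.DataFrame, template: str = DEFAULT_TEMPLATE
) -> pd.DataFrame:
    """Build synthesis oligos: 5' flank + spacer + 3' flank per guide.

    The template must contain the ``{SPACER}`` placeholder exactly once.
    Oligo ids are ``<gene_id>.<guide_id>``. Returns columns
    ``oligo_id, sequence``; write with :func:`write_oligo_fasta`.
    """
    if template.count(SPACER_PLACEHOLDER) != 1:
        raise DataError(
            f"cassette template must contain {SPACER_PLACEHOLDER} exactly once"
        )
    five, three = template.split(SPACER_PLACEHOLDER)
    rows = [
        {
            "oligo_id": f"{row.gene_id}.{row.guide_id}",
            "sequence": five + row.spacer + three,
        }
        for row in guides.itertuples()
    ]
    oligos = pd.DataFrame(rows, columns=["oligo_id", "sequence"])
    if oligos["oligo_id"].duplicated().any():
        raise DataError("duplicate oligo ids (guide_id not unique within gene?)")
    return oligos


def write_oligo_fasta(oligos: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in oligos.itertuples():
            fh.write(f">{row.oligo_id}\n{row.sequence}\n")


def assign_multiplex_vectors(
    targets: list[str], guides: pd.DataFrame, capacity: int = 4
) -> pd.DataFrame:
    """Pack knockout targets into multiplexed vectors of bounded capacity.

    Greedy sequential fill in input order; with singleton demands this
    attains the optimal covering of ceil(n / capacity) vectors. Each target
    gets its top-ranked guide. Targets lacking any designed guide are an
    error (listed). Returns columns ``vector_id, gene_id, guide_id``.
    """
    if capacity < 1:
        raise ConfigError("capacity must be >= 1")
    if len(set(targets)) != len(targets):
        raise DataError("duplicate target ids")
    best_guide = (
        guides.drop_duplicates("gene_id").set_index("gene_id")["guide_id"].to_dict()
    )
    uncovered = [t for t in targets if t not in best_guide]
    if uncovered:
        raise DataError(f"targets with no designed guide: {uncovered[:10]}")
    rows = []
    for i, t in enumerate(targets):
        rows.append(
            {
                "vector_id": f"V{i // capacity + 1:02d}",
                "gene_id": t,
                "guide_id": best_guide[t],
            }
        )
    return pd.DataFrame(rows, columns=["vector_id", "gene_id", "guide_id"])
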