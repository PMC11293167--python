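# Methods

## Scope and model

The package analyzes pooled CRISPR-Cas9 knockout screens of a defined gene
set (here: the secretome of a protein-production yeast) and the selection
of non-essential knockout targets from the result. The statistical core is
guide-level: each gene g is represented by the log2 fold changes (LFCs) of
its sgRNAs between a pre-selection and a post-selection sequencing sample.
Genes whose loss costs fitness have systematically depleted guides.

### Secretome definition

Membership is the union of two evidence sources: a signal-peptide
prediction probability strictly greater than a threshold (default 0.5, the
conventional SignalP Sec/SPI cutoff; ties at exactly the threshold are
excluded, and the same strictness is used everywhere a 0.5 cutoff appears),
and experimental detection in culture supernatant in *any* cultivation
phase. "Detected" means the protein appears in the abundance table with a
positive summed area-under-the-curve; upstream spectral-quality filtering
(search-engine score, isolation interference) is assumed done by the
instrument pipeline, with a generic numeric row filter
(`secretome.filter_rows`) available when the table still carries those
columns. Relative abundance is log10 of the AUC summed over replicates
(default four); proteins detected in only one phase carry a missing — not
zero — abundance in the other and are excluded from the cross-phase
Pearson correlation. Identifier reconciliation between protein and gene
namespaces is exact string match; callers with divergent namespaces apply
their own alias map before entry.

### Essentiality score

For each gene with at least `min_guides` (default 2) guides, the
background is every guide of every *other* gene (leave-one-gene-out; with
hundreds of genes the exclusion barely moves the background but avoids
self-contamination). The one-sided two-sample KS statistic

    D = sup_x [ ECDF_gene(x) − ECDF_background(x) ]

is sensitive to the gene's LFCs being stochastically smaller (depleted).
Both ECDFs are right-continuous and evaluated at every pooled sorted
unique data point, which handles ties exactly; the sup over x is attained
at one of those points. The p-value is the one-sided asymptotic tail bound

    p = exp(−2 m D²),  m = n_g n_b / (n_g + n_b),

which by the one-sided Dvoretzky–Kiefer–Wolfowitz inequality is a valid
(conservative) bound at any sample size, and the score is s = 1 − p with
genes s > 0.5 called likely essential. The score is rank-based: any
strictly increasing transformation applied to all LFCs leaves it
unchanged. A label-permutation p-value (`method="permutation"`, +1
correction) is provided for very small guide counts; the scoring interface
is a single function so alternative score definitions can be dropped in.

**What the 0.5 threshold does and does not give.** Essential genes
saturate the score (D near 1 drives p below 1e-4 at six guides per gene),
so sensitivity is excellent — on the packaged simulation all true
essentials rank above all neutral genes. Specificity at 0.5 is
intrinsically limited: s = 1 − p for a valid p-value, so under the
exchangeable null P(s > 0.5) = P(p < 0.5), which is ≈ 0.3–0.5 for any
calibrated or mildly conservative test and does not shrink with more
guides. The threshold should be read as "insufficient evidence of
essentiality below 0.5" (safe to target) rather than "essential above
0.5"; on the packaged simulation roughly a third of neutral genes exceed
it, consistent with screens of this design calling over half their genes
above 0.5. Raising specificity requires a smaller p cutoff (higher score
threshold), at no cost to the target-selection side, which only consumes
the s < 0.5 complement.

### Normalization and LFC

Counts are converted to counts-per-million with pseudocount 0.5:
norm = (c + 0.5) / (total + 0.5·n_guides) × 1e6, so every sample sums to
exactly 1e6 and LFC = log2(post) − log2(pre) is always finite. CPM was
chosen over median-ratio normalization deliberately: a screen in which
many genes deplete violates the mostly-unchanged assumption median-ratio
methods rely on. Reads shorter than anchor+spacer count as unmapped, never
truncated-matched; the optional 1-mismatch mode precomputes the full
mismatch neighborhood of the library and drops ambiguous variants, so such
reads fall to unmapped rather than being guessed.

### Weighted GSEA

Genes are ranked by score descending, ties broken by gene id for
determinism. For a set S of size k in a universe of N, the running sum
gains |s_i|^w / Σ_{hits}|s_j|^w on members and loses 1/(N−k) on
non-members; ES is the signed maximal deviation (a set containing the
whole universe has no misses and ES = 1; w = 0 recovers the classic
unweighted KS running sum). The null permutes gene labels, which for a
fixed ranking is equivalent to drawing k member positions uniformly —
nulls are cached per set size. NES divides ES by the mean |null ES| of the
same sign; the permutation p uses the +1 correction against same-sign
nulls; FDR is Benjamini-Hochberg across sets.

### Guide design

Candidates are 20-nt spacers 5' of an NGG PAM on either strand of the CDS.
The spacer must lie within the first 50% of the CDS (`cds_window_frac`) —
knockouts rely on early frameshifts, and the main design surface offers no
finer guidance — while the PAM itself may extend past the window (it must
stay inside the CDS). The blunt cut is placed 3 nt 5' of the PAM (standard
SpCas9 convention), and `cut_offset` records its distance from the CDS
start. Filters: GC in [0.2, 0.8]; no TTTT run (pol III terminator);
genome-wide uniqueness, defined as the exact spacer+PAM string occurring
exactly once in the genome counting both strands — no mismatch-based
off-target scoring is attempted. Ranking is cut_offset ascending; ties by
strand then spacer. Coordinates are GFF3 1-based inclusive at the file
boundary and 0-based half-open internally.

### Vector packing

Selected targets are packed greedily in input order into vectors of
capacity 4. With each target needing exactly one slot, greedy fill is
optimal (ceil(n/4) vectors; 54 targets → 14 vectors). The grouping of
genes within a vector is otherwise unconstrained — combination effects
such as synthetic lethality are outside the model — so callers who care
about co-occurrence order their target list accordingly.

## Synthetic data: what it emulates, what it does not

The generator produces a single-contig genome with non-overlapping,
length-divisible-by-3 CDSs at a target GC content; paired per-protein
log10 abundances from a bivariate normal with correlation `abundance_rho`
(default 0.93, matching the cross-phase agreement the pipeline is expected
to report); and screen counts in which guide baselines are lognormal
around `nb_mean` (log2 σ = 0.5 — pooled libraries are never uniform) and
counts are negative binomial with variance μ + φμ² (φ = `nb_dispersion`).
Essential-gene guides have their post-selection mean divided by
`depletion_factor`; depletion is purely multiplicative on the NB mean with
no partial-essentiality gradient by default, though per-gene fitness
factors are accepted. One pre and one post sample is the default; a
multi-passage series applies the fitness factor cumulatively.

The packaged acceptance simulation is `SimConfig()`: 361 genes (the
secretome cardinality), 6 guides/gene, 10% essential, 8-fold depletion,
NB(500, 0.1), ρ = 0.93, seed 17. The guides-per-gene, depth and passaging
of any particular real screen differ; these values are realistic
mid-range choices for a small pooled library, not measurements.

Not modeled: raw spectra or TMT channels (abundance enters at the
summarized per-protein level); sequencing error beyond optional uniform
substitution noise in FASTQ emission; guide efficiency variation; repair
outcomes (in-frame deletions that rescue a knockout); synthetic lethality
between multiplexed targets. Passing tests therefore demonstrate correct
arithmetic and sound statistical behavior under an idealized screen, not
robustness to chimeric reads, recombination during pooled cloning, or
copy-number effects in real libraries.

A fixed deterministic fixture (`simulate.marginals_fixture`) encodes the
reference selection arithmetic — 361 proteins split 30/227/104 between
the evidence classes, 61 detected non-essential candidates, 7 exclusions,
54 final targets — with synthetic ids; the seven excluded genes stand in
for a methanol-metabolism exclusion list that real analyses supply as a
curated file, since those identities are screen-specific curation, not
computation.

## Numerical and interface choices

- All RNG flows through `numpy.random.default_rng` seeded from explicit
  config values; a fixed seed reproduces every artifact byte for byte
  (gzip members are written with zeroed mtime and no filename for this
  reason). The pipeline refuses to run if a stochastic stage's seed is
  absent from the config.
- Degenerate inputs: |ρ| = 1 abundance pairs are generated exactly
  collinear (the covariance is singular); a sample with zero mapped reads,
  an empty guide library, fewer than two shared proteins for correlation,
  or a gene/background below two observations are errors, not NaNs.
- Exclusion-list ids that are not current candidates warn rather than
  fail: curated lists legitimately outlive a given screen's candidate set.
- Guide counting is order-independent at 0 mismatches; duplicate spacers
  in a library are rejected up front as inherently ambiguous.
- Demo problem sizes (60 genes, 4 guides/gene, NB mean 100) are chosen so
  the full simulated chain, including FASTQ round-trip, stays in the tens
  of thousands of reads; statistical checks use the 361-gene acceptance
  simulation where distributional claims need the full cardinality.

## Known limitations

- The asymptotic one-sided KS p is conservative for very small n_g; the
  permutation option exists for that regime but costs n_perm × O(n log n)
  per gene.
- Spacer+PAM uniqueness is exact-match only; near-miss off-targets are not
  scored, matching the design surface of the screens this supports.
- The orchestrator wires stages through in-memory products or file paths
  but does not manage partial re-runs; rerun the whole config (it is fast
  and deterministic).
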