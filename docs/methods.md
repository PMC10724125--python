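# Methods

This note documents the models, conventions and design choices behind
`araliome`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, and what
the synthetic data do and do not establish.

## Plastome ingestion and genome structure

GenBank records are parsed with Biopython; gene-bearing CDS/tRNA/rRNA
features are kept with strand, join coordinates and `codon_start`.
Coordinates are 0-based half-open internally and converted to the
format's 1-based inclusive convention only at the I/O boundary.  All
translation uses the plastid/bacterial genetic code (table 11); plastomes
conventionally use this table, and its sense/stop assignments match the
standard code, so the choice only matters for start-codon semantics that
this package never relies on.

CDS extraction splices a feature's intervals in genome order, reverse
complements minus-strand genes, trims `codon_start − 1` leading bases and
any trailing partial codon, and reports one sequence per gene symbol.
Genes duplicated in the inverted repeat are reported once — first copy by
genome position — because downstream matrices are built per unique gene
symbol.  `rps12` (trans-spliced) and `ycf15` (frequently pseudogenized)
are excluded by default; the exclusion list is configurable.  An internal
stop codon in a translation raises a warning rather than an error, since
annotation slippage is common in public records.

Inverted-repeat detection seeds on exact k-mer matches between the
doubled (circular) sequence and its reverse complement, extends them
maximally, and keeps the longest pair of disjoint intervals at least
`min_ir` (default 1000 bp) long.  The two single-copy gaps are assigned so
the LSC is the longer.  Working on the doubled sequence makes detection
invariant to the arbitrary linearization point of a circular record; a
mismatch-fraction parameter is accepted for interface stability but the
current extension is exact, which suffices for assembler-quality IRs.
Detection is quadratic-free but holds the sequence in memory; it is meant
for single plastome-scale records, not chromosomes.

GC content is (G+C)/(A+C+G+T) with ambiguity codes excluded from
numerator and denominator, and is undefined (an error) on all-ambiguous
input.

45S segmentation projects reference boundaries through a global pairwise
alignment.  Insertions at a segment junction are assigned to the upstream
segment; the projection refuses to guess below a configurable identity
floor (default 0.70), since boundary placement through a poor alignment
is not meaningful.

## Alignment and matrices

The pairwise primitive is global Needleman–Wunsch with affine gaps
(Gotoh), cost `open + (k−1)·extend` for a k-long gap run, default DNA
scoring match +1 / mismatch −1 / open −2 / extend −1 and BLOSUM62 with
open −10 / extend −1 for proteins.  Tie-breaking is deterministic:
substitution over gap-in-first over gap-in-second.  The dynamic program
is vectorized row-wise (the within-row gap recurrence is solved with a
running-maximum transformation), with full score matrices retained for
traceback; memory is therefore quadratic, appropriate for gene-length
sequences and 45S units but not whole genomes.

Multiple alignment is progressive: NJ on pairwise p-distances provides
the guide tree and profiles are merged with profile–profile Gotoh
(average-of-pairs column scores).  Gene alignment is protein-guided —
translations are aligned and back-translated — which guarantees in-frame
codon matrices with gaps in whole triplets, the invariant the codon
position extraction, translation and dS/dN stages depend on.  Aligning
CDS at the nucleotide level instead would not guarantee frame
preservation; this is a deliberate behavioral choice.  A whole-genome
matrix is supported only through the external-aligner hook (a pre-aligned
FASTA): aligning full ~155 kb plastomes internally is out of scope, as is
any alignment trimming/masking heuristic.

The supermatrix records an inclusive `(first_col, last_col)` range per
gene; missing taxon×gene cells are gap-filled so the taxon set is
constant across partitions.  The pos12 matrix keeps columns ≢ 2 (mod 3)
within each partition.  Translation converts `---` to `-`, rejects
partial-gap codons, and drops a gene's terminal column when it contains
only stops and gaps.

## Trees and discordance

Distances: p (mismatch fraction over shared unambiguous columns), JC69
(−¾·ln(1−4p/3)) and K2P (−½·ln(1−2P−Q) − ¼·ln(1−2Q) from transition and
transversion fractions).  Pairs outside the log domain are flagged as
saturated rather than raising; neighbor joining refuses saturated input
with an instruction to change model, because silently dropping pairs
would bias the topology.

NJ uses the classical Q-criterion with two determinism guarantees: ties
are broken by sorted taxon-label order of the candidate pair, and
negative branch lengths are clamped to zero with the deficit moved to the
sister branch (preserving the pair's summed length).  On additive
matrices the algorithm reconstructs the generating tree exactly; this is
tested over random trees up to 12 taxa.

Bootstrap resamples columns with replacement; support is the percentage
of replicate NJ trees containing each original split, stored as integer
percent node labels (the Newick convention the writer emits).  RF
distance counts non-trivial splits present in exactly one tree; monophyly
uses unrooted semantics (some edge bipartitions exactly the query tips).
Support collapsing contracts internal edges with support strictly below
the threshold — an edge at exactly the threshold survives.  Maximum
likelihood and Bayesian tree inference are non-goals; ML trees from
external programs enter through Newick and flow through every comparison
identically.

## Directional substitution spectra

Direction is defined as reference-state → query-state with an outgroup
reference standing proxy for the ancestral state; no ancestral-state
reconstruction is attempted, because reconstruction would change the
statistic being reported.  Columns with a gap or ambiguity code in either
row are skipped, never imputed; a column is counted once regardless of
how many historical hits produced the observed pair, an undercount that
is inherent to pairwise counting.  The six classes pool each change with
its reverse-strand image; the A–T and G–C classes are their own images,
so direction is not strand-resolvable there and both directions pool.
Spectra are counted on the concatenated matrix; totals are identical to
per-gene counting whenever the alignments agree.  Group summaries report
mean ± sample standard deviation; singleton groups carry a flag and no
dispersion.

## dS/dN estimation

NG86 sites: per codon position, the fraction of the counted single-base
changes that are synonymous, where changes to stop codons are excluded
from the counted set (the denominator).  With this convention S + N =
3 × codons exactly.  Differences at multi-hit codons average over all
minimal mutational pathways that avoid stops; a codon whose pathways are
all blocked is skipped entirely.  Proportions receive the classical
Jukes–Cantor correction; p ≥ 3/4 flags the pair as saturated instead of
failing the run.

The ML estimator fits the 61-state Goldman–Yang model with F3×4
equilibrium frequencies (positional base frequencies multiplied and
renormalized over sense codons; zero positional frequencies receive
small-count smoothing with a warning).  The generator is normalized to
one expected substitution per codon per unit branch length, so t is in
substitutions/codon.  Transition probabilities come from an
eigendecomposition of the π-symmetrized generator (the model is
reversible, so the likelihood is invariant to swapping the sequences).
Optimization is Nelder–Mead on log-parameters from the fixed start
(t, κ, ω) = (0.1, 2, 0.2) with a 500-iteration cap, for reproducibility;
non-convergence and boundary estimates are flagged.  dS and dN derive
from the fitted generator: with ρ_s the equilibrium synonymous flux
fraction and ρ_s¹ its value at ω = 1 (the site measure),
dS = t·ρ_s/(3ρ_s¹) and dN = t·ρ_n/(3(1−ρ_s¹)).

Rates are estimated pairwise, query versus reference, which matches a
per-taxon presentation of group summaries; branch-wise (free-ratio)
estimation on a fixed tree is a different estimator and out of scope, so
agreement with tree-based published values is expected to be approximate
only.  Group contrasts use one-way ANOVA plus all pairwise two-sample t
tests with Bonferroni multiplication (not Holm) capped at 1; groups with
a single member are excluded from testing but still summarized.

## The synthetic-data generator

The generator evolves gap-free CDS alignments along a fixed tree under an
HKY generator (default κ = 2 over an AT-rich plastome-like composition
A/C/G/T = 0.31/0.19/0.19/0.31), normalized to one expected substitution
per site per unit branch length *before* any perturbation.  A perturbed
clade multiplies the C→T and G→A generator entries; because
normalization precedes perturbation, the multiplier raises both that
clade's spectrum bias and its overall rate — the hypothesized coupling
for lineages under AT-biased mutational pressure.  Evolution is simulated
exactly (per-site exponential waiting times), and every realized event is
logged per branch with its directed type, so recovery tests compare
against exact ground truth rather than expectations alone.

The generator is nucleotide-level with optional codon-aware stop
rejection (a substitution creating an in-frame stop is discarded by
thinning; time still advances).  ω is therefore induced, not
parameterized — ML codon-model recovery tests simulate from the codon
model itself instead.  Stop rejection removes a small set of C→T and G→A
events (stops contain no C, so the reverse classes are unaffected),
depressing the null C–T/T–C ratio by a few percent; measured background
ratios stay within the 99% binomial band of 1 at the canonical study
size.  Indels, among-site rate heterogeneity beyond per-gene scalars, and
rearrangements are not simulated — so passing recovery tests demonstrate
estimator correctness under the model, not robustness to alignment error
or rate heterogeneity in real data.

The canonical study design (`two_clade_config`) is fixed: 16 taxa — an
outgroup reference, a 4-tip perturbed clade with a 3× C→T multiplier, an
11-tip background clade — 20 genes × 300 codons, reference-to-tip
divergence ≈ 0.15 substitutions/site, chosen to match the scale of an
outgroup-anchored family-level plastome comparison (thousands of
substitutions per taxon against the reference).  All recovery tests and
the acceptance script run this design; only the seed varies.

The toy plastome factory plants an exact IR pair in a
LSC | IRa | SSC | IRb layout with stop-free CDS features including a
two-exon gene, a minus-strand gene, and `rps12`/`ycf15` to exercise the
exclusion list; ground truth is returned alongside the record.

## Numerical and determinism notes

- All randomness flows through explicitly passed, seeded NumPy
  generators; identical configurations give byte-identical outputs.
- Alignment traceback compares scores with a 1e-9 tolerance; default
  scoring schemes are integer-valued, making comparisons exact.
- NJ and the pipeline sort taxa and genes, so input order never affects
  results.
- The pipeline writes a config fingerprint in its manifest; re-running a
  completed run with the same configuration performs no recomputation and
  changes no artifact.
- Problem sizes in the test and acceptance runs (20 genes × 300 codons ×
  16 taxa; 20 ML replicates × 5000 codons) were chosen as the smallest
  sizes at which the binomial/recovery bands in the tests are meaningful.

## Known limitations

- Whole-genome alignment, ML/Bayesian tree search, divergence-time
  estimation and ancestral-area reconstruction are intentionally external
  to this package.
- The spectrum statistic attributes all changes on the reference→query
  path to the query lineage; changes on the reference's own terminal
  branch contribute symmetrically to all queries and cancel only in
  contrasts between queries.
- IR detection requires an exact seed match; heavily degraded IRs below
  the seed length would be missed.
- The pairwise ML estimator assumes a single (t, κ, ω) per pair; lineage
  heterogeneity within a pair is averaged, not modeled.
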