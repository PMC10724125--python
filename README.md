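# araliome

A comparative plastome evolution toolkit for phylogenomic studies of plant
families: extract protein-coding genes from annotated plastid genomes,
build codon-aware concatenated data matrices, infer and compare trees, and
quantify directional mutational pressure and synonymous/nonsynonymous
substitution rates against an outgroup reference.

## Who it is for and what it does

Plastomes (plastid genomes) are ~150 kb circular genomes with a conserved
quadripartite structure — a large and a small single-copy region (LSC,
SSC) separated by two inverted-repeat copies (IRa/IRb).  Family-level
plastome studies typically (i) assemble/ingest a few dozen annotated
plastomes, (ii) build several data matrices from the same genes
(concatenated CDS, first+second codon positions, translated proteins,
whole genomes), (iii) compare the resulting phylogenies, and (iv) ask
whether particular lineages evolve under unusual mutational pressure.
`araliome` implements that workflow as a tested, scriptable pipeline:

- **`plastome`** — GenBank I/O, in-frame CDS extraction (with gene-name
  normalization, IR deduplication, and a default `rps12`/`ycf15`
  exclusion), GC content, and detection of the LSC/SSC/IR partition from
  sequence alone.
- **`nrdna`** — 45S ribosomal unit segmentation (18S–ITS1–5.8S–ITS2–26S)
  by boundary projection from an annotated reference.
- **`align` / `matrices`** — protein-guided codon alignment
  (Needleman–Wunsch/Gotoh with affine gaps, NJ-guided progressive
  profiles, codon back-translation) and supermatrix construction with a
  per-gene partition table; writers for FASTA, relaxed PHYLIP and NEXUS
  (charsets included).
- **`trees`** — p/JC69/K2P distances, neighbor joining, column bootstrap,
  Robinson–Foulds distances, monophyly tests, low-support collapsing, and
  a per-clade support-by-matrix discordance report.  Externally inferred
  ML trees are ingested via Newick and treated identically.
- **`mutspec`** — the directional substitution spectrum: every query is
  compared column-wise to a designated reference (an outgroup proxy for
  the ancestral state) and substitutions are pooled into six
  complement-collapsed classes (T–C, C–T, T–G, G–T, A–T, G–C).  The
  headline statistic is the C–T/T–C ratio: values above 1 indicate an
  excess of C→T (G→A) transitions — AT-biased mutational pressure.
- **`dnds`** — Nei–Gojobori (NG86) dS/dN with pathway averaging,
  stop-exclusion site counting and Jukes–Cantor correction, plus a
  pairwise maximum-likelihood estimator under a Goldman–Yang-type 61-state
  codon model with F3×4 frequencies (fits t, κ, ω); one-way ANOVA with
  Bonferroni-adjusted pairwise tests for group contrasts.
- **`simulate`** — a seeded sequence-evolution generator (HKY-type, with a
  clade-specific multiplier on the C→T/G→A generator entries) that logs
  every substitution event, plus a toy annotated-plastome factory with a
  planted IR pair.  It provides exact ground truth for recovery tests.
- **`pipeline` / `araliome` CLI** — one YAML configuration drives
  ingest → matrices → trees → discordance → spectra → dS/dN → report,
  deterministically and idempotently.

## The statistics at the core

For a reference base *i* and query base *j* at an aligned coding position,
substitutions are classified by the complement-collapsed map (e.g. C→T and
G→A are one class), making the spectrum invariant to the strand a gene was
annotated on.  NG86 counts synonymous sites per codon as the fraction of
non-stop single-base changes that preserve the amino acid (so S + N = 3 ×
codons), averages synonymous/nonsynonymous differences over all stop-free
minimal mutational pathways, and corrects proportions with
d = −(3/4)·ln(1 − (4/3)p).  The ML estimator maximizes
Σ log(π_i P_ij(t)) over codon-pair patterns under the GY rate matrix
Q_ij ∝ π_j·κ^[transition]·ω^[nonsynonymous], and decomposes the fitted
flow into dS and dN.  Distances for tree building use p, JC69 or K2P
(d = −½ln(1−2P−Q) − ¼ln(1−2Q)).

## Worked example

Simulate the canonical two-clade experiment — an outgroup reference `REF`,
a four-taxon clade (`P1`–`P4`) carrying a 3× C→T multiplier, and an
eleven-taxon background clade — then measure the spectrum and rates:

```python
from araliome.simulate import simulate_alignment, two_clade_config
from araliome.mutspec import spectra_vs_reference, spectrum_bias_ratio
from araliome.dnds import estimates_vs_reference

sim = simulate_alignment(two_clade_config(seed=1, n_genes=6,
                                          codons_per_gene=200))
cds = sim.concatenated()
for s in spectra_vs_reference(cds, "REF")[:4]:
    print(f"{s.query}: C-T={s.counts['C-T']}  T-C={s.counts['T-C']}  "
          f"ratio={spectrum_bias_ratio(s):.2f}")
est = estimates_vs_reference(cds.rows, "REF")[0]
print(f"{est.pair[0]}: dS={est.dS:.4f}  dN={est.dN:.4f}  "
      f"omega={est.omega:.3f}")
```

```
P1: C-T=199  T-C=113  ratio=1.76
P2: C-T=190  T-C=104  ratio=1.83
P3: C-T=183  T-C=119  ratio=1.54
P4: C-T=184  T-C=121  ratio=1.52
P1: dS=0.1884  dN=0.1582  omega=0.840
```

Every perturbed taxon shows a C–T/T–C ratio well above 1 — the planted
AT-biased pressure, recovered from sequence alone — while background taxa
(not shown) stay near 1.  The same analyses run from the shell:

```
araliome simulate --config sim.yaml --out simdata/
araliome matrices --genes simdata/ --prealigned --out matrices/
araliome tree     --matrix matrices/cds.fasta --model k2p --bootstrap 100 --seed 42
araliome mutspec  --matrix matrices/cds.fasta --reference REF --out spectra.tsv
araliome run      --config run.yaml        # full pipeline from one file
```

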