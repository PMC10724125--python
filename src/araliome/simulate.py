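"""Synthetic-data generator for clade-structured plastid CDS evolution.

Coding sequences are evolved along a fixed tree under an HKY/GTR-type
nucleotide model.  A designated clade can carry a multiplier on the C->T
and G->A generator entries — the strand-symmetric image of AT-biased
mutational pressure — applied *after* the generator is normalized to one
expected substitution per site per unit branch length, so the multiplier
raises both the C–T spectrum class and the overall rate of that clade, as
hypothesized for semi-aquatic lineages with accelerated plastome
evolution.

Every realized substitution is logged per branch with its directed type,
giving exact ground truth for spectrum- and rate-recovery tests.  A
toy annotated plastome factory plants an inverted-repeat pair and typical
awkward features (multi-exon CDS, minus-strand CDS, excluded genes) for
exercising the ingestion code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
from scipy.linalg import expm

from ._codons import NUCLEOTIDES, STOP_CODONS
from .align import Alignment
from .plastome import Feature, GenomeRecord, reverse_complement

_BASE_IDX = {b: i for i, b in enumerate(NUCLEOTIDES)}
_STOP_CODES = {tuple(_BASE_IDX[b] for b in stop) for stop in STOP_CODONS}

#: plastome-like AT-rich equilibrium base composition (A, C, G, T)
DEFAULT_PI = (0.31, 0.19, 0.19, 0.31)


def hky_rate_matrix(kappa: float = 2.0,
                    pi: tuple[float, ...] = DEFAULT_PI) -> np.ndarray:
    """HKY85 generator over (A, C, G, T), normalized to mean rate 1."""
    pi_arr = np.asarray(pi, dtype=float)
    pi_arr = pi_arr / pi_arr.sum()
    q = np.zeros((4, 4))
    for i, a in enumerate(NUCLEOTIDES):
        for j, b in enumerate(NUCLEOTIDES):
            if i == j:
                continue
            rate = pi_arr[j]
            if (a in "AG") == (b in "AG"):  # transition
                rate *= kappa
            q[i, j] = rate
    total = (pi_arr[:, None] * q).sum()
    q /= total
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def perturb_ct(q: np.ndarray, multiplier: float) -> np.ndarray:
    """Multiply the C->T and G->A generator entries (the complement-
    collapsed C–T class) by ``multiplier``; no renormalization, so the
    perturbation accelerates the clade as well as skewing its spectrum."""
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    out = q.copy()
    np.fill_diagonal(out, 0.0)
    out[_BASE_IDX["C"], _BASE_IDX["T"]] *= multiplier
    out[_BASE_IDX["G"], _BASE_IDX["A"]] *= multiplier
    np.fill_diagonal(out, -out.sum(axis=1))
    return out


@dataclass
class SimConfig:
    """Ground-truth configuration for one simulation.

    ``tree`` is a Newick string with branch lengths in expected
    substitutions per site (before perturbation).  ``perturbed_clades``
    maps a clade name to its tip set; ``ct_multipliers`` gives each named
    clade's C->T/G->A multiplier.  ``stop_free`` rejects substitutions that
    would create an in-frame stop codon, keeping all sequences translatable.
    """

    tree: str
    n_genes: int = 20
    codons_per_gene: int = 300
    kappa: float = 2.0
    pi: tuple[float, ...] = DEFAULT_PI
    perturbed_clades: dict[str, tuple[str, ...]] = field(default_factory=dict)
    ct_multipliers: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    stop_free: bool = True

    def __post_init__(self) -> None:
        for name, mult in self.ct_multipliers.items():
            if name not in self.perturbed_clades:
                raise ValueError(f"multiplier for unknown clade {name!r}")
            if mult <= 0:
                raise ValueError("multipliers must be positive")


@dataclass
class SimResult:
    """Simulated gene alignments plus exact per-branch event counts.

    ``branch_counts`` maps the label of each edge's child node to a 4x4
    matrix of realized parent-base -> child-base substitution events
    (A, C, G, T order), summed over genes.
    """

    config: SimConfig
    tree: dendropy.Tree
    gene_alignments: dict[str, Alignment]
    branch_counts: dict[str, np.ndarray]

    @property
    def total_events(self) -> int:
        return int(sum(c.sum() for c in self.branch_counts.values()))

    def concatenated(self) -> Alignment:
        taxa = next(iter(self.gene_alignments.values())).taxa
        rows = [(t, "".join(self.gene_alignments[g].row(t)
                            for g in self.gene_alignments)) for t in taxa]
        return Alignment(kind="codon", rows=rows)


def _label_tree(tree: dendropy.Tree) -> None:
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.sim_label = node.taxon.label
        else:
            node.sim_label = f"node{counter}"
            counter += 1


def _edge_is_perturbed(node: dendropy.Node,
                       clades: Mapping[str, tuple[str, ...]]) -> str | None:
    below = {lf.taxon.label for lf in node.leaf_iter()}
    for name, tips in clades.items():
        if below <= set(tips):
            return name
    return None


def _draw_root(n_sites: int, pi: np.ndarray, stop_free: bool,
               rng: np.random.Generator) -> np.ndarray:
    seq = rng.choice(4, size=n_sites, p=pi)
    if stop_free:
        for c in range(n_sites // 3):
            while tuple(seq[3 * c:3 * c + 3]) in _STOP_CODES:
                seq[3 * c:3 * c + 3] = rng.choice(4, size=3, p=pi)
    return seq


def _evolve_branch(parent: np.ndarray, q: np.ndarray, t: float,
                   stop_free: bool, rng: np.random.Generator,
                   counts: np.ndarray, max_stall: int = 10_000) -> np.ndarray:
    """Evolve one branch by exact event simulation (thinning for the
    stop-free constraint: a rejected event consumes time but changes
    nothing).  Appends realized events to ``counts`` (4x4)."""
    seq = parent.copy()
    if t <= 0:
        return seq
    rate_away = -np.diag(q)
    jump = q.copy()
    np.fill_diagonal(jump, 0.0)
    jump = jump / rate_away[:, None]
    waits = rng.exponential(1.0 / rate_away[seq])
    active = np.nonzero(waits < t)[0]
    for site in active:
        elapsed = waits[site]
        stalls = 0
        while elapsed < t:
            state = seq[site]
            new = rng.choice(4, p=jump[state])
            ok = True
            if stop_free:
                c = site // 3
                codon = seq[3 * c:3 * c + 3].copy()
                codon[site % 3] = new
                if tuple(codon) in _STOP_CODES:
                    ok = False
                    stalls += 1
                    if stalls > max_stall:
                        raise RuntimeError(
                            "stop-free rejection stalled; multiplier or "
                            "branch length too extreme")
            if ok:
                counts[state, new] += 1
                seq[site] = new
            elapsed += rng.exponential(1.0 / rate_away[seq[site]])
    return seq


def simulate_alignment(cfg: SimConfig) -> SimResult:
    """Evolve ``n_genes`` gap-free CDS alignments along the configured tree.

    The root sequence is drawn from the equilibrium frequencies; each
    branch applies its (possibly perturbed) generator by exact stochastic
    simulation, and every substitution event is logged with its directed
    type.  Identical configs (including seed) give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    _label_tree(tree)
    pi = np.asarray(cfg.pi, dtype=float)
    pi = pi / pi.sum()
    q_base = hky_rate_matrix(cfg.kappa, tuple(pi))
    q_by_clade = {name: perturb_ct(q_base, cfg.ct_multipliers.get(name, 1.0))
                  for name in cfg.perturbed_clades}
    edge_q: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        clade = _edge_is_perturbed(node, cfg.perturbed_clades)
        edge_q[node.sim_label] = q_by_clade[clade] if clade else q_base
    branch_counts = {label: np.zeros((4, 4), dtype=int) for label in edge_q}
    n_sites = 3 * cfg.codons_per_gene
    gene_alignments: dict[str, Alignment] = {}
    for g in range(cfg.n_genes):
        root_seq = _draw_root(n_sites, pi, cfg.stop_free, rng)
        seqs: dict[str, np.ndarray] = {}
        state = {tree.seed_node.sim_label: root_seq}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent_seq = state[node.parent_node.sim_label]
            t = node.edge.length or 0.0
            child = _evolve_branch(parent_seq, edge_q[node.sim_label], t,
                                   cfg.stop_free, rng,
                                   branch_counts[node.sim_label])
            state[node.sim_label] = child
            if node.is_leaf():
                seqs[node.taxon.label] = child
        rows = [(taxon, "".join(NUCLEOTIDES[b] for b in seq))
                for taxon, seq in seqs.items()]
        gene_alignments[f"gene{g + 1:03d}"] = Alignment(kind="codon",
                                                        rows=rows)
    return SimResult(config=cfg, tree=tree,
                     gene_alignments=gene_alignments,
                     branch_counts=branch_counts)


def expected_spectrum(q: np.ndarray, t: float,
                      pi: np.ndarray | None = None) -> dict[str, float]:
    """Analytic expected proportions of directed substitution types.

    Computes pi_i · exp(Qt)_ij for i != j (the probability that a site is
    i in the reference/ancestor and j != i in the query), normalized to
    proportions among differing sites, then complement-collapsed into the
    six classes.  Oracle for spectrum-counting tests.
    """
    from .mutspec import COLLAPSE, CLASSES

    if pi is None:
        # equilibrium of q: left null vector
        w, v = np.linalg.eig(q.T)
        k = np.argmin(np.abs(w))
        pi = np.real(v[:, k])
        pi = pi / pi.sum()
    p = expm(q * t)
    joint = pi[:, None] * p
    out = {cls: 0.0 for cls in CLASSES}
    total = 0.0
    for i, a in enumerate(NUCLEOTIDES):
        for j, b in enumerate(NUCLEOTIDES):
            if i == j:
                continue
            out[COLLAPSE[(a, b)]] += joint[i, j]
            total += joint[i, j]
    if total > 0:
        out = {cls: val / total for cls, val in out.items()}
    return out


#: canonical two-clade study tree: an outgroup reference, a 4-tip clade
#: carrying the mutational-pressure perturbation, and an 11-tip background
#: clade (16 taxa).  Branch lengths in expected substitutions/site give a
#: reference-to-tip divergence of roughly 0.15, comparable to an
#: outgroup-anchored family-level plastome comparison.
TWO_CLADE_TREE = (
    "(REF:0.08,(((P1:0.02,P2:0.02):0.01,(P3:0.02,P4:0.02):0.01):0.04,"
    "((B1:0.01,B2:0.01):0.01,((B3:0.01,B4:0.01):0.01,(B5:0.01,(B6:0.01,"
    "(B7:0.01,(B8:0.01,(B9:0.01,(B10:0.01,B11:0.01):0.005):0.005):0.005)"
    ":0.005):0.005):0.01):0.01):0.04):0.0);"
)

PERTURBED_TIPS = ("P1", "P2", "P3", "P4")
BACKGROUND_TIPS = ("B1", "B2", "B3", "B4", "B5", "B6", "B7", "B8", "B9",
                   "B10", "B11")


def two_clade_config(seed: int = 0, n_genes: int = 20,
                     codons_per_gene: int = 300,
                     ct_multiplier: float = 3.0) -> SimConfig:
    """The canonical two-clade experiment: one clade under 3x C->T pressure.

    This is the fixed in-silico analogue of a family with an aquatic
    subfamily under AT-biased mutational pressure; recovery tests and the
    acceptance pipeline all run on this design.
    """
    return SimConfig(tree=TWO_CLADE_TREE, n_genes=n_genes,
                     codons_per_gene=codons_per_gene, kappa=2.0,
                     perturbed_clades={"pressure": PERTURBED_TIPS},
                     ct_multipliers={"pressure": ct_multiplier},
                     seed=seed, stop_free=True)


# ---------------------------------------------------------------------------
# Toy annotated plastome


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Stop-free CDS with ATG start and TAA terminal stop."""
    body = []
    while len(body) < n_codons - 2:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if codon not in STOP_CODONS:
            body.append(codon)
    return "ATG" + "".join(body) + "TAA"


def make_toy_plastome(n_genes: int = 6, ir_length: int = 1500,
                      genome_length: int = 10_000, seed: int = 0
                      ) -> tuple[GenomeRecord, dict]:
    """Fabricate a circular annotated plastome with planted ground truth.

    Layout: LSC | IRa | SSC | IRb, with all gene features inside the LSC.
    The gene set includes a two-exon CDS, a minus-strand CDS, and an
    ``rps12`` and ``ycf15`` to exercise the default exclusion list.
    Returns the record and a dict of planted truths (region coordinates and
    per-gene CDS sequences).
    """
    if 2 * ir_length >= genome_length - 2000:
        raise ValueError("ir_length too large for the requested genome")
    rng = np.random.default_rng(seed)
    ssc_length = max(1000, (genome_length - 2 * ir_length) // 4)
    lsc_length = genome_length - 2 * ir_length - ssc_length
    if lsc_length <= ssc_length:
        raise ValueError("infeasible layout: LSC would not be the longest")
    seq = list(rng.choice(list("ACGT"), size=genome_length))
    lsc = (0, lsc_length)
    ira = (lsc_length, lsc_length + ir_length)
    ssc = (ira[1], ira[1] + ssc_length)
    irb = (ssc[1], ssc[1] + ir_length)
    ir_seq = "".join(seq[ira[0]:ira[1]])
    seq[irb[0]:irb[1]] = list(reverse_complement(ir_seq))

    features: list[Feature] = []
    truth_genes: dict[str, str] = {}
    pos = 50
    gene_names = [f"gene{i + 1:02d}" for i in range(max(0, n_genes - 2))]
    gene_names += ["rps12", "ycf15"]
    for k, gene in enumerate(gene_names):
        n_codons = int(rng.integers(40, 80))
        cds = _random_cds(n_codons, rng)
        if pos + len(cds) + 60 >= lsc_length:
            raise ValueError("infeasible layout: genes exceed the LSC")
        if k == 0 and len(cds) >= 30:
            # two-exon gene: split the CDS around a 40 bp intron
            cut = (len(cds) // 2) // 3 * 3
            intron_len = 40
            exon1, exon2 = cds[:cut], cds[cut:]
            seq[pos:pos + cut] = list(exon1)
            start2 = pos + cut + intron_len
            seq[start2:start2 + len(exon2)] = list(exon2)
            features.append(Feature(gene=gene, kind="CDS", intervals=[
                (pos, pos + cut, "+"),
                (start2, start2 + len(exon2), "+")]))
            end = start2 + len(exon2)
        elif k == 1:
            # minus-strand gene: genome carries the reverse complement
            seq[pos:pos + len(cds)] = list(reverse_complement(cds))
            features.append(Feature(gene=gene, kind="CDS",
                                    intervals=[(pos, pos + len(cds), "-")]))
            end = pos + len(cds)
        else:
            seq[pos:pos + len(cds)] = list(cds)
            features.append(Feature(gene=gene, kind="CDS",
                                    intervals=[(pos, pos + len(cds), "+")]))
            end = pos + len(cds)
        truth_genes[gene] = cds
        pos = end + int(rng.integers(20, 60))

    record = GenomeRecord(id=f"TOY{seed:04d}", taxon="Synthetica plastoma",
                          sequence="".join(seq), topology="circular",
                          features=features)
    truth = {"lsc": lsc, "ira": ira, "ssc": ssc, "irb": irb,
             "ir_length": ir_length, "lsc_length": lsc_length,
             "ssc_length": ssc_length, "genes": truth_genes}
    return record, truth
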