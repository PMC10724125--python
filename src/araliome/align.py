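"""Pairwise and progressive alignment, and codon back-translation.

The pairwise primitive is global Needleman–Wunsch with affine gaps (Gotoh),
with deterministic tie-breaking: a substitution column is preferred over a
gap in the first sequence, which is preferred over a gap in the second.
A gap run of length k costs ``gap_open + (k-1)*gap_extend``.

The progressive aligner builds a neighbor-joining guide tree from pairwise
distances and merges alignment profiles in guide-tree order; it is meant
for protein-guided codon alignment of single plastid genes, not
whole-genome alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._codons import translate_codon

_NEG = -1e30

_DNA_CHARS = set("ACGTUN-")
_PROTEIN_ONLY = set("EFILPQZ*")  # residues that cannot be nucleotides


@dataclass
class Scoring:
    """Substitution scoring and affine gap parameters.

    Either a (match, mismatch) pair or an explicit symbol-pair matrix.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    matrix: Mapping[tuple[str, str], float] | None = None

    def score(self, a: str, b: str) -> float:
        if self.matrix is not None:
            return self.matrix.get((a, b), self.matrix.get((b, a), self.mismatch))
        return self.match if a == b else self.mismatch


def _blosum62() -> dict[tuple[str, str], float]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            out[(a, b)] = float(mat[a, b])
    return out


DNA_SCORING = Scoring(match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0)
PROTEIN_SCORING = Scoring(mismatch=-4.0, gap_open=-10.0, gap_extend=-1.0,
                          matrix=_blosum62())


@dataclass
class Alignment:
    """A rectangular multiple alignment.

    ``rows`` is an ordered list of ``(taxon, gapped sequence)``; ``kind`` is
    nucleotide, codon or protein.  Codon alignments keep gaps in whole
    triplets.
    """

    kind: str
    rows: list[tuple[str, str]]
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("nucleotide", "codon", "protein"):
            raise ValueError(f"unknown alignment kind {self.kind!r}")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if self.kind == "codon" and self.rows and self.n_cols % 3:
            raise ValueError("codon alignment length not divisible by 3")
        taxa = [t for t, _ in self.rows]
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon in alignment")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def taxa(self) -> list[str]:
        return [t for t, _ in self.rows]

    def row(self, taxon: str) -> str:
        for t, s in self.rows:
            if t == taxon:
                return s
        raise KeyError(taxon)


def _check_same_alphabet(a: str, b: str) -> None:
    def looks_protein(s: str) -> bool:
        return bool(set(s.upper()) & _PROTEIN_ONLY)

    if looks_protein(a) != looks_protein(b):
        raise ValueError("mixed alphabets: one sequence looks like protein, "
                         "the other like DNA")


def _gotoh(S: np.ndarray, gap_open: float, gap_extend: float
           ) -> tuple[float, list[str]]:
    """Affine-gap global alignment over a column score matrix.

    ``S[i, j]`` scores pairing element i of A with element j of B.  Returns
    the optimal score and the operation list over ('D', 'A', 'B'):
    D consumes one element of each, A consumes A only (gap in B), B
    consumes B only (gap in A).  Tie order: D, then B (gap in A), then A.
    """
    m, n = S.shape
    go, ge = float(gap_open), float(gap_extend)
    M = np.full((m + 1, n + 1), _NEG)
    X = np.full((m + 1, n + 1), _NEG)  # gap in B (consumes A)
    Y = np.full((m + 1, n + 1), _NEG)  # gap in A (consumes B)
    M[0, 0] = 0.0
    if m:
        X[1:, 0] = go + ge * np.arange(m)
    if n:
        Y[0, 1:] = go + ge * np.arange(n)
    for i in range(1, m + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        best_prev = np.maximum(prevM, np.maximum(prevX, prevY))
        M[i, 1:] = best_prev[:-1] + S[i - 1]
        X[i, :] = np.maximum(np.maximum(prevM, prevY) + go, prevX + ge)
        X[i, 0] = go + ge * (i - 1)
        # Y[i, j] = max(max(M, X)[i, j-1] + go, Y[i, j-1] + ge): running max
        Z = np.maximum(M[i, :-1], X[i, :-1]) + go
        if n:
            j = np.arange(1, n + 1)
            Y[i, 1:] = np.maximum.accumulate(Z - ge * j) + ge * j
        Y[i, 0] = _NEG
    eps = 1e-9
    score = max(M[m, n], Y[m, n], X[m, n])
    # traceback; preference D > gap-in-A > gap-in-B
    ops: list[str] = []
    if M[m, n] >= score - eps:
        state = "M"
    elif Y[m, n] >= score - eps:
        state = "Y"
    else:
        state = "X"
    i, j = m, n
    while i > 0 or j > 0:
        if state == "M":
            ops.append("D")
            tgt = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if M[i, j] >= tgt - eps:
                state = "M"
            elif Y[i, j] >= tgt - eps:
                state = "Y"
            else:
                state = "X"
        elif state == "Y":  # gap in A, consumed B[j-1]
            ops.append("B")
            val = Y[i, j]
            j -= 1
            if j == 0 and i == 0:
                break
            if M[i, j] + go >= val - eps:
                state = "M"
            elif Y[i, j] + ge >= val - eps:
                state = "Y"
            else:
                state = "X"
        else:  # X: gap in B, consumed A[i-1]
            ops.append("A")
            val = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + go >= val - eps:
                state = "M"
            elif Y[i, j] + go >= val - eps:
                state = "Y"
            else:
                state = "X"
        if i == 0 and j == 0:
            break
        if i == 0 and state not in ("Y",):
            state = "Y"
        if j == 0 and state not in ("X",):
            state = "X"
    ops.reverse()
    return float(score), ops


def pairwise_align(a: str, b: str, scoring: Scoring | None = None,
                   kind: str = "nucleotide",
                   ids: tuple[str, str] = ("a", "b")) -> Alignment:
    """Optimal global alignment of two sequences.

    Deterministic tie-breaking prefers a substitution column over a gap in
    ``a``, over a gap in ``b``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _check_same_alphabet(a, b)
    if scoring is None:
        scoring = PROTEIN_SCORING if kind == "protein" else DNA_SCORING
    a, b = a.upper(), b.upper()
    S = np.array([[scoring.score(x, y) for y in b] for x in a])
    score, ops = _gotoh(S, scoring.gap_open, scoring.gap_extend)
    ra, rb = [], []
    ia = ib = 0
    for op in ops:
        if op == "D":
            ra.append(a[ia]); rb.append(b[ib]); ia += 1; ib += 1
        elif op == "A":
            ra.append(a[ia]); rb.append("-"); ia += 1
        else:
            ra.append("-"); rb.append(b[ib]); ib += 1
    return Alignment(kind=kind, rows=[(ids[0], "".join(ra)),
                                      (ids[1], "".join(rb))], score=score)


def alignment_identity(aln: Alignment) -> float:
    """Fraction of identical residues over columns where both rows are
    ungapped (pairwise alignments only)."""
    (_, ra), (_, rb) = aln.rows
    both = [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]
    if not both:
        return 0.0
    return sum(x == y for x, y in both) / len(both)


# ---------------------------------------------------------------------------
# Progressive alignment

_PROT_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _profile_matrix(rows: list[str], alphabet: str) -> np.ndarray:
    """Column frequency matrix (n_cols x len(alphabet)); gaps weight 0."""
    idx = {c: k for k, c in enumerate(alphabet)}
    arr = np.zeros((len(rows[0]), len(alphabet)))
    for row in rows:
        for j, c in enumerate(row):
            k = idx.get(c)
            if k is not None:
                arr[j, k] += 1.0
    arr /= len(rows)
    return arr


def _merge_profiles(pa: list[tuple[str, str]], pb: list[tuple[str, str]],
                    scoring: Scoring, alphabet: str) -> list[tuple[str, str]]:
    sub = np.array([[scoring.score(x, y) for y in alphabet] for x in alphabet])
    fa = _profile_matrix([s for _, s in pa], alphabet)
    fb = _profile_matrix([s for _, s in pb], alphabet)
    S = fa @ sub @ fb.T
    _, ops = _gotoh(S, scoring.gap_open, scoring.gap_extend)
    out: list[tuple[str, str]] = []
    for taxon, row in pa:
        pieces, i = [], 0
        for op in ops:
            if op in ("D", "A"):
                pieces.append(row[i]); i += 1
            else:
                pieces.append("-")
        out.append((taxon, "".join(pieces)))
    for taxon, row in pb:
        pieces, j = [], 0
        for op in ops:
            if op in ("D", "B"):
                pieces.append(row[j]); j += 1
            else:
                pieces.append("-")
        out.append((taxon, "".join(pieces)))
    return out


def progressive_align(seqs: Mapping[str, str], scoring: Scoring | None = None,
                      kind: str = "protein") -> Alignment:
    """Progressive multiple alignment guided by a neighbor-joining tree.

    Pairwise p-distances feed NJ; profiles are merged bottom-up with
    profile-profile Gotoh alignment (average-of-pairs column scores).
    """
    if not seqs:
        raise ValueError("no sequences")
    items = list(seqs.items())
    if scoring is None:
        scoring = PROTEIN_SCORING if kind == "protein" else DNA_SCORING
    alphabet = _PROT_ALPHABET if kind == "protein" else "ACGT"
    if len(items) == 1:
        taxon, s = items[0]
        return Alignment(kind=kind, rows=[(taxon, s.upper())])
    if len(items) == 2:
        (ta, sa), (tb, sb) = items
        aln = pairwise_align(sa, sb, scoring, kind=kind, ids=(ta, tb))
        return aln
    n = len(items)
    dist = np.zeros((n, n))
    cache: dict[tuple[int, int], Alignment] = {}
    for i in range(n):
        for j in range(i + 1, n):
            aln = pairwise_align(items[i][1], items[j][1], scoring, kind=kind)
            cache[(i, j)] = aln
            dist[i, j] = dist[j, i] = 1.0 - alignment_identity(aln)
    order = _guide_merge_order(dist, [t for t, _ in items])
    profiles: dict[int, list[tuple[str, str]]] = {
        i: [(t, s.upper())] for i, (t, s) in enumerate(items)
    }
    next_id = n
    for left, right in order:
        merged = _merge_profiles(profiles.pop(left), profiles.pop(right),
                                 scoring, alphabet)
        profiles[next_id] = merged
        next_id += 1
    (final,) = profiles.values()
    by_taxon = dict(final)
    rows = [(t, by_taxon[t]) for t, _ in items]
    return Alignment(kind=kind, rows=rows)


def _guide_merge_order(dist: np.ndarray, labels: list[str]
                       ) -> list[tuple[int, int]]:
    """Merge order (pairs of working indices) from an NJ guide tree."""
    from .trees import nj

    tree = nj(dist, labels)
    label_to_idx = {lab: i for i, lab in enumerate(labels)}
    merges: list[tuple[int, int]] = []
    next_id = len(labels)

    def visit(node) -> int:
        nonlocal next_id
        if node.is_leaf():
            return label_to_idx[node.taxon.label]
        child_ids = [visit(c) for c in node.child_nodes()]
        current = child_ids[0]
        for cid in child_ids[1:]:
            merges.append((current, cid))
            current = next_id
            next_id += 1
        return current

    visit(tree.seed_node)
    return merges


# ---------------------------------------------------------------------------
# Codon back-translation


def codon_backtranslate(protein_aln: Alignment,
                        cds: Mapping[str, str]) -> Alignment:
    """Expand a protein alignment to its source codons.

    Each amino-acid column becomes the corresponding codon; protein gaps
    become ``---``.  Every CDS must translate to its ungapped protein row
    (a trailing stop codon on the CDS is tolerated and dropped).
    """
    rows: list[tuple[str, str]] = []
    for taxon, prow in protein_aln.rows:
        nt = cds[taxon].upper()
        nt = nt[: len(nt) - len(nt) % 3]
        codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
        if codons and translate_codon(codons[-1]) == "*":
            codons = codons[:-1]
        residues = prow.replace("-", "")
        if len(codons) != len(residues):
            raise ValueError(
                f"{taxon}: CDS has {len(codons)} codons but protein row has "
                f"{len(residues)} residues")
        for pos, (codon, aa) in enumerate(zip(codons, residues)):
            if translate_codon(codon) != aa.upper():
                raise ValueError(
                    f"{taxon}: codon {codon} at position {pos} translates to "
                    f"{translate_codon(codon)}, protein row has {aa}")
        it = iter(codons)
        gapped = "".join(next(it) if c != "-" else "---" for c in prow)
        rows.append((taxon, gapped))
    return Alignment(kind="codon", rows=rows)
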