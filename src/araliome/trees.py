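"""Distance-based tree inference and topological discordance analysis.

Trees are :class:`dendropy.Tree` objects throughout; bootstrap supports are
stored as integer-percent node labels on internal nodes (the common Newick
convention, which the writer emits).  Inference here is neighbor joining on
p/JC69/K2P distances; trees from external maximum-likelihood programs can
be read from Newick and fed to every downstream analysis identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .align import Alignment

# ---------------------------------------------------------------------------
# Distances


class SaturationError(ValueError):
    """Distances undefined for some pair; use a different model."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    saturated: np.ndarray  # boolean mask of saturated pairs

    @property
    def has_saturation(self) -> bool:
        return bool(self.saturated.any())


_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """uint8 matrix (rows x cols) and validity mask (unambiguous, ungapped)."""
    mat = np.frombuffer(
        "".join(s for _, s in aln.rows).encode("ascii"), dtype=np.uint8
    ).reshape(len(aln.rows), aln.n_cols)
    if aln.kind == "protein":
        valid = (mat != ord("-")) & (mat != ord("X")) & (mat != ord("?"))
        return mat, valid
    codes = _CODE[mat & 0x7F]
    return codes, codes != 255


def distance_matrix(aln: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances under p, JC69 or K2P.

    p is the mismatch fraction over shared ungapped, unambiguous columns;
    JC69 is ``-(3/4)·ln(1 - (4/3)p)``; K2P uses the transition fraction P
    and transversion fraction Q, ``d = -(1/2)·ln(1-2P-Q) - (1/4)·ln(1-2Q)``.
    Pairs whose correction leaves the log domain are flagged as saturated
    (NaN distance), not raised here.
    """
    model = model.lower()
    if model not in ("p", "jc69", "k2p"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(aln.rows) < 2:
        raise ValueError("need at least two rows")
    if aln.kind == "protein" and model != "p":
        raise ValueError("protein alignments support only the p distance")
    codes, valid = _encode(aln)
    n = len(aln.rows)
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    purine = np.isin(codes, (_CODE[ord("A")], _CODE[ord("G")]))
    for i in range(n):
        for j in range(i + 1, n):
            shared = valid[i] & valid[j]
            total = int(shared.sum())
            if total == 0:
                raise ValueError(
                    f"no shared ungapped columns for pair "
                    f"({aln.rows[i][0]}, {aln.rows[j][0]})")
            diff = shared & (codes[i] != codes[j])
            p = diff.sum() / total
            if model == "p":
                dij = p
            elif model == "jc69":
                if p >= 0.75:
                    dij, sat[i, j] = np.nan, True
                else:
                    dij = -0.75 * np.log1p(-4.0 * p / 3.0)
            else:
                ts = (diff & (purine[i] == purine[j])).sum() / total
                tv = p - ts
                a1, a2 = 1.0 - 2.0 * ts - tv, 1.0 - 2.0 * tv
                if a1 <= 0 or a2 <= 0:
                    dij, sat[i, j] = np.nan, True
                else:
                    dij = -0.5 * np.log(a1) - 0.25 * np.log(a2)
            d[i, j] = d[j, i] = dij
            sat[j, i] = sat[i, j]
    return DistanceMatrix(labels=list(aln.taxa), values=d, saturated=sat)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj(dist: DistanceMatrix | np.ndarray, labels: list[str] | None = None
       ) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted; trifurcating seed node).

    Deterministic: ties in the Q criterion are broken by sorted taxon-label
    order of the candidate pair.  Negative branch lengths are clamped to
    zero with the deficit moved to the adjacent (sister) branch.
    """
    if isinstance(dist, DistanceMatrix):
        if dist.has_saturation:
            bad = [(dist.labels[i], dist.labels[j])
                   for i, j in zip(*np.nonzero(np.triu(dist.saturated)))]
            raise SaturationError(
                f"saturated pairs {bad}: switch to a different distance model")
        labels = dist.labels
        d = dist.values.astype(float).copy()
    else:
        if labels is None:
            raise ValueError("labels required with a raw matrix")
        d = np.asarray(dist, dtype=float).copy()
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")

    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
    # cluster_label: for deterministic tie-breaks, the smallest leaf label
    # in each cluster
    clabels = list(labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cands = []
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12:
                    pair = tuple(sorted((clabels[active[a]],
                                         clabels[active[b]])))
                    cands.append((pair, a, b))
        _, a, b = min(cands)
        ia, ib = active[a], active[b]
        dab = sub[a, b]
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[ia])
        parent.add_child(nodes[ib])
        nodes[ia].edge.length = la
        nodes[ib].edge.length = lb
        # distances from the new node
        newd = 0.5 * (d[ia, :] + d[ib, :] - dab)
        d = np.vstack([d, newd])
        newd2 = np.append(newd, 0.0)
        d = np.column_stack([d, newd2])
        nodes.append(parent)
        clabels.append(min(clabels[ia], clabels[ib]))
        active = [k for k in active if k not in (ia, ib)]
        active.append(len(nodes) - 1)

    # final three clusters joined at the trifurcating seed
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        tree.seed_node.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Splits, RF, monophyly


def _split_map(tree: dendropy.Tree, include_trivial: bool = False
               ) -> dict[frozenset, dendropy.Node]:
    """Normalized splits -> defining child node.

    A split is the frozenset of taxa on the side *not* containing the
    lexicographically first taxon (unrooted normalization).
    """
    taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    pivot = min(taxa)
    out: dict[frozenset, dendropy.Node] = {}
    ntax = len(taxa)

    def leafset(node, memo={}):
        if node.is_leaf():
            return frozenset([node.taxon.label])
        return frozenset().union(*(leafset(c) for c in node.child_nodes()))

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label
                          for lf in node.leaf_iter())
        side = taxa - below if pivot in below else below
        if not include_trivial and not (2 <= len(side) <= ntax - 2):
            continue
        if len(side) == 0 or len(side) == ntax:
            continue
        out[side] = node
    return out


def nontrivial_splits(tree: dendropy.Tree) -> set[frozenset]:
    return set(_split_map(tree, include_trivial=False))


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds distance: splits present in exactly one tree."""
    tax1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    tax2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if tax1 != tax2:
        raise ValueError(
            f"taxon sets differ: only in first {sorted(tax1 - tax2)}, "
            f"only in second {sorted(tax2 - tax1)}")
    return len(nontrivial_splits(t1) ^ nontrivial_splits(t2))


def is_monophyletic(tree: dendropy.Tree, tips: Iterable[str]) -> bool:
    """Unrooted monophyly: some edge bipartitions exactly ``tips``."""
    tips = frozenset(tips)
    taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if not tips or tips == taxa:
        raise ValueError("tip set must be a non-empty proper subset")
    if not tips <= taxa:
        raise ValueError(f"tips not in tree: {sorted(tips - taxa)}")
    pivot = min(taxa)
    side = taxa - tips if pivot in tips else tips
    return side in _split_map(tree, include_trivial=True)


# ---------------------------------------------------------------------------
# Supports


def get_support(node: dendropy.Node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def bootstrap_support(aln: Alignment, B: int = 100, model: str = "p",
                      seed: int = 0) -> dendropy.Tree:
    """NJ tree with bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate trees containing each original-tree split.
    """
    if B < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    base = nj(distance_matrix(aln, model))
    target = _split_map(base, include_trivial=False)
    counts = {split: 0 for split in target}
    n_cols = aln.n_cols
    rows = [s for _, s in aln.rows]
    chars = np.frombuffer("".join(rows).encode("ascii"),
                          dtype=np.uint8).reshape(len(rows), n_cols)
    for _ in range(B):
        idx = rng.integers(0, n_cols, size=n_cols)
        resampled = chars[:, idx]
        rep_rows = [(taxon, resampled[i].tobytes().decode("ascii"))
                    for i, (taxon, _) in enumerate(aln.rows)]
        rep = Alignment(kind=aln.kind, rows=rep_rows)
        rep_splits = nontrivial_splits(nj(distance_matrix(rep, model)))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    for split, node in target.items():
        node.label = f"{100.0 * counts[split] / B:g}"
    return base


def collapse_low_support(tree: dendropy.Tree, threshold: float
                         ) -> dendropy.Tree:
    """Contract internal edges with support strictly below ``threshold``.

    An edge with support exactly equal to the threshold is retained.
    Returns a modified clone; taxa are never removed.
    """
    out = tree.clone(depth=1)
    doomed = []
    for node in out.preorder_internal_node_iter():
        if node is out.seed_node:
            continue
        support = get_support(node)
        if support is not None and support < threshold:
            doomed.append(node)
    for node in doomed:
        parent = node.parent_node
        for child in list(node.child_nodes()):
            node.remove_child(child)
            parent.add_child(child)
        parent.remove_child(node)
    return out


# ---------------------------------------------------------------------------
# Discordance report


@dataclass
class DiscordanceReport:
    """Cross-matrix topology comparison.

    ``rf`` is the symmetric Robinson–Foulds matrix over the input trees;
    ``clade_table`` has one row per named clade with, per matrix, whether
    the clade is monophyletic and the support of its defining edge;
    ``best_matrix`` flags the matrix with the highest support per clade.
    """

    rf: pd.DataFrame
    clade_table: pd.DataFrame
    best_matrix: dict[str, str | None] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# Robinson-Foulds distances\n")
            self.rf.to_csv(fh, sep="\t")
            fh.write("\n# Clade support by matrix\n")
            self.clade_table.to_csv(fh, sep="\t")


def clade_support_table(trees: Mapping[str, dendropy.Tree],
                        clades: Mapping[str, Iterable[str]]
                        ) -> DiscordanceReport:
    """Per-clade presence/support across matrices, plus RF distances."""
    names = list(trees)
    rf = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            val = rf_distance(trees[a], trees[b])
            rf.loc[a, b] = rf.loc[b, a] = val
    records = {}
    best: dict[str, str | None] = {}
    for clade, tips in clades.items():
        tips = frozenset(tips)
        row = {}
        best_support, best_name = -1.0, None
        for name in names:
            tree = trees[name]
            taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
            present = is_monophyletic(tree, tips)
            support = None
            if present:
                pivot = min(taxa)
                side = taxa - tips if pivot in tips else tips
                node = _split_map(tree, include_trivial=True).get(side)
                if node is not None:
                    support = get_support(node)
                if support is not None and support > best_support:
                    best_support, best_name = support, name
            row[(name, "present")] = present
            row[(name, "support")] = support
        records[clade] = row
        best[clade] = best_name
    table = pd.DataFrame.from_dict(records, orient="index")
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    return DiscordanceReport(rf=rf, clade_table=table, best_matrix=best)


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree (from a path or a literal string)."""
    text = str(source)
    try:
        p = Path(text)
        if p.exists():
            text = p.read_text()
    except OSError:
        pass
    return dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True)


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Write Newick with supports as internal node labels."""
    s = tree.as_string(schema="newick", suppress_rooting=True).strip()
    if path is not None:
        Path(path).write_text(s + "\n")
    return s
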