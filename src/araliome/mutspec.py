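"""Reference-anchored directional substitution spectra.

Each query genome's protein-coding sites are compared column-by-column with
a designated reference (an outgroup standing in for the ancestral state).
Substitutions are recorded as directed reference->query changes and pooled
into six complement-collapsed classes, so the spectrum is invariant to
which strand a gene was read from: a C->T on one strand is a G->A on the
other, and both land in the C–T class.  An excess of the C–T class over
T–C is the signature of AT-biased (C->T transition) mutational pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from ._codons import NUCLEOTIDES, is_transition
from .align import Alignment

#: the six complement-collapsed substitution classes, transitions first
CLASSES = ("T-C", "C-T", "T-G", "G-T", "A-T", "G-C")

#: directed (ref, query) base pair -> collapsed class
COLLAPSE: dict[tuple[str, str], str] = {
    ("T", "C"): "T-C", ("A", "G"): "T-C",
    ("C", "T"): "C-T", ("G", "A"): "C-T",
    ("T", "G"): "T-G", ("A", "C"): "T-G",
    ("G", "T"): "G-T", ("C", "A"): "G-T",
    ("A", "T"): "A-T", ("T", "A"): "A-T",
    ("G", "C"): "G-C", ("C", "G"): "G-C",
}

_BASE_IDX = {b: i for i, b in enumerate(NUCLEOTIDES)}


def classify_substitution(ref_base: str, qry_base: str
                          ) -> tuple[tuple[str, str], str, str]:
    """Classify one substitution observed against the reference.

    Returns the directed pair, the collapsed class, and whether the change
    is a transition or a transversion.  Identical or ambiguous bases are an
    error: the caller filters comparable columns first.
    """
    a, b = ref_base.upper(), qry_base.upper()
    if a not in _BASE_IDX or b not in _BASE_IDX:
        raise ValueError(f"ambiguous base in ({ref_base!r}, {qry_base!r})")
    if a == b:
        raise ValueError("bases are identical; nothing to classify")
    kind = "transition" if is_transition(a, b) else "transversion"
    return (a, b), COLLAPSE[(a, b)], kind


@dataclass
class SubstitutionSpectrum:
    """Per-query substitution counts against the reference.

    ``counts`` holds the six collapsed classes; ``directed`` is the 4x4
    matrix of reference-base -> query-base counts (A,C,G,T order);
    ``sites_compared`` counts columns with unambiguous bases in both rows,
    ``sites_skipped`` the columns excluded for gaps or ambiguity.
    """

    query: str
    reference: str
    counts: dict[str, int]
    directed: np.ndarray
    sites_compared: int
    sites_skipped: int

    @property
    def n_substitutions(self) -> int:
        return sum(self.counts.values())

    @property
    def transitions(self) -> int:
        return self.counts["T-C"] + self.counts["C-T"]

    @property
    def transversions(self) -> int:
        return self.n_substitutions - self.transitions


def count_spectrum(aln: Alignment, reference_id: str) -> SubstitutionSpectrum:
    """Count the substitution spectrum of a pairwise alignment.

    The alignment must contain exactly the reference row and one query row.
    Columns with a gap or ambiguity code in either row are skipped, never
    imputed; multiple hits at a column are necessarily counted once (only
    the end states are observable).
    """
    if len(aln.rows) != 2:
        raise ValueError("count_spectrum expects a pairwise alignment")
    taxa = aln.taxa
    if reference_id not in taxa:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    ref_row = aln.row(reference_id)
    (query_id,) = [t for t in taxa if t != reference_id]
    qry_row = aln.row(query_id)
    directed = np.zeros((4, 4), dtype=int)
    counts = {cls: 0 for cls in CLASSES}
    compared = skipped = 0
    for rb, qb in zip(ref_row.upper(), qry_row.upper()):
        i = _BASE_IDX.get(rb)
        j = _BASE_IDX.get(qb)
        if i is None or j is None:
            skipped += 1
            continue
        compared += 1
        if i != j:
            directed[i, j] += 1
            counts[COLLAPSE[(rb, qb)]] += 1
    return SubstitutionSpectrum(query=query_id, reference=reference_id,
                                counts=counts, directed=directed,
                                sites_compared=compared, sites_skipped=skipped)


def spectra_vs_reference(aln: Alignment, reference_id: str
                         ) -> list[SubstitutionSpectrum]:
    """Spectrum of every non-reference row against the reference."""
    ref_row = aln.row(reference_id)
    out = []
    for taxon, seq in aln.rows:
        if taxon == reference_id:
            continue
        pair = Alignment(kind=aln.kind,
                         rows=[(reference_id, ref_row), (taxon, seq)])
        out.append(count_spectrum(pair, reference_id))
    return out


@dataclass
class SpectrumSummary:
    """Mean ± sd of each substitution class over a group of spectra.

    ``sd`` is None for singleton groups (flagged), mirroring how groups
    represented by a single genome cannot contribute a dispersion estimate.
    """

    group: str
    n: int
    mean: dict[str, float]
    sd: dict[str, float] | None
    singleton: bool = False
    members: list[str] = field(default_factory=list)


def summarize_groups(spectra: Iterable[SubstitutionSpectrum],
                     grouping: Mapping[str, str]) -> list[SpectrumSummary]:
    """Group spectra and report per-class mean ± sample sd.

    Every spectrum's query must be mapped to a group.  Singleton groups get
    mean only, with the singleton flag set.
    """
    by_group: dict[str, list[SubstitutionSpectrum]] = {}
    for s in spectra:
        if s.query not in grouping:
            raise KeyError(f"query {s.query!r} has no group assignment")
        by_group.setdefault(grouping[s.query], []).append(s)
    out = []
    for group, members in by_group.items():
        n = len(members)
        mean = {cls: float(np.mean([m.counts[cls] for m in members]))
                for cls in CLASSES}
        if n >= 2:
            sd = {cls: float(np.std([m.counts[cls] for m in members], ddof=1))
                  for cls in CLASSES}
            singleton = False
        else:
            sd, singleton = None, True
        out.append(SpectrumSummary(group=group, n=n, mean=mean, sd=sd,
                                   singleton=singleton,
                                   members=[m.query for m in members]))
    return out


def spectrum_bias_ratio(s: SubstitutionSpectrum) -> float | None:
    """The headline bias statistic: C–T count over T–C count.

    Values above 1 indicate an excess of C->T (G->A) changes relative to
    the reverse class, the AT-biased mutational-pressure signature.
    Returns None (undefined) when the T–C count is zero.
    """
    denom = s.counts["T-C"]
    if denom == 0:
        return None
    return s.counts["C-T"] / denom


def spectrum_table(spectra: Iterable[SubstitutionSpectrum]):
    """Tab-separated-friendly DataFrame: one row per query, collapsed
    classes plus the 12 directed counts."""
    import pandas as pd

    rows = []
    for s in spectra:
        row = {"query": s.query, "reference": s.reference,
               "sites_compared": s.sites_compared,
               "sites_skipped": s.sites_skipped}
        row.update(s.counts)
        for i, a in enumerate(NUCLEOTIDES):
            for j, b in enumerate(NUCLEOTIDES):
                if i != j:
                    row[f"{a}>{b}"] = int(s.directed[i, j])
        ratio = spectrum_bias_ratio(s)
        row["CT_TC_ratio"] = math.nan if ratio is None else ratio
        rows.append(row)
    return pd.DataFrame(rows).set_index("query")
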