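"""Concatenated data matrices with partition bookkeeping.

From per-gene codon alignments this module builds the analysis matrices:
the concatenated CDS supermatrix, its first+second codon position
extraction, and its translation to protein.  A whole-genome matrix is
supported only by ingesting an externally aligned FASTA (aligning full
plastomes is out of scope here).  Partitions map each gene to an inclusive
``(first_col, last_col)`` column range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from ._codons import translate_codon
from .align import Alignment, codon_backtranslate, progressive_align

MATRIX_KINDS = ("whole", "cds", "pos12", "protein")


@dataclass
class SuperMatrix:
    """A concatenated alignment plus a gene -> column-range partition table.

    Partitions tile ``[0, n_cols)`` without overlap; every taxon is present
    in every partition (gap-filled where a gene is missing).
    """

    alignment: Alignment
    partitions: dict[str, tuple[int, int]]
    matrix_kind: str

    def __post_init__(self) -> None:
        if self.matrix_kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.matrix_kind!r}")
        covered = 0
        prev_end = -1
        for gene, (first, last) in self.partitions.items():
            if first != prev_end + 1:
                raise ValueError(f"partition {gene!r} does not tile: "
                                 f"starts at {first}, expected {prev_end + 1}")
            if last < first:
                raise ValueError(f"partition {gene!r} empty")
            covered += last - first + 1
            prev_end = last
        if self.partitions and covered != self.alignment.n_cols:
            raise ValueError("partitions do not cover the alignment")

    @property
    def taxa(self) -> list[str]:
        return self.alignment.taxa

    @property
    def n_cols(self) -> int:
        return self.alignment.n_cols

    def gene_block(self, gene: str) -> Alignment:
        first, last = self.partitions[gene]
        rows = [(t, s[first:last + 1]) for t, s in self.alignment.rows]
        return Alignment(kind=self.alignment.kind, rows=rows)


def align_gene(cds: Mapping[str, str]) -> Alignment:
    """Protein-guided codon alignment of one gene's CDS set.

    Translations are aligned progressively and back-translated, which keeps
    the codon alignment in frame by construction.
    """
    proteins = {}
    trimmed = {}
    for taxon, seq in cds.items():
        seq = seq.upper()
        seq = seq[: len(seq) - len(seq) % 3]
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        if codons and translate_codon(codons[-1]) == "*":
            codons = codons[:-1]
        trimmed[taxon] = "".join(codons)
        proteins[taxon] = "".join(translate_codon(c) if "N" not in c else "X"
                                  for c in codons)
    protein_aln = progressive_align(proteins, kind="protein")
    return codon_backtranslate(protein_aln, trimmed)


def build_supermatrix(per_gene: Mapping[str, Alignment],
                      taxa: Sequence[str]) -> SuperMatrix:
    """Concatenate per-gene codon alignments over a fixed taxon set.

    Genes are concatenated in mapping order; a taxon missing from a gene
    gets an all-gap block there.
    """
    taxa = list(taxa)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    col = 0
    for gene, aln in per_gene.items():
        if aln.kind != "codon":
            raise ValueError(f"gene {gene!r}: expected a codon alignment")
        present = dict(aln.rows)
        extra = set(present) - set(taxa)
        if extra:
            raise ValueError(f"gene {gene!r} has taxa outside the matrix "
                             f"taxon set: {sorted(extra)}")
        width = aln.n_cols
        for t in taxa:
            parts[t].append(present.get(t, "-" * width))
        partitions[gene] = (col, col + width - 1)
        col += width
    rows = [(t, "".join(parts[t])) for t in taxa]
    return SuperMatrix(alignment=Alignment(kind="codon", rows=rows),
                       partitions=partitions, matrix_kind="cds")


def extract_pos12(sm: SuperMatrix) -> SuperMatrix:
    """Keep first and second codon positions of every partition."""
    if sm.matrix_kind != "cds":
        raise ValueError("pos12 extraction requires a cds matrix")
    keep: list[int] = []
    partitions: dict[str, tuple[int, int]] = {}
    out_col = 0
    for gene, (first, last) in sm.partitions.items():
        n_kept = 0
        for c in range(first, last + 1):
            if (c - first) % 3 != 2:
                keep.append(c)
                n_kept += 1
        partitions[gene] = (out_col, out_col + n_kept - 1)
        out_col += n_kept
    rows = [(t, "".join(s[c] for c in keep)) for t, s in sm.alignment.rows]
    return SuperMatrix(alignment=Alignment(kind="nucleotide", rows=rows),
                       partitions=partitions, matrix_kind="pos12")


def translate_matrix(sm: SuperMatrix) -> SuperMatrix:
    """Translate a cds matrix to protein, partition-wise.

    Whole-codon gaps become ``-``; a gene's final column is dropped when it
    holds only stop codons and gaps (the terminal stop).  An untranslatable
    non-gap triple (e.g. ``A-G``) violates the whole-codon gap invariant
    and is an error.
    """
    if sm.matrix_kind != "cds":
        raise ValueError("translation requires a cds matrix")
    taxa = sm.taxa
    blocks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    out_col = 0
    for gene, (first, last) in sm.partitions.items():
        width = last - first + 1
        cols: list[list[str]] = []
        for t, s in sm.alignment.rows:
            seg = s[first:last + 1]
            aas = []
            for i in range(0, width, 3):
                codon = seg[i:i + 3]
                if codon == "---":
                    aas.append("-")
                elif "-" in codon:
                    raise ValueError(
                        f"{t}:{gene}: partial-gap codon {codon!r} at column "
                        f"{first + i}")
                elif "N" in codon:
                    aas.append("X")
                else:
                    aas.append(translate_codon(codon))
            cols.append(aas)
        n_aa = len(cols[0])
        if n_aa and all(row[-1] in "*-" for row in cols) \
                and any(row[-1] == "*" for row in cols):
            for row in cols:
                del row[-1]
            n_aa -= 1
        for t, row in zip(taxa, cols):
            blocks[t].append("".join(row))
        partitions[gene] = (out_col, out_col + n_aa - 1)
        out_col += n_aa
    rows = [(t, "".join(blocks[t])) for t in taxa]
    return SuperMatrix(alignment=Alignment(kind="protein", rows=rows),
                       partitions=partitions, matrix_kind="protein")


def load_prealigned_fasta(path: str | Path, kind: str = "nucleotide",
                          matrix_kind: str = "whole") -> SuperMatrix:
    """External-aligner hook: ingest a pre-aligned FASTA as a one-partition
    matrix (used for the whole-genome dataset)."""
    rows = list(read_fasta(path).items())
    aln = Alignment(kind=kind, rows=rows)
    return SuperMatrix(alignment=aln,
                       partitions={"all": (0, aln.n_cols - 1)},
                       matrix_kind=matrix_kind)


# ---------------------------------------------------------------------------
# Writers / readers


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_fasta(aln: Alignment | Mapping[str, str], path: str | Path,
                wrap: int = 70) -> None:
    items = aln.rows if isinstance(aln, Alignment) else list(aln.items())
    with open(path, "w") as fh:
        for taxon, seq in items:
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


def write_phylip(aln: Alignment, path: str | Path) -> None:
    """Relaxed PHYLIP: full names, two-space separator."""
    with open(path, "w") as fh:
        fh.write(f" {len(aln.rows)} {aln.n_cols}\n")
        width = max(len(t) for t, _ in aln.rows)
        for taxon, seq in aln.rows:
            fh.write(f"{taxon:<{width}}  {seq}\n")


def write_nexus(sm: SuperMatrix, path: str | Path) -> None:
    """NEXUS with a sets block of per-gene charsets."""
    aln = sm.alignment
    datatype = "protein" if aln.kind == "protein" else "dna"
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin data;\n")
        fh.write(f"  dimensions ntax={len(aln.rows)} nchar={aln.n_cols};\n")
        fh.write(f"  format datatype={datatype} gap=- missing=?;\n  matrix\n")
        width = max(len(t) for t, _ in aln.rows)
        for taxon, seq in aln.rows:
            safe = taxon.replace(" ", "_")
            fh.write(f"    {safe:<{width}}  {seq}\n")
        fh.write("  ;\nend;\n\nbegin sets;\n")
        for gene, (first, last) in sm.partitions.items():
            fh.write(f"  charset {gene} = {first + 1}-{last + 1};\n")
        fh.write("end;\n")
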