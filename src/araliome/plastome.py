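"""Annotated plastome records: GenBank I/O, gene extraction, genome structure.

Plastomes are ~150 kb circular genomes with a quadripartite architecture:
a large and a small single-copy region (LSC, SSC) separated by two
reverse-complement copies of an inverted repeat (IRa, IRb).  This module
ingests annotated records, pulls out coding sequences in-frame, and locates
the quadripartite partition from sequence alone.

Coordinates are 0-based half-open internally; the GenBank boundary converts
to/from the format's 1-based inclusive convention (Biopython does this).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation

from ._codons import COMPLEMENT, translate_codon

#: genes the 78-gene concatenation leaves out (trans-spliced rps12 and the
#: pseudogene-prone ycf15)
DEFAULT_EXCLUDE = frozenset({"rps12", "ycf15"})

# Canonical spellings of plastid gene symbols.  GenBank records are
# inconsistent in case ("RBCL", "Rbcl"); unknown names pass through.
_CANONICAL_GENES = [
    "accD", "atpA", "atpB", "atpE", "atpF", "atpH", "atpI",
    "ccsA", "cemA", "clpP", "infA", "matK",
    "ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG", "ndhH",
    "ndhI", "ndhJ", "ndhK",
    "petA", "petB", "petD", "petG", "petL", "petN",
    "psaA", "psaB", "psaC", "psaI", "psaJ",
    "psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI",
    "psbJ", "psbK", "psbL", "psbM", "psbN", "psbT", "psbZ",
    "rbcL", "rpl14", "rpl16", "rpl2", "rpl20", "rpl22", "rpl23",
    "rpl32", "rpl33", "rpl36",
    "rpoA", "rpoB", "rpoC1", "rpoC2",
    "rps11", "rps12", "rps14", "rps15", "rps16", "rps18", "rps19",
    "rps2", "rps3", "rps4", "rps7", "rps8",
    "ycf1", "ycf2", "ycf3", "ycf4", "ycf15",
    "rrn16", "rrn23", "rrn4.5", "rrn5",
]
_CANONICAL_LOOKUP = {g.lower(): g for g in _CANONICAL_GENES}


@dataclass
class Feature:
    """A typed gene feature with (possibly spliced) genomic intervals.

    ``intervals`` is an ordered list of ``(start, end, strand)`` triples in
    0-based half-open genome coordinates; strand is ``"+"`` or ``"-"``.
    """

    gene: str
    kind: str  # CDS | tRNA | rRNA | misc
    intervals: list[tuple[int, int, str]]
    codon_start: int = 1

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"feature {self.gene!r} has no intervals")
        for start, end, strand in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval on {self.gene!r}")
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r} on {self.gene!r}")
        if self.codon_start not in (1, 2, 3):
            raise ValueError("codon_start must be 1, 2 or 3")

    @property
    def strand(self) -> str:
        return self.intervals[0][2]

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end, _ in self.intervals)

    @property
    def start(self) -> int:
        return min(start for start, _, _ in self.intervals)


@dataclass
class GenomeRecord:
    """An annotated (usually circular) genome sequence."""

    id: str
    taxon: str
    sequence: str
    topology: str = "circular"  # circular | linear
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for feat in self.features:
            for start, end, _ in feat.intervals:
                if not (0 <= start < end <= n):
                    raise CoordinateError(
                        f"{self.id}: feature {feat.gene!r} interval "
                        f"({start}, {end}) outside sequence of length {n}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def splice(self, feature: Feature) -> str:
        """Extract a feature's nucleotide sequence, strand-resolved."""
        parts = [self.sequence[s:e] for s, e, _ in feature.intervals]
        seq = "".join(parts)
        if feature.strand == "-":
            seq = reverse_complement(seq)
        return seq


@dataclass
class QuadripartiteStructure:
    """LSC / SSC / IRa / IRb partition of a circular plastome.

    Intervals are (start, end) in genome coordinates; an interval with
    ``end <= start`` wraps around the origin.  ``found`` is False when no
    inverted repeat of the requested minimum size exists.
    """

    lsc: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    irb: tuple[int, int]
    genome_length: int
    found: bool = True

    def _length(self, iv: tuple[int, int]) -> int:
        start, end = iv
        if end > start:
            return end - start
        return self.genome_length - start + end

    @property
    def ir_length(self) -> int:
        return self._length(self.ira) if self.found else 0

    @property
    def lsc_length(self) -> int:
        return self._length(self.lsc) if self.found else 0

    @property
    def ssc_length(self) -> int:
        return self._length(self.ssc) if self.found else 0

    @classmethod
    def none(cls, genome_length: int) -> "QuadripartiteStructure":
        z = (0, 0)
        return cls(z, z, z, z, genome_length, found=False)


class ParseError(ValueError):
    """Malformed GenBank input."""


class CoordinateError(ValueError):
    """Feature interval outside its sequence."""


class InternalStopWarning(UserWarning):
    """A CDS translation contains an internal stop codon."""


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT.get(b, "N") for b in reversed(seq))


def gc_content(sequence: str) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T); ambiguity codes ignored.

    Raises ``ValueError`` on an empty or all-ambiguous sequence, where the
    fraction is undefined.
    """
    seq = sequence.upper()
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    if gc + at == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return gc / (gc + at)


def normalize_gene_name(raw: str) -> str:
    """Map a raw GenBank gene qualifier to its canonical symbol.

    Case-insensitive lookup against the plastid gene inventory; surrounding
    whitespace is stripped; unknown names pass through unchanged (trimmed).
    """
    name = raw.strip()
    return _CANONICAL_LOOKUP.get(name.lower(), name)


# ---------------------------------------------------------------------------
# GenBank I/O


def _convert_feature(seqfeat: SeqFeature) -> Feature | None:
    kind = seqfeat.type
    if kind not in ("CDS", "tRNA", "rRNA", "misc_feature"):
        return None
    quals = seqfeat.qualifiers
    gene = quals.get("gene", quals.get("locus_tag", [""]))[0]
    if not gene:
        return None
    strand = "-" if seqfeat.location.strand == -1 else "+"
    intervals = sorted(
        (int(part.start), int(part.end), strand)
        for part in seqfeat.location.parts
    )
    codon_start = int(quals.get("codon_start", ["1"])[0])
    return Feature(
        gene=normalize_gene_name(gene),
        kind="misc" if kind == "misc_feature" else kind,
        intervals=intervals,
        codon_start=codon_start,
    )


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Parse a GenBank flat file into :class:`GenomeRecord` objects.

    Captures every gene-bearing CDS/tRNA/rRNA feature with strand, join
    coordinates and codon_start, converted to 0-based half-open intervals.
    """
    records: list[GenomeRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not parsed:
        raise ParseError(f"{path}: no GenBank records found")
    for rec in parsed:
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"{path}: record {rec.id} has no ORIGIN sequence")
        topology = rec.annotations.get("topology", "linear")
        features = []
        for seqfeat in rec.features:
            feat = _convert_feature(seqfeat)
            if feat is not None:
                features.append(feat)
        records.append(
            GenomeRecord(
                id=rec.id,
                taxon=rec.annotations.get("organism", rec.description or rec.id),
                sequence=seq,
                topology=topology,
                features=features,
            )
        )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate record ids")
    return records


def write_genbank(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write records back to GenBank flat-file format (round-trip safe)."""
    seqrecords = []
    for rec in records:
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, name=rec.id.split(".")[0],
                       description=rec.taxon)
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = rec.topology
        sr.annotations["organism"] = rec.taxon
        for feat in rec.features:
            strand = -1 if feat.strand == "-" else 1
            locs = [SimpleLocation(s, e, strand) for s, e, _ in feat.intervals]
            if strand == -1:
                locs = locs[::-1]
            location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
            kind = "misc_feature" if feat.kind == "misc" else feat.kind
            quals = {"gene": [feat.gene]}
            if kind == "CDS":
                quals["codon_start"] = [str(feat.codon_start)]
            sr.features.append(SeqFeature(location, type=kind, qualifiers=quals))
        seqrecords.append(sr)
    SeqIO.write(seqrecords, str(path), "genbank")


# ---------------------------------------------------------------------------
# CDS extraction


def extract_cds(
    record: GenomeRecord,
    exclude: frozenset[str] | set[str] = DEFAULT_EXCLUDE,
) -> dict[str, str]:
    """Extract in-frame CDS nucleotide sequences, one per gene symbol.

    Each CDS is spliced across its intervals, strand-resolved, trimmed at
    ``codon_start`` and at any trailing partial codon, so every returned
    sequence has length divisible by 3.  Genes duplicated in the inverted
    repeat are reported once (first copy by genome position); genes in
    ``exclude`` are omitted silently.  An internal stop codon triggers an
    :class:`InternalStopWarning` but the sequence is still returned.
    """
    out: dict[str, str] = {}
    cds_feats = sorted(
        (f for f in record.features if f.kind == "CDS"),
        key=lambda f: f.start,
    )
    for feat in cds_feats:
        gene = feat.gene
        if gene in exclude or gene in out:
            continue
        seq = record.splice(feat)
        seq = seq[feat.codon_start - 1:]
        seq = seq[: len(seq) - len(seq) % 3]
        if len(seq) < 3:
            continue
        protein = [translate_codon(seq[i:i + 3])
                   for i in range(0, len(seq), 3)
                   if "N" not in seq[i:i + 3]]
        if "*" in protein[:-1]:
            warnings.warn(
                f"{record.id}:{gene}: internal stop codon in translation",
                InternalStopWarning,
                stacklevel=2,
            )
        out[gene] = seq
    return out


# ---------------------------------------------------------------------------
# Quadripartite structure detection


def _maximal_rc_repeats(seq: str, seed: int) -> list[tuple[int, int, int]]:
    """Maximal exact reverse-complement repeats as (posA, posB_rc, length).

    posA indexes the doubled sequence (circular scan); posB_rc indexes the
    reverse complement R of the original; length is the exact match length.
    """
    n = len(seq)
    doubled = seq + seq
    rc = reverse_complement(seq)
    kmers: dict[str, list[int]] = {}
    for p in range(n - seed + 1):
        kmers.setdefault(rc[p:p + seed], []).append(p)
    seen: set[tuple[int, int]] = set()  # (diagonal, start) of processed runs
    runs: list[tuple[int, int, int]] = []
    for i in range(n):
        hits = kmers.get(doubled[i:i + seed])
        if not hits:
            continue
        for p in hits:
            diag = i - p
            # extend left
            a, b = i, p
            while a > 0 and b > 0 and doubled[a - 1] == rc[b - 1]:
                a -= 1
                b -= 1
            if (diag, a) in seen:
                continue
            seen.add((diag, a))
            # extend right
            length = seed
            while (a + length < 2 * n and b + length < n
                   and doubled[a + length] == rc[b + length]):
                length += 1
            runs.append((a, b, length))
    return runs


def detect_quadripartite(
    record: GenomeRecord,
    min_ir: int = 1000,
    max_mismatch_frac: float = 0.01,
) -> QuadripartiteStructure:
    """Locate the LSC/SSC/IR partition of a circular plastome.

    Finds the maximal-length pair of disjoint intervals whose sequences are
    reverse complements (exact seed match, currently without mismatch
    extension beyond ``max_mismatch_frac`` bookkeeping), then assigns the
    two single-copy gaps so that LSC is the longer.  Returns a "no IR"
    result when no repeat of at least ``min_ir`` bp exists — valid for
    non-plastome input.
    """
    seq = record.sequence
    n = len(seq)
    if record.topology != "circular":
        raise ValueError("quadripartite detection requires a circular genome")
    seed = min(21, max(8, min_ir // 4))
    best: tuple[int, int, int] | None = None
    for a, b, length in _maximal_rc_repeats(seq, seed):
        if length < min_ir or length > n // 2:
            continue
        # interval A on the circle
        a_start = a % n
        a_end = (a + length) % n
        # interval B: rc positions [b, b+length) map to genome
        # positions [n-b-length, n-b)
        b_start = (n - b - length) % n
        b_end = (n - b) % n
        if _circular_overlap(a_start, length, b_start, length, n):
            continue
        if best is None or length > best[2]:
            best = (a_start, b_start, length)
    if best is None:
        return QuadripartiteStructure.none(n)
    a_start, b_start, length = best
    ira = (a_start, (a_start + length) % n)
    irb = (b_start, (b_start + length) % n)
    # single-copy gaps: from end of one IR to start of the other
    gap1 = (ira[1], irb[0])
    gap2 = (irb[1], ira[0])
    len1 = (gap1[1] - gap1[0]) % n
    len2 = (gap2[1] - gap2[0]) % n
    if len1 >= len2:
        lsc, ssc = gap1, gap2
    else:
        lsc, ssc = gap2, gap1
    # canonical orientation: IRa is the IR that follows the LSC
    if lsc == gap2:
        ira, irb = irb, ira
    return QuadripartiteStructure(lsc=lsc, ssc=ssc, ira=ira, irb=irb,
                                  genome_length=n)


def _circular_overlap(s1: int, l1: int, s2: int, l2: int, n: int) -> bool:
    """Do circular intervals [s1, s1+l1) and [s2, s2+l2) overlap (mod n)?"""
    for offset in range(2):
        a, b = (s1, l1) if offset == 0 else (s2, l2)
        c, d = (s2, l2) if offset == 0 else (s1, l1)
        rel = (c - a) % n
        if rel < b:
            return True
    return False
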