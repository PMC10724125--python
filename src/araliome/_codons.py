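"""Genetic-code helpers (plastid/bacterial translation table 11).

Table 11 shares sense/stop assignments with the standard code; it differs
only in permitted start codons, which never matter for site counting.
"""

from __future__ import annotations

from Bio.Data import CodonTable

PLASTID_TABLE_ID = 11

_TABLE = CodonTable.unambiguous_dna_by_id[PLASTID_TABLE_ID]

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(a + b + c
           for a in "TCAG" for b in "TCAG" for c in "TCAG"
           if a + b + c not in STOP_CODONS)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

AA_OF: dict[str, str] = dict(_TABLE.forward_table)  # sense codons only

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon, '*' for a stop."""
    codon = codon.upper().replace("U", "T")
    if codon in STOP_CODONS:
        return "*"
    return AA_OF[codon]


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS


def is_transition(a: str, b: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine changes."""
    if a == b:
        raise ValueError("bases are identical")
    return (a in PURINES) == (b in PURINES)
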