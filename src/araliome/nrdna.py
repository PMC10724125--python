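"""45S nuclear ribosomal DNA unit segmentation.

The 45S transcription unit is 18S – ITS1 – 5.8S – ITS2 – 26S.  Segment
boundaries of a query sequence are placed by global pairwise alignment to
an annotated reference and projection of the reference boundaries through
the alignment; no de novo annotation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import DNA_SCORING, alignment_identity, pairwise_align

SEGMENT_ORDER = ("18S", "ITS1", "5.8S", "ITS2", "26S")


@dataclass
class NrdnaUnit:
    """A 45S unit with its five segment intervals (0-based half-open)."""

    id: str
    sequence: str
    segments: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        missing = [s for s in SEGMENT_ORDER if s not in self.segments]
        if missing:
            raise ValueError(f"missing segments: {missing}")
        prev_end = -1
        for name in SEGMENT_ORDER:
            start, end = self.segments[name]
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"segment {name} outside sequence")
            if start < prev_end:
                raise ValueError(f"segment {name} overlaps its predecessor")
            prev_end = end

    def segment_length(self, name: str) -> int:
        start, end = self.segments[name]
        return end - start

    def segment_sequence(self, name: str) -> str:
        start, end = self.segments[name]
        return self.sequence[start:end]


class SegmentationError(ValueError):
    """Query too divergent from the reference to project boundaries."""


def segment_45s(query: str, reference: NrdnaUnit, query_id: str = "query",
                min_identity: float = 0.7) -> NrdnaUnit:
    """Segment a query 45S unit by boundary projection from the reference.

    The query is globally aligned to the reference; each reference segment
    boundary maps to the number of query residues consumed before it.
    Refuses (``SegmentationError``) when alignment identity falls below
    ``min_identity``.
    """
    query = query.upper()
    aln = pairwise_align(reference.sequence, query, DNA_SCORING,
                         kind="nucleotide", ids=("ref", "query"))
    identity = alignment_identity(aln)
    if identity < min_identity:
        raise SegmentationError(
            f"alignment identity {identity:.3f} below floor {min_identity}")
    ref_row = aln.row("ref")
    qry_row = aln.row("query")
    # query position corresponding to each reference boundary coordinate
    boundary_map: dict[int, int] = {0: 0}
    r = q = 0
    for rc, qc in zip(ref_row, qry_row):
        if rc != "-":
            r += 1
        if qc != "-":
            q += 1
        boundary_map[r] = q
    segments = {}
    for name in SEGMENT_ORDER:
        start, end = reference.segments[name]
        segments[name] = (boundary_map[start], boundary_map[end])
    return NrdnaUnit(id=query_id, sequence=query, segments=segments)
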