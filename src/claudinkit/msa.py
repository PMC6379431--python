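"""Alignment-column composition mapped to a reference residue.

Answers questions of the form "what occupies the position corresponding to
Pro134 across the family?": given a FASTA multiple alignment and a
reference sequence, the 1-based ungapped residue number is mapped through
the reference's gaps to its alignment column and the amino-acid
composition of that column is tallied. Residue letters are
case-insensitive; ``-`` and ``.`` both count as gaps and are reported
separately from the amino-acid fractions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .errors import MappingError, ValidationError

_GAPS = {"-", "."}


@dataclass
class AlignmentColumnReport:
    reference_id: str
    reference_residue: int
    column_index: int  # 0-based alignment column
    composition: dict[str, float]  # amino acid → fraction over non-gap symbols
    gap_fraction: float
    n_sequences: int


def _load_alignment(alignment) -> MultipleSeqAlignment:
    if isinstance(alignment, MultipleSeqAlignment):
        return alignment
    if isinstance(alignment, str) and "\n" in alignment:
        return AlignIO.read(StringIO(alignment), "fasta")
    return AlignIO.read(str(Path(alignment)), "fasta")


def column_composition(
    alignment, reference_id: str, reference_residue: int
) -> AlignmentColumnReport:
    """Amino-acid composition at the column holding a reference residue.

    ``alignment`` may be a FASTA path, FASTA text, or a Biopython
    :class:`MultipleSeqAlignment`. ``reference_residue`` is 1-based within
    the ungapped reference sequence, consistent with author numbering.
    """
    aln = _load_alignment(alignment)
    ids = [rec.id for rec in aln]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sequence ids in alignment: {dupes}")
    try:
        ref = next(rec for rec in aln if rec.id == reference_id)
    except StopIteration:
        raise ValidationError(f"reference id {reference_id!r} not in alignment") from None
    if reference_residue < 1:
        raise MappingError("reference_residue is 1-based and must be ≥ 1")
    column = -1
    seen = 0
    for col, symbol in enumerate(str(ref.seq)):
        if symbol not in _GAPS:
            seen += 1
            if seen == reference_residue:
                column = col
                break
    if column < 0:
        raise MappingError(
            f"residue {reference_residue} beyond the ungapped length ({seen}) "
            f"of {reference_id!r}"
        )
    symbols = [str(rec.seq[column]).upper() for rec in aln]
    non_gap = [s for s in symbols if s not in _GAPS]
    counts = Counter(non_gap)
    total = len(non_gap)
    composition = (
        {aa: n / total for aa, n in sorted(counts.items())} if total else {}
    )
    return AlignmentColumnReport(
        reference_id=reference_id,
        reference_residue=reference_residue,
        column_index=column,
        composition=composition,
        gap_fraction=(len(symbols) - total) / len(symbols),
        n_sequences=len(aln),
    )
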