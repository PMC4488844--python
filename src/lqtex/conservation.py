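"""Evolutionary conservation calls from multi-species protein alignments.

A mutated residue is labelled conserved when the alignment column holding
it carries the identical amino acid in every species and no gaps — strict
identity, not similarity-group conservation.  Human residue numbers are
mapped to alignment columns through the human row's ungapped numbering
(human row first by convention, or located by record id).
"""

from __future__ import annotations

import re

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

__all__ = [
    "read_msa",
    "write_msa",
    "is_conserved",
    "residue_to_column",
    "conservation_report",
]

GAP_CHARS = {"-", "."}


def read_msa(path) -> MultipleSeqAlignment:
    """Read an aligned FASTA (one record per species)."""
    return AlignIO.read(str(path), "fasta")


def write_msa(msa: MultipleSeqAlignment, path) -> None:
    AlignIO.write(msa, str(path), "fasta")


def is_conserved(msa: MultipleSeqAlignment, column_index: int) -> bool:
    """True iff all rows carry the identical residue (and no gap) at the column."""
    if len(msa) < 2:
        raise ValueError("alignment needs at least two rows")
    if not 0 <= column_index < msa.get_alignment_length():
        raise IndexError(f"column {column_index} outside alignment length")
    column = {str(rec.seq[column_index]).upper() for rec in msa}
    return len(column) == 1 and not (column & GAP_CHARS)


def residue_to_column(msa: MultipleSeqAlignment, residue_number: int, human_row: int = 0) -> int:
    """Alignment column (0-based) of the human row's 1-based residue number.

    Gap columns in the human row do not advance the residue counter.
    """
    if residue_number < 1:
        raise ValueError("residue numbers are 1-based")
    seq = str(msa[human_row].seq)
    count = 0
    for col, ch in enumerate(seq):
        if ch in GAP_CHARS:
            continue
        count += 1
        if count == residue_number:
            return col
    raise IndexError(
        f"residue {residue_number} beyond human sequence length ({count} residues)"
    )


_PROT_RE = re.compile(r"^p\.([A-Za-z*]+?)(\d+)([A-Za-z*]+)$")


def protein_change_residue(protein_change: str) -> int:
    """1-based residue number from a p.<ref><pos><alt> style string."""
    m = _PROT_RE.match(protein_change)
    if not m:
        raise ValueError(f"cannot parse protein change {protein_change!r}")
    return int(m.group(2))


def conservation_report(
    msa_per_gene: dict[str, MultipleSeqAlignment],
    mutations: list[tuple[str, str]],
) -> dict[tuple[str, str], bool]:
    """Label each (gene, protein_change) mutation conserved / not conserved.

    The protein change's residue number is mapped to its alignment column
    via the gene's human row; mutations in genes without an alignment are
    omitted from the result.
    """
    out: dict[tuple[str, str], bool] = {}
    for gene, pchange in mutations:
        msa = msa_per_gene.get(gene)
        if msa is None:
            continue
        try:
            col = residue_to_column(msa, protein_change_residue(pchange))
        except IndexError as exc:
            raise IndexError(f"{gene} {pchange}: {exc}") from exc
        out[(gene, pchange)] = is_conserved(msa, col)
    return out
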