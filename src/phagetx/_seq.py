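"""Small sequence helpers shared across modules."""

from Bio.Seq import Seq

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (delegates to Biopython)."""
    return str(Seq(seq).reverse_complement())
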