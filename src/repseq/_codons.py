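"""Standard-code codon tables (data from Biopython)."""

from __future__ import annotations

from collections import defaultdict

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, with stop codons mapped to "*"
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> sorted list of synonymous codons
AA_TO_CODONS: dict[str, list[str]] = defaultdict(list)
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    AA_TO_CODONS[_aa].append(_codon)
AA_TO_CODONS = dict(AA_TO_CODONS)

#: the 20 standard residues, alphabetical
AA_ALPHABET: str = "".join(sorted(AA_TO_CODONS))


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string; stops become ``*``.

    Raises ValueError if the length is not a multiple of three.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    try:
        return "".join(CODON_TO_AA[nt[i : i + 3]] for i in range(0, len(nt), 3))
    except KeyError as exc:  # non-ACGT character
        raise ValueError(f"invalid codon in {nt!r}") from exc
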