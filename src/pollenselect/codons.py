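"""Standard nuclear codon table helpers shared across modules.

Degeneracy convention: a codon position is four-fold degenerate if all three
alternative bases preserve the amino acid, zero-fold if none do, and "other"
otherwise (two-/three-fold).  Stop codons are never classified as coding
sites here; callers exclude them.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable as _CT

BASES = "ACGT"

_standard = _CT.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)
)

#: amino acid -> number of synonymous codons (family size), stops excluded
FAMILY_SIZE: dict[str, int] = {}
for _c in SENSE_CODONS:
    FAMILY_SIZE[CODON_TO_AA[_c]] = FAMILY_SIZE.get(CODON_TO_AA[_c], 0) + 1


def translate(cds: str) -> str:
    """Translate an in-frame CDS; unknown codons (ambiguity) become 'X'."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(
        CODON_TO_AA.get(cds[i : i + 3].upper(), "X") for i in range(0, len(cds), 3)
    )


@lru_cache(maxsize=None)
def position_degeneracy(codon: str, position: int) -> str:
    """Degeneracy class of one codon position: zero_fold / four_fold / other.

    Defined for sense codons only; raises for stops or ambiguous codons.
    """
    codon = codon.upper()
    aa = CODON_TO_AA.get(codon)
    if aa is None or aa == "*":
        raise ValueError(f"no degeneracy for codon {codon!r}")
    syn = 0
    for base in BASES:
        if base == codon[position]:
            continue
        alt = codon[:position] + base + codon[position + 1 :]
        if CODON_TO_AA.get(alt) == aa:
            syn += 1
    if syn == 3:
        return "four_fold"
    if syn == 0:
        return "zero_fold"
    return "other"


@lru_cache(maxsize=None)
def synonymous_fraction(codon: str, position: int) -> float:
    """Fraction of the three one-step changes at a position that are
    synonymous (Nei-Gojobori site counting; changes to stop codons count as
    nonsynonymous)."""
    codon = codon.upper()
    aa = CODON_TO_AA[codon]
    syn = 0
    for base in BASES:
        if base == codon[position]:
            continue
        alt = codon[:position] + base + codon[position + 1 :]
        if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
            syn += 1
    return syn / 3.0


def codon_synonymous_sites(codon: str) -> float:
    """Nei-Gojobori synonymous site count of one codon (0..3)."""
    return sum(synonymous_fraction(codon, p) for p in range(3))
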