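"""Heuristic wobble-decoding model for natural tRNA sets.

tRNAs are modeled abstractly as an anticodon (written 5'->3') plus a
chemistry category for position 34, the anticodon base that pairs with the
codon's 3' (wobble) position.  The model implements five heuristic rules
for which codons a tRNA reads:

1. G34 (or queuosine, Q34) pairs wobble C and U: the tRNA reads both NNC
   and NNU, and cannot discriminate between them.
2. A modified U34 (cmnm5U, mcm5U, Um, xm5s2U, ...) pairs wobble A and G:
   the tRNA reads both NNA and NNG.
3. An unmodified C34 pairs only G: the tRNA reads NNG one-to-one.
4. Lysidine (k2C) at position 34 of the CAU anticodon lets Ile-tRNA(CAU)
   read AUA and not AUG; this trick does not generalize to other NNA
   codons.
5. Anticodon positions 35 and 36 pair Watson-Crick only, so no tRNA reads
   across the first two codon positions.

Minimal tRNA sets pick, for each sense codon, the species recognizing the
fewest additional codons; the resulting "effective code" (every codon any
tRNA can read, assuming wobble decoding works as well as cognate decoding)
is what the simulator uses for with-wobbling predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from .codes import NULL, STOP, GeneticCode, normalize_codon

__all__ = [
    "WobbleCategory",
    "TRNASpecies",
    "decoded_codons",
    "minimal_trna_set",
    "effective_code",
    "ambiguous_codons",
    "trna_set_to_tsv",
]

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: Codon wobble letters read by each position-34 category.
_WOBBLE_READS = {
    "G34": ("C", "U"),  # rule 1 (G pairs C Watson-Crick, U by wobble)
    "Q34": ("C", "U"),  # rule 1, queuosine behaves like G34
    "modifiedU34": ("A", "G"),  # rule 2
    "unmodifiedC34": ("G",),  # rule 3
    "k2C34": ("A",),  # rule 4, CAU anticodon only
}

#: Anticodon base at position 34 required by each category.
_P34_BASE = {
    "G34": "G",
    "Q34": "G",
    "modifiedU34": "U",
    "unmodifiedC34": "C",
    "k2C34": "C",
}


class WobbleCategory(str, Enum):
    G34 = "G34"
    Q34 = "Q34"
    MODIFIED_U34 = "modifiedU34"
    UNMODIFIED_C34 = "unmodifiedC34"
    K2C34 = "k2C34"


@dataclass(frozen=True)
class TRNASpecies:
    """An abstract tRNA: anticodon (5'->3'), position-34 category, charge.

    The anticodon pairs the codon antiparallel, so position 34 (the first
    anticodon letter as written) reads the codon's third position, and
    positions 35-36 read codon positions 2 and 1 by Watson-Crick pairing.
    """

    anticodon: str
    category: WobbleCategory
    amino_acid: str
    is_initiator: bool = False

    def __post_init__(self):
        ac = normalize_codon(self.anticodon, 3)
        object.__setattr__(self, "anticodon", ac)
        cat = WobbleCategory(self.category)
        object.__setattr__(self, "category", cat)
        if ac[0] != _P34_BASE[cat.value]:
            raise ValueError(
                f"category {cat.value} requires {_P34_BASE[cat.value]} at "
                f"anticodon position 34, got {ac[0]} (anticodon {ac})"
            )
        if cat is WobbleCategory.K2C34 and ac != "CAU":
            raise ValueError("k2C34 is only defined for the CAU anticodon")


def decoded_codons(trna: TRNASpecies) -> frozenset[str]:
    """The set of codons this species reads under the five wobble rules."""
    ac = trna.anticodon
    stem = _COMPLEMENT[ac[2]] + _COMPLEMENT[ac[1]]  # codon positions 1-2
    return frozenset(stem + w for w in _WOBBLE_READS[trna.category.value])


def _candidate_readers(codon: str, amino_acid: str) -> list[TRNASpecies]:
    """Admissible species for one codon, best (fewest extra codons) first.

    Ties are broken by preferring unmodifiedC34, then G34, then
    modifiedU34; Q34 is never proposed (equivalent to G34 here).
    """
    codon = normalize_codon(codon, 3)
    stem34 = _COMPLEMENT[codon[1]] + _COMPLEMENT[codon[0]]  # anticodon 35-36
    wob = codon[2]
    candidates = []
    if wob == "G":
        candidates.append(TRNASpecies("C" + stem34, WobbleCategory.UNMODIFIED_C34, amino_acid))
        candidates.append(TRNASpecies("U" + stem34, WobbleCategory.MODIFIED_U34, amino_acid))
    elif wob in ("U", "C"):
        candidates.append(TRNASpecies("G" + stem34, WobbleCategory.G34, amino_acid))
    elif wob == "A":
        if codon == "AUA":
            candidates.append(TRNASpecies("CAU", WobbleCategory.K2C34, amino_acid))
        candidates.append(TRNASpecies("U" + stem34, WobbleCategory.MODIFIED_U34, amino_acid))
    return candidates


def minimal_trna_set(code: GeneticCode) -> list[TRNASpecies]:
    """One reader per sense codon, minimizing off-target codon recognition.

    Returns elongator species in canonical codon order, plus one initiator
    (anticodon CAU, unmodified C34) when the code assigns AUG to
    methionine.  Only triplet codes are supported: no wobble model is
    attempted for quadruplet codons.
    """
    if code.codon_length != 3:
        raise ValueError("wobble decoding is modeled for triplet codes only")
    species = []
    for codon in code.sense_codons:
        aa = code.assignment[codon]
        candidates = _candidate_readers(codon, aa)
        if not candidates:
            raise ValueError(f"no admissible tRNA reads sense codon {codon}")
        best = min(candidates, key=lambda t: len(decoded_codons(t) - {codon}))
        species.append(best)
    if "AUG" in code.sense_codons and code.assignment["AUG"] == "M":
        species.append(
            TRNASpecies("CAU", WobbleCategory.UNMODIFIED_C34, "M", is_initiator=True)
        )
    return species


def ambiguous_codons(trnas: list[TRNASpecies]) -> dict[str, tuple[str, ...]]:
    """Codons read by two or more tRNAs charged with different amino acids."""
    readers: dict[str, set[str]] = {}
    for t in trnas:
        for c in decoded_codons(t):
            readers.setdefault(c, set()).add(t.amino_acid)
    return {c: tuple(sorted(aas)) for c, aas in readers.items() if len(aas) > 1}


def effective_code(
    code: GeneticCode, trnas: list[TRNASpecies] | None = None
) -> GeneticCode:
    """The code actually implemented if wobble reads work like cognate reads.

    Every codon read by some tRNA becomes sense; stop codons keep their
    release factors; unread non-stop codons remain null.  Codons read by
    differently charged tRNAs are resolved in favor of the tRNA whose
    designated codon it is (falling back to the first reader in input
    order) and can be inspected via :func:`ambiguous_codons`.
    """
    if trnas is None:
        trnas = minimal_trna_set(code)
    assignment = dict.fromkeys(code.assignment, NULL)
    for stop in code.stop_codons:
        assignment[stop] = STOP
    # wobble-read codons, first reader wins provisionally
    for t in trnas:
        for c in decoded_codons(t):
            if assignment[c] == NULL:
                assignment[c] = t.amino_acid
    # designated codons always keep their own designated amino acid
    for c in code.sense_codons:
        assignment[c] = code.assignment[c]
    return GeneticCode(
        name=f"{code.name}+wobble",
        codon_length=code.codon_length,
        assignment=assignment,
    )


def trna_set_to_tsv(trnas: list[TRNASpecies], path: str | Path | None = None) -> str:
    """Serialize a tRNA set as TSV: anticodon, category, amino_acid, is_initiator."""
    lines = ["anticodon\tcategory\tamino_acid\tis_initiator"]
    for t in trnas:
        lines.append(
            f"{t.anticodon}\t{t.category.value}\t{t.amino_acid}\t{int(t.is_initiator)}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
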