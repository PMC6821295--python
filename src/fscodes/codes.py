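"""Genetic-code data model: codon tables, translation, and point-mutation structure.

A genetic code is a *total* map from every codon of length ``k`` (triplet codes,
or quadruplet codes with ``k=4``) to one of 22 labels: the 20 proteinogenic
amino acids (one-letter), a stop signal (``*``), or *null* (``-``).  Null
codons are codons recognized by no tRNA or release factor; attempting to
translate one stalls the ribosome, which is what makes "fail-safe" codes
fail safely.  Stop and null are kept distinct throughout: a mutation into a
stop codon truncates the protein, a mutation into a null codon yields an
untranslatable message, and only the former exists in natural codes.

Codons are RNA strings over {A, C, G, U}; DNA input (T) is normalized to U.
The canonical codon order used everywhere (iteration, serialization, and
deterministic tie-breaking) is lexicographic over U < C < A < G, the order of
the classic printed codon table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

__all__ = [
    "RNA_ALPHABET",
    "AMINO_ACIDS",
    "STOP",
    "NULL",
    "BUILTIN_CODE_NAMES",
    "MutationClass",
    "NullCodonError",
    "GeneticCode",
    "all_codons",
    "normalize_codon",
    "mutation_neighbors",
    "hamming",
    "classify_mutation",
    "builtin_code",
]

#: Nucleotide alphabet in canonical (printed codon table) order.
RNA_ALPHABET = "UCAG"

#: The 20 proteinogenic amino acids, one-letter, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

STOP = "*"
NULL = "-"

_VALID_LABELS = frozenset(AMINO_ACIDS) | {STOP, NULL}

_CODON_CACHE: dict[int, tuple[str, ...]] = {}


def all_codons(k: int = 3) -> tuple[str, ...]:
    """Return all 4**k codons of length ``k`` in canonical order.

    The order is lexicographic over U < C < A < G, so for ``k=3`` the list
    starts UUU, UUC, UUA, UUG, UCU, ... and ends GGG.  Only triplet (k=3)
    and quadruplet (k=4) codes are supported.
    """
    if k not in (3, 4):
        raise ValueError(f"unsupported codon length {k}; expected 3 or 4")
    if k not in _CODON_CACHE:
        codons = [""]
        for _ in range(k):
            codons = [c + nt for c in codons for nt in RNA_ALPHABET]
        _CODON_CACHE[k] = tuple(codons)
    return _CODON_CACHE[k]


def normalize_codon(codon: str, k: int | None = None) -> str:
    """Uppercase a codon and convert DNA (T) to RNA (U), validating letters."""
    c = codon.strip().upper().replace("T", "U")
    if k is not None and len(c) != k:
        raise ValueError(f"codon {codon!r} has length {len(c)}, expected {k}")
    if len(c) not in (3, 4):
        raise ValueError(f"codon {codon!r} has unsupported length {len(c)}")
    bad = set(c) - set(RNA_ALPHABET)
    if bad:
        raise ValueError(f"codon {codon!r} contains invalid characters {sorted(bad)}")
    return c


def mutation_neighbors(codon: str) -> list[str]:
    """All codons at Hamming distance 1 from ``codon`` (3k of them, each once)."""
    c = normalize_codon(codon)
    out = []
    for i, nt in enumerate(c):
        for alt in RNA_ALPHABET:
            if alt != nt:
                out.append(c[:i] + alt + c[i + 1 :])
    return out


def hamming(c1: str, c2: str) -> int:
    """Hamming distance between two equal-length codons."""
    if len(c1) != len(c2):
        raise ValueError("codons differ in length")
    return sum(a != b for a, b in zip(c1, c2))


class MutationClass(str, Enum):
    """Classification of a single point mutation c1 -> c2 under a code."""

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    TO_NULL = "to_null"
    FROM_NONSENSE = "from_nonsense"


class NullCodonError(ValueError):
    """Raised when translation encounters a null codon.

    Attributes
    ----------
    codon : the offending codon
    position : 0-based codon index within the CDS
    """

    def __init__(self, codon: str, position: int):
        self.codon = codon
        self.position = position
        super().__init__(
            f"null codon {codon} at codon position {position}: message is untranslatable"
        )


def _read_maybe_path(source: str | Path) -> str:
    """Accept either a filesystem path or already-loaded file content."""
    if isinstance(source, Path):
        return source.read_text()
    text = str(source)
    try:
        p = Path(text)
        if p.exists():
            return p.read_text()
    except OSError:
        pass
    return text


@dataclass(frozen=True)
class GeneticCode:
    """A total map from all 4**k codons to amino acid, stop, or null.

    Parameters
    ----------
    name : identifier for the code (e.g. ``"standard"``, ``"red20"``).
    codon_length : 3 for triplet codes, 4 for quadruplet codes.
    assignment : mapping codon -> label covering every codon exactly once.
        Labels are one-letter amino acids, ``"*"`` (stop), or ``"-"`` (null).
    """

    name: str
    codon_length: int
    assignment: Mapping[str, str]
    _sense: tuple[str, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        codons = all_codons(self.codon_length)
        norm = {}
        for codon, label in self.assignment.items():
            c = normalize_codon(codon, self.codon_length)
            if label not in _VALID_LABELS:
                raise ValueError(f"invalid label {label!r} for codon {c}")
            if c in norm:
                raise ValueError(f"duplicate assignment for codon {c}")
            norm[c] = label
        missing = set(codons) - set(norm)
        if missing:
            raise ValueError(
                f"assignment is not total: {len(missing)} codons unassigned "
                f"(e.g. {sorted(missing)[:3]})"
            )
        if len(norm) != len(codons):
            raise ValueError("assignment contains codons of the wrong length")
        object.__setattr__(self, "assignment", dict((c, norm[c]) for c in codons))
        object.__setattr__(
            self,
            "_sense",
            tuple(c for c in codons if norm[c] not in (STOP, NULL)),
        )

    # -- basic queries ---------------------------------------------------

    def label(self, codon: str) -> str:
        return self.assignment[normalize_codon(codon, self.codon_length)]

    def is_sense(self, codon: str) -> bool:
        return self.label(codon) not in (STOP, NULL)

    def is_stop(self, codon: str) -> bool:
        return self.label(codon) == STOP

    def is_null(self, codon: str) -> bool:
        return self.label(codon) == NULL

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """Sense codons in canonical order."""
        return self._sense

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c, a in self.assignment.items() if a == STOP)

    @property
    def null_codons(self) -> tuple[str, ...]:
        return tuple(c for c, a in self.assignment.items() if a == NULL)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        """Encoded amino acids, alphabetical."""
        return tuple(sorted({a for a in self.assignment.values() if a not in (STOP, NULL)}))

    def codons_for(self, amino_acid: str) -> tuple[str, ...]:
        """All codons encoding ``amino_acid`` (the synonym block), canonical order."""
        return tuple(c for c, a in self.assignment.items() if a == amino_acid)

    def counts(self) -> tuple[int, int, int]:
        """(sense, stop, null) codon counts; they sum to 4**k."""
        labels = list(self.assignment.values())
        n_stop = labels.count(STOP)
        n_null = labels.count(NULL)
        return len(labels) - n_stop - n_null, n_stop, n_null

    # -- translation -----------------------------------------------------

    def translate(self, cds: str) -> str:
        """Translate a CDS, stopping at the first stop codon.

        Raises :class:`NullCodonError` if a null codon is reached before a
        stop, and ``ValueError`` if the length is not a multiple of the
        codon length.  Translation of the empty sequence is the empty
        protein.
        """
        k = self.codon_length
        seq = cds.strip().upper().replace("T", "U")
        if len(seq) % k:
            raise ValueError(
                f"CDS length {len(seq)} is not a multiple of codon length {k}"
            )
        protein = []
        for i in range(0, len(seq), k):
            codon = normalize_codon(seq[i : i + k], k)
            label = self.assignment[codon]
            if label == STOP:
                break
            if label == NULL:
                raise NullCodonError(codon, i // k)
            protein.append(label)
        return "".join(protein)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "codon_length": self.codon_length,
            "assignments": dict(self.assignment),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneticCode":
        return cls(
            name=d["name"],
            codon_length=int(d["codon_length"]),
            assignment=d["assignments"],
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GeneticCode":
        return cls.from_dict(json.loads(_read_maybe_path(source)))

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["codon\tlabel"]
        lines += [f"{c}\t{a}" for c, a in self.assignment.items()]
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_tsv(cls, source: str | Path, name: str = "custom") -> "GeneticCode":
        text = _read_maybe_path(source)
        assignment = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.lower().startswith("codon"):
                continue
            codon, label = line.split("\t")
            assignment[codon] = label
        k = len(next(iter(assignment)))
        return cls(name=name, codon_length=k, assignment=assignment)

    # -- construction helpers -------------------------------------------

    @classmethod
    def from_partial(
        cls,
        assignments: Mapping[str, str],
        name: str = "custom",
        codon_length: int = 3,
    ) -> "GeneticCode":
        """Build a code from a partial map, filling unassigned codons with null."""
        partial = {normalize_codon(c, codon_length): a for c, a in assignments.items()}
        if len(partial) != len(assignments):
            raise ValueError("conflicting assignments for the same codon")
        full = {c: partial.get(c, NULL) for c in all_codons(codon_length)}
        return cls(name=name, codon_length=codon_length, assignment=full)


def classify_mutation(code: GeneticCode, c1: str, c2: str) -> MutationClass:
    """Classify the point mutation ``c1 -> c2`` under ``code``.

    ``c1`` must be a sense or stop codon and the two codons must be at
    Hamming distance exactly 1.
    """
    a = normalize_codon(c1, code.codon_length)
    b = normalize_codon(c2, code.codon_length)
    if hamming(a, b) != 1:
        raise ValueError(f"{a} and {b} are not at Hamming distance 1")
    la, lb = code.assignment[a], code.assignment[b]
    if la == NULL:
        raise ValueError(f"mutation origin {a} is a null codon")
    if la == STOP:
        return MutationClass.FROM_NONSENSE
    if lb == NULL:
        return MutationClass.TO_NULL
    if lb == STOP:
        return MutationClass.NONSENSE
    return MutationClass.SYNONYMOUS if la == lb else MutationClass.MISSENSE


# ---------------------------------------------------------------------------
# built-in codes
# ---------------------------------------------------------------------------

#: Names accepted by :func:`builtin_code`.
BUILTIN_CODE_NAMES = (
    "standard",
    "colorado",
    "fs20",
    "red20",
    "fs16",
    "red15",
    "fsquad",
)

_BUILTIN_CACHE: dict[str, GeneticCode] = {}


def _standard_code() -> GeneticCode:
    # NCBI translation table 1, via Biopython, with T -> U.
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_rna_by_id[1]
    assignment = {c: a for c, a in table.forward_table.items() if len(c) == 3}
    for stop in table.stop_codons:
        assignment[stop] = STOP
    return GeneticCode(name="standard", codon_length=3, assignment=assignment)


def builtin_code(name: str) -> GeneticCode:
    """Return one of the built-in code tables.

    ``standard`` is the canonical NCBI translation table 1 (RNA form).  The
    fail-safe families (``fs20``, ``red20``, ``fs16``, ``red15``, ``fsquad``)
    and the hyperevolvable ``colorado`` code are representative family
    members produced by the design optimizer (:mod:`fscodes.design`) under
    each family's defining constraints, shipped as JSON tables; see
    ``scripts/generate_builtin_tables.py`` for the exact regeneration recipe.
    """
    key = name.strip().lower()
    if key not in BUILTIN_CODE_NAMES:
        raise ValueError(
            f"unknown code {name!r}; expected one of {', '.join(BUILTIN_CODE_NAMES)}"
        )
    if key not in _BUILTIN_CACHE:
        if key == "standard":
            _BUILTIN_CACHE[key] = _standard_code()
        else:
            from importlib.resources import files

            data = files("fscodes.data").joinpath(f"{key}.json").read_text()
            _BUILTIN_CACHE[key] = GeneticCode.from_json(data)
    return _BUILTIN_CACHE[key]
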