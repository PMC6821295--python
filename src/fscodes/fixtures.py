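"""Deterministic synthetic fixtures: toy codes, proteins, CDS, strain states.

Everything the test suite and examples need is generated in code from a
seed — no downloads, no committed data beyond the built-in code tables.
The sfGFP sequence used in recoding examples is a synthetic stand-in: a
reproducible random 239-residue protein, not the real superfolder GFP.
"""

from __future__ import annotations

import numpy as np

from .codes import AMINO_ACIDS, GeneticCode
from .evosim import PopulationState

__all__ = [
    "toy_code",
    "toy_protein",
    "toy_cds",
    "strain_state",
    "synthetic_sfgfp_like_protein",
]


def toy_code(
    assignments: dict[str, str], name: str = "toy", codon_length: int = 3
) -> GeneticCode:
    """A code from an explicit partial map; unassigned codons become null."""
    return GeneticCode.from_partial(assignments, name=name, codon_length=codon_length)


def toy_protein(
    length: int, aa_subset: str | tuple[str, ...] = AMINO_ACIDS, rng=None
) -> str:
    """Uniform random protein over ``aa_subset`` (e.g. a RED15 residue set)."""
    subset = list(aa_subset)
    if not subset:
        raise ValueError("aa_subset must be non-empty")
    if length == 0:
        return ""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return "".join(rng.choice(subset, size=length))


def toy_cds(
    n_codons: int, code: GeneticCode, rng=None, with_stop: bool = True
) -> str:
    """A random CDS of sense codons of ``code`` (optionally stop-terminated)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sense = code.sense_codons
    parts = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
    if with_stop and code.stop_codons:
        parts.append(code.stop_codons[0])
    return "".join(parts)


def strain_state(
    sizes: list[float], fitnesses: list[float], stochastic: list[bool] | None = None
) -> PopulationState:
    """A small hand-specified strain census for simulator unit tests."""
    n = np.asarray(sizes, dtype=float)
    f = np.asarray(fitnesses, dtype=float)
    if stochastic is None:
        stoch = np.zeros(len(n), dtype=bool)
    else:
        stoch = np.asarray(stochastic, dtype=bool)
    if not (len(n) == len(f) == len(stoch)):
        raise ValueError("sizes, fitnesses, stochastic must have equal length")
    return PopulationState(
        n=n, f=f, stochastic=stoch, side=np.zeros(len(n), dtype=np.int8)
    )


def synthetic_sfgfp_like_protein(rng=1868) -> str:
    """A 239-residue random protein standing in for a fluorescent-protein ORF.

    Synthetic: generated from a fixed seed with the residue composition of
    a typical globular protein (uniform over the 20 amino acids, leading
    methionine).  Used where examples need a realistic-length ORF.
    """
    return "M" + toy_protein(238, AMINO_ACIDS, rng=rng)
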