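"""Code-level mutation statistics.

All statistics enumerate the single point mutations that *originate at sense
codons*: a code with ``n`` sense codons of length ``k`` has exactly
``n * 3k`` such mutations, and every one of them is synonymous, missense,
nonsense (into a stop codon), or null-directed (into a null codon).  Stop
and null codons contribute no origin mutations.  With this denominator the
Standard Code's synonymous-mutation frequency f_s comes out at 0.24 and a
uniformly random code's at ~0.04.

phi is the missense fraction of a code normalized by the missense fraction
of the Standard Code; it scales the beneficial mutation supply in the
evolutionary simulator, because only missense mutations can change a
protein without truncating it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codes import (
    AMINO_ACIDS,
    NULL,
    STOP,
    GeneticCode,
    all_codons,
    mutation_neighbors,
)

__all__ = [
    "KYTE_DOOLITTLE",
    "MutationCounts",
    "CodeMetrics",
    "mutation_counts",
    "synonymous_fraction",
    "mean_delta_kd",
    "null_mutation_fraction",
    "missense_fraction",
    "phi",
    "random_code",
    "ensemble_metrics",
    "code_metrics",
]

#: Kyte-Doolittle hydropathy scale (Kyte & Doolittle 1982).  Isoleucine is
#: the most hydrophobic (4.5) and arginine the most hydrophilic (-4.5).
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class MutationCounts:
    """Raw counts of point mutations from sense codons, by class."""

    synonymous: int
    missense: int
    nonsense: int
    to_null: int

    @property
    def total(self) -> int:
        return self.synonymous + self.missense + self.nonsense + self.to_null


@dataclass(frozen=True)
class CodeMetrics:
    """Summary statistics for one genetic code."""

    f_s: float
    mean_delta_kd: float | None
    null_fraction: float
    phi: float | None = None


def mutation_counts(code: GeneticCode) -> MutationCounts:
    """Exhaustively classify all sense-origin point mutations of ``code``."""
    syn = mis = non = null = 0
    assignment = code.assignment
    for c1 in code.sense_codons:
        a1 = assignment[c1]
        for c2 in mutation_neighbors(c1):
            a2 = assignment[c2]
            if a2 == NULL:
                null += 1
            elif a2 == STOP:
                non += 1
            elif a2 == a1:
                syn += 1
            else:
                mis += 1
    return MutationCounts(syn, mis, non, null)


def synonymous_fraction(code: GeneticCode) -> float:
    """Fraction of sense-origin point mutations conserving the amino acid."""
    counts = mutation_counts(code)
    if counts.total == 0:
        raise ValueError(f"code {code.name!r} has no sense codons")
    return counts.synonymous / counts.total


def null_mutation_fraction(code: GeneticCode) -> float:
    """Fraction of sense-origin point mutations landing on null codons."""
    counts = mutation_counts(code)
    if counts.total == 0:
        raise ValueError(f"code {code.name!r} has no sense codons")
    return counts.to_null / counts.total


def missense_fraction(code: GeneticCode, truncating_denominator: bool = False) -> float:
    """Missense mutations as a fraction of sense-origin mutations.

    With ``truncating_denominator=True`` the denominator is restricted to
    missense plus truncating (nonsense or null-directed) mutations, i.e.
    synonymous mutations are not counted as opportunities.  Both readings
    give zero for ideal fail-safe codes; the default (all sense-origin
    mutations) is the one calibrated against the Standard Code's printed
    synonymous frequency.
    """
    counts = mutation_counts(code)
    if truncating_denominator:
        den = counts.missense + counts.nonsense + counts.to_null
    else:
        den = counts.total
    if den == 0:
        raise ValueError(f"code {code.name!r} has no qualifying mutations")
    return counts.missense / den


def phi(
    code: GeneticCode,
    reference: GeneticCode | None = None,
    truncating_denominator: bool = False,
) -> float:
    """Missense fraction of ``code`` normalized by that of ``reference``.

    The reference defaults to the Standard Code, for which phi is exactly 1.
    Ideal fail-safe codes have phi = 0.
    """
    if reference is None:
        from .codes import builtin_code

        reference = builtin_code("standard")
    ref = missense_fraction(reference, truncating_denominator)
    if ref == 0:
        raise ValueError("reference code has zero missense fraction")
    return missense_fraction(code, truncating_denominator) / ref


def mean_delta_kd(
    code: GeneticCode, scale: dict[str, float] | None = None
) -> float:
    """Mean |KD(a2) - KD(a1)| over all missense point mutations.

    The average is taken per mutation event (each ordered distance-1
    sense->sense pair with differing amino acids counts once).  Raises
    ``ValueError`` for codes with no missense mutations (ideal fail-safe
    codes), for which the quantity is undefined rather than zero.
    """
    kd = KYTE_DOOLITTLE if scale is None else scale
    assignment = code.assignment
    total = 0.0
    n = 0
    for c1 in code.sense_codons:
        a1 = assignment[c1]
        for c2 in mutation_neighbors(c1):
            a2 = assignment[c2]
            if a2 not in (STOP, NULL) and a2 != a1:
                total += abs(kd[a2] - kd[a1])
                n += 1
    if n == 0:
        raise ValueError(f"code {code.name!r} has no missense mutations")
    return total / n


def code_metrics(code: GeneticCode, reference: GeneticCode | None = None) -> CodeMetrics:
    """Convenience bundle of f_s, <dKD>, null fraction, and phi."""
    counts = mutation_counts(code)
    if counts.total == 0:
        raise ValueError(f"code {code.name!r} has no sense codons")
    try:
        dkd = mean_delta_kd(code)
    except ValueError:
        dkd = None
    try:
        ph = phi(code, reference)
    except ValueError:
        ph = None
    return CodeMetrics(
        f_s=counts.synonymous / counts.total,
        mean_delta_kd=dkd,
        null_fraction=counts.to_null / counts.total,
        phi=ph,
    )


def random_code(
    rng: np.random.Generator, k: int = 3, name: str = "random"
) -> GeneticCode:
    """Draw a random genetic code with no null codons.

    Every codon is independently assigned a uniform label among the 20
    amino acids and stop; draws in which any of the 21 labels is absent are
    rejected and regenerated, so every returned code encodes all 20 amino
    acids and at least one stop.  (Without the filter roughly one draw in
    three misses some label at k=3; the filter also nudges the ensemble
    mean f_s down from 1/21 to ~0.043.)
    """
    labels = np.array(list(AMINO_ACIDS + STOP))
    codons = all_codons(k)
    while True:
        draw = rng.integers(0, len(labels), size=len(codons))
        if len(np.unique(draw)) == len(labels):
            assignment = dict(zip(codons, labels[draw]))
            return GeneticCode(name=name, codon_length=k, assignment=assignment)


def ensemble_metrics(
    n: int, rng: np.random.Generator, k: int = 3
) -> "pandas.DataFrame":  # noqa: F821
    """Per-code f_s and <dKD> for ``n`` random codes, as a DataFrame.

    The returned frame has columns ``code_id``, ``fs``, ``mean_dkd`` and a
    ``.attrs`` entry with the ensemble means, matching the random-code
    ensembles used to situate designed codes.
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    codons = all_codons(k)
    index = {c: i for i, c in enumerate(codons)}
    nbr = np.array(
        [[index[t] for t in mutation_neighbors(c)] for c in codons]
    )  # (4^k, 3k)
    n_labels = len(AMINO_ACIDS) + 1  # stop is label index 20
    stop_idx = n_labels - 1
    kd = np.array([KYTE_DOOLITTLE[a] for a in AMINO_ACIDS] + [np.nan])

    fs_out = np.empty(n)
    dkd_out = np.empty(n)
    done = 0
    chunk = 2048
    while done < n:
        # same stream as repeated random_code() calls: one 4^k-long uniform
        # draw per attempted code, rejecting draws missing any label
        draws = rng.integers(0, n_labels, size=(chunk, len(codons)))
        counts = np.zeros((chunk, n_labels), dtype=np.int64)
        np.add.at(counts, (np.arange(chunk)[:, None], draws), 1)
        ok = (counts > 0).all(axis=1)
        labels = draws[ok][: n - done]
        if labels.size == 0:
            continue
        origin = labels[:, :, None]  # (m, 4^k, 1)
        target = labels[:, nbr]  # (m, 4^k, 3k)
        sense = origin != stop_idx
        syn = (sense & (target == origin)).sum(axis=(1, 2))
        den = sense[:, :, 0].sum(axis=1) * nbr.shape[1]
        mis = sense & (target != stop_idx) & (target != origin)
        dkd_pair = np.abs(kd[target] - kd[origin])
        dkd_sum = np.where(mis, dkd_pair, 0.0).sum(axis=(1, 2))
        m = labels.shape[0]
        fs_out[done : done + m] = syn / den
        with np.errstate(invalid="ignore"):
            dkd_out[done : done + m] = dkd_sum / mis.sum(axis=(1, 2))
        done += m

    df = pd.DataFrame(
        {"code_id": np.arange(n), "fs": fs_out, "mean_dkd": dkd_out}
    )
    df.attrs["mean_fs"] = float(df["fs"].mean())
    df.attrs["mean_dkd"] = float(np.nanmean(df["mean_dkd"]))
    return df
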