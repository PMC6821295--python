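"""Construction of fail-safe (and hyperevolvable) genetic codes.

A fail-safe code surrounds its sense codons with null codons so that point
mutations destroy translation instead of substituting amino acids.  Design
reduces to combinatorics on the Hamming graph of codons: a code has *no
missense and no synonymous* mutations exactly when its sense codons are
pairwise at Hamming distance >= 2, i.e. they form an independent set in
the distance-1 graph.  We call such codes *ideal*: every point mutation in
a coding sequence truncates the protein (null codon) or terminates it
(stop codon), so phi = 0 and ORF evolution by point mutation arrests.

Coding-theory limits shape the families:

* For triplet codes the largest set of pairwise-distance->=2 codons has
  exactly 16 members (one codon per "line" of the 4x4x4 Hamming cube in
  each direction), so ideal triplet codes encode at most 16 amino acids
  (FS16 with synthetic machinery, RED15 with natural E. coli machinery and
  its three natural stops).  With 20 amino acids (FS20/RED20) some sense-
  sense adjacency is unavoidable and the optimizer instead maximizes the
  fraction of point mutations landing on null codons.
* Quadruplet codes have 256 codons and distance-2 sets of up to 64, so
  ideal codes with 20+ amino acids (FSQUAD) exist with room to spare; here
  even the stop codon can sit at distance >= 2 from every sense codon.

"Natural machinery" (RED) codes reuse E. coli tRNAs, so each sense codon
must keep its Standard Code amino acid (the natural tRNA reading a codon
is charged with that amino acid), stops are the natural UAA/UAG/UGA, and
the designated readers chosen by :mod:`fscodes.wobble` must not read any
other sense codon ambiguously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .codes import (
    AMINO_ACIDS,
    NULL,
    STOP,
    GeneticCode,
    all_codons,
    builtin_code,
    hamming,
    mutation_neighbors,
)

__all__ = [
    "DesignConstraints",
    "is_ideal",
    "null_adjacent_fraction",
    "optimize_code",
    "design_hyperevolvable",
    "family_size",
    "falling_factorial",
    "max_ideal_sense_count",
]

_NATURAL_STOPS = ("UAA", "UAG", "UGA")


@dataclass(frozen=True)
class DesignConstraints:
    """Constraints for the code optimizer.

    ``amino_acids`` selects which residues to encode (defaults to the
    first ``n_amino_acids`` in a documented priority order).  With
    ``natural_machinery_only`` each amino acid's codon is drawn from its
    Standard Code synonym block and the stops are UAA/UAG/UGA.
    ``require_ideal`` demands a code with no missense and no synonymous
    mutations.
    """

    n_amino_acids: int
    n_stops: int = 1
    codon_length: int = 3
    natural_machinery_only: bool = False
    require_ideal: bool = False
    amino_acids: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_amino_acids + self.n_stops > 4**self.codon_length:
            raise ValueError("more labels than codons")
        if self.amino_acids is not None:
            aas = tuple(self.amino_acids)
            if len(aas) != self.n_amino_acids or not set(aas) <= set(AMINO_ACIDS):
                raise ValueError("amino_acids must list n_amino_acids valid residues")


#: Order in which amino acids are dropped when fewer than 20 are encoded:
#: cysteine first (rare, special disulfide chemistry), then one member of
#: each chemically redundant group — aspartate (glutamate keeps the negative
#: charge), isoleucine (leucine/valine cover branched hydrophobics), and the
#: two amides (histidine is retained as the polar aromatic).  This order was
#: also chosen so that the 15-residue subset admits an ideal natural-
#: machinery code (only six 5-residue omissions do).
REDUCTION_ORDER = "CDINQ"


def default_amino_acid_subset(n: int) -> tuple[str, ...]:
    """The ``n`` amino acids retained by the default reduction order."""
    if not 1 <= n <= 20:
        raise ValueError("n must be in 1..20")
    dropped = set(REDUCTION_ORDER[: 20 - n]) if n >= 15 else None
    if dropped is None:
        # below 15 residues drop alphabetically after the named five
        extra = [a for a in AMINO_ACIDS if a not in set(REDUCTION_ORDER)]
        dropped = set(REDUCTION_ORDER) | set(extra[: 15 - n])
    return tuple(a for a in AMINO_ACIDS if a not in dropped)


def is_ideal(code: GeneticCode, strict: bool = False) -> bool:
    """True if every point mutation from a sense codon truncates.

    By default a mutation into a stop codon counts as truncating, so
    *ideal* means "no missense and no synonymous mutations" (phi = 0 and
    f_s = 0); this is the sense in which 16-amino-acid triplet codes can
    be ideal at all, since any 17th codon (the stop) necessarily sits at
    distance 1 from some sense codon.  With ``strict=True`` every
    distance-1 neighbor of every sense codon must be null, which is
    attainable for quadruplet codes.
    """
    assignment = code.assignment
    for c1 in code.sense_codons:
        for c2 in mutation_neighbors(c1):
            label = assignment[c2]
            if label == NULL:
                continue
            if label == STOP and not strict:
                continue
            return False
    return True


def null_adjacent_fraction(code: GeneticCode) -> float:
    """Fraction of sense-origin point mutations landing on null codons."""
    from .metrics import null_mutation_fraction

    return null_mutation_fraction(code)


def max_ideal_sense_count(k: int) -> int:
    """Largest number of pairwise-distance->=2 codons for codon length k.

    One codon per line of the Hamming cube in each direction: 4**(k-1).
    """
    if k not in (3, 4):
        raise ValueError("unsupported codon length")
    return 4 ** (k - 1)


def falling_factorial(n: int, k: int) -> int:
    """P(n, k) = n! / (n-k)! — ordered selections of k items from n."""
    return math.perm(n, k)


def family_size(family: str) -> int:
    """Exact size of the FS20 / FS16 code families.

    FS20 assigns 20 amino acids plus one stop to distinct codons:
    P(64, 21).  FS16 additionally chooses which 16 of the 20 amino acids
    to encode, in codon order: P(64, 17) * P(20, 16).  RED-family counts
    depend on wobble-realizability constraints and are not enumerated
    here.
    """
    fam = family.strip().lower()
    if fam == "fs20":
        return falling_factorial(64, 21)
    if fam == "fs16":
        return falling_factorial(64, 17) * falling_factorial(20, 16)
    raise ValueError(f"unsupported family {family!r} (expected fs20 or fs16)")


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------


def _neighbor_index(k: int) -> tuple[dict[str, int], list[list[int]]]:
    codons = all_codons(k)
    index = {c: i for i, c in enumerate(codons)}
    nbrs = [[index[t] for t in mutation_neighbors(c)] for c in codons]
    return index, nbrs


def _cost(sense: set[int], stops: set[int], nbrs: list[list[int]]) -> tuple[int, int]:
    """(non-null hits, missense hits) over ordered sense-origin mutations."""
    non_null = missense = 0
    for c in sense:
        for t in nbrs[c]:
            if t in sense:
                non_null += 1
                missense += 1
            elif t in stops:
                non_null += 1
    return non_null, missense


def _anneal_subset(
    rng: np.random.Generator,
    k: int,
    n_sense: int,
    n_stops: int,
    iterations: int,
) -> tuple[list[int], list[int], tuple[int, int]]:
    """Simulated annealing over free codon subsets (synthetic machinery).

    State: a set of n_sense + n_stops distinct codons with a designated
    stop subset; move: swap one chosen codon for an unchosen one (or swap
    the stop role within the chosen set).  Cost is lexicographic
    (non-null hits, missense hits), minimized.
    """
    n_codons = 4**k
    _, nbrs = _neighbor_index(k)
    chosen = list(rng.choice(n_codons, size=n_sense + n_stops, replace=False))
    stops = set(chosen[n_sense:])
    sense = set(chosen[:n_sense])

    def scalar(cost):
        return cost[0] * (n_codons + 1) + cost[1]

    cost = _cost(sense, stops, nbrs)
    best = (sorted(sense), sorted(stops), cost)
    t0, t1 = 3.0, 0.01
    for i in range(iterations):
        temp = t0 * (t1 / t0) ** (i / max(iterations - 1, 1))
        if rng.random() < 0.1 and n_stops:
            # swap the stop role between a stop and a sense codon
            s = int(rng.choice(sorted(stops)))
            c = int(rng.choice(sorted(sense)))
            new_sense = (sense - {c}) | {s}
            new_stops = (stops - {s}) | {c}
        else:
            out = int(rng.choice(sorted(sense | stops)))
            pool = [c for c in range(n_codons) if c not in sense and c not in stops]
            inn = int(rng.choice(pool))
            if out in sense:
                new_sense, new_stops = (sense - {out}) | {inn}, stops
            else:
                new_sense, new_stops = sense, (stops - {out}) | {inn}
        new_cost = _cost(new_sense, new_stops, nbrs)
        delta = scalar(new_cost) - scalar(cost)
        if delta <= 0 or rng.random() < math.exp(-delta / max(temp, 1e-9)):
            sense, stops, cost = new_sense, new_stops, new_cost
            if scalar(cost) < scalar(best[2]):
                best = (sorted(sense), sorted(stops), cost)
    return best


def _standard_blocks(amino_acids: tuple[str, ...]) -> dict[str, tuple[str, ...]]:
    std = builtin_code("standard")
    return {aa: std.codons_for(aa) for aa in amino_acids}


def _anneal_natural(
    rng: np.random.Generator,
    amino_acids: tuple[str, ...],
    iterations: int,
) -> tuple[dict[str, str], tuple[int, int]]:
    """Annealing over one-codon-per-standard-block choices (RED codes)."""
    index, nbrs = _neighbor_index(3)
    blocks = _standard_blocks(amino_acids)
    stops = {index[s] for s in _NATURAL_STOPS}
    choice = {aa: codons[rng.integers(len(codons))] for aa, codons in blocks.items()}

    def cost_of(ch):
        sense = {index[c] for c in ch.values()}
        return _cost(sense, stops, nbrs)

    def scalar(cost):
        return cost[0] * 65 + cost[1]

    cost = cost_of(choice)
    best = (dict(choice), cost)
    mutable = [aa for aa, codons in blocks.items() if len(codons) > 1]
    t0, t1 = 3.0, 0.01
    for i in range(iterations):
        temp = t0 * (t1 / t0) ** (i / max(iterations - 1, 1))
        aa = mutable[rng.integers(len(mutable))]
        old = choice[aa]
        alts = [c for c in blocks[aa] if c != old]
        choice[aa] = alts[rng.integers(len(alts))]
        new_cost = cost_of(choice)
        delta = scalar(new_cost) - scalar(cost)
        if delta <= 0 or rng.random() < math.exp(-delta / max(temp, 1e-9)):
            cost = new_cost
            if scalar(cost) < scalar(best[1]):
                best = (dict(choice), cost)
        else:
            choice[aa] = old
    return best


def _ideal_natural(
    rng: np.random.Generator, amino_acids: tuple[str, ...]
) -> dict[str, str] | None:
    """Backtracking search for a one-per-block selection, pairwise d >= 2.

    Blocks are processed smallest-first (forced single-codon blocks like
    AUG/UGG immediately); candidate order within a block is randomized so
    repeated calls sample different family members.
    """
    blocks = _standard_blocks(amino_acids)
    order = sorted(blocks, key=lambda aa: len(blocks[aa]))
    chosen: list[str] = []

    def compatible(codon):
        return all(hamming(codon, c) >= 2 for c in chosen)

    def search(i):
        if i == len(order):
            return True
        codons = list(blocks[order[i]])
        rng.shuffle(codons)
        for codon in codons:
            if compatible(codon):
                chosen.append(codon)
                if search(i + 1):
                    return True
                chosen.pop()
        return False

    if not search(0):
        return None
    return dict(zip(order, chosen))


def _latin_square(rng: np.random.Generator) -> list[list[int]]:
    """Random 4x4 Latin square: shuffled rows/columns/symbols of the cyclic square."""
    base = [[(r + c) % 4 for c in range(4)] for r in range(4)]
    rows = rng.permutation(4)
    cols = rng.permutation(4)
    syms = rng.permutation(4)
    return [[int(syms[base[r][c]]) for c in cols] for r in rows]


def _ideal_free_triplet(rng: np.random.Generator) -> list[str]:
    """A 16-codon set, pairwise distance >= 2, via a random Latin square.

    Words (x, y, L(x, y)) of a Latin square L differ in >= 2 positions
    whenever they differ at all, which is exactly the distance-2 property.
    """
    nts = "UCAG"
    sq = _latin_square(rng)
    return [nts[x] + nts[y] + nts[sq[x][y]] for x in range(4) for y in range(4)]


def _parity_code(k: int) -> list[str]:
    """Quaternary sum-zero code: 4**(k-1) words, pairwise distance >= 2."""
    vals = {"U": 0, "C": 1, "A": 2, "G": 3}
    return [c for c in all_codons(k) if sum(vals[x] for x in c) % 4 == 0]


# ---------------------------------------------------------------------------
# public designers
# ---------------------------------------------------------------------------


def optimize_code(
    constraints: DesignConstraints,
    rng: np.random.Generator,
    iterations: int = 20000,
    restarts: int = 3,
    name: str | None = None,
) -> GeneticCode:
    """Search for a code maximizing the null-adjacent mutation fraction.

    Ideal constructions (all mutations truncating) are produced directly
    when the constraints admit them — for triplet codes whenever
    ``n_amino_acids <= 16`` (Latin-square / block backtracking), for
    quadruplet codes from the sum-zero parity code — and an error is
    raised when ideality is required but combinatorially impossible.
    Non-ideal families (FS20, RED20) are optimized by simulated annealing
    with lexicographic cost (non-null hits, then missense hits), restarted
    ``restarts`` times.
    """
    k = constraints.codon_length
    n_aa = constraints.n_amino_acids
    aas = constraints.amino_acids or default_amino_acid_subset(n_aa)
    codons = all_codons(k)

    if constraints.require_ideal and n_aa > max_ideal_sense_count(k) - (
        constraints.n_stops if k == 4 else 0
    ):
        raise ValueError(
            f"no ideal code exists for {n_aa} amino acids at codon length {k}: "
            f"at most {max_ideal_sense_count(k)} codons are pairwise at distance >= 2"
        )

    if constraints.natural_machinery_only:
        if k != 3:
            raise ValueError("natural machinery implies triplet codons")
        if constraints.n_stops != 3:
            raise ValueError("natural release factors decode exactly UAA, UAG, UGA")
        if constraints.require_ideal or n_aa <= max_ideal_sense_count(3):
            ideal = _ideal_natural(rng, aas)
        else:
            ideal = None
        if constraints.require_ideal:
            if ideal is None:
                raise ValueError(
                    f"no ideal natural-machinery code found for residues {aas}"
                )
            choice = ideal
        else:
            best = None
            for _ in range(restarts):
                cand = _anneal_natural(rng, aas, iterations)
                if best is None or cand[1] < best[1]:
                    best = cand
            choice = best[0]
        assignment = {c: NULL for c in codons}
        for stop in _NATURAL_STOPS:
            assignment[stop] = STOP
        for aa, codon in choice.items():
            assignment[codon] = aa
        code_name = name or f"red{n_aa}"
        return GeneticCode(name=code_name, codon_length=k, assignment=assignment)

    # synthetic machinery: free codon placement
    if constraints.require_ideal or (k == 3 and n_aa <= 16 and constraints.n_stops == 1):
        if k == 3:
            words = _ideal_free_triplet(rng)
            picks = list(rng.choice(len(words), size=n_aa, replace=False))
            sense = [words[i] for i in picks]
            nulls = [c for c in codons if c not in set(words)]
            stops = [nulls[int(rng.integers(len(nulls)))]]
        else:
            words = _parity_code(k)
            picks = list(rng.choice(len(words), size=n_aa + constraints.n_stops, replace=False))
            sense = [words[i] for i in picks[:n_aa]]
            stops = [words[i] for i in picks[n_aa:]]
    else:
        best = None
        for _ in range(restarts):
            cand = _anneal_subset(rng, k, n_aa, constraints.n_stops, iterations)
            if best is None or cand[2] < best[2]:
                best = cand
        sense = [codons[i] for i in best[0]]
        stops = [codons[i] for i in best[1]]

    assignment = {c: NULL for c in codons}
    for stop in stops:
        assignment[stop] = STOP
    # arbitrary amino-acid placement (synthetic tRNAs impose no pairing),
    # alphabetical residues onto sense codons in canonical order
    for codon, aa in zip(sorted(sense, key=codons.index), sorted(aas)):
        assignment[codon] = aa
    code_name = name or f"fs{n_aa}" + ("quad" if k == 4 else "")
    return GeneticCode(name=code_name, codon_length=k, assignment=assignment)


def design_hyperevolvable(
    rng: np.random.Generator,
    iterations: int = 30000,
    name: str = "hyperevolvable",
) -> GeneticCode:
    """A complete 64-codon code built to *accelerate* evolution.

    The design goals are the opposite of fail-safe: no null codons, a
    single stop, zero synonymous mutations (each amino acid's codons kept
    pairwise at distance >= 2 by allocating synonym blocks within cosets
    of the sum-zero parity code), and amino-acid placement annealed to
    maximize the mean Kyte-Doolittle hydropathy change per missense
    mutation.
    """
    from .metrics import KYTE_DOOLITTLE

    codons = all_codons(3)
    vals = {"U": 0, "C": 1, "A": 2, "G": 3}
    cosets: list[list[str]] = [[], [], [], []]
    for c in codons:
        cosets[sum(vals[x] for x in c) % 4].append(c)

    # 63 sense codons in 20 blocks (17 of size 3, 3 of size 4) + 1 stop;
    # each block drawn from a single coset so f_s = 0 by construction.
    sizes = [4, 4, 4] + [3] * 17
    blocks: list[list[str]] = []
    pool = [list(rng.permutation(c)) for c in cosets]
    stop = pool[0].pop()
    order = sorted(range(4), key=lambda i: -len(pool[i]))
    for size in sizes:
        order = sorted(range(4), key=lambda i: -len(pool[i]))
        src = pool[order[0]]
        blocks.append([src.pop() for _ in range(size)])
    assert all(not p for p in pool)

    aas = list(AMINO_ACIDS)
    rng.shuffle(aas)
    assignment = {stop: STOP}
    for aa, block in zip(aas, blocks):
        for c in block:
            assignment[c] = aa

    index, nbrs = _neighbor_index(3)
    labels = [assignment[c] for c in codons]
    kd = {**KYTE_DOOLITTLE, STOP: np.nan}

    def dkd_sum(lab):
        total = 0.0
        for i, a1 in enumerate(lab):
            if a1 == STOP:
                continue
            for j in nbrs[i]:
                a2 = lab[j]
                if a2 != STOP and a2 != a1:
                    total += abs(kd[a2] - kd[a1])
        return total

    # anneal amino-acid placement (swap the residues of two whole blocks)
    block_codons = {i: [index[c] for c in b] for i, b in enumerate(blocks)}
    block_aa = {i: assignment[blocks[i][0]] for i in range(20)}

    def apply_labels():
        lab = [None] * 64
        lab[index[stop]] = STOP
        for i, cods in block_codons.items():
            for c in cods:
                lab[c] = block_aa[i]
        return lab

    current = dkd_sum(apply_labels())
    for i in range(iterations):
        temp = 50.0 * (0.01) ** (i / max(iterations - 1, 1))
        a, b = rng.choice(20, size=2, replace=False)
        block_aa[a], block_aa[b] = block_aa[b], block_aa[a]
        cand = dkd_sum(apply_labels())
        if cand >= current or rng.random() < math.exp((cand - current) / max(temp, 1e-9)):
            current = cand
        else:
            block_aa[a], block_aa[b] = block_aa[b], block_aa[a]

    lab = apply_labels()
    return GeneticCode(
        name=name, codon_length=3, assignment=dict(zip(codons, lab))
    )
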