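# Methods

This note documents the models implemented in `fscodes`, the defaults they
ship with, and the reasoning behind the design choices that were genuinely
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Codon tables and mutation statistics

A genetic code is a total map from all 4^k codons (k = 3 or 4) to one of
22 labels: twenty amino acids, stop (`*`), or null (`-`).  Null codons are
recognized by no tRNA and no release factor; ribosomes reaching one stall,
so a mutation into a null codon destroys the protein product.  Stop and
null are deliberately kept distinct: a nonsense mutation truncates through
the normal termination pathway, a null-directed mutation fails
translation outright, and the two enter the statistics differently.

All code-level statistics enumerate the single point mutations that
originate at sense codons (a code with n sense codons has exactly
n x 3k of them); stop and null codons contribute no origin events.  The
statistics are

* `f_s` — fraction of those mutations conserving the amino acid.  With
  this denominator the Standard Code gives 0.244 and the random-code
  ensemble mean is about 0.043, matching the conventional 24%-versus-4%
  contrast; restricting the denominator to non-truncating events would
  give 0.25 for the Standard Code, which is how the denominator
  convention was fixed.
* `<dKD>` — mean |KD(a2) − KD(a1)| over missense events, using the
  Kyte–Doolittle hydropathy scale (isoleucine +4.5 … arginine −4.5).
  Averaging is per mutation event, not per amino-acid pair.  The quantity
  is undefined (raises, never returns 0) for codes without missense
  mutations.
* null-mutation fraction — sense-origin mutations landing on null codons.
* `phi` — the missense fraction normalized by the Standard Code's
  (392/549).  `phi` is the quantity that scales the beneficial mutation
  supply in the simulator: only missense mutations can alter a protein
  without destroying it.  An alternative reading of the normalizing
  fraction (missense over truncating-plus-missense) is available via
  `truncating_denominator=True`; both give phi = 0 for ideal fail-safe
  codes and the default is the one calibrated by the f_s convention
  above.

Random codes assign each codon an independent uniform label among the 20
amino acids plus stop, rejecting draws in which any label is absent.  The
rejection filter matters: about two thirds of unfiltered draws miss some
label at k = 3, and conditioning on full coverage pulls the ensemble mean
f_s from 1/21 ≈ 0.048 down to ≈ 0.043.

## Mutation-distance networks

Edge weights between amino acids a1, a2 sum p^l(c1,c2) · delta(c1,c2)
over all codon pairs in the two synonym blocks, with p = 1/12 by default.
The bridge indicator delta is 1 when codons synonymously reachable from
c1 and c2 come within Hamming distance 1 of each other.  Two choices were
open and are fixed as follows: reachability is the full transitive
closure of synonymous point-mutation steps (including zero steps, so a
codon always reaches itself), and stop codons are not network nodes (null
codons appear only as an optional aggregate display node).  The toy-code
oracle tests in `tests/test_network.py` pin these conventions, including
the hand-computed 13/144 bridge case.

## Wobble decoding

tRNAs are abstract: an anticodon plus one of five position-34 chemistry
categories (G34, Q34, modified U34, unmodified C34, k2C34).  The decoded
codon set follows five heuristic rules (G/Q34 read NNC and NNU; modified
U34 reads NNA and NNG; unmodified C34 reads NNG only; lysidine-modified
CAU reads AUA only; positions 35–36 pair Watson–Crick only).  Minimal
tRNA sets pick, per sense codon, the admissible reader recognizing the
fewest extra codons, breaking ties in favor of unmodified C34, then G34,
then modified U34.  The *effective code* makes every tRNA-readable codon
sense (wobble reads assumed as efficient as cognate reads), keeps stops
with their release factors, and leaves unread codons null.  Codons read
by differently charged tRNAs are flagged ambiguous and resolved in favor
of the designated reader; none arise for the built-in RED codes, whose
one-codon-per-natural-block structure makes minimal sets unambiguous by
construction.  No wobble model is offered for quadruplet codons — the
physics is not predictable from these rules.

## Code design

Ideality.  A code in which every sense-origin point mutation truncates
(null or stop target) has phi = 0 and f_s = 0; we call it *ideal*.  This
is equivalent to the sense codons being pairwise at Hamming distance >= 2.
For triplets the maximum such set has exactly 16 members (one codon per
axis-line of the 4x4x4 cube), and any 17th codon — including the stop —
necessarily sits at distance 1 from the set.  Strict ideality (every
neighbor null, stop included) is therefore impossible for triplet codes
with >= 16 amino acids but attainable for quadruplet codes, where
distance-2 sets reach 64 codons.  `is_ideal(code, strict=True)` exposes
the distinction.

Families.  FS20/FS16 place codons freely (synthetic machinery, arbitrary
amino-acid placement); RED20/RED15 must be realizable with natural E.
coli machinery, which pins each sense codon to its Standard Code amino
acid (a natural tRNA is charged with its natural residue), fixes the
stops at UAA/UAG/UGA, and reduces design to choosing one codon per
standard synonym block.  The product of block sizes, ~3.4 x 10^8, is the
RED20 family size.  Only six of the C(20,5) possible 5-residue omissions
admit an ideal RED15; the shipped choice drops C, D, I, N, Q (cysteine's
special chemistry; D covered by E; I covered by L/V; the amides dropped
in favor of histidine).

Optimization.  Non-ideal families are searched by simulated annealing
over codon subsets (or per-block choices for RED codes) with a
lexicographic objective: first minimize non-null hits from sense codons,
then missense hits.  For FS20 the optimum is known combinatorially — 21
codons admit at least 15 same-line pairs and the stop can absorb at most
3 of them, so the best achievable census is 24 missense + 3 nonsense +
153 null out of 180 — and the shipped table attains it (asserted by a
regeneration test).  Ideal constructions are direct: random 4x4 Latin
squares give 16-word distance-2 sets for FS16, backtracking over synonym
blocks gives RED15, and the quaternary sum-zero parity code gives FSQUAD.

The hyperevolvable comparison code ("colorado") is built with the
opposite goals: complete (no nulls), a single stop, zero synonymous
mutations (synonym blocks allocated within parity-code cosets), and
amino-acid placement annealed to maximize the mean hydropathy change per
missense event.  It is a representative reconstruction of that design
philosophy, not a transcription of any published table, and its phi
(~1.38) should be read accordingly.

## Evolutionary simulator

The hybrid scheme follows the birth–death/analytic split described in the
package docstrings: epochs of dt = 0.1 generations; stochastic strains
update by independent Binomial(N_i, p_b) births and Binomial(N_i, p_d)
deaths with p_b = [1 + (f_i − <f>)]dt (clamped to [0,1]) and p_d = dt;
analytic strains multiply by exp[(f_i − <f>)dt]; after the census the
mean is recomputed and strains are reallocated, entering the analytic
group above eps_i = xi/(f_i − <f>) (xi = 3).  eps_i is undefined for
at-or-below-mean strains; they stay stochastic unless larger than
10·xi/dt = 300 individuals, at which point drift is negligible and the
analytic update is forced.  Mutants (Poisson, mean N_i·U_b·phi·dt with
U_b = 10^-5.5) arise only from analytic-group strains and enter as
stochastic strains of size 1.  Pruning removes strains that are both
below the mean and in the stochastic group; paired-seed tests confirm the
resulting fitness inflation is positive and small.

DFE scale.  The generalized half-normal DFE P(df) ∝ exp[−(λ·df)^β] is
sampled exactly via a Gamma(1/β) transform.  Two calibrations ship:
`SimulationConfig()` keeps the printed λ = 2 (mean effect 0.5/gen at
β = 1), and `SimulationConfig.ref45()` sets the scale so the mean effect
is the empirical ~2% per generation (λ = 50 at β = 1).  The printed scale
produces runaway dynamics (population mean fitness grows by two orders of
magnitude in a few hundred generations) that are irreconcilable with
fitness-gain rates of order 10^-4/gen^2, so all headline rate and
containment predictions use `ref45`; λ = 2 remains available for
sensitivity analysis.

Problem sizes.  Total population size is a free parameter; the package's
desk scale for reproducing rate and containment predictions is
N_total = 10^6 with 500-generation horizons and >= 50 replicates —
large enough for strong clonal interference and fitness-gain rates of
the right order, small enough that a full comparison across six codes
runs in minutes on one CPU.  Rate *ratios* between codes, the primary
outputs, vary systematically with N_total (clonal interference compresses
them as N grows), so comparisons are only meaningful at matched N; the
per-replicate rate is the full-trace least-squares slope of mean fitness
(the regression window is configurable).

## Competition and containment

Both populations share one culture and one mean fitness (zero-sum,
constant total size); each side mutates with its own phi.  A replicate
ends when a side's total drops below one individual.  P_contain(f0, t) is
the fraction of replicates with the invader eliminated by t, reported
with Wilson 95% intervals and optional bootstrap traces; censored
replicates count as not contained (conservative).  Steady state is
reached when all replicates resolve — with matched initial fitness the
weaker-phi side cannot recover once the fitness gap opens, so resolution
is almost sure well before the default t_max = 5000 generations at the
desk scale.  P_contain is monotone nonincreasing in f0 (more invaders,
more invader mutation supply), which the threshold search in the
acceptance script exploits.

## Synthetic data and its limits

All fixtures are generated in code: toy codes (partial maps completed
with nulls), random proteins/CDS over chosen residue subsets, and small
hand-built strain censuses.  The "sfGFP-like" example ORF is a synthetic
239-residue random protein, not the real superfolder GFP.  What passing
tests show is therefore internal consistency of the models — exact
combinatorics of the tables, agreement with closed forms and brute-force
oracles, reproducibility under seeding — not agreement with wet-lab
expression data, real tRNA modification biochemistry, transition/
transversion-biased mutation spectra, or frameshift dynamics, all of
which are outside the model family (point mutations with a flat rate,
beneficial-only DFE, well-mixed constant-size culture).

## Known limitations

* The simulator's absolute rates and all rate ratios depend on N_total
  and the DFE scale; only matched-configuration comparisons are
  meaningful, and the desk scale above is a calibration choice, not a
  measurement.
* The built-in FS/RED/FSQUAD and hyperevolvable tables are
  optimizer-generated representative family members; other members of
  the same families (equally optimal under the same constraints) can
  have different missense availabilities, and published tables of the
  same names need not coincide with them codon for codon.
* Wobble rules are heuristics at the anticodon-category level; no
  thermodynamics, no modification chemistry beyond the five categories.
* RED-family sizes other than the block-product count are not
  enumerated: realizability constraints beyond the five wobble rules
  (actual E. coli tRNA gene inventories) are out of scope.
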