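# fscodes

Tools for designing and evaluating **fail-safe genetic codes** — codon
tables engineered so that point mutations in protein-coding sequences land
on *null codons* (codons recognized by no tRNA and no release factor) and
therefore destroy the protein instead of substituting an amino acid.
Organisms encoded this way are predicted to evolve more slowly, or not at
all, and to be intrinsically poor invaders of established populations,
which makes fail-safe encoding a candidate base layer for biocontainment.

The package is aimed at synthetic-biology and molecular-evolution
researchers who want to design such codes, quantify their mutational
robustness, and predict their population-genetic consequences.

## What it computes

A genetic code is a total map 𝕋 : C → A ∪ {stop, null} from all 4^k
codons (k = 3 or 4).  Over the single point mutations originating at sense
codons, the package computes:

* **f_s** — synonymous-mutation frequency (Standard Code: 0.24; random
  codes: ≈ 0.04);
* **⟨ΔKD⟩** — mean |KD(a₂) − KD(a₁)| Kyte–Doolittle hydropathy change per
  missense mutation;
* **φ** — missense fraction normalized to the Standard Code; the
  beneficial-mutation supply factor.  Ideal fail-safe codes have φ = 0;
* **mutation-distance networks** — amino-acid graphs with edge weights
  w(a₁,a₂) = Σ p^l(c₁,c₂) δ(c₁,c₂), p = 1/12, where δ tests adjacency up
  to synonymous bridging;
* **wobble-effective codes** — what a code becomes if its minimal natural
  tRNA set (G34/Q34 read NNY; modified U34 reads NNR; unmodified C34 reads
  NNG; lysidine-CAU reads AUA) decodes wobble targets as well as cognate
  codons;
* **evolutionary rates** — a hybrid birth-death/deterministic simulator of
  adapting asexual populations (epoch dt = 0.1 gen; p_b = [1 + (f_i −
  ⟨f⟩)]dt, p_d = dt for small strains; N_i ← N_i e^{(f_i−⟨f⟩)dt} for large
  ones; Poisson mutant influx N_i·U_b·φ·dt with U_b = 10^-5.5; exponential
  DFE) and the least-squares rate d⟨f⟩/dt per replicate;
* **containment probability** — P_contain(f₀, t): the chance a monoclonal
  invader starting at population fraction f₀ is eliminated by a native
  population in shared culture.

Built-in tables: the Standard Code (NCBI table 1), a hyperevolvable
comparison code (`colorado`), and optimizer-generated representative
members of the fail-safe families `fs20`, `red20`, `fs16`, `red15`
(triplet; RED codes use only natural *E. coli* machinery) and `fsquad`
(quadruplet, 256 codons).  See `docs/methods.md` for the models,
parameters, and design decisions.

## Worked example

```
$ fscodes metrics --code fs20
fs      0.0
dkd     4.2583
null    0.85
phi     0.1867
```

FS20 encodes all 20 amino acids in 20 codons (plus one stop) chosen so
that 85% of the 180 possible point mutations hit null codons and none are
synonymous; its missense availability is φ = 0.187, i.e. a FS20-encoded
ORF samples beneficial missense mutations at ~19% of the Standard-Code
rate.  The ideal codes go further:

```
$ fscodes metrics --code red15 --stat phi
phi     0.0
```

φ = 0 means *no* point mutation in a RED15-encoded ORF can change one
amino acid into another — every mutation truncates — so simulated
adaptation through missense mutations arrests completely:

```
$ fscodes simulate evolve --code red15 --reps 4 --gens 100 --n-total 1e6 \
      --seed 7 --out red15_traj.tsv
rate = 0.000e+00 +/- 0.000e+00 1/gen^2
```

whereas the same command with `--code standard` prints a positive rate of
order 10^-4 1/gen² (exact value depends on seed and scale; see
`docs/methods.md` for how rates depend on population size).  Wobble
promiscuity partially re-opens evolution for the RED codes:

```
$ fscodes wobble effective --code red15 | python -c \
      "import json,sys; d=json.load(sys.stdin); \
       print(sum(v not in '*-' for v in d['assignments'].values()), 'sense codons')"
26 sense codons
```

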