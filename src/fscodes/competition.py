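"""Two-population invasion simulations and containment probability.

A single well-mixed culture holds a *native* population and a monoclonal
*invader*, identical in initial fitness but encoded in different genetic
codes (hence different missense availabilities phi).  Both share one mean
fitness, so the culture is zero-sum: whichever side accumulates beneficial
mutations faster drives the other's lineages below the mean, where they
shrink exponentially and finally resolve by drift.  A replicate ends when
one side's total population drops below one individual (or at t_max).

P_contain(f0, t) is the fraction of replicates in which the invader — with
initial population fraction f0 — has been eliminated by time t.  Run to
steady state (all replicates resolved), it depends only on f0 and the two
codes, which is the summary used to assess whether fail-safe encoding acts
as an intrinsic biocontainment layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .codes import GeneticCode
from .evosim import (
    PopulationState,
    SimulationConfig,
    phi_for_code,
    step_epoch,
)

__all__ = [
    "CompetitionSetup",
    "CompetitionOutcome",
    "run_competition",
    "containment_probability",
    "containment_curve",
    "wilson_interval",
]

NATIVE, INVADER = 0, 1


@dataclass(frozen=True)
class CompetitionSetup:
    """Native and invader codes (or phi values) plus shared simulator config."""

    native_code: GeneticCode | float
    invader_code: GeneticCode | float
    f0: float
    config: SimulationConfig
    t_max: float = 5000.0

    def __post_init__(self):
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError("f0 must lie in [0, 1]")

    def phis(self) -> np.ndarray:
        out = []
        for code in (self.native_code, self.invader_code):
            if isinstance(code, (int, float)):
                out.append(float(code))
            else:
                out.append(phi_for_code(code, self.config.wobble))
        return np.array(out)


@dataclass(frozen=True)
class CompetitionOutcome:
    """One replicate: which side was eliminated, and when."""

    winner: int  # NATIVE or INVADER; -1 if censored at t_max
    extinction_time: float  # time the losing side died (inf if censored)
    invader_extinct: bool

    @property
    def censored(self) -> bool:
        return self.winner == -1


def _initial_state(setup: CompetitionSetup) -> PopulationState:
    n_total = setup.config.n_total
    n_inv = setup.f0 * n_total
    n_nat = n_total - n_inv
    n = np.array([n_nat, n_inv])
    keep = n >= 1.0
    return PopulationState(
        n=n[keep],
        f=np.ones(int(keep.sum())),
        stochastic=np.zeros(int(keep.sum()), dtype=bool),
        side=np.array([NATIVE, INVADER], dtype=np.int8)[keep],
    )


def run_one_competition(
    setup: CompetitionSetup, rng: np.random.Generator
) -> CompetitionOutcome:
    """Simulate one replicate until one side is extinct or t_max."""
    state = _initial_state(setup)
    phis = setup.phis()
    config = setup.config
    n_epochs = int(round(setup.t_max / config.dt))
    for side in (NATIVE, INVADER):
        if state.side_total(side) < 1.0:
            return CompetitionOutcome(
                winner=1 - side, extinction_time=0.0, invader_extinct=side == INVADER
            )
    for _ in range(n_epochs):
        step_epoch(state, config, rng, phis)
        for side in (NATIVE, INVADER):
            if state.side_total(side) < 1.0:
                return CompetitionOutcome(
                    winner=1 - side,
                    extinction_time=state.t,
                    invader_extinct=side == INVADER,
                )
    return CompetitionOutcome(winner=-1, extinction_time=math.inf, invader_extinct=False)


def run_competition(
    setup: CompetitionSetup, n_replicates: int, seed: int | None = None
) -> list[CompetitionOutcome]:
    """Independent replicates, seeded from ``seed`` (default: config seed)."""
    master = setup.config.seed if seed is None else seed
    streams = np.random.SeedSequence(master).spawn(n_replicates)
    return [run_one_competition(setup, np.random.default_rng(s)) for s in streams]


def wilson_interval(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def containment_probability(
    outcomes: list[CompetitionOutcome], t: float = math.inf
) -> tuple[float, tuple[float, float]]:
    """Fraction of replicates with the invader eliminated by time ``t``.

    Returns (estimate, Wilson 95% interval).  Censored replicates count as
    not-contained, so the estimate is conservative.
    """
    if not outcomes:
        raise ValueError("need at least one outcome")
    k = sum(1 for o in outcomes if o.invader_extinct and o.extinction_time <= t)
    n = len(outcomes)
    return k / n, wilson_interval(k, n)


def containment_curve(
    native_code: GeneticCode | float,
    invader_code: GeneticCode | float,
    f0_grid: np.ndarray,
    config: SimulationConfig,
    n_replicates: int = 100,
    t_max: float = 5000.0,
    n_bootstrap: int = 200,
    seed: int | None = None,
) -> "pandas.DataFrame":  # noqa: F821
    """Steady-state P_contain versus initial invader fraction.

    Each grid point runs ``n_replicates`` competitions to resolution (or
    ``t_max``); bootstrap resampling of replicate outcomes provides the
    spread columns ``boot_low``/``boot_high`` (2.5/97.5 percentiles)
    alongside the Wilson interval.
    """
    import pandas as pd

    master = config.seed if seed is None else seed
    root = np.random.SeedSequence(master)
    grid_seeds = root.spawn(len(f0_grid))
    rows = []
    for f0, ss in zip(f0_grid, grid_seeds):
        setup = CompetitionSetup(native_code, invader_code, float(f0), config, t_max)
        streams = ss.spawn(n_replicates)
        outcomes = [run_one_competition(setup, np.random.default_rng(s)) for s in streams]
        p, (lo, hi) = containment_probability(outcomes)
        flags = np.array([o.invader_extinct for o in outcomes])
        boot_rng = np.random.default_rng(ss.spawn(1)[0])
        boots = boot_rng.choice(flags, size=(n_bootstrap, len(flags)), replace=True).mean(axis=1)
        rows.append(
            (
                float(f0),
                p,
                lo,
                hi,
                float(np.percentile(boots, 2.5)),
                float(np.percentile(boots, 97.5)),
                int(sum(o.censored for o in outcomes)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["f0", "p_contain", "ci_low", "ci_high", "boot_low", "boot_high", "censored"],
    )
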