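"""Gillespie simulation of a peroxisomal substrate population with ages.

A single peroxisome is modeled as a pool of molecules subject to three
event types: **import** of a new (age-0) molecule at a constant rate,
**maturation** of a nascent ("unstable") molecule into the mature
("stable") state, and **degradation** of one molecule with a
state-dependent per-molecule rate.  Event waiting times are exponential in
the summed rate; all ages advance by the waiting time; the event is chosen
by a rate-weighted draw.

Starting conditions are a steady-state population: ages drawn from an
exponential distribution with the configured half-life; in the 2-state
regime a fixed fraction of molecules starts nascent, drawn age-weighted
(young molecules favored with weight e^{-k_mat age}).  The import rate is
set to balance steady-state decay (N0 * k_ss).  At t = 0 the regime's
activated decay constant replaces the steady-state one — modeling
induction of the extraction machinery — while in the 2-state regime the
mature state keeps decaying at the steady-state rate (k_decay2 = k_ss).

Protein age is read out through a tandem fluorescent timer: each molecule
contributes 1 - 2^{-age/halftime} expected fluorescence per fluorophore,
and the slow-maturing mCherry / fast-maturing sfYFP total ratio reports
population age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimConfig",
    "Molecule",
    "Population",
    "EventRates",
    "Trajectory",
    "init_steady_state_population",
    "gillespie_step",
    "run_simulation",
    "run_ensemble",
    "compute_fluorescence",
    "ensemble_summarize",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class SimConfig:
    """Simulation configuration (rates in hr^-1, times in the units noted).

    ``half_life_min`` sets the steady-state turnover: k_ss = ln2/half-life.
    In the 2-state regime the mature decay constant equals k_ss, and
    ``k_mat_hr`` defaults to the value whose steady state reproduces
    ``unstable_fraction``: k_mat = k_ss (1 - f_u)/f_u.
    """

    n_initial: int = 1000
    half_life_min: float = 58.0
    regime: str = "one_state"
    k_decay_hr: float = 2.82  #: activated 1-state decay constant
    k_decay1_hr: float = 3.45  #: activated nascent decay constant (2-state)
    k_mat_hr: float | None = None
    unstable_fraction: float = 0.6
    duration_hr: float = 4.0
    record_interval_min: float = 1.0
    replicates: int = 100
    sfyfp_halftime_min: float = 15.0
    mcherry_halftime_min: float = 40.0
    seed: int = 0
    nascent_import: bool = True  #: imported molecules enter the nascent state

    def __post_init__(self) -> None:
        if self.regime not in ("one_state", "two_state"):
            raise ValueError(f"regime must be 'one_state' or 'two_state', got {self.regime!r}")
        for name in ("half_life_min", "k_decay_hr", "k_decay1_hr",
                     "sfyfp_halftime_min", "mcherry_halftime_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_mat_hr is not None and self.k_mat_hr <= 0:
            raise ValueError("k_mat_hr must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_initial < 0:
            raise ValueError("n_initial must be >= 0")
        if not 0.0 < self.unstable_fraction < 1.0:
            raise ValueError("unstable_fraction must lie in (0, 1)")
        if self.duration_hr < 0 or self.record_interval_min <= 0:
            raise ValueError("invalid duration or record interval")

    @property
    def k_ss_per_min(self) -> float:
        """Steady-state turnover rate constant, min^-1."""
        return _LN2 / self.half_life_min

    @property
    def k_decay2_hr(self) -> float:
        """Mature-state decay constant: equals the steady-state constant."""
        return self.k_ss_per_min * 60.0

    @property
    def k_mat_per_min(self) -> float:
        if self.k_mat_hr is not None:
            return self.k_mat_hr / 60.0
        f = self.unstable_fraction
        return self.k_ss_per_min * (1.0 - f) / f


@dataclass(frozen=True)
class Molecule:
    """Snapshot of one molecule: age in minutes and maturation state."""

    age_min: float
    unstable: bool

    def __post_init__(self) -> None:
        if self.age_min < 0:
            raise ValueError("age must be >= 0")


class Population:
    """Molecule pool tracked by birth time, split by maturation state.

    Birth times (minutes; negative for molecules pre-dating t=0) make
    aging O(1) per event: age = now - birth.  ``now`` is the current
    simulation time in minutes.
    """

    def __init__(self, unstable_birth=(), stable_birth=(), now: float = 0.0) -> None:
        self.unstable_birth: list[float] = list(unstable_birth)
        self.stable_birth: list[float] = list(stable_birth)
        self.now = float(now)

    @property
    def n_unstable(self) -> int:
        return len(self.unstable_birth)

    @property
    def n_stable(self) -> int:
        return len(self.stable_birth)

    def __len__(self) -> int:
        return self.n_unstable + self.n_stable

    def ages(self) -> np.ndarray:
        """Ages in minutes of all molecules at the current time."""
        births = np.array(self.unstable_birth + self.stable_birth, dtype=float)
        return self.now - births

    def molecules(self) -> list[Molecule]:
        return [Molecule(self.now - b, True) for b in self.unstable_birth] + [
            Molecule(self.now - b, False) for b in self.stable_birth
        ]


@dataclass(frozen=True)
class EventRates:
    """Per-minute event rates: import is absolute, others per molecule.

    ``nascent_import`` routes imported molecules into the nascent pool
    (2-state regime) instead of the mature one.
    """

    import_rate: float = 0.0
    k_mat: float = 0.0
    k_deg_unstable: float = 0.0
    k_deg_stable: float = 0.0
    nascent_import: bool = False

    def channels(self, pop: Population) -> np.ndarray:
        return np.array(
            [
                self.import_rate,
                self.k_mat * pop.n_unstable,
                self.k_deg_unstable * pop.n_unstable,
                self.k_deg_stable * pop.n_stable,
            ]
        )

    def total(self, pop: Population) -> float:
        return float(self.channels(pop).sum())


def init_steady_state_population(cfg: SimConfig, rng: np.random.Generator) -> Population:
    """Draw a steady-state starting population at t = 0.

    Ages are exponential with mean half-life/ln2.  In the 2-state regime,
    ``round(unstable_fraction * N)`` molecules are assigned nascent by
    age-weighted draws without replacement favoring young molecules
    (weight e^{-k_mat age}, implemented via the Gumbel top-k trick so
    arbitrarily large k_mat selects exactly the youngest molecules).
    """
    n = cfg.n_initial
    ages = rng.exponential(scale=cfg.half_life_min / _LN2, size=n)
    births = -ages
    if cfg.regime == "one_state":
        return Population(stable_birth=births.tolist())
    n_unstable = int(round(cfg.unstable_fraction * n))
    if n_unstable > n:
        raise ValueError("unstable count exceeds population size")
    keys = -cfg.k_mat_per_min * ages + rng.gumbel(size=n)
    order = np.argsort(keys)[::-1]
    unstable_idx = order[:n_unstable]
    mask = np.zeros(n, dtype=bool)
    mask[unstable_idx] = True
    return Population(
        unstable_birth=births[mask].tolist(), stable_birth=births[~mask].tolist()
    )


def gillespie_step(
    pop: Population, rates: EventRates, rng: np.random.Generator
) -> tuple[Population, float]:
    """Advance one stochastic event; returns (pop, elapsed minutes).

    Waiting time is exponential in the summed rate; all ages advance by it
    (via the population clock); exactly one event executes: import appends
    an age-0 molecule, maturation flips one nascent molecule, degradation
    removes one molecule from the state chosen by rate weight (uniform
    within the state).  A zero total rate returns infinite elapsed time so
    callers can halt cleanly.
    """
    total = rates.total(pop)
    if total <= 0:
        return pop, math.inf
    dt = rng.exponential(1.0 / total)
    pop.now += dt
    _execute_event(pop, rates, rng, total)
    return pop, dt


def _execute_event(
    pop: Population, rates: EventRates, rng: np.random.Generator, total: float
) -> None:
    """Choose one event by rate weight and apply it at the current clock."""
    event = rng.choice(4, p=rates.channels(pop) / total)
    if event == 0:  # import: new age-0 molecule
        if rates.nascent_import:
            pop.unstable_birth.append(pop.now)
        else:
            pop.stable_birth.append(pop.now)
    elif event == 1:  # maturation: nascent -> mature, age preserved
        i = int(rng.integers(pop.n_unstable))
        pop.stable_birth.append(pop.unstable_birth[i])
        pop.unstable_birth[i] = pop.unstable_birth[-1]
        pop.unstable_birth.pop()
    elif event == 2:  # degradation of a nascent molecule
        i = int(rng.integers(pop.n_unstable))
        pop.unstable_birth[i] = pop.unstable_birth[-1]
        pop.unstable_birth.pop()
    else:  # degradation of a mature molecule
        i = int(rng.integers(pop.n_stable))
        pop.stable_birth[i] = pop.stable_birth[-1]
        pop.stable_birth.pop()


def compute_fluorescence(pop, cfg: SimConfig) -> tuple[float, float, float]:
    """Expected sfYFP and mCherry totals and their mCherry/sfYFP ratio.

    Each molecule contributes 1 - 2^{-age/halftime} per fluorophore
    (single-step exponential chromophore maturation).  An empty population
    returns (0, 0, nan).
    """
    if isinstance(pop, Population):
        ages = pop.ages()
    elif isinstance(pop, (list, tuple)) and pop and isinstance(pop[0], Molecule):
        ages = np.array([m.age_min for m in pop], dtype=float)
    else:
        ages = np.asarray(pop, dtype=float)
    if ages.size == 0:
        return 0.0, 0.0, math.nan
    yfp = float(np.sum(1.0 - 2.0 ** (-ages / cfg.sfyfp_halftime_min)))
    mch = float(np.sum(1.0 - 2.0 ** (-ages / cfg.mcherry_halftime_min)))
    ratio = mch / yfp if yfp > 0 else math.nan
    return yfp, mch, ratio


@dataclass
class Trajectory:
    """Per-minute record of one simulation (or of an ensemble mean)."""

    minutes: np.ndarray
    abundance: np.ndarray
    mean_age_min: np.ndarray
    sfyfp: np.ndarray
    mcherry: np.ndarray
    tft_ratio: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.minutes.size

    def normalized(self) -> "Trajectory":
        """Each series divided by its value at the starting point."""

        def norm(x):
            x = np.asarray(x, dtype=float)
            return x / x[0] if x[0] != 0 else x.copy()

        return Trajectory(
            minutes=self.minutes.copy(),
            abundance=norm(self.abundance),
            mean_age_min=norm(self.mean_age_min),
            sfyfp=norm(self.sfyfp),
            mcherry=norm(self.mcherry),
            tft_ratio=norm(self.tft_ratio),
            meta={**self.meta, "normalized": True},
        )


def _activated_rates(cfg: SimConfig, perturbed: bool) -> EventRates:
    k_ss = cfg.k_ss_per_min
    import_rate = cfg.n_initial * k_ss
    if cfg.regime == "one_state":
        k = cfg.k_decay_hr / 60.0 if perturbed else k_ss
        return EventRates(import_rate=import_rate, k_mat=0.0,
                          k_deg_unstable=k, k_deg_stable=k, nascent_import=False)
    k_u = cfg.k_decay1_hr / 60.0 if perturbed else k_ss
    return EventRates(
        import_rate=import_rate,
        k_mat=cfg.k_mat_per_min,
        k_deg_unstable=k_u,
        k_deg_stable=k_ss,  # mature state keeps the steady-state constant
        nascent_import=cfg.nascent_import,
    )


def run_simulation(
    cfg: SimConfig, rng: np.random.Generator | None = None, perturbed: bool = True
) -> Trajectory:
    """One replicate: per-minute records over ``duration_hr``.

    ``perturbed=False`` keeps all decay constants at their steady-state
    values (used to validate that the starting conditions are a stable
    steady state).  Deterministic for a fixed generator state.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pop = init_steady_state_population(cfg, rng)
    rates = _activated_rates(cfg, perturbed)
    total_min = cfg.duration_hr * 60.0
    n_records = int(round(total_min / cfg.record_interval_min)) + 1
    rec_times = np.arange(n_records) * cfg.record_interval_min

    abundance = np.zeros(n_records)
    mean_age = np.zeros(n_records)
    yfp = np.zeros(n_records)
    mch = np.zeros(n_records)
    ratio = np.zeros(n_records)

    def record(i: int) -> None:
        saved = pop.now
        pop.now = rec_times[i]
        ages = pop.ages()
        abundance[i] = ages.size
        mean_age[i] = float(ages.mean()) if ages.size else math.nan
        y, m, r = compute_fluorescence(pop, cfg)
        yfp[i], mch[i], ratio[i] = y, m, r
        pop.now = saved

    rec = 0
    while rec < n_records:
        total = rates.total(pop)
        if total <= 0:
            while rec < n_records:  # empty pool, no import: state frozen
                record(rec)
                rec += 1
            break
        t_event = pop.now + rng.exponential(1.0 / total)
        while rec < n_records and rec_times[rec] <= min(t_event, total_min):
            record(rec)
            rec += 1
        if t_event > total_min:
            break
        # execute the event at t_event (composition unchanged in between)
        pop.now = t_event
        _execute_event(pop, rates, rng, total)

    return Trajectory(
        minutes=rec_times,
        abundance=abundance,
        mean_age_min=mean_age,
        sfyfp=yfp,
        mcherry=mch,
        tft_ratio=ratio,
        meta={"regime": cfg.regime, "perturbed": perturbed},
    )


def run_ensemble(cfg: SimConfig, perturbed: bool = True) -> list[Trajectory]:
    """Independent replicates from substreams of the master seed."""
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    return [
        run_simulation(cfg, rng=np.random.default_rng(s), perturbed=perturbed)
        for s in seqs
    ]


def ensemble_summarize(trajectories: list[Trajectory], normalize: bool = True) -> Trajectory:
    """Pointwise ensemble means; optionally normalized to the t=0 value.

    The ensemble tFT ratio is the mean across replicates of each
    replicate's population ratio (ratio of within-replicate totals).
    Per-minute standard deviations across replicates are stored in
    ``meta["sd"]``.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    n = len(trajectories[0])
    if any(len(tr) != n for tr in trajectories):
        raise ValueError("trajectories have mismatched lengths")

    def stack(attr):
        return np.vstack([getattr(tr, attr) for tr in trajectories])

    fields_ = ["abundance", "mean_age_min", "sfyfp", "mcherry", "tft_ratio"]
    means = {f: np.nanmean(stack(f), axis=0) for f in fields_}
    sds = {f: np.nanstd(stack(f), axis=0, ddof=1) if len(trajectories) > 1 else np.zeros(n)
           for f in fields_}
    out = Trajectory(
        minutes=trajectories[0].minutes.copy(),
        abundance=means["abundance"],
        mean_age_min=means["mean_age_min"],
        sfyfp=means["sfyfp"],
        mcherry=means["mcherry"],
        tft_ratio=means["tft_ratio"],
        meta={"n_replicates": len(trajectories), "sd": sds},
    )
    return out.normalized() if normalize else out
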