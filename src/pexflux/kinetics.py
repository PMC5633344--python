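"""Degradation-kinetics models for pulse-chase fluorescence time courses.

Two competing descriptions of substrate turnover are implemented:

* **1-state model** — every molecule decays with the same probability per
  unit time, so the normalized population signal is a single exponential
  ``F(t) = exp(-k_decay * t)``.  On a log scale this is a straight line and
  is fit by ordinary least squares.

* **2-state model** — molecules are imported in a *nascent* state that
  decays with rate ``k_decay1`` and matures with rate ``k_mat`` into a
  *mature* state decaying with rate ``k_decay2``.  With an initial nascent
  fraction ``f0`` the total signal is a constrained biexponential (see
  :func:`two_state_curve`), fit by bounded nonlinear least squares on the
  log scale with multi-start initialization.

The degree of non-exponentiality of a time course is summarized by the
time-normalized area between the two fitted curves
(:func:`area_between_fits`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "KineticParams",
    "NormalizedTimeCourse",
    "FitResult",
    "one_state_curve",
    "two_state_curve",
    "fit_one_state",
    "fit_two_state",
    "area_between_fits",
    "half_life_minutes",
    "fraction_remaining",
]

#: |a - k_decay2| below which the degenerate closed form is used.
_DEGENERATE_EPS = 1e-8


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of a decay model.

    Parameters
    ----------
    model:
        ``"one_state"`` or ``"two_state"``.
    k_decay:
        1-state decay rate constant (hr^-1).
    k_mat, k_decay1, k_decay2:
        2-state maturation rate and nascent/mature decay rate constants
        (hr^-1).
    f0:
        Initial nascent fraction in [0, 1] (2-state only).
    """

    model: str = "one_state"
    k_decay: float = 0.0
    k_mat: float = 0.0
    k_decay1: float = 0.0
    k_decay2: float = 0.0
    f0: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in ("one_state", "two_state"):
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("k_decay", "k_mat", "k_decay1", "k_decay2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError(f"f0 must lie in [0, 1], got {self.f0}")

    def curve(self, t):
        """Evaluate the model's normalized decay curve F(t)."""
        if self.model == "one_state":
            return one_state_curve(t, self.k_decay)
        return two_state_curve(t, self.k_mat, self.k_decay1, self.k_decay2, self.f0)


@dataclass(frozen=True)
class NormalizedTimeCourse:
    """Mean-density series normalized to its t=0 value.

    ``time_hr[0]`` must be 0 and ``value[0]`` must be 1 (use
    :meth:`from_raw` to normalize a raw series).
    """

    time_hr: np.ndarray
    value: np.ndarray
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_hr, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "time_hr", t)
        object.__setattr__(self, "value", v)
        if self.sem is not None:
            object.__setattr__(self, "sem", np.asarray(self.sem, dtype=float))
        if t.size != v.size:
            raise ValueError("time and value arrays differ in length")
        if t.size < 2:
            raise ValueError("need at least 2 timepoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if t[0] != 0.0:
            raise ValueError("first timepoint must be 0")
        if not math.isclose(v[0], 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("first value must be 1 (normalize with from_raw)")

    @classmethod
    def from_raw(cls, time_hr, mean_density, sem=None) -> "NormalizedTimeCourse":
        """Normalize a raw mean-density series by its value at time 0."""
        t = np.asarray(time_hr, dtype=float)
        y = np.asarray(mean_density, dtype=float)
        if t[0] != 0.0:
            raise ValueError("series must start at time 0")
        if y[0] <= 0:
            raise ValueError("t=0 mean density must be positive")
        s = None if sem is None else np.asarray(sem, dtype=float) / y[0]
        return cls(t, y / y[0], s)


@dataclass(frozen=True)
class FitResult:
    """Parameter estimates from fitting one model to a time course."""

    params: KineticParams
    stderr: dict = field(default_factory=dict)
    rss_log: float = np.nan
    time_hr: np.ndarray | None = None
    converged: bool = True
    n_starts: int = 1
    intercept_log: float = 0.0

    def predict(self, t):
        """Model curve at times ``t`` (includes the fitted log-intercept)."""
        return np.exp(self.intercept_log) * self.params.curve(np.asarray(t, dtype=float))


def one_state_curve(t, k_decay: float):
    """Single-exponential survival fraction exp(-k_decay * t)."""
    return np.exp(-k_decay * np.asarray(t, dtype=float))


def two_state_curve(t, k_mat: float, k_decay1: float, k_decay2: float, f0: float = 1.0):
    """Normalized 2-state decay curve.

    Solves the two-compartment linear system

        dN/dt = -(k_mat + k_decay1) N,      N(0) = f0
        dM/dt = k_mat N - k_decay2 M,       M(0) = 1 - f0

    and returns F(t) = N(t) + M(t).  With a = k_mat + k_decay1 and
    c = k_mat / (a - k_decay2),

        F(t) = f0 (1 - c) e^{-a t} + (1 - f0 + f0 c) e^{-k_decay2 t}.

    When a ≈ k_decay2 the analytic limit
    F(t) = e^{-a t} (1 + f0 k_mat t) is used instead.
    F(0) = 1 always, and F is monotone non-increasing for non-negative
    rates and f0 in [0, 1].
    """
    for name, v in (("k_mat", k_mat), ("k_decay1", k_decay1), ("k_decay2", k_decay2)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if not 0.0 <= f0 <= 1.0:
        raise ValueError(f"f0 must lie in [0, 1], got {f0}")
    t = np.asarray(t, dtype=float)
    a = k_mat + k_decay1
    if abs(a - k_decay2) < _DEGENERATE_EPS:
        return np.exp(-a * t) * (1.0 + f0 * k_mat * t)
    c = k_mat / (a - k_decay2)
    return f0 * (1.0 - c) * np.exp(-a * t) + (1.0 - f0 + f0 * c) * np.exp(-k_decay2 * t)


def fit_one_state(tc: NormalizedTimeCourse) -> FitResult:
    """Fit the 1-state model by least squares on log-transformed values.

    The slope of log F vs t gives -k_decay; the intercept is reported but
    not constrained to 0.
    """
    if np.any(tc.value <= 0):
        bad = tc.time_hr[tc.value <= 0]
        raise ValueError(
            f"cannot log-transform non-positive values at timepoints {bad.tolist()}"
        )
    logy = np.log(tc.value)
    res = stats.linregress(tc.time_hr, logy)
    k = -res.slope
    pred = res.intercept + res.slope * tc.time_hr
    rss = float(np.sum((logy - pred) ** 2))
    return FitResult(
        params=KineticParams(model="one_state", k_decay=max(k, 0.0)),
        stderr={"k_decay": float(res.stderr), "intercept": float(res.intercept_stderr)},
        rss_log=rss,
        time_hr=tc.time_hr.copy(),
        intercept_log=float(res.intercept),
    )


def _two_state_residuals(x, t, logy, f0_fixed):
    k_mat, k1, k2 = x[:3]
    f0 = f0_fixed if f0_fixed is not None else x[3]
    curve = two_state_curve(t, k_mat, k1, k2, f0)
    return np.log(np.clip(curve, 1e-300, None)) - logy


def fit_two_state(
    tc: NormalizedTimeCourse,
    init: KineticParams | None = None,
    bounds: tuple | None = None,
    fix_f0: float | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit the 2-state model by bounded nonlinear least squares.

    Squared residuals of log F(t) against the log-transformed data are
    minimized with ``scipy.optimize.least_squares`` (Trust-Region-Reflective,
    a bound-aware Levenberg–Marquardt-type algorithm).  Because the problem
    is local, ``n_starts`` multiplicatively perturbed initial guesses are
    tried from a fixed seed and the best-RSS solution is returned.

    Parameters
    ----------
    init:
        Initial guess; defaults are derived from a 1-state pre-fit.
    bounds:
        ``(lower, upper)`` arrays over (k_mat, k_decay1, k_decay2[, f0]);
        default non-negative rates and f0 in [0, 1].
    fix_f0:
        Fix the initial nascent fraction (pure-pulse designs) instead of
        fitting it.
    """
    if tc.time_hr.size < 4:
        raise ValueError("need at least 4 timepoints for the 2-state model")
    if np.any(tc.value <= 0):
        bad = tc.time_hr[tc.value <= 0]
        raise ValueError(
            f"cannot log-transform non-positive values at timepoints {bad.tolist()}"
        )
    logy = np.log(tc.value)

    if init is None:
        k_guess = max(fit_one_state(tc).params.k_decay, 0.1)
        init = KineticParams(
            model="two_state",
            k_mat=1.0,
            k_decay1=2.0 * k_guess,
            k_decay2=0.5 * k_guess,
            f0=1.0 if fix_f0 is None else fix_f0,
        )
    x0 = [init.k_mat, init.k_decay1, init.k_decay2]
    if fix_f0 is None:
        x0.append(min(max(init.f0, 1e-3), 1.0 - 1e-3))
    x0 = np.asarray(x0, dtype=float)
    x0[:3] = np.maximum(x0[:3], 1e-6)

    if bounds is None:
        lo = np.zeros(x0.size)
        hi = np.full(x0.size, np.inf)
        if fix_f0 is None:
            hi[3] = 1.0
        bounds = (lo, hi)

    rng = np.random.default_rng(seed)
    best = None
    n_ok = 0
    for i in range(max(n_starts, 1)):
        if i == 0:
            xi = x0.copy()
        else:
            xi = x0 * np.exp(rng.normal(0.0, 0.5, size=x0.size))
        xi = np.clip(xi, bounds[0] + 1e-12, np.where(np.isfinite(bounds[1]), bounds[1] - 1e-12, xi))
        try:
            sol = optimize.least_squares(
                _two_state_residuals,
                xi,
                bounds=bounds,
                args=(tc.time_hr, logy, fix_f0),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        if not sol.success:
            continue
        n_ok += 1
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("2-state fit failed to converge from any start")
    rss, sol = best

    names = ["k_mat", "k_decay1", "k_decay2"] + ([] if fix_f0 is not None else ["f0"])
    dof = max(tc.time_hr.size - sol.x.size, 1)
    s2 = rss / dof
    jtj = sol.jac.T @ sol.jac
    cov = np.linalg.pinv(jtj) * s2
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    stderr = dict(zip(names, se.tolist()))

    f0 = fix_f0 if fix_f0 is not None else float(sol.x[3])
    params = KineticParams(
        model="two_state",
        k_mat=float(sol.x[0]),
        k_decay1=float(sol.x[1]),
        k_decay2=float(sol.x[2]),
        f0=float(min(max(f0, 0.0), 1.0)),
    )
    return FitResult(
        params=params,
        stderr=stderr,
        rss_log=rss,
        time_hr=tc.time_hr.copy(),
        converged=True,
        n_starts=n_ok,
    )


def area_between_fits(fit1: FitResult, fit2: FitResult, interval: tuple[float, float]) -> float:
    """Time-normalized area between two fitted decay curves.

    Integrates |F1(t) - F2(t)| over ``interval`` by adaptive quadrature and
    divides by the interval length, so time courses of different durations
    are comparable.  The absolute difference is used because fitted curves
    may cross.
    """
    t0, t1 = float(interval[0]), float(interval[1])
    if t1 <= t0:
        raise ValueError("interval must have positive length")
    val, _ = integrate.quad(
        lambda t: abs(float(fit1.predict(t)) - float(fit2.predict(t))),
        t0,
        t1,
        limit=200,
    )
    return val / (t1 - t0)


def half_life_minutes(k_decay: float) -> float:
    """Convert a decay rate constant (hr^-1) to a half-life in minutes.

    half-life = ln(2)/k_decay hours, times 60.
    """
    if k_decay <= 0:
        raise ValueError(f"k_decay must be > 0, got {k_decay}")
    return math.log(2.0) / k_decay * 60.0


def fraction_remaining(half_life: float, elapsed: float) -> float:
    """Fraction of a species remaining after ``elapsed`` given its half-life.

    Both arguments share units (e.g. minutes); returns 2^(-elapsed/half_life).
    """
    if half_life <= 0:
        raise ValueError(f"half_life must be > 0, got {half_life}")
    return 2.0 ** (-elapsed / half_life)
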