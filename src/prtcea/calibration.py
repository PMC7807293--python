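"""Calibration of transition probabilities to survival target curves.

The published trial reports Kaplan-Meier overall-survival (OS) and
failure-free-survival (FFS) curves; here users supply them as plain tabular
(month, proportion) files, and free transition probabilities are fitted by a
derivative-free search (Nelder-Mead on logit-transformed probabilities)
minimizing the sum of squared deviations between the model's curves and the
targets.  The objective is evaluated on the exact Markov-occupancy
expectation, so it is smooth and noise-free; the fit should afterwards be
validated against the full microsimulation.

A synthetic-target generator produces OS/FFS curves from known parameters
(optionally perturbed by binomial sampling noise emulating trial arm sizes)
so that calibration can be tested by parameter recovery.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression, minimize

from .engine import cohort_expectation, simulate_cohort, hr_adjust_probability
from .params import ModelParameters, ModelSettings

OS = "overall_survival"
FFS = "failure_free_survival"
CURVE_KINDS = (OS, FFS)


# ---------------------------------------------------------------------------
# Target curves
# ---------------------------------------------------------------------------


@dataclass
class TargetCurve:
    """A survival-type curve: non-increasing proportions starting at 1."""

    kind: str
    arm: str
    times: np.ndarray        # months
    proportions: np.ndarray  # fraction surviving / failure-free

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"kind must be one of {CURVE_KINDS}; got {self.kind!r}")
        if self.times.shape != self.proportions.shape or self.times.ndim != 1:
            raise ValueError("times and proportions must be equal-length vectors")
        if self.times[0] != 0.0 or abs(self.proportions[0] - 1.0) > 1e-9:
            raise ValueError("curves must start at (time 0, proportion 1)")
        if np.any(np.diff(self.proportions) > 1e-9):
            raise ValueError("proportions must be non-increasing in time")
        if np.any((self.proportions < 0) | (self.proportions > 1)):
            raise ValueError("proportions must lie in [0, 1]")


def write_target_curve(path, curve: TargetCurve) -> None:
    """Write a curve as two-column CSV with a header naming kind and arm."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# kind={curve.kind} arm={curve.arm}\n")
        w = csv.writer(fh)
        w.writerow(["month", "proportion"])
        for t, p in zip(curve.times, curve.proportions):
            w.writerow([f"{t:g}", f"{p:.10g}"])


def read_target_curve(path) -> TargetCurve:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("missing '# kind=... arm=...' header line")
        meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
        rows = list(csv.DictReader(fh))
    return TargetCurve(
        kind=meta["kind"], arm=meta["arm"],
        times=np.array([float(r["month"]) for r in rows]),
        proportions=np.array([float(r["proportion"]) for r in rows]),
    )


# ---------------------------------------------------------------------------
# Model curves and synthetic targets
# ---------------------------------------------------------------------------


def model_curves(
    params: ModelParameters,
    settings: ModelSettings,
    *,
    arms=("adt", "prt"),
    horizon: int | None = None,
    n_trials: int | None = None,
    rng=None,
    overrides: dict | None = None,
) -> list[TargetCurve]:
    """OS and FFS curves per arm, on the monthly cycle grid.

    With ``n_trials`` unset the exact Markov expectation is used; otherwise
    the curves come from a microsimulated cohort of that size.
    """
    H = settings.horizon_cycles if horizon is None else horizon
    out = []
    for arm in arms:
        ov = (overrides or {}).get(arm)
        if n_trials is None:
            res = cohort_expectation(arm, params, settings, horizon=H, overrides=ov)
            os_curve, ffs_curve = res.os_curve, res.ffs_curve
        else:
            res = simulate_cohort(arm, params, settings, rng=rng,
                                  n_trials=n_trials, horizon=H, overrides=ov)
            os_curve, ffs_curve = res.alive_curve, res.ffs_curve
        times = np.arange(H, dtype=float)
        out.append(TargetCurve(OS, arm, times, os_curve))
        out.append(TargetCurve(FFS, arm, times, ffs_curve))
    return out


def _project_monotone(p: np.ndarray) -> np.ndarray:
    """Project onto non-increasing curves starting at 1 (isotonic, L2)."""
    res = isotonic_regression(-p, increasing=True)
    q = np.clip(-res.x, 0.0, 1.0)
    q[0] = 1.0
    return np.minimum.accumulate(q)


def generate_synthetic_targets(
    params: ModelParameters,
    settings: ModelSettings,
    *,
    arms=("adt", "prt"),
    horizon: int | None = None,
    noise: str = "none",
    n_at_risk: int = 410,
    rng: np.random.Generator | int | None = None,
) -> list[TargetCurve]:
    """Synthetic OS/FFS target curves from known parameters.

    ``noise="binomial"`` perturbs each point by binomial sampling with
    ``n_at_risk`` subjects (roughly one low-burden trial arm), then restores
    monotonicity by isotonic projection, emulating curves digitized from a
    published trial figure.
    """
    curves = model_curves(params, settings, arms=arms, horizon=horizon)
    if noise == "none":
        return curves
    if noise != "binomial":
        raise ValueError(f"noise must be 'none' or 'binomial'; got {noise!r}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    noisy = []
    for c in curves:
        p = rng.binomial(n_at_risk, c.proportions) / n_at_risk
        noisy.append(TargetCurve(c.kind, c.arm, c.times, _project_monotone(p)))
    return noisy


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

#: Model parameters the calibration may vary, and which arm-input field each
#: one drives (None = affects the PRT progression probability via the HR).
_CALIBRATABLE = {
    "p_progress_adt": "p_progress",
    "p_progress_prt": "p_progress",
    "p_death_stable": "p_death_stable",
    "p_death_progression": ("p_death_p1", "p_death_p2"),
    "p_prog1_to_prog2": "p_p1_to_p2",
}


@dataclass
class FreeParameter:
    """One calibrated quantity: a model parameter, piecewise-constant in time.

    ``breakpoints`` are cycle indices starting each constant segment; the
    default single segment reproduces a time-constant probability.
    """

    name: str
    breakpoints: tuple[int, ...] = (0,)
    init: float | None = None

    def __post_init__(self) -> None:
        if self.name not in _CALIBRATABLE:
            raise KeyError(
                f"{self.name!r} is not calibratable; choose from {sorted(_CALIBRATABLE)}"
            )
        if self.breakpoints[0] != 0 or list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing and start at 0")

    @property
    def n_segments(self) -> int:
        return len(self.breakpoints)

    def expand(self, values: np.ndarray, horizon: int) -> np.ndarray:
        """Per-cycle schedule from per-segment values."""
        out = np.empty(horizon)
        bps = list(self.breakpoints) + [horizon]
        for v, a, b in zip(values, bps[:-1], bps[1:]):
            out[a:b] = v
        return out


@dataclass
class CalibrationResult:
    free_parameters: list[FreeParameter]
    fitted: dict[str, np.ndarray]      # per-segment fitted probabilities
    schedules: dict[str, np.ndarray]   # per-cycle expansion of the above
    objective: float
    initial_objective: float
    converged: bool
    n_iterations: int
    trace: list[float] = field(default_factory=list)

    def apply(self, params: ModelParameters) -> ModelParameters:
        """Write constant fitted values back into a parameter bundle.

        Only defined when every free parameter used a single segment.
        """
        p = params.copy()
        for fp in self.free_parameters:
            vals = self.fitted[fp.name]
            if len(vals) != 1:
                raise ValueError(
                    f"{fp.name} was fitted piecewise; apply() needs constant fits"
                )
            p.set_value(fp.name, float(vals[0]))
        return p


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _build_overrides(
    free_parameters: list[FreeParameter],
    values: dict[str, np.ndarray],
    params: ModelParameters,
    horizon: int,
) -> dict[str, dict]:
    """Per-arm engine overrides implied by the current free-parameter values."""
    ov: dict[str, dict] = {"adt": {}, "prt": {}}
    schedules = {fp.name: fp.expand(values[fp.name], horizon) for fp in free_parameters}
    names = set(schedules)
    for name, sched in schedules.items():
        target = _CALIBRATABLE[name]
        if name == "p_progress_adt":
            ov["adt"]["p_progress"] = sched
            if params.hr_mode and "p_progress_prt" not in names:
                hr = params["hr_progression_prt"]
                ov["prt"]["p_progress"] = 1.0 - (1.0 - sched) ** hr
        elif name == "p_progress_prt":
            ov["prt"]["p_progress"] = sched
        elif name == "p_death_progression":
            for arm in ("adt", "prt"):
                ov[arm]["p_death_p1"] = sched
                ov[arm]["p_death_p2"] = sched
        else:
            for arm in ("adt", "prt"):
                ov[arm][target] = sched
    return ov


def calibrate(
    targets: list[TargetCurve],
    free_parameters: list[FreeParameter | str],
    params: ModelParameters,
    settings: ModelSettings,
    *,
    maxiter: int = 2000,
    tol: float = 1e-10,
) -> CalibrationResult:
    """Fit free transition probabilities to target OS/FFS curves.

    The objective is the equally weighted sum of squared deviations between
    the model's exact (Markov-expectation) curves and every target curve, at
    the target time points.  Optimization is Nelder-Mead on logit-transformed
    per-segment probabilities, so fitted values stay in (0, 1) by
    construction and the objective trace is non-increasing over accepted
    simplex moves.
    """
    if not targets:
        raise ValueError("need at least one target curve")
    if not free_parameters:
        raise ValueError("need at least one free parameter")
    fps = [fp if isinstance(fp, FreeParameter) else FreeParameter(fp) for fp in free_parameters]
    horizon = int(max(c.times.max() for c in targets)) + 1
    arms = sorted({c.arm for c in targets})

    x0 = []
    for fp in fps:
        init = fp.init if fp.init is not None else params[fp.name]
        x0.extend([_logit(init)] * fp.n_segments)
    x0 = np.asarray(x0)

    def unpack(x: np.ndarray) -> dict[str, np.ndarray]:
        out, i = {}, 0
        for fp in fps:
            out[fp.name] = _expit(x[i:i + fp.n_segments])
            i += fp.n_segments
        return out

    def objective(x: np.ndarray) -> float:
        ov = _build_overrides(fps, unpack(x), params, horizon)
        sse = 0.0
        for arm in arms:
            res = cohort_expectation(arm, params, settings, horizon=horizon,
                                     overrides=ov[arm])
            for c in targets:
                if c.arm != arm:
                    continue
                model = res.os_curve if c.kind == OS else res.ffs_curve
                idx = c.times.astype(int)
                sse += float(np.sum((model[idx] - c.proportions) ** 2))
        return sse

    trace: list[float] = []
    best = np.inf

    def cb(x):
        nonlocal best
        f = objective(x)
        best = min(best, f)
        trace.append(best)

    f0 = objective(x0)
    res = minimize(objective, x0, method="Nelder-Mead", callback=cb,
                   options={"maxiter": maxiter, "fatol": tol, "xatol": 1e-8})
    values = unpack(res.x)
    return CalibrationResult(
        free_parameters=fps,
        fitted=values,
        schedules={fp.name: fp.expand(values[fp.name], horizon) for fp in fps},
        objective=float(res.fun),
        initial_objective=f0,
        converged=bool(res.success),
        n_iterations=int(res.nit),
        trace=trace,
    )
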