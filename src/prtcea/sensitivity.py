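"""One-way deterministic sensitivity analysis, threshold search, scenarios.

Sweeps vary one named input over a grid while holding everything else at the
base case; each grid point reruns the full two-arm model with a fixed seed so
that adjacent points differ only through the swept parameter.  Threshold
detection bisects for the parameter value at which the dominance criterion
flips, evaluated on smoothed (large-n fixed-seed or exact-expectation)
outputs to suppress Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import CEComparison, DOMINANT, run_comparison
from .params import ModelParameters, ModelSettings

SCENARIOS = ("weekly_prt", "upfront_abiraterone", "lifetime")

#: Trials per evaluation for threshold searches (smoothed MC mode).
THRESHOLD_N_TRIALS = 100_000


def _with_value(params: ModelParameters, name: str, value: float) -> ModelParameters:
    p = params.copy()
    p.set_value(name, value)
    return p


@dataclass
class SweepResult:
    parameter: str
    grid: np.ndarray
    comparisons: list[CEComparison]
    thresholds: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([c.to_dict() for c in self.comparisons])
        df.insert(0, self.parameter, self.grid)
        return df


def one_way_sweep(
    parameter: str,
    lo: float,
    hi: float,
    n_points: int,
    params: ModelParameters,
    settings: ModelSettings,
    *,
    n_trials: int | None = None,
    method: str = "mc",
) -> SweepResult:
    """Sweep one parameter over a uniform grid, re-running the model per point.

    Thresholds are recorded wherever the dominance class changes between
    adjacent grid points (located by linear interpolation of the incremental
    cost when the flip is a cost-sign change).
    """
    if parameter not in set(params.names()) | {"p_death_progression1", "p_death_progression2"}:
        raise KeyError(f"unknown parameter {parameter!r}")
    if lo > hi:
        raise ValueError("lo must be <= hi")
    grid = np.linspace(lo, hi, n_points)
    comparisons = []
    for v in grid:
        comp, _, _ = run_comparison(
            _with_value(params, parameter, float(v)), settings,
            n_trials=n_trials, seed=settings.rng_seed, method=method,
        )
        comparisons.append(comp)
    thresholds = []
    for i in range(1, len(grid)):
        a, b = comparisons[i - 1], comparisons[i]
        if a.dominance != b.dominance:
            if (a.delta_cost < 0) != (b.delta_cost < 0) and b.delta_cost != a.delta_cost:
                frac = -a.delta_cost / (b.delta_cost - a.delta_cost)
            else:
                frac = 0.5
            thresholds.append(float(grid[i - 1] + frac * (grid[i] - grid[i - 1])))
    return SweepResult(parameter=parameter, grid=grid, comparisons=comparisons,
                       thresholds=thresholds)


def find_threshold(
    parameter: str,
    lo: float,
    hi: float,
    params: ModelParameters,
    settings: ModelSettings,
    *,
    criterion=None,
    tol: float = 1e-3,
    n_trials: int = THRESHOLD_N_TRIALS,
    method: str = "mc",
) -> float | None:
    """Bisect for the parameter value where ``criterion`` flips.

    The default criterion is strategy dominance (incremental cost < 0 and
    incremental QALYs > 0).  Every evaluation reuses the same seed and a
    large cohort so the criterion is effectively deterministic in the
    parameter.  Returns ``None`` when the criterion does not differ between
    the interval ends (no threshold inside the interval).
    """
    if criterion is None:
        criterion = lambda comp: comp.dominance == DOMINANT

    def ok(value: float) -> bool:
        comp, _, _ = run_comparison(
            _with_value(params, parameter, value), settings,
            n_trials=n_trials, seed=settings.rng_seed, method=method,
        )
        return bool(criterion(comp))

    lo_ok, hi_ok = ok(lo), ok(hi)
    if lo_ok == hi_ok:
        return None
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if ok(mid) == lo_ok:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def scenario_inputs(
    name: str, params: ModelParameters, settings: ModelSettings
) -> tuple[ModelParameters, ModelSettings]:
    """Parameter/settings bundle for one named scenario analysis."""
    p = params.copy()
    s = settings.copy()
    if name == "weekly_prt":
        # 6 weekly 6 Gy fractions: the cheap end of the radiation cost range;
        # the treatment period spans two monthly cycles.
        p.set_value("c_prt_once", p.params["c_prt_once"].lo)
        s = s.copy(prt_treatment_cycles=2)
    elif name == "upfront_abiraterone":
        s = s.copy(upfront_abiraterone=True)
    elif name == "lifetime":
        s = s.copy(horizon_cycles=s.lifetime_cap_cycles)
    else:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    return p, s


def run_scenario(
    name: str,
    params: ModelParameters,
    settings: ModelSettings,
    *,
    n_trials: int | None = None,
    seed: int | None = None,
) -> CEComparison:
    """Run one named scenario and return its two-arm comparison."""
    p, s = scenario_inputs(name, params, settings)
    comp, _, _ = run_comparison(p, s, n_trials=n_trials, seed=seed)
    return comp


def tornado(
    params: ModelParameters,
    settings: ModelSettings,
    *,
    output: str = "nmb_at_wtp",
    n_trials: int | None = None,
    method: str = "expectation",
) -> pd.DataFrame:
    """Tornado table: output at each uncertain parameter's range ends.

    Rows are sorted by descending output range, so the first row is the
    parameter the model is most sensitive to.
    """
    rows = []
    for name, par in params.params.items():
        if par.lo is None or par.hi is None:
            continue
        vals = {}
        for side, v in (("low", par.lo), ("high", par.hi)):
            comp, _, _ = run_comparison(
                _with_value(params, name, v), settings,
                n_trials=n_trials, seed=settings.rng_seed, method=method,
            )
            vals[side] = getattr(comp, output)
        rows.append({
            "parameter": name, "lo": par.lo, "hi": par.hi,
            "output_low": vals["low"], "output_high": vals["high"],
            "range": abs(vals["high"] - vals["low"]),
        })
    return (
        pd.DataFrame(rows)
        .sort_values("range", ascending=False, ignore_index=True)
    )
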