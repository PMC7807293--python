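"""Probabilistic sensitivity analysis (PSA).

Every uncertain input is drawn from its fitted beta/gamma distribution, the
two-arm model is rerun per draw, and the resulting cloud of incremental
(cost, QALY) pairs summarizes decision uncertainty: the cost-effectiveness
plane, quadrant fractions, and the acceptability curve (probability of a
positive net monetary benefit as a function of willingness to pay).

Two uncertainty levels are explicit: ``n_outer`` parameter draws times
``n_inner`` simulated patients per arm per draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import classify
from .engine import simulate_cohort
from .params import ModelParameters, ModelSettings


@dataclass
class PSAResult:
    """Outer-draw table plus the design metadata needed to interpret it.

    ``draws`` has one row per outer draw: every sampled parameter value,
    per-arm mean cost/QALYs, the incremental pair, NMB at the design WTP and
    the dominance class.
    """

    draws: pd.DataFrame
    wtp: float
    n_outer: int
    n_inner: int
    fixed: dict = field(default_factory=dict)

    # -- summaries ----------------------------------------------------------

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        """Fraction of draws with positive net monetary benefit at ``wtp``."""
        w = self.wtp if wtp is None else wtp
        nmb = w * self.draws["delta_qalys"] - self.draws["delta_cost"]
        return float((nmb > 0).mean())

    def summary(self) -> dict:
        """Means with percentile 95% intervals across outer draws."""
        out = {}
        for col in ("cost_adt", "qalys_adt", "cost_prt", "qalys_prt",
                    "delta_cost", "delta_qalys"):
            v = self.draws[col].to_numpy()
            out[col] = {
                "mean": float(v.mean()),
                "ci95": (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))),
            }
        out["prob_cost_effective"] = self.prob_cost_effective()
        out["wtp"] = self.wtp
        out["n_outer"] = self.n_outer
        out["n_inner"] = self.n_inner
        return out


def run_psa(
    params: ModelParameters,
    settings: ModelSettings,
    *,
    n_outer: int = 10_000,
    n_inner: int = 1_000,
    seed: int | None = None,
    fixed: dict[str, float] | None = None,
    horizon: int | None = None,
) -> PSAResult:
    """Sample parameters, rerun the two-arm model per draw, collect outputs.

    ``fixed`` pins named parameters at given values (they are not sampled);
    this is how the scenario rows fixing the progression hazard ratio are
    produced.  All other uncertain parameters are drawn independently from
    their fitted distributions.  Arms use independent random streams per
    draw; everything is reproducible from ``seed``.
    """
    if n_outer < 1 or n_inner < 1:
        raise ValueError("n_outer and n_inner must both be >= 1")
    fixed = dict(fixed or {})
    base = params.copy()
    for name, value in fixed.items():
        base.set_value(name, value)

    dists = base.distributions()
    # the PRT progression probability is derived through the hazard ratio
    # whenever hr_mode is on, so its marginal distribution is not sampled
    if base.hr_mode:
        dists.pop("p_progress_prt", None)
    for name in fixed:
        dists.pop(name, None)

    ss = np.random.SeedSequence(settings.rng_seed if seed is None else seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    sampled = {name: dist.rvs(param_rng, size=n_outer) for name, dist in dists.items()}

    rows = []
    arm_seeds = ss.spawn(n_outer)
    for i in range(n_outer):
        p = base.copy()
        for name in sampled:
            p.set_value(name, float(sampled[name][i]))
        sa, sb = arm_seeds[i].spawn(2)
        ra = simulate_cohort("adt", p, settings, rng=np.random.default_rng(sa),
                             n_trials=n_inner, horizon=horizon)
        rb = simulate_cohort("prt", p, settings, rng=np.random.default_rng(sb),
                             n_trials=n_inner, horizon=horizon)
        dc = rb.mean_cost - ra.mean_cost
        dq = rb.mean_qalys - ra.mean_qalys
        icer, dominance = classify(dc, dq, settings.wtp)
        row = {name: sampled[name][i] for name in sampled}
        row.update(
            cost_adt=ra.mean_cost, qalys_adt=ra.mean_qalys,
            cost_prt=rb.mean_cost, qalys_prt=rb.mean_qalys,
            delta_cost=dc, delta_qalys=dq, icer=icer, dominance=dominance,
            nmb=settings.wtp * dq - dc,
        )
        rows.append(row)

    return PSAResult(
        draws=pd.DataFrame(rows), wtp=settings.wtp,
        n_outer=n_outer, n_inner=n_inner, fixed=fixed,
    )


def ce_plane(result: PSAResult) -> tuple[pd.DataFrame, dict[str, float]]:
    """Cost-effectiveness-plane scatter data and quadrant fractions.

    Quadrants are named from the PRT-minus-ADT orientation:
    ``dominant`` (more QALYs, lower cost), ``trade_off_ne`` (more QALYs,
    higher cost), ``dominated`` (fewer QALYs, higher cost) and
    ``trade_off_sw`` (fewer QALYs, lower cost).
    """
    if len(result.draws) == 0:
        raise ValueError("need at least one draw")
    pts = result.draws[["delta_qalys", "delta_cost"]].copy()
    dq = pts["delta_qalys"].to_numpy()
    dc = pts["delta_cost"].to_numpy()
    n = len(pts)
    quadrants = {
        "dominant": float(((dq >= 0) & (dc < 0)).sum() / n),
        "trade_off_ne": float(((dq >= 0) & (dc >= 0)).sum() / n),
        "dominated": float(((dq < 0) & (dc >= 0)).sum() / n),
        "trade_off_sw": float(((dq < 0) & (dc < 0)).sum() / n),
    }
    return pts, quadrants


def ceac(result: PSAResult, wtp_grid) -> pd.DataFrame:
    """Acceptability curve: P(NMB > 0) at each willingness-to-pay value."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if np.any(wtp_grid < 0):
        raise ValueError("wtp values must be non-negative")
    dq = result.draws["delta_qalys"].to_numpy()
    dc = result.draws["delta_cost"].to_numpy()
    prob = [(w * dq - dc > 0).mean() for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": prob})
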