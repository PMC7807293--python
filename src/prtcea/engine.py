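"""Individual-level microsimulation engine.

Patients move monthly through four health states::

    STABLE -> PROGRESSION1 -> PROGRESSION2 -> DEAD
       \\___________ \\______________ \\________^

Progression 1 is progression after initial treatment (patients start monthly
abiraterone); progression 2 is progression after abiraterone (second-line
systemic therapy).  DEAD is absorbing.  In the PRT arm, grade >=2
genitourinary and gastrointestinal radiation toxicity is followed with
per-patient trackers: each fires at most once, carries a one-time cost at
onset, and lowers utility from onset onward.

Accrual conventions (shared by the scalar, vectorized and closed-form paths):

* cycle ``t`` accrues the cost and utility of the state occupied at its
  start, discounted by ``(1+r)^(-t/12)``;
* toxicity draws happen at the start of each alive PRT-arm cycle and take
  effect in that same cycle;
* the transition at the end of cycle ``t`` determines the state of cycle
  ``t+1``; no transition is drawn after the final cycle of the horizon;
* the one-time death cost is booked in the cycle whose transition fired,
  i.e. at the discount factor of the last alive cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .params import ModelParameters, ModelSettings, ARMS


class HealthState(IntEnum):
    STABLE = 0
    PROGRESSION1 = 1
    PROGRESSION2 = 2
    DEAD = 3


#: Allowed one-cycle moves; DEAD is absorbing.
ALLOWED_TRANSITIONS = {
    HealthState.STABLE: {HealthState.STABLE, HealthState.PROGRESSION1, HealthState.DEAD},
    HealthState.PROGRESSION1: {HealthState.PROGRESSION1, HealthState.PROGRESSION2, HealthState.DEAD},
    HealthState.PROGRESSION2: {HealthState.PROGRESSION2, HealthState.DEAD},
    HealthState.DEAD: {HealthState.DEAD},
}


def hr_adjust_probability(p: float, hr: float) -> float:
    """Apply a hazard ratio to a per-cycle probability on the rate scale.

    The per-cycle probability is converted to a rate, scaled by ``hr``, and
    converted back: ``1 - (1 - p)**hr``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1]; got {p}")
    if hr <= 0.0:
        raise ValueError(f"hazard ratio must be > 0; got {hr}")
    if p == 1.0:
        if hr != 1.0:
            raise ValueError("p = 1 has an infinite rate; hazard ratio undefined")
        return 1.0
    return 1.0 - (1.0 - p) ** hr


def discount_factor(cycle, annual_rate: float):
    """Discount factor ``(1 + r)^(-cycle/12)`` for a monthly cycle index."""
    cycle = np.asarray(cycle)
    if np.any(cycle < 0):
        raise ValueError("cycle must be >= 0")
    return (1.0 + annual_rate) ** (-cycle / 12.0)


# ---------------------------------------------------------------------------
# Resolved per-arm inputs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArmInputs:
    """All scalars the simulation of one arm needs, fully resolved."""

    arm: str
    p_progress: float
    p_death_stable: float
    p_death_p1: float
    p_death_p2: float
    p_p1_to_p2: float
    p_tox_gu: float
    p_tox_gi: float
    u_stable: float            # stable-state utility after any treatment period
    u_stable_treatment: float  # stable-state utility during the treatment period
    treatment_cycles: int      # cycles for which u_stable_treatment applies
    u_tox_gi: float
    u_tox_gu: float
    u_tox_both: float
    u_p1: float
    u_p2: float
    c_once: float              # one-time cycle-0 cost (PRT course)
    c_monthly: float           # every alive cycle (ADT backbone +- upfront abiraterone)
    c_p1: float
    c_p2: float
    c_death: float
    c_tox: float

    def stable_utility(self, cycle: int) -> float:
        if cycle < self.treatment_cycles:
            return self.u_stable_treatment
        return self.u_stable


def resolve_arm(arm: str, params: ModelParameters, settings: ModelSettings) -> ArmInputs:
    """Resolve the parameter bundle into the concrete inputs for one arm."""
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}; got {arm!r}")
    prt = arm == "prt"
    if prt:
        if settings.prt_utility_mode == "persistent":
            u_stable = params["u_stable_prt"]
            treatment_cycles = 0
        else:
            u_stable = params["u_stable_adt"]
            treatment_cycles = settings.prt_treatment_cycles
    else:
        u_stable = params["u_stable_adt"]
        treatment_cycles = 0
    c_monthly = params["c_adt_monthly"]
    return ArmInputs(
        arm=arm,
        p_progress=params.progression_probability(arm),
        p_death_stable=params["p_death_stable"],
        p_death_p1=params.death_progression(1),
        p_death_p2=params.death_progression(2),
        p_p1_to_p2=params["p_prog1_to_prog2"],
        p_tox_gu=params["p_tox_gu"] if prt else 0.0,
        p_tox_gi=params["p_tox_gi"] if prt else 0.0,
        u_stable=u_stable,
        u_stable_treatment=params["u_stable_prt"] if prt else u_stable,
        treatment_cycles=treatment_cycles,
        u_tox_gi=params["u_tox_gi"],
        u_tox_gu=params["u_tox_gu"],
        u_tox_both=params["u_tox_both"],
        u_p1=params["u_progression1"],
        u_p2=params["u_progression2"],
        c_once=params["c_prt_once"] if prt else 0.0,
        c_monthly=c_monthly,
        c_p1=params["c_progression1_monthly"],
        c_p2=params["c_progression2_monthly"],
        c_death=params["c_death_once"],
        c_tox=params["c_tox_once"],
    )


#: ArmInputs fields that may carry a per-cycle schedule instead of a scalar.
SCHEDULABLE_FIELDS = (
    "p_progress", "p_death_stable", "p_death_p1", "p_death_p2", "p_p1_to_p2",
)


def apply_overrides(inputs: ArmInputs, overrides: dict | None) -> ArmInputs:
    """Replace resolved arm inputs with scalar or per-cycle-array values.

    Calibration uses this to evaluate piecewise-constant transition
    probabilities without touching the parameter bundle.
    """
    if not overrides:
        return inputs
    unknown = set(overrides) - set(SCHEDULABLE_FIELDS)
    if unknown:
        raise KeyError(f"cannot override field(s) {sorted(unknown)}")
    import dataclasses

    return dataclasses.replace(
        inputs, **{k: (np.asarray(v, dtype=float) if np.ndim(v) else float(v))
                   for k, v in overrides.items()}
    )


def _schedule(x, H: int) -> np.ndarray:
    """Expand a scalar or partial per-cycle array to length ``H`` cycles."""
    if np.ndim(x) == 0:
        return np.full(H, float(x))
    x = np.asarray(x, dtype=float)
    if len(x) >= H:
        return x[:H]
    return np.concatenate([x, np.full(H - len(x), x[-1])])


def _upfront_abi_cost(params: ModelParameters, settings: ModelSettings) -> float:
    # Upfront-abiraterone scenario: abiraterone (priced as the progression-1
    # monthly cost) is given during the stable state in both arms.
    return params["c_progression1_monthly"] if settings.upfront_abiraterone else 0.0


# ---------------------------------------------------------------------------
# Per-cycle utility and cost (scalar contracts)
# ---------------------------------------------------------------------------


def _tox_utility(tox_gu: bool, tox_gi: bool, inputs: ArmInputs) -> float:
    if tox_gu and tox_gi:
        return inputs.u_tox_both
    if tox_gi:
        return inputs.u_tox_gi
    if tox_gu:
        return inputs.u_tox_gu
    return 1.0


def utility_for_cycle(
    state: HealthState,
    inputs: ArmInputs,
    cycle: int,
    tox_gu: bool = False,
    tox_gi: bool = False,
) -> float:
    """Utility weight for one alive cycle.

    Toxicity combines with the state utility by ``min`` (the joint
    GI+GU value is an explicitly elicited weight, not a product).
    """
    if state == HealthState.DEAD:
        raise ValueError("dead patients have no utility accrual")
    tox = _tox_utility(tox_gu, tox_gi, inputs)
    if state == HealthState.STABLE:
        return min(inputs.stable_utility(cycle), tox)
    if state == HealthState.PROGRESSION1:
        return min(inputs.u_p1, tox)
    return min(inputs.u_p2, tox)


def cost_for_cycle(
    state: HealthState,
    inputs: ArmInputs,
    cycle: int,
    *,
    n_tox_onsets: int = 0,
    death_this_cycle: bool = False,
    upfront_abi_cost: float = 0.0,
) -> float:
    """Undiscounted cost booked in one alive cycle.

    Sums the one-time treatment cost at cycle 0, the monthly systemic-therapy
    backbone, state-specific monthly drug costs, toxicity onset costs, and the
    one-time end-of-life cost when the death transition fires this cycle.
    """
    total = inputs.c_monthly
    if cycle == 0:
        total += inputs.c_once
    if state == HealthState.STABLE:
        total += upfront_abi_cost
    elif state == HealthState.PROGRESSION1:
        total += inputs.c_p1
    elif state == HealthState.PROGRESSION2:
        total += inputs.c_p2
    total += n_tox_onsets * inputs.c_tox
    if death_this_cycle:
        total += inputs.c_death
    return total


# ---------------------------------------------------------------------------
# Scalar patient simulation
# ---------------------------------------------------------------------------


@dataclass
class PatientTrajectory:
    state_path: list
    tox_gu: bool
    tox_gi: bool
    tox_gu_cycle: int | None
    tox_gi_cycle: int | None
    discounted_cost: float
    discounted_qalys: float
    death_cycle: int | None  # None = alive at horizon


def simulate_patient(
    arm: str,
    params: ModelParameters,
    settings: ModelSettings,
    rng: np.random.Generator,
    horizon: int | None = None,
) -> PatientTrajectory:
    """Simulate a single patient; readable reference for the vectorized path."""
    inputs = resolve_arm(arm, params, settings)
    abi = _upfront_abi_cost(params, settings)
    H = settings.horizon_cycles if horizon is None else horizon
    state = HealthState.STABLE
    path = [state]
    tox_gu = tox_gi = False
    gu_cycle = gi_cycle = None
    cost = qalys = 0.0
    death_cycle = None
    for t in range(H):
        if state == HealthState.DEAD:
            path.append(state)
            continue
        df = float(discount_factor(t, settings.annual_discount_rate))
        n_onsets = 0
        if inputs.p_tox_gu > 0 and not tox_gu and rng.random() < inputs.p_tox_gu:
            tox_gu, gu_cycle, n_onsets = True, t, n_onsets + 1
        if inputs.p_tox_gi > 0 and not tox_gi and rng.random() < inputs.p_tox_gi:
            tox_gi, gi_cycle, n_onsets = True, t, n_onsets + 1
        qalys += utility_for_cycle(state, inputs, t, tox_gu, tox_gi) / 12.0 * df
        died = False
        new_state = state
        if t < H - 1:
            u = rng.random()
            if state == HealthState.STABLE:
                if u < inputs.p_progress:
                    new_state = HealthState.PROGRESSION1
                elif u < inputs.p_progress + inputs.p_death_stable:
                    new_state = HealthState.DEAD
            elif state == HealthState.PROGRESSION1:
                if u < inputs.p_p1_to_p2:
                    new_state = HealthState.PROGRESSION2
                elif u < inputs.p_p1_to_p2 + inputs.p_death_p1:
                    new_state = HealthState.DEAD
            else:
                if u < inputs.p_death_p2:
                    new_state = HealthState.DEAD
            died = new_state == HealthState.DEAD
        cost += df * cost_for_cycle(
            state, inputs, t,
            n_tox_onsets=n_onsets, death_this_cycle=died, upfront_abi_cost=abi,
        )
        if t < H - 1:
            if died:
                death_cycle = t + 1
            state = new_state
            path.append(state)
    return PatientTrajectory(
        state_path=path, tox_gu=tox_gu, tox_gi=tox_gi,
        tox_gu_cycle=gu_cycle, tox_gi_cycle=gi_cycle,
        discounted_cost=cost, discounted_qalys=qalys, death_cycle=death_cycle,
    )


# ---------------------------------------------------------------------------
# Vectorized cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    """Monte-Carlo cohort outcome for one strategy arm."""

    arm: str
    n_trials: int
    horizon: int
    cost_trials: np.ndarray
    qaly_trials: np.ndarray
    alive_curve: np.ndarray  # proportion alive at the start of each cycle
    ffs_curve: np.ndarray    # proportion alive and still stable
    tox_gu_incidence: float
    tox_gi_incidence: float

    @property
    def mean_cost(self) -> float:
        return float(self.cost_trials.mean())

    @property
    def mean_qalys(self) -> float:
        return float(self.qaly_trials.mean())

    @property
    def se_cost(self) -> float:
        if self.n_trials < 2:
            return float("nan")
        return float(self.cost_trials.std(ddof=1) / np.sqrt(self.n_trials))

    @property
    def se_qalys(self) -> float:
        if self.n_trials < 2:
            return float("nan")
        return float(self.qaly_trials.std(ddof=1) / np.sqrt(self.n_trials))

    @property
    def ci_cost(self) -> tuple[float, float]:
        return (self.mean_cost - 1.96 * self.se_cost, self.mean_cost + 1.96 * self.se_cost)

    @property
    def ci_qalys(self) -> tuple[float, float]:
        return (self.mean_qalys - 1.96 * self.se_qalys, self.mean_qalys + 1.96 * self.se_qalys)


def simulate_cohort(
    arm: str,
    params: ModelParameters,
    settings: ModelSettings,
    rng: np.random.Generator | int | None = None,
    n_trials: int | None = None,
    horizon: int | None = None,
    overrides: dict | None = None,
    force_tox_draws: bool = False,
) -> CohortResult:
    """Simulate a cohort of independent patients through one strategy arm.

    Vectorized over patients; bit-reproducible for a given seed and size.
    The returned survival (alive) curve is the per-cycle proportion of
    patients not yet dead, evaluated at the start of each cycle.
    ``overrides`` may replace transition probabilities with scalars or
    per-cycle schedules (see :func:`apply_overrides`).

    ``force_tox_draws`` makes an arm without toxicity consume the same
    number of random draws per cycle as the PRT arm, so that two arms run
    from identical generator states see identical transition uniforms
    (common random numbers).
    """
    inputs = apply_overrides(resolve_arm(arm, params, settings), overrides)
    abi = _upfront_abi_cost(params, settings)
    n = settings.n_trials if n_trials is None else n_trials
    H = settings.horizon_cycles if horizon is None else horizon
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(settings.rng_seed if rng is None else rng)

    STABLE, P1, P2, DEAD = 0, 1, 2, 3
    state = np.zeros(n, dtype=np.int8)
    cost = np.zeros(n)
    qalys = np.zeros(n)
    tox_gu = np.zeros(n, dtype=bool)
    tox_gi = np.zeros(n, dtype=bool)
    alive_curve = np.zeros(H)
    ffs_curve = np.zeros(H)
    dfs = discount_factor(np.arange(H), settings.annual_discount_rate)
    prt_arm = inputs.p_tox_gu > 0 or inputs.p_tox_gi > 0 or force_tox_draws
    pp_s = _schedule(inputs.p_progress, H)
    ds_s = _schedule(inputs.p_death_stable, H)
    d1_s = _schedule(inputs.p_death_p1, H)
    d2_s = _schedule(inputs.p_death_p2, H)
    q_s = _schedule(inputs.p_p1_to_p2, H)
    if np.any(pp_s + ds_s > 1.0) or np.any(q_s + d1_s > 1.0):
        raise ValueError("competing per-cycle probabilities exceed 1 in one state")

    for t in range(H):
        alive = state != DEAD
        n_alive = int(alive.sum())
        alive_curve[t] = n_alive / n
        ffs_curve[t] = int((state == STABLE).sum()) / n
        if n_alive == 0:
            continue
        df = dfs[t]
        if prt_arm:
            draws = rng.random((2, n))
            new_gu = alive & ~tox_gu & (draws[0] < inputs.p_tox_gu)
            new_gi = alive & ~tox_gi & (draws[1] < inputs.p_tox_gi)
            tox_gu |= new_gu
            tox_gi |= new_gi
            cost += (new_gu.astype(float) + new_gi.astype(float)) * inputs.c_tox * df

        # utilities: toxicity combines with the state utility by min()
        tox_u = np.where(
            tox_gu & tox_gi, inputs.u_tox_both,
            np.where(tox_gi, inputs.u_tox_gi, np.where(tox_gu, inputs.u_tox_gu, 1.0)),
        )
        u_stable_t = inputs.stable_utility(t)
        u = np.where(
            state == STABLE, np.minimum(u_stable_t, tox_u),
            np.where(
                state == P1, np.minimum(inputs.u_p1, tox_u),
                np.minimum(inputs.u_p2, tox_u),
            ),
        )
        qalys += np.where(alive, u, 0.0) / 12.0 * df

        c = np.where(
            state == STABLE, inputs.c_monthly + abi,
            np.where(state == P1, inputs.c_monthly + inputs.c_p1,
                     inputs.c_monthly + inputs.c_p2),
        )
        if t == 0:
            c = c + inputs.c_once
        cost += np.where(alive, c, 0.0) * df

        if t < H - 1:
            r = rng.random(n)
            is_s = alive & (state == STABLE)
            is_p1 = alive & (state == P1)
            is_p2 = alive & (state == P2)
            to_p1 = is_s & (r < pp_s[t])
            die_s = is_s & ~to_p1 & (r < pp_s[t] + ds_s[t])
            to_p2 = is_p1 & (r < q_s[t])
            die_p1 = is_p1 & ~to_p2 & (r < q_s[t] + d1_s[t])
            die_p2 = is_p2 & (r < d2_s[t])
            died = die_s | die_p1 | die_p2
            cost += died.astype(float) * inputs.c_death * df
            state[to_p1] = P1
            state[to_p2] = P2
            state[died] = DEAD

    return CohortResult(
        arm=arm,
        n_trials=n,
        horizon=H,
        cost_trials=cost,
        qaly_trials=qalys,
        alive_curve=alive_curve,
        ffs_curve=ffs_curve,
        tox_gu_incidence=float(tox_gu.mean()),
        tox_gi_incidence=float(tox_gi.mean()),
    )


# ---------------------------------------------------------------------------
# Closed-form cohort expectation (Markov occupancy)
# ---------------------------------------------------------------------------


@dataclass
class ExpectedOutcome:
    """Exact expected outcome of the simulation model for one arm."""

    arm: str
    horizon: int
    cost: float
    qalys: float
    os_curve: np.ndarray
    ffs_curve: np.ndarray


def transition_matrix(inputs: ArmInputs) -> np.ndarray:
    """One-cycle transition matrix over (STABLE, P1, P2, DEAD)."""
    p, ds = inputs.p_progress, inputs.p_death_stable
    q, d1, d2 = inputs.p_p1_to_p2, inputs.p_death_p1, inputs.p_death_p2
    if p + ds > 1.0 or q + d1 > 1.0:
        raise ValueError("competing per-cycle probabilities exceed 1 in one state")
    return np.array([
        [1.0 - p - ds, p, 0.0, ds],
        [0.0, 1.0 - q - d1, q, d1],
        [0.0, 0.0, 1.0 - d2, d2],
        [0.0, 0.0, 0.0, 1.0],
    ])


def cohort_expectation(
    arm: str,
    params: ModelParameters,
    settings: ModelSettings,
    horizon: int | None = None,
    include_toxicity: bool = True,
    overrides: dict | None = None,
) -> ExpectedOutcome:
    """Expected discounted cost/QALYs and OS/FFS curves, computed exactly.

    This is the deterministic counterpart of :func:`simulate_cohort`: state
    occupancy evolves by the one-cycle transition matrix, and because
    toxicity draws are independent of the disease process, their expected
    cost and utility effect can be folded in exactly.  Used for calibration
    (smooth, noise-free objective) and as an oracle for the microsimulation.
    """
    inputs = apply_overrides(resolve_arm(arm, params, settings), overrides)
    abi = _upfront_abi_cost(params, settings)
    H = settings.horizon_cycles if horizon is None else horizon
    pp_s = _schedule(inputs.p_progress, H)
    ds_s = _schedule(inputs.p_death_stable, H)
    d1_s = _schedule(inputs.p_death_p1, H)
    d2_s = _schedule(inputs.p_death_p2, H)
    q_s = _schedule(inputs.p_p1_to_p2, H)
    if np.any(pp_s + ds_s > 1.0) or np.any(q_s + d1_s > 1.0):
        raise ValueError("competing per-cycle probabilities exceed 1 in one state")
    occ = np.zeros(4)
    occ[0] = 1.0
    dfs = discount_factor(np.arange(H), settings.annual_discount_rate)
    cost = 0.0
    qalys = 0.0
    os_curve = np.zeros(H)
    ffs_curve = np.zeros(H)
    pgu, pgi = inputs.p_tox_gu, inputs.p_tox_gi
    with_tox = include_toxicity and (pgu > 0 or pgi > 0)

    for t in range(H):
        alive = 1.0 - occ[3]
        os_curve[t] = alive
        ffs_curve[t] = occ[0]
        df = dfs[t]
        u_stable_t = inputs.stable_utility(t)
        if with_tox:
            # P(tracker active at cycle t): one draw per alive cycle 0..t,
            # effective in the onset cycle; independent of the disease path.
            a_gu = 1.0 - (1.0 - pgu) ** (t + 1)
            a_gi = 1.0 - (1.0 - pgi) ** (t + 1)
            p_both = a_gu * a_gi
            p_gu_only = a_gu * (1.0 - a_gi)
            p_gi_only = a_gi * (1.0 - a_gu)
            p_none = (1.0 - a_gu) * (1.0 - a_gi)

            def mean_u(base: float) -> float:
                return (
                    p_none * base
                    + p_gu_only * min(base, inputs.u_tox_gu)
                    + p_gi_only * min(base, inputs.u_tox_gi)
                    + p_both * min(base, inputs.u_tox_both)
                )

            eu = (
                occ[0] * mean_u(u_stable_t)
                + occ[1] * mean_u(inputs.u_p1)
                + occ[2] * mean_u(inputs.u_p2)
            )
            onset = pgu * (1.0 - pgu) ** t + pgi * (1.0 - pgi) ** t
            cost += df * alive * onset * inputs.c_tox
        else:
            eu = occ[0] * u_stable_t + occ[1] * inputs.u_p1 + occ[2] * inputs.u_p2
        qalys += df * eu / 12.0

        c = (
            alive * inputs.c_monthly
            + occ[0] * abi
            + occ[1] * inputs.c_p1
            + occ[2] * inputs.c_p2
        )
        if t == 0:
            c += inputs.c_once
        cost += df * c

        if t < H - 1:
            death_inflow = occ[0] * ds_s[t] + occ[1] * d1_s[t] + occ[2] * d2_s[t]
            cost += df * death_inflow * inputs.c_death
            occ = np.array([
                occ[0] * (1.0 - pp_s[t] - ds_s[t]),
                occ[0] * pp_s[t] + occ[1] * (1.0 - q_s[t] - d1_s[t]),
                occ[1] * q_s[t] + occ[2] * (1.0 - d2_s[t]),
                occ[3] + death_inflow,
            ])

    return ExpectedOutcome(arm=arm, horizon=H, cost=cost, qalys=qalys,
                           os_curve=os_curve, ffs_curve=ffs_curve)
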