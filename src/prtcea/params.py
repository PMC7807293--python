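"""Model parameters, uncertainty distributions and configuration I/O.

The model compares two strategies for newly diagnosed low-volume metastatic
hormone-sensitive prostate cancer (mHSPC):

* ``adt`` — androgen deprivation therapy alone, and
* ``prt`` — ADT plus prostate radiation therapy (PRT).

Every input is a per-cycle (monthly) transition probability, a health-state
utility weight, or a US-payer cost.  Each uncertain input carries a plausible
range; ranges are converted to beta distributions (for probabilities and
utilities, support [0, 1]) or gamma distributions (for costs and the
progression hazard ratio, support [0, inf)) by method of moments, treating
the range as a central 95% interval unless a per-parameter divisor override
is given.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import yaml
from scipy import stats

ARMS = ("adt", "prt")

#: Interval half-width divisor: a central 95% interval spans 2 * 1.96 sd.
DEFAULT_RANGE_DIVISOR = 2.0 * 1.959963984540054


class ConfigError(ValueError):
    """Raised when a configuration file violates the documented schema."""


class ValidationError(ValueError):
    """Raised when a parameter value violates a model invariant."""


class InfeasibleSpreadError(ValueError):
    """Raised when no beta distribution can have the requested mean/sd."""


# ---------------------------------------------------------------------------
# Uncertainty distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterDistribution:
    """A fitted uncertainty distribution for one model input.

    ``kind`` is ``"beta"``, ``"gamma"`` or ``"fixed"``.  ``shape_a`` and
    ``shape_b`` hold (alpha, beta) for the beta kind and (k, theta) for the
    gamma kind; both are zero for fixed parameters.
    """

    kind: str
    base: float
    lo: float
    hi: float
    shape_a: float = 0.0
    shape_b: float = 0.0

    def mean(self) -> float:
        if self.kind == "beta":
            return self.shape_a / (self.shape_a + self.shape_b)
        if self.kind == "gamma":
            return self.shape_a * self.shape_b
        return self.base

    def sd(self) -> float:
        if self.kind == "beta":
            a, b = self.shape_a, self.shape_b
            return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))
        if self.kind == "gamma":
            return float(np.sqrt(self.shape_a) * self.shape_b)
        return 0.0

    def rvs(self, rng: np.random.Generator, size=None):
        if self.kind == "beta":
            return rng.beta(self.shape_a, self.shape_b, size=size)
        if self.kind == "gamma":
            return rng.gamma(self.shape_a, self.shape_b, size=size)
        if size is None:
            return self.base
        return np.full(size, self.base)

    def frozen(self):
        """The equivalent ``scipy.stats`` frozen distribution."""
        if self.kind == "beta":
            return stats.beta(self.shape_a, self.shape_b)
        if self.kind == "gamma":
            return stats.gamma(self.shape_a, scale=self.shape_b)
        raise ValueError("fixed parameters have no distribution")


def beta_from_range(
    base: float, lo: float, hi: float, divisor: float = DEFAULT_RANGE_DIVISOR
) -> ParameterDistribution:
    """Fit a beta distribution with mean ``base`` and sd ``(hi-lo)/divisor``.

    The (lo, hi) range is read as a central 95% interval by default, so the
    implied standard deviation is its width over 2*1.96.

    Raises
    ------
    InfeasibleSpreadError
        If the implied variance reaches base*(1-base), the maximum any
        distribution on [0, 1] with that mean can have.
    """
    if not 0.0 < base < 1.0:
        raise ValidationError(f"beta mean must lie in (0, 1); got {base}")
    if not (0.0 <= lo < hi <= 1.0):
        raise ValidationError(f"beta range must satisfy 0 <= lo < hi <= 1; got ({lo}, {hi})")
    sd = (hi - lo) / divisor
    var = sd * sd
    if var >= base * (1.0 - base):
        raise InfeasibleSpreadError(
            f"sd {sd:.6g} infeasible for a beta with mean {base:.6g}"
        )
    nu = base * (1.0 - base) / var - 1.0
    return ParameterDistribution(
        "beta", base, lo, hi, shape_a=base * nu, shape_b=(1.0 - base) * nu
    )


def gamma_from_range(
    base: float, lo: float, hi: float, divisor: float = DEFAULT_RANGE_DIVISOR
) -> ParameterDistribution:
    """Fit a gamma distribution with mean ``base`` and sd ``(hi-lo)/divisor``."""
    if base <= 0.0:
        raise ValidationError(f"gamma mean must be positive; got {base}")
    if not (0.0 <= lo < hi):
        raise ValidationError(f"gamma range must satisfy 0 <= lo < hi; got ({lo}, {hi})")
    sd = (hi - lo) / divisor
    k = (base / sd) ** 2
    theta = sd * sd / base
    return ParameterDistribution("gamma", base, lo, hi, shape_a=k, shape_b=theta)


def fit_distribution(
    kind: str, base: float, lo: float, hi: float, divisor: float = DEFAULT_RANGE_DIVISOR
) -> ParameterDistribution:
    if kind == "beta":
        return beta_from_range(base, lo, hi, divisor)
    if kind == "gamma":
        return gamma_from_range(base, lo, hi, divisor)
    if kind == "fixed":
        return ParameterDistribution("fixed", base, base, base)
    raise ConfigError(f"unknown distribution kind {kind!r}")


# ---------------------------------------------------------------------------
# Parameter bundle
# ---------------------------------------------------------------------------


@dataclass
class Param:
    """One named model input: base value plus its uncertainty description."""

    value: float
    kind: str = "fixed"
    lo: float | None = None
    hi: float | None = None
    divisor: float = DEFAULT_RANGE_DIVISOR

    def distribution(self) -> ParameterDistribution:
        if self.kind == "fixed" or self.lo is None or self.hi is None:
            return ParameterDistribution("fixed", self.value, self.value, self.value)
        return fit_distribution(self.kind, self.value, self.lo, self.hi, self.divisor)


# (name, kind, unit) for every model input.  ``p_progress_prt`` is present so
# the hazard-ratio link can be switched off, but when ``hr_mode`` is on it is
# derived, not read.
_PARAM_SPECS: dict[str, str] = {
    "p_progress_adt": "beta",
    "p_progress_prt": "beta",
    "hr_progression_prt": "gamma",
    "p_death_stable": "beta",
    "p_death_progression": "beta",
    "p_prog1_to_prog2": "fixed",
    "p_tox_gu": "beta",
    "p_tox_gi": "beta",
    "u_stable_adt": "beta",
    "u_stable_prt": "beta",
    "u_tox_gi": "beta",
    "u_tox_gu": "beta",
    "u_tox_both": "beta",
    "u_progression1": "beta",
    "u_progression2": "beta",
    "c_prt_once": "gamma",
    "c_adt_monthly": "gamma",
    "c_progression1_monthly": "gamma",
    "c_progression2_monthly": "gamma",
    "c_death_once": "gamma",
    "c_tox_once": "gamma",
}

_PROBABILITY_PARAMS = {
    "p_progress_adt",
    "p_progress_prt",
    "p_death_stable",
    "p_death_progression",
    "p_prog1_to_prog2",
    "p_tox_gu",
    "p_tox_gi",
}
_UTILITY_PARAMS = {
    "u_stable_adt",
    "u_stable_prt",
    "u_tox_gi",
    "u_tox_gu",
    "u_tox_both",
    "u_progression1",
    "u_progression2",
}
_COST_PARAMS = {
    "c_prt_once",
    "c_adt_monthly",
    "c_progression1_monthly",
    "c_progression2_monthly",
    "c_death_once",
    "c_tox_once",
}


@dataclass
class ModelParameters:
    """All model inputs for both strategies.

    Per-state death overrides ``p_death_progression1``/``p_death_progression2``
    default to the shared ``p_death_progression`` value.
    """

    params: dict[str, Param]
    hr_mode: bool = True
    p_death_progression1: float | None = None
    p_death_progression2: float | None = None

    def __post_init__(self) -> None:
        missing = set(_PARAM_SPECS) - set(self.params)
        if missing:
            raise ConfigError(f"missing required parameter(s): {sorted(missing)}")
        unknown = set(self.params) - set(_PARAM_SPECS)
        if unknown:
            raise ConfigError(f"unknown parameter(s): {sorted(unknown)}")
        self.validate(strict=False)

    def __getitem__(self, name: str) -> float:
        return self.params[name].value

    def set_value(self, name: str, value: float) -> None:
        if name == "p_death_progression1":
            self.p_death_progression1 = value
            return
        if name == "p_death_progression2":
            self.p_death_progression2 = value
            return
        if name not in self.params:
            raise KeyError(name)
        self.params[name] = dataclasses.replace(self.params[name], value=value)

    def names(self) -> Iterator[str]:
        return iter(self.params)

    def validate(self, strict: bool = True) -> None:
        """Check model invariants.

        Range invariants (probabilities/utilities in [0, 1], costs >= 0,
        hazard ratio > 0) are always enforced.  The cross-parameter utility
        ordering is checked only when ``strict`` — probabilistic sensitivity
        draws sample each utility independently and may transiently invert
        the ordering, which is sampling noise, not a configuration error.
        """
        for name in _PROBABILITY_PARAMS | _UTILITY_PARAMS:
            v = self.params[name].value
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        for name in _COST_PARAMS:
            if self.params[name].value < 0.0:
                raise ValidationError(f"{name} must be >= 0")
        if self.params["hr_progression_prt"].value <= 0.0:
            raise ValidationError("hr_progression_prt must be > 0")
        if not strict:
            return
        p = self.params
        if p["u_tox_both"].value > min(p["u_tox_gi"].value, p["u_tox_gu"].value) + 1e-12:
            raise ValidationError("u_tox_both must not exceed either single-site toxicity utility")
        if not (
            p["u_progression2"].value
            <= p["u_progression1"].value
            <= max(p["u_stable_adt"].value, p["u_stable_prt"].value) + 1e-12
        ):
            raise ValidationError("utilities must be ordered progression2 <= progression1 <= stable")

    # -- derived quantities -------------------------------------------------

    def progression_probability(self, arm: str) -> float:
        """Per-cycle progression probability from the stable state."""
        from .engine import hr_adjust_probability  # local import: no cycle at load

        if arm == "adt":
            return self["p_progress_adt"]
        if arm != "prt":
            raise ValueError(f"unknown arm {arm!r}")
        if self.hr_mode:
            return hr_adjust_probability(self["p_progress_adt"], self["hr_progression_prt"])
        return self["p_progress_prt"]

    def death_progression(self, state: int) -> float:
        if state == 1 and self.p_death_progression1 is not None:
            return self.p_death_progression1
        if state == 2 and self.p_death_progression2 is not None:
            return self.p_death_progression2
        return self["p_death_progression"]

    def distributions(self) -> dict[str, ParameterDistribution]:
        """Fitted distribution per uncertain (non-fixed) parameter."""
        out = {}
        for name, par in self.params.items():
            dist = par.distribution()
            if dist.kind != "fixed":
                out[name] = dist
        return out

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            params={k: dataclasses.replace(v) for k, v in self.params.items()},
            hr_mode=self.hr_mode,
            p_death_progression1=self.p_death_progression1,
            p_death_progression2=self.p_death_progression2,
        )


@dataclass
class ModelSettings:
    """Run-level settings shared by both strategies."""

    cycle_length_months: float = 1.0
    horizon_cycles: int = 37
    annual_discount_rate: float = 0.03
    wtp: float = 100_000.0
    n_trials: int = 10_000
    rng_seed: int = 2021
    lifetime_cap_cycles: int = 480
    upfront_abiraterone: bool = False
    #: "persistent": the PRT arm's stable-state utility applies from cycle 0 on;
    #: "treatment_only": it applies only for ``prt_treatment_cycles`` cycles.
    prt_utility_mode: str = "persistent"
    prt_treatment_cycles: int = 1

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ValidationError("horizon_cycles must be >= 1")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise ValidationError("annual_discount_rate must lie in [0, 1)")
        if self.prt_utility_mode not in ("persistent", "treatment_only"):
            raise ValidationError("prt_utility_mode must be 'persistent' or 'treatment_only'")

    def copy(self, **overrides) -> "ModelSettings":
        return dataclasses.replace(self, **overrides)


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------

_SETTINGS_FIELDS = {f.name for f in dataclasses.fields(ModelSettings)}


def _params_from_mapping(raw: dict) -> ModelParameters:
    if "parameters" not in raw:
        raise ConfigError("missing required section 'parameters'")
    entries = raw["parameters"]
    params: dict[str, Param] = {}
    for name, spec in entries.items():
        if name not in _PARAM_SPECS:
            raise ConfigError(f"unknown parameter {name!r}")
        if isinstance(spec, (int, float)):
            spec = {"base": float(spec)}
        if "base" not in spec:
            raise ConfigError(f"parameter {name!r} missing required field 'base'")
        kind = spec.get("dist", _PARAM_SPECS[name])
        params[name] = Param(
            value=float(spec["base"]),
            kind=kind if ("lo" in spec and "hi" in spec) else "fixed",
            lo=float(spec["lo"]) if "lo" in spec else None,
            hi=float(spec["hi"]) if "hi" in spec else None,
            divisor=float(spec.get("range_divisor", DEFAULT_RANGE_DIVISOR)),
        )
    overrides = raw.get("overrides", {}) or {}
    return ModelParameters(
        params=params,
        hr_mode=bool(raw.get("hr_mode", True)),
        p_death_progression1=overrides.get("p_death_progression1"),
        p_death_progression2=overrides.get("p_death_progression2"),
    )


def load_config(path) -> tuple[ModelParameters, ModelSettings]:
    """Read a YAML configuration and return validated parameters + settings.

    Any settings field omitted from the file keeps its default.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    params = _params_from_mapping(raw)
    params.validate(strict=True)
    settings_raw = raw.get("settings", {}) or {}
    unknown = set(settings_raw) - _SETTINGS_FIELDS
    if unknown:
        raise ConfigError(f"unknown settings field(s): {sorted(unknown)}")
    return params, ModelSettings(**settings_raw)


def write_config(path, params: ModelParameters, settings: ModelSettings) -> None:
    """Write parameters and settings back to YAML; round-trips exactly."""
    doc: dict = {"hr_mode": params.hr_mode, "parameters": {}, "settings": {}}
    for name, par in params.params.items():
        entry: dict = {"base": par.value}
        if par.lo is not None and par.hi is not None:
            entry.update(lo=par.lo, hi=par.hi, dist=par.kind)
            if par.divisor != DEFAULT_RANGE_DIVISOR:
                entry["range_divisor"] = par.divisor
        doc["parameters"][name] = entry
    if params.p_death_progression1 is not None or params.p_death_progression2 is not None:
        doc["overrides"] = {}
        if params.p_death_progression1 is not None:
            doc["overrides"]["p_death_progression1"] = params.p_death_progression1
        if params.p_death_progression2 is not None:
            doc["overrides"]["p_death_progression2"] = params.p_death_progression2
    doc["settings"] = dataclasses.asdict(settings)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_config_path():
    """Path to the base-case fixture shipped inside the package."""
    return importlib.resources.files("prtcea").joinpath("data/basecase.yaml")


def load_default() -> tuple[ModelParameters, ModelSettings]:
    """Load the shipped base-case parameter set."""
    with importlib.resources.as_file(default_config_path()) as p:
        return load_config(p)
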