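"""Parameter schema, validation, loading, and probabilistic sampling.

Every clinical, cost, and utility input of the decision model is carried as a
:class:`DistributionSpec` — a point estimate plus a second-order uncertainty
distribution (beta for probabilities and utilities, gamma for costs and
survival medians), parameterized by method of moments from ``(mean, se)``.
A bare number in a config file is coerced to a ``fixed`` spec, so a fully
deterministic model is just a config with no ``se`` fields.

Sampling is inverse-CDF: each distributed parameter consumes exactly one
uniform variate in a fixed traversal order, so two structurally identical
parameter sets sampled from the same seed see identical uniform streams.
This makes common-random-numbers across strategy arms and scenario overlays
exact, which is what keeps incremental outcomes low-variance in the PSA.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator
from scipy import special

__all__ = [
    "ParameterError",
    "DistributionSpec",
    "SurvivalSpec",
    "AdverseEvent",
    "TreatmentLineParams",
    "ParameterSet",
    "LINE_KEYS",
    "fit_beta",
    "fit_gamma",
    "load_parameters",
    "save_parameters",
    "sample_parameters",
    "parameter_table",
]

SCHEMA_VERSION = 1

#: required keys of ``ParameterSet.lines``
LINE_KEYS = (
    "abiraterone",
    "enzalutamide",
    "arpi_durable_responder",
    "docetaxel",
    "cabazitaxel",
    "bsc",
)


class ParameterError(ValueError):
    """Raised on schema or invariant violations in a parameter set."""


def fit_beta(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments Beta(alpha, beta) matching the given mean and SE.

    Solves ``alpha + beta = mean(1-mean)/se^2 - 1`` with ``alpha`` set so the
    mean is preserved exactly.

    Raises
    ------
    ParameterError
        If ``mean`` is outside (0, 1) or the variance is infeasible
        (``se^2 >= mean(1-mean)``) or non-positive.
    """
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta mean must lie in (0, 1), got {mean}")
    if se <= 0.0:
        raise ParameterError(f"beta se must be positive, got {se}")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ParameterError(
            f"infeasible beta variance: se^2={var:g} >= mean(1-mean)={mean * (1 - mean):g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments Gamma(shape, scale) matching the given mean and SE."""
    if mean <= 0.0 or se <= 0.0:
        raise ParameterError(f"gamma requires mean > 0 and se > 0, got ({mean}, {se})")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DistributionSpec(_StrictModel):
    """A parameter with a point estimate and an uncertainty distribution.

    ``kind='fixed'`` always returns ``mean`` when sampled. ``lo``/``hi`` are
    optional bounds used by one-way sensitivity analysis, not by sampling.
    """

    kind: Literal["fixed", "beta", "gamma"] = "fixed"
    mean: float
    se: float = 0.0
    lo: Optional[float] = None
    hi: Optional[float] = None

    @model_validator(mode="before")
    @classmethod
    def _coerce_scalar(cls, value):
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return {"kind": "fixed", "mean": float(value)}
        return value

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if self.kind == "beta":
            fit_beta(self.mean, self.se) if self.se > 0 else None
            if not 0.0 < self.mean < 1.0:
                raise ValueError("beta requires 0 < mean < 1")
            if self.se > 0 and self.se**2 >= self.mean * (1 - self.mean):
                raise ValueError("beta requires se^2 < mean(1-mean)")
        elif self.kind == "gamma":
            if self.mean <= 0:
                raise ValueError("gamma requires mean > 0")
        if self.lo is not None and self.hi is not None and self.lo > self.hi:
            raise ValueError("lo must be <= hi")
        return self

    def sample(self, rng: np.random.Generator) -> float:
        """One inverse-CDF draw; ``fixed`` (or se == 0) returns the mean.

        Always consumes exactly one uniform so that parallel parameter sets
        sampled from the same stream stay synchronized.
        """
        u = rng.random()
        if self.kind == "fixed" or self.se == 0.0:
            return self.mean
        if self.kind == "beta":
            a, b = fit_beta(self.mean, self.se)
            return float(special.betaincinv(a, b, u))
        shape, scale = fit_gamma(self.mean, self.se)
        return float(special.gammaincinv(shape, u) * scale)

    def fixed_at(self, value: float) -> "DistributionSpec":
        return DistributionSpec(kind="fixed", mean=value, lo=self.lo, hi=self.hi)


class SurvivalSpec(_StrictModel):
    """A survival summary: exponential-from-median or piecewise hazards.

    ``median`` is in months; piecewise ``breakpoints`` are months from line
    entry (starting at 0) with per-month ``hazards``. ``median_se`` attaches
    gamma uncertainty to the median for the PSA (0 = fixed).
    """

    form: Literal["exponential_median", "piecewise_hazard"] = "exponential_median"
    median: Optional[float] = None
    median_se: float = 0.0
    breakpoints: Optional[list[float]] = None
    hazards: Optional[list[float]] = None

    @model_validator(mode="after")
    def _check(self) -> "SurvivalSpec":
        if self.form == "exponential_median":
            if self.median is None or self.median <= 0:
                raise ValueError("exponential_median requires median > 0")
            if self.median_se < 0:
                raise ValueError("median_se must be >= 0")
        else:
            if not self.breakpoints or not self.hazards:
                raise ValueError("piecewise_hazard requires breakpoints and hazards")
            if len(self.breakpoints) != len(self.hazards):
                raise ValueError("breakpoints and hazards must have equal length")
            if self.breakpoints[0] != 0:
                raise ValueError("breakpoints must start at 0")
            if any(b >= a for a, b in zip(self.breakpoints[1:], self.breakpoints[:-1])):
                raise ValueError("breakpoints must be strictly increasing")
            if any(h < 0 for h in self.hazards):
                raise ValueError("hazards must be >= 0")
        return self


class AdverseEvent(_StrictModel):
    """A grade >=3 adverse event: per-line probability and management cost."""

    name: str = "adverse_event"
    probability: DistributionSpec
    cost: DistributionSpec

    @model_validator(mode="after")
    def _check(self) -> "AdverseEvent":
        if not 0.0 <= self.probability.mean <= 1.0:
            raise ValueError("adverse event probability mean must lie in [0, 1]")
        if self.cost.mean < 0:
            raise ValueError("adverse event cost mean must be >= 0")
        return self


class TreatmentLineParams(_StrictModel):
    """Per-treatment-line inputs: survival, per-cycle costs, AEs, utility."""

    pfs: SurvivalSpec
    os: SurvivalSpec
    drug_cost_per_cycle: DistributionSpec = DistributionSpec(mean=0.0)
    admin_cost_per_cycle: DistributionSpec = DistributionSpec(mean=0.0)
    ae_events: list[AdverseEvent] = Field(default_factory=list)
    utility: DistributionSpec = DistributionSpec(mean=1.0)
    max_cycles: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "TreatmentLineParams":
        if not 0.0 <= self.utility.mean <= 1.0:
            raise ValueError("utility mean must lie in [0, 1]")
        for f in ("drug_cost_per_cycle", "admin_cost_per_cycle"):
            if getattr(self, f).mean < 0:
                raise ValueError(f"{f} mean must be >= 0")
        if self.max_cycles is not None and self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1 when bounded")
        return self

    def expected_ae_cost(self) -> float:
        """Expected one-off AE management cost on line entry: sum p_i * c_i."""
        return sum(ae.probability.mean * ae.cost.mean for ae in self.ae_events)


class ParameterSet(_StrictModel):
    """The complete input set of the decision model (base case defaults).

    Cohort evolution works in occupancy fractions; ``cohort_size`` scales
    reported per-cohort figures only.
    """

    schema_version: int = SCHEMA_VERSION
    arpi_abi_share: float = 0.5
    lines: dict[str, TreatmentLineParams]
    ctdna_ppv: DistributionSpec = DistributionSpec(mean=0.85)
    ctdna_flag_fraction: DistributionSpec = DistributionSpec(mean=0.4)
    ctdna_cost_per_sample: DistributionSpec = DistributionSpec(mean=350.0)
    ctdna_n_samples: int = 3
    visit_cost_per_cycle: DistributionSpec = DistributionSpec(mean=0.0)
    diagnostic_cost: DistributionSpec = DistributionSpec(mean=0.0)
    bsc_cost_per_cycle: DistributionSpec = DistributionSpec(mean=0.0)
    bsc_entry_monthly_prob: DistributionSpec = DistributionSpec(mean=0.004)
    discount_rate_costs: float = 0.04
    discount_rate_effects: float = 0.015
    wtp: float = 80000.0
    horizon_years: float = 5.0
    cycle1_days: float = 28.0
    cycle_days: float = 21.0
    cohort_size: int = 1000
    durable_six_month_hold: bool = False
    durable_curves_equal_trial: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ParameterSet":
        missing = [k for k in LINE_KEYS if k not in self.lines]
        if missing:
            raise ValueError(f"lines is missing required treatment lines: {missing}")
        for prob_name in ("arpi_abi_share",):
            v = getattr(self, prob_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{prob_name} must lie in [0, 1], got {v}")
        for spec_name in ("ctdna_ppv", "ctdna_flag_fraction", "bsc_entry_monthly_prob"):
            m = getattr(self, spec_name).mean
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"{spec_name} mean must lie in [0, 1], got {m}")
        for cost_name in (
            "ctdna_cost_per_sample",
            "visit_cost_per_cycle",
            "diagnostic_cost",
            "bsc_cost_per_cycle",
        ):
            if getattr(self, cost_name).mean < 0:
                raise ValueError(f"{cost_name} mean must be >= 0")
        if self.discount_rate_costs < 0 or self.discount_rate_effects < 0:
            raise ValueError("discount rates must be >= 0")
        if self.cycle1_days <= 0 or self.cycle_days <= 0:
            raise ValueError("cycle lengths must be > 0")
        if self.horizon_years * 365.25 <= self.cycle1_days:
            raise ValueError("horizon must exceed the first cycle length")
        if self.ctdna_n_samples < 0:
            raise ValueError("ctdna_n_samples must be >= 0")
        for key in ("docetaxel", "cabazitaxel"):
            mc = self.lines[key].max_cycles
            if mc is not None and mc != 10:
                raise ValueError(
                    f"lines.{key}.max_cycles must be 10 (tunnel depth is structural)"
                )
        if not self.durable_curves_equal_trial:
            self._check_durable_medians()
        return self

    def _check_durable_medians(self) -> None:
        """Durable responders must live at least as long as the pooled cohort."""
        durable = self.lines["arpi_durable_responder"]
        w = self.arpi_abi_share
        for endpoint in ("pfs", "os"):
            d = getattr(durable, endpoint)
            abi = getattr(self.lines["abiraterone"], endpoint)
            enz = getattr(self.lines["enzalutamide"], endpoint)
            if (
                d.form == "exponential_median"
                and abi.form == "exponential_median"
                and enz.form == "exponential_median"
            ):
                pooled = w * abi.median + (1.0 - w) * enz.median
                if d.median < pooled - 1e-9:
                    raise ValueError(
                        f"durable-responder {endpoint} median ({d.median}) must be >= "
                        f"pooled ARPI median ({pooled:g})"
                    )


# ---------------------------------------------------------------------------
# IO


def _read_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a YAML/JSON parameter file.

    Missing optional fields are filled with the documented base-case defaults.
    Raises :class:`ParameterError` naming the offending field on schema or
    invariant violations.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"parameter file not found: {path}")
    raw = _read_structured(path)
    if not isinstance(raw, dict):
        raise ParameterError(f"parameter file {path} does not contain a mapping")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ParameterError(
            f"unsupported schema_version {version} (this package reads {SCHEMA_VERSION})"
        )
    try:
        return ParameterSet.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ParameterError(f"invalid parameter file {path}: {locs}") from exc


def save_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as YAML (or JSON by extension); round-trips."""
    path = Path(path)
    data = ps.model_dump(exclude_none=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# Sampling

def _iter_distributions(ps: ParameterSet):
    """Yield every DistributionSpec/SurvivalSpec holder in a fixed order.

    The order is part of the sampling contract (it defines which uniform each
    parameter consumes) and must not depend on dict insertion order.
    """
    for key in LINE_KEYS:
        line = ps.lines[key]
        yield line, "drug_cost_per_cycle"
        yield line, "admin_cost_per_cycle"
        yield line, "utility"
        for ae in line.ae_events:
            yield ae, "probability"
            yield ae, "cost"
        yield line, "pfs"
        yield line, "os"
    for name in (
        "ctdna_ppv",
        "ctdna_flag_fraction",
        "ctdna_cost_per_sample",
        "visit_cost_per_cycle",
        "diagnostic_cost",
        "bsc_cost_per_cycle",
        "bsc_entry_monthly_prob",
    ):
        yield ps, name


def sample_parameters(
    ps: ParameterSet, rng_seed: int | np.random.Generator
) -> ParameterSet:
    """One probabilistic draw of every distributed parameter.

    Returns a new ParameterSet in which every beta/gamma parameter is replaced
    by a ``fixed`` spec holding its draw, and every survival median with
    ``median_se > 0`` is replaced by a gamma draw. Fixed parameters pass
    through unchanged; the same seed always produces the same draw.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    out = ps.model_copy(deep=True)
    # assignments bypass per-field validation for speed; the final
    # model_validate re-checks every schema invariant on the drawn set
    for holder, field in _iter_distributions(out):
        value = getattr(holder, field)
        if isinstance(value, SurvivalSpec):
            u = rng.random()
            if value.form == "exponential_median" and value.median_se > 0:
                shape, scale = fit_gamma(value.median, value.median_se)
                new = value.model_copy(
                    update={
                        "median": float(special.gammaincinv(shape, u) * scale),
                        "median_se": 0.0,
                    }
                )
                object.__setattr__(holder, field, new)
        else:
            draw = value.sample(rng)
            if value.kind != "fixed":
                object.__setattr__(holder, field, value.fixed_at(draw))
    # a draw must still satisfy every schema invariant
    sampled = ParameterSet.model_validate(out.model_dump())
    return sampled


def parameter_table(ps: ParameterSet) -> "pd.DataFrame":
    """Resolved parameter table (one row per scalar) for audit export."""
    import pandas as pd

    rows: list[dict] = []

    def add(name: str, spec) -> None:
        if isinstance(spec, DistributionSpec):
            rows.append(
                {"parameter": name, "kind": spec.kind, "mean": spec.mean, "se": spec.se,
                 "lo": spec.lo, "hi": spec.hi}
            )
        elif isinstance(spec, SurvivalSpec):
            if spec.form == "exponential_median":
                rows.append(
                    {"parameter": name, "kind": "median_months", "mean": spec.median,
                     "se": spec.median_se, "lo": None, "hi": None}
                )
            else:
                rows.append(
                    {"parameter": name, "kind": "piecewise_hazard",
                     "mean": math.nan, "se": math.nan, "lo": None, "hi": None}
                )
        else:
            rows.append({"parameter": name, "kind": "scalar", "mean": spec, "se": 0.0,
                         "lo": None, "hi": None})

    for key in LINE_KEYS:
        line = ps.lines[key]
        for f in ("pfs", "os", "drug_cost_per_cycle", "admin_cost_per_cycle", "utility"):
            add(f"lines.{key}.{f}", getattr(line, f))
        for i, ae in enumerate(line.ae_events):
            add(f"lines.{key}.ae_events[{i}].probability", ae.probability)
            add(f"lines.{key}.ae_events[{i}].cost", ae.cost)
    for name in (
        "arpi_abi_share", "ctdna_ppv", "ctdna_flag_fraction", "ctdna_cost_per_sample",
        "ctdna_n_samples", "visit_cost_per_cycle", "diagnostic_cost",
        "bsc_cost_per_cycle", "bsc_entry_monthly_prob", "discount_rate_costs",
        "discount_rate_effects", "wtp", "horizon_years", "cycle1_days", "cycle_days",
        "cohort_size",
    ):
        add(name, getattr(ps, name))
    return pd.DataFrame(rows)
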