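"""One-way sensitivity analysis (tornado) and scenario overlays.

A one-way entry pins a single parameter at its low and high value (all else
at base) and records the mean incremental net monetary benefit at each
endpoint; entries are sorted by bar width for the tornado diagram. A
scenario is a declarative overlay of parameter overrides — global or scoped
to one arm — on the base configuration, reported as a Table-style row (arm
costs, arm QALYs, ICER, probability of cost-effectiveness at the WTP).

Overrides are addressed by dotted paths into the parameter schema
(``lines.docetaxel.utility``, ``ctdna_cost_per_sample``, ...). Assigning a
scalar to a distributed parameter moves its mean and rescales the standard
error to preserve the coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .economics import CEAResult, PSAResult, run_deterministic, run_psa
from .parameters import (
    DistributionSpec,
    ParameterError,
    ParameterSet,
    SurvivalSpec,
)

__all__ = [
    "TornadoEntry",
    "ScenarioSpec",
    "set_parameter",
    "valid_parameter_paths",
    "run_owsa",
    "apply_scenario",
    "run_scenario",
    "load_scenario",
    "load_owsa_ranges",
]


# --- dotted-path parameter access ------------------------------------------

_SCALAR_FIELDS = (
    "arpi_abi_share", "ctdna_n_samples", "discount_rate_costs",
    "discount_rate_effects", "wtp", "horizon_years", "cycle1_days",
    "cycle_days", "cohort_size", "durable_six_month_hold",
    "durable_curves_equal_trial",
)
_DIST_FIELDS = (
    "ctdna_ppv", "ctdna_flag_fraction", "ctdna_cost_per_sample",
    "visit_cost_per_cycle", "diagnostic_cost", "bsc_cost_per_cycle",
    "bsc_entry_monthly_prob",
)


def valid_parameter_paths(ps: ParameterSet) -> list[str]:
    paths = list(_SCALAR_FIELDS) + list(_DIST_FIELDS)
    for key in ps.lines:
        for f in ("drug_cost_per_cycle", "admin_cost_per_cycle", "utility"):
            paths.append(f"lines.{key}.{f}")
        for f in ("pfs", "os"):
            paths.append(f"lines.{key}.{f}")
            paths.append(f"lines.{key}.{f}.median")
    return paths


def _assign_dist(spec: DistributionSpec, value: Any) -> DistributionSpec:
    if isinstance(value, dict):
        return DistributionSpec.model_validate(value)
    v = float(value)
    # boundary values leave the open support of beta/gamma: degrade to fixed
    if (spec.kind == "beta" and not 0.0 < v < 1.0) or (spec.kind == "gamma" and v <= 0.0):
        return DistributionSpec(kind="fixed", mean=v, lo=spec.lo, hi=spec.hi)
    se = spec.se * (v / spec.mean) if spec.mean != 0 else spec.se
    return spec.model_copy(update={"mean": v, "se": abs(se)})


def set_parameter(ps: ParameterSet, path: str, value: Any) -> ParameterSet:
    """Return a copy of ``ps`` with the parameter at ``path`` replaced.

    The base set is never mutated; the result is re-validated against every
    schema invariant. Unknown paths raise listing the valid names.
    """
    out = ps.model_copy(deep=True)
    parts = path.split(".")
    try:
        if parts[0] == "lines":
            line = out.lines[parts[1]]
            fname = parts[2]
            if fname in ("pfs", "os"):
                if len(parts) == 4 and parts[3] == "median":
                    spec = getattr(line, fname)
                    v = float(value)
                    mse = (
                        spec.median_se * (v / spec.median) if spec.median else spec.median_se
                    )
                    setattr(line, fname, spec.model_copy(
                        update={"median": v, "median_se": abs(mse)}))
                else:
                    setattr(line, fname, SurvivalSpec.model_validate(value))
            elif fname in ("drug_cost_per_cycle", "admin_cost_per_cycle", "utility"):
                setattr(line, fname, _assign_dist(getattr(line, fname), value))
            else:
                raise KeyError(fname)
        elif parts[0] in _DIST_FIELDS and len(parts) == 1:
            setattr(out, parts[0], _assign_dist(getattr(out, parts[0]), value))
        elif parts[0] in _SCALAR_FIELDS and len(parts) == 1:
            setattr(out, parts[0], value)
        else:
            raise KeyError(parts[0])
    except (KeyError, IndexError):
        raise ParameterError(
            f"unknown parameter path {path!r}; valid paths include: "
            + ", ".join(valid_parameter_paths(ps))
        ) from None
    return ParameterSet.model_validate(out.model_dump())


# --- one-way sensitivity ---------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    """One tornado bar: parameter name, endpoint inputs and iNMBs."""

    name: str
    lo: float
    hi: float
    inmb_lo: float
    inmb_hi: float

    @property
    def width(self) -> float:
        return abs(self.inmb_hi - self.inmb_lo)


def _mean_inmb(ps: ParameterSet, n_psa: int, seed: int) -> float:
    if n_psa <= 0:
        return run_deterministic(ps).inmb
    return run_psa(ps, n_psa, seed).mean_inmb


def run_owsa(
    ps: ParameterSet,
    specs: list[tuple[str, float, float]],
    n_psa: int,
    seed: int,
) -> list[TornadoEntry]:
    """One-way variation of each ``(name, lo, hi)`` spec, all else at base.

    With ``n_psa > 0`` each endpoint is a full PSA mean (common seed across
    endpoints, so differences are attributable to the varied scalar);
    ``n_psa = 0`` runs deterministic endpoints. Entries are returned sorted
    by descending bar width.
    """
    entries = []
    for name, lo, hi in specs:
        if lo > hi:
            raise ParameterError(f"OWSA spec {name}: lo ({lo}) must be <= hi ({hi})")
        inmb_lo = _mean_inmb(set_parameter(ps, name, lo), n_psa, seed)
        inmb_hi = _mean_inmb(set_parameter(ps, name, hi), n_psa, seed)
        entries.append(TornadoEntry(name=name, lo=lo, hi=hi,
                                    inmb_lo=inmb_lo, inmb_hi=inmb_hi))
    return sorted(entries, key=lambda e: e.width, reverse=True)


def load_owsa_ranges(path: str | Path) -> list[tuple[str, float, float]]:
    """Read an OWSA ranges file: mapping of parameter path → [lo, hi]."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParameterError(f"ranges file {path} must contain a mapping")
    specs = []
    for name, rng in raw.items():
        if not isinstance(rng, (list, tuple)) or len(rng) != 2:
            raise ParameterError(f"range for {name!r} must be [lo, hi]")
        specs.append((str(name), float(rng[0]), float(rng[1])))
    return specs


# --- scenarios -------------------------------------------------------------

SCENARIO_IDS = (
    "s1_registration_pfs_os",
    "s2_proselica_cabazitaxel",
    "s3_docetaxel_utility",
    "s4_reallife_docetaxel",
)


class ScenarioSpec(BaseModel):
    """A declarative scenario overlay on the base configuration."""

    model_config = ConfigDict(extra="forbid")

    id: str
    description: str = ""
    overrides: dict[str, Any] = Field(default_factory=dict)
    soc_overrides: dict[str, Any] = Field(default_factory=dict)
    intervention_overrides: dict[str, Any] = Field(default_factory=dict)
    durable_equals_trial: bool = False


def load_scenario(path: str | Path) -> ScenarioSpec:
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"scenario overlay file not found: {path}")
    return ScenarioSpec.model_validate(yaml.safe_load(path.read_text()))


def apply_scenario(
    base: ParameterSet, spec: ScenarioSpec
) -> tuple[ParameterSet, ParameterSet]:
    """Apply a scenario, returning (soc_params, intervention_params).

    The base set is unchanged (overlays are pure)."""
    soc = itv = base
    for path, value in spec.overrides.items():
        soc = set_parameter(soc, path, value)
        itv = set_parameter(itv, path, value)
    for path, value in spec.soc_overrides.items():
        soc = set_parameter(soc, path, value)
    for path, value in spec.intervention_overrides.items():
        itv = set_parameter(itv, path, value)
    if spec.durable_equals_trial:
        itv = set_parameter(itv, "durable_curves_equal_trial", True)
    return soc, itv


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    cea: CEAResult
    psa: Optional[PSAResult]

    def table_row(self) -> dict:
        """Arm costs/QALYs, ICER, and % cost-effective at the WTP threshold."""
        row = {
            "scenario": self.spec.id,
            "intervention_cost": self.cea.intervention.total_cost_disc,
            "intervention_qalys": self.cea.intervention.qalys_disc,
            "soc_cost": self.cea.soc.total_cost_disc,
            "soc_qalys": self.cea.soc.qalys_disc,
            "icer": self.cea.icer,
            "inmb": self.cea.inmb,
        }
        if self.psa is not None:
            row.update(
                intervention_cost=float(self.psa.costs[:, 1].mean()),
                intervention_qalys=float(self.psa.qalys[:, 1].mean()),
                soc_cost=float(self.psa.costs[:, 0].mean()),
                soc_qalys=float(self.psa.qalys[:, 0].mean()),
                icer=self.psa.mean_icer,
                inmb=self.psa.mean_inmb,
                prob_cost_effective=self.psa.prob_cost_effective,
            )
        return row


def run_scenario(
    base: ParameterSet, spec: ScenarioSpec, n_psa: int, seed: int
) -> ScenarioResult:
    """Deterministic CEA plus (if ``n_psa > 0``) a PSA under the overlay."""
    ps_soc, ps_itv = apply_scenario(base, spec)
    cea = run_deterministic(ps_soc, ps_itv)
    psa = run_psa(ps_soc, n_psa, seed, ps_intervention=ps_itv) if n_psa > 0 else None
    return ScenarioResult(spec=spec, cea=cea, psa=psa)
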