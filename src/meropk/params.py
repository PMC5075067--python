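"""Domain types: structural PK parameters, dosing regimens, population spec.

Field names carry explicit units (``cl1_l_per_h``, ``drainage_l_per_day``) so
that serialized configs are self-describing.  All containers are frozen
dataclasses validated on construction; invalid values raise
:class:`ValidationError` naming the offending field.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ValidationError",
    "NumericalError",
    "PKParameters",
    "DosingRegimen",
    "PopulationSpec",
    "TABLE_TYPICAL",
    "TABLE_BSV_CV_PCT",
    "TABLE_RESIDUAL_CV_PCT",
    "load_config",
    "dump_config",
]


class ValidationError(ValueError):
    """Invalid user input (bad parameter value, malformed regimen/design)."""


class NumericalError(RuntimeError):
    """A numerical step failed (singular steady-state system, non-convergence)."""


def _require_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ValidationError(f"{name} must be strictly positive, got {value!r}")


def _require_nonnegative(name: str, value: float) -> None:
    if not (value >= 0):
        raise ValidationError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class PKParameters:
    """Structural parameters of the three-compartment plasma-CSF model.

    The model has a central (plasma) compartment, a peripheral tissue
    compartment, and a small CSF compartment.  Drug leaves the central
    compartment by clearance ``cl1``; it distributes to the peripheral
    compartment via intercompartmental clearance ``q2`` and to CSF via
    clearance ``q1`` scaled on the way in by the dimensionless transfer
    multiplier ``pc`` (central->CSF flux uses ``q1*pc``, CSF->central uses
    ``q1``; the asymmetry encodes net barrier penetration).  CSF drainage
    through an external catheter removes drug from the CSF compartment:
    the drained volume per day translates into a CSF clearance
    ``cl2 = drainage_l_per_day / 24`` (liters/h).

    ``drainage_as_rate_constant`` switches to the literal alternative
    reading in which ``drainage/24`` is taken directly as a first-order
    rate constant (1/h) acting on the CSF amount, instead of a clearance
    divided by the CSF volume.  The default (clearance) reading is
    dimensionally consistent; the switch exists so the sensitivity of
    downstream conclusions to the reading can be reported.
    """

    v1_l: float = 17.9
    v2_l: float = 0.13
    v3_l: float = 3.84
    cl1_l_per_h: float = 22.2
    q1_l_per_h: float = 0.010
    q2_l_per_h: float = 1.79
    pc: float = 0.172
    drainage_l_per_day: float = 0.0
    drainage_as_rate_constant: bool = False

    def __post_init__(self) -> None:
        for name in ("v1_l", "v2_l", "v3_l", "q1_l_per_h", "q2_l_per_h", "pc"):
            _require_positive(name, getattr(self, name))
        # cl1 = 0 is allowed so closed-system mass-balance checks can be run;
        # a periodic steady state then no longer exists.
        _require_nonnegative("cl1_l_per_h", self.cl1_l_per_h)
        _require_nonnegative("drainage_l_per_day", self.drainage_l_per_day)

    # ---- derived quantities -------------------------------------------------
    @property
    def cl2_l_per_h(self) -> float:
        """CSF drainage clearance (liters/h) = drained volume per day / 24."""
        return self.drainage_l_per_day / 24.0

    @property
    def k10_per_h(self) -> float:
        return self.cl1_l_per_h / self.v1_l

    @property
    def k12_per_h(self) -> float:
        """Central -> CSF rate constant, Q1*PC/V1."""
        return self.q1_l_per_h * self.pc / self.v1_l

    @property
    def k21_per_h(self) -> float:
        """CSF -> central rate constant, Q1/V2."""
        return self.q1_l_per_h / self.v2_l

    @property
    def k20_per_h(self) -> float:
        """CSF elimination rate constant due to drainage (1/h)."""
        if self.drainage_as_rate_constant:
            return self.drainage_l_per_day / 24.0
        return self.cl2_l_per_h / self.v2_l

    @property
    def csf_elimination_clearance_l_per_h(self) -> float:
        """Effective CSF elimination clearance k20*V2 under either reading."""
        return self.k20_per_h * self.v2_l

    def with_drainage_ml_per_day(self, drainage_ml_day: float) -> "PKParameters":
        _require_nonnegative("drainage_ml_day", drainage_ml_day)
        return replace(self, drainage_l_per_day=drainage_ml_day / 1000.0)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PKParameters":
        return cls(**dict(d))


@dataclass(frozen=True)
class DosingRegimen:
    """One repeated intravenous dosing regimen.

    ``infusion_h == interval_h`` means continuous infusion: the regimen's
    total daily dose is given at a constant rate (e.g. 2 g q8h as continuous
    infusion runs at 2000 mg / 8 h = 250 mg/h).
    """

    dose_mg: float
    interval_h: float
    infusion_h: float
    label: str = ""

    def __post_init__(self) -> None:
        _require_positive("dose_mg", self.dose_mg)
        _require_positive("interval_h", self.interval_h)
        _require_positive("infusion_h", self.infusion_h)
        if self.infusion_h > self.interval_h + 1e-12:
            raise ValidationError(
                f"infusion_h ({self.infusion_h}) must not exceed "
                f"interval_h ({self.interval_h})"
            )
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    @property
    def rate_mg_per_h(self) -> float:
        return self.dose_mg / self.infusion_h

    @property
    def is_continuous(self) -> bool:
        return abs(self.infusion_h - self.interval_h) <= 1e-12

    @classmethod
    def continuous(cls, dose_mg: float, interval_h: float) -> "DosingRegimen":
        """The continuous-infusion counterpart of ``dose_mg`` q``interval_h``h."""
        return cls(dose_mg=dose_mg, interval_h=interval_h, infusion_h=interval_h)

    def default_label(self) -> str:
        dose = (f"{self.dose_mg / 1000:g} g" if self.dose_mg >= 1000
                else f"{self.dose_mg:g} mg")
        inf = "CI" if self.is_continuous else f"{self.infusion_h:g}h inf"
        return f"{dose} q{self.interval_h:g}h {inf}"

    def to_dict(self) -> dict[str, Any]:
        return {"dose_mg": self.dose_mg, "interval_h": self.interval_h,
                "infusion_h": self.infusion_h, "label": self.label}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DosingRegimen":
        return cls(**dict(d))


# Published typical values and variability for the postneurosurgical
# meningitis population (final model estimates).
TABLE_TYPICAL = PKParameters()
TABLE_BSV_CV_PCT: dict[str, float] = {
    "v1_l": 13.2,
    "v2_l": 37.4,
    "cl1_l_per_h": 22.4,
    "q1_l_per_h": 84.4,
    "pc": 39.4,
}
TABLE_RESIDUAL_CV_PCT = 34.9


@dataclass(frozen=True)
class PopulationSpec:
    """Typical parameter values plus between-subject and residual variability.

    ``bsv_cv_pct`` maps a :class:`PKParameters` field name to its
    between-subject coefficient of variation in percent; parameters absent
    from the map have no between-subject variability.  Individual parameters
    are log-normal around the typical value: ``P_i = TV * exp(eta)`` with
    ``eta ~ N(0, omega^2)`` and ``omega^2 = ln(1 + (CV/100)^2)``.
    ``residual_cv_pct`` is the proportional residual error CV (percent).
    """

    typical: PKParameters = field(default_factory=PKParameters)
    bsv_cv_pct: Mapping[str, float] = field(
        default_factory=lambda: dict(TABLE_BSV_CV_PCT))
    residual_cv_pct: float = TABLE_RESIDUAL_CV_PCT

    def __post_init__(self) -> None:
        valid = {f.name for f in dataclasses.fields(PKParameters)}
        for name, cv in self.bsv_cv_pct.items():
            if name not in valid:
                raise ValidationError(f"unknown parameter in bsv_cv_pct: {name!r}")
            _require_nonnegative(f"bsv_cv_pct[{name}]", cv)
        _require_nonnegative("residual_cv_pct", self.residual_cv_pct)

    def to_dict(self) -> dict[str, Any]:
        return {"typical": self.typical.to_dict(),
                "bsv_cv_pct": dict(self.bsv_cv_pct),
                "residual_cv_pct": self.residual_cv_pct}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PopulationSpec":
        d = dict(d)
        typical = d.get("typical", {})
        if isinstance(typical, Mapping):
            typical = PKParameters.from_dict(typical)
        return cls(typical=typical,
                   bsv_cv_pct=dict(d.get("bsv_cv_pct", {})),
                   residual_cv_pct=d.get("residual_cv_pct", TABLE_RESIDUAL_CV_PCT))


# ---- config I/O -------------------------------------------------------------

_TYPES = {"pk_parameters": PKParameters, "dosing_regimen": DosingRegimen,
          "population_spec": PopulationSpec}


def dump_config(obj: Any, path: str | Path) -> None:
    """Write a domain object as YAML or JSON (by extension) with a type tag."""
    kind = {PKParameters: "pk_parameters", DosingRegimen: "dosing_regimen",
            PopulationSpec: "population_spec"}[type(obj)]
    payload = {"kind": kind, **obj.to_dict()}
    path = Path(path)
    text = (json.dumps(payload, indent=2, sort_keys=True)
            if path.suffix.lower() == ".json"
            else yaml.safe_dump(payload, sort_keys=True))
    path.write_text(text)


def load_config(path: str | Path) -> Any:
    path = Path(path)
    raw = path.read_text()
    data = (json.loads(raw) if path.suffix.lower() == ".json"
            else yaml.safe_load(raw))
    if not isinstance(data, Mapping) or "kind" not in data:
        raise ValidationError(f"config {path} lacks a 'kind' tag")
    data = dict(data)
    kind = data.pop("kind")
    if kind not in _TYPES:
        raise ValidationError(f"unknown config kind {kind!r} in {path}")
    return _TYPES[kind].from_dict(data)
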