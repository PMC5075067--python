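"""Virtual-patient generation: log-normal between-subject variability and
proportional residual error.

Individual parameters are ``P_i = TV * exp(eta_i)`` with independent
``eta_i ~ N(0, omega^2)`` and ``omega^2 = ln(1 + (CV/100)^2)``, the exact
relation between a log-normal's coefficient of variation and its log-scale
variance.  Parameters without a listed CV are carried over unchanged.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .params import PKParameters, PopulationSpec, ValidationError

__all__ = [
    "cv_pct_to_omega",
    "sample_individuals",
    "individuals_frame",
    "apply_residual_error",
]

# deterministic sampling order for reproducibility across runs
_SAMPLED_ORDER = ("v1_l", "v2_l", "v3_l", "cl1_l_per_h", "q1_l_per_h",
                  "q2_l_per_h", "pc")


def cv_pct_to_omega(cv_pct: float) -> float:
    """Log-scale SD omega with exp(omega^2) - 1 = (CV/100)^2."""
    if cv_pct < 0:
        raise ValidationError(f"CV% must be non-negative, got {cv_pct}")
    return float(np.sqrt(np.log1p((cv_pct / 100.0) ** 2)))


def sample_individuals(spec: PopulationSpec, n: int,
                       seed: int | np.random.Generator = 0,
                       ) -> list[PKParameters]:
    """Draw ``n`` virtual patients from the population.

    Reproducible for a given integer seed; an existing Generator may be
    passed to embed the draw in a larger reproducible stream.  Drainage and
    the drainage-reading switch are copied from ``spec.typical`` (drainage is
    a design covariate, not a biological random effect).
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    typ = spec.typical
    columns: dict[str, np.ndarray] = {}
    for name in _SAMPLED_ORDER:
        tv = getattr(typ, name)
        cv = spec.bsv_cv_pct.get(name, 0.0)
        if cv > 0:
            omega = cv_pct_to_omega(cv)
            columns[name] = tv * np.exp(rng.normal(0.0, omega, size=n))
        else:
            columns[name] = np.full(n, tv)
    return [
        PKParameters(
            **{name: float(columns[name][i]) for name in _SAMPLED_ORDER},
            drainage_l_per_day=typ.drainage_l_per_day,
            drainage_as_rate_constant=typ.drainage_as_rate_constant,
        )
        for i in range(n)
    ]


def individuals_frame(individuals: Sequence[PKParameters]) -> pd.DataFrame:
    """One row per virtual subject, one column per parameter."""
    rows = [dataclasses.asdict(p) for p in individuals]
    df = pd.DataFrame(rows)
    df.insert(0, "id", np.arange(1, len(df) + 1))
    return df


def apply_residual_error(concentrations: np.ndarray, residual_cv_pct: float,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Proportional residual error ``y = c * (1 + eps)``, eps ~ N(0, sigma^2).

    sigma = residual_cv_pct / 100 on the concentration scale; negative draws
    are truncated at zero.  Used only when generating synthetic observations
    and in predictive checks, never inside PTA simulation.
    """
    if residual_cv_pct < 0:
        raise ValidationError("residual_cv_pct must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    c = np.asarray(concentrations, dtype=float)
    eps = rng.normal(0.0, residual_cv_pct / 100.0, size=c.shape)
    return np.maximum(c * (1.0 + eps), 0.0)
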