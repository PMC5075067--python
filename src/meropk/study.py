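"""Synthetic-trial generation emulating the postneurosurgical-meningitis study.

The design: 82 patients split 42/19/21 across 1 g q8h, 1 g q6h and 2 g q8h
(infusion rate fixed at 1 g/h, so 1-g doses infuse over 1 h and 2-g doses
over 2 h); paired plasma and CSF samples drawn after the fourth dose at one
of two sparse nominal-time schedules; CSF drainage volumes from a truncated
normal (mean 126, SD 81, range 0-350 ml/day).  The generated table uses the
NONMEM-convention rectangular layout (ID, TIME, AMT, RATE, EVID, CMT, DV,
MDV plus covariates); the true individual parameters are kept in a separate
subjects table so estimation code cannot accidentally peek at them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import pk_core
from .params import DosingRegimen, PopulationSpec, ValidationError
from .population import apply_residual_error, sample_individuals

__all__ = [
    "TruncatedNormalSpec",
    "StudyDesign",
    "StudyDataset",
    "generate_study",
    "cockcroft_gault",
    "nominal_sampling_times",
    "write_dataset",
    "read_dataset",
]

CMT_PLASMA = 1
CMT_CSF = 2


@dataclass(frozen=True)
class TruncatedNormalSpec:
    mean: float
    sd: float
    lower: float
    upper: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd <= 0:
            return np.full(n, self.mean)
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n,
                             random_state=rng)


@dataclass(frozen=True)
class StudyDesign:
    """Trial design: regimen allocation, sparse sampling schedule, covariates."""

    n_patients: int = 82
    # (count, dose mg, interval h); infusion duration = dose / infusion_rate
    regimen_split: tuple[tuple[int, float, float], ...] = (
        (42, 1000.0, 8.0), (19, 1000.0, 6.0), (21, 2000.0, 8.0))
    infusion_rate_mg_per_h: float = 1000.0
    group_split: tuple[int, int] = (40, 42)
    n_doses_before_sampling: int = 4
    drainage_ml_day: TruncatedNormalSpec = TruncatedNormalSpec(126.0, 81.0,
                                                               0.0, 350.0)
    age_yr: TruncatedNormalSpec = TruncatedNormalSpec(43.4, 13.1, 19.0, 77.0)
    weight_kg: TruncatedNormalSpec = TruncatedNormalSpec(65.2, 11.6, 41.5, 100.0)
    clcr_ml_min: TruncatedNormalSpec = TruncatedNormalSpec(142.6, 52.8, 57.3,
                                                           355.7)
    n_male: int = 50
    time_jitter_sd_min: float = 0.0   # optional clinical sampling-time jitter
    missing_fraction: float = 0.0     # optional random observation loss

    def __post_init__(self) -> None:
        if sum(c for c, _, _ in self.regimen_split) != self.n_patients:
            raise ValidationError("regimen_split counts must sum to n_patients")
        if sum(self.group_split) != self.n_patients:
            raise ValidationError("group_split must sum to n_patients")
        if not (0 <= self.n_male <= self.n_patients):
            raise ValidationError("n_male must be between 0 and n_patients")
        if not (0 <= self.missing_fraction < 1):
            raise ValidationError("missing_fraction must be in [0, 1)")

    def regimens(self) -> list[DosingRegimen]:
        out = []
        for _, dose, interval in self.regimen_split:
            out.append(DosingRegimen(dose, interval,
                                     dose / self.infusion_rate_mg_per_h))
        return out


def nominal_sampling_times(regimen: DosingRegimen, group: int) -> np.ndarray:
    """Nominal sampling times (h after the sampled dose starts).

    Group 1: mid-infusion, then 10 min, 2 h and 4 h after the infusion ends.
    Group 2: end of infusion, 1 h and 3 h after it, and just before the next
    dose.  Times beyond the dosing interval are a design error.
    """
    tinf, tau = regimen.infusion_h, regimen.interval_h
    if group == 1:
        times = np.array([tinf / 2.0, tinf + 10.0 / 60.0, tinf + 2.0,
                          tinf + 4.0])
    elif group == 2:
        times = np.array([tinf, tinf + 1.0, tinf + 3.0, tau])
    else:
        raise ValidationError(f"sampling group must be 1 or 2, got {group}")
    if np.any(times > tau + 1e-9):
        raise ValidationError(
            f"sampling times {times} exceed the dosing interval {tau} h "
            f"for regimen {regimen.label}")
    return times


def cockcroft_gault(age_yr: float, weight_kg: float, scr_mg_dl: float,
                    sex: str) -> float:
    """Cockcroft-Gault creatinine clearance (ml/min).

    CLcr = (140 - age) * weight / (72 * SCr), times 0.85 for females.
    """
    if scr_mg_dl <= 0:
        raise ValidationError("serum creatinine must be positive")
    if weight_kg <= 0:
        raise ValidationError("weight must be positive")
    if not (0 < age_yr <= 140):
        raise ValidationError("age must be in (0, 140] years")
    sex_norm = sex.strip().upper()[:1]
    if sex_norm not in ("M", "F"):
        raise ValidationError(f"sex must be male/female, got {sex!r}")
    clcr = (140.0 - age_yr) * weight_kg / (72.0 * scr_mg_dl)
    if sex_norm == "F":
        clcr *= 0.85
    return clcr


def _scr_from_clcr(clcr: float, age: float, weight: float, sex: str) -> float:
    """Back-solve serum creatinine from a target Cockcroft-Gault CLcr."""
    factor = 0.85 if sex == "F" else 1.0
    return (140.0 - age) * weight * factor / (72.0 * clcr)


@dataclass(frozen=True)
class StudyDataset:
    """Observable table + per-subject truth, as generated."""

    observations: pd.DataFrame   # NONMEM-style rows (doses and observations)
    subjects: pd.DataFrame       # one row per subject: design + true params
    design: StudyDesign
    spec: PopulationSpec
    seed: int

    def n_observations(self, cmt: int | None = None) -> int:
        obs = self.observations[self.observations["EVID"] == 0]
        if cmt is not None:
            obs = obs[obs["CMT"] == cmt]
        return len(obs)


def generate_study(design: StudyDesign, spec: PopulationSpec,
                   seed: int = 0) -> StudyDataset:
    """Generate one complete synthetic trial.

    Individuals are sampled from ``spec``; their concentration profiles over
    the interval after dose ``n_doses_before_sampling`` are simulated from a
    drug-free start (no steady-state shortcut), and proportional residual
    error is added to paired plasma/CSF observations at the group-specific
    nominal times.
    """
    rng = np.random.default_rng(seed)
    n = design.n_patients

    # --- allocation ----------------------------------------------------------
    regimens = design.regimens()
    regimen_idx = np.repeat(np.arange(len(regimens)),
                            [c for c, _, _ in design.regimen_split])
    regimen_idx = rng.permutation(regimen_idx)
    groups = rng.permutation(np.repeat([1, 2], design.group_split))

    # --- covariates ----------------------------------------------------------
    sex = rng.permutation(np.array(["M"] * design.n_male
                                   + ["F"] * (n - design.n_male)))
    age = design.age_yr.sample(n, rng)
    weight = design.weight_kg.sample(n, rng)
    clcr = design.clcr_ml_min.sample(n, rng)
    scr = np.array([_scr_from_clcr(clcr[i], age[i], weight[i], sex[i])
                    for i in range(n)])
    drainage = design.drainage_ml_day.sample(n, rng)

    # --- individual parameters ----------------------------------------------
    individuals = sample_individuals(spec, n, rng)
    individuals = [p.with_drainage_ml_per_day(d)
                   for p, d in zip(individuals, drainage)]

    obs_rows: list[dict] = []
    subj_rows: list[dict] = []
    for i in range(n):
        sid = i + 1
        regimen = regimens[regimen_idx[i]]
        params = individuals[i]
        tau = regimen.interval_h
        t_rel = nominal_sampling_times(regimen, int(groups[i]))
        if design.time_jitter_sd_min > 0:
            jitter = rng.normal(0.0, design.time_jitter_sd_min / 60.0,
                                size=t_rel.size)
            t_rel = np.clip(t_rel + jitter, 0.0, tau)
        profile = pk_core.simulate_doses(params, regimen,
                                         design.n_doses_before_sampling,
                                         times_within_last=t_rel)
        plasma_obs = apply_residual_error(profile.conc_plasma_mg_l,
                                          spec.residual_cv_pct, rng)
        csf_obs = apply_residual_error(profile.conc_csf_mg_l,
                                       spec.residual_cv_pct, rng)
        cov = {"DRAIN_ML_DAY": round(float(drainage[i]), 6),
               "AGE": round(float(age[i]), 6),
               "WT": round(float(weight[i]), 6),
               "SEX": sex[i], "SCR": round(float(scr[i]), 6),
               "CLCR": round(float(clcr[i]), 6)}
        for k in range(design.n_doses_before_sampling):
            obs_rows.append({"ID": sid, "TIME": k * tau,
                             "AMT": regimen.dose_mg,
                             "RATE": regimen.rate_mg_per_h, "EVID": 1,
                             "CMT": CMT_PLASMA, "DV": np.nan, "MDV": 1, **cov})
        t_abs = (design.n_doses_before_sampling - 1) * tau + t_rel
        for j in range(t_rel.size):
            for cmt, dv in ((CMT_PLASMA, plasma_obs[j]), (CMT_CSF, csf_obs[j])):
                if design.missing_fraction > 0 and (rng.random()
                                                    < design.missing_fraction):
                    continue
                obs_rows.append({"ID": sid, "TIME": float(t_abs[j]),
                                 "AMT": 0.0, "RATE": 0.0, "EVID": 0,
                                 "CMT": cmt, "DV": float(dv), "MDV": 0, **cov})
        subj_rows.append({"ID": sid, "regimen": regimen.label,
                          "dose_mg": regimen.dose_mg,
                          "interval_h": regimen.interval_h,
                          "infusion_h": regimen.infusion_h,
                          "group": int(groups[i]), **cov,
                          **{f"true_{k}": v
                             for k, v in dataclasses.asdict(params).items()}})
    observations = pd.DataFrame(obs_rows)
    subjects = pd.DataFrame(subj_rows)
    return StudyDataset(observations=observations, subjects=subjects,
                        design=design, spec=spec, seed=seed)


# ---- rectangular CSV I/O ----------------------------------------------------

def write_dataset(dataset: StudyDataset, obs_path: str | Path,
                  subjects_path: str | Path | None = None,
                  header_lines: Sequence[str] = ()) -> None:
    """Write the observable table (and optionally the truth table) as CSV."""
    _write_csv(dataset.observations, obs_path, header_lines)
    if subjects_path is not None:
        _write_csv(dataset.subjects, subjects_path, header_lines)


def _write_csv(df: pd.DataFrame, path: str | Path,
               header_lines: Sequence[str] = ()) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_dataset(obs_path: str | Path) -> pd.DataFrame:
    """Read a rectangular NONMEM-convention CSV (comment lines start with #)."""
    df = pd.read_csv(obs_path, comment="#")
    required = {"ID", "TIME", "AMT", "RATE", "EVID", "CMT", "DV", "MDV"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"dataset lacks required columns: {sorted(missing)}")
    return df
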