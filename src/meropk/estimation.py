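"""Model fitting and simulation-based diagnostics.

Two estimators are provided, both deliberately simpler than a full
nonlinear mixed-effects (FOCE-type) engine, which is out of scope:

``fit_pooled``
    Naive-pooled maximum likelihood under a proportional Gaussian error
    model: one set of structural parameters fitted to all subjects jointly,
    per-subject CSF drainage entering as a known covariate.  Exact on
    variability-free data; on data with between-subject variability the
    pooled typical values are biased by lognormal-mixture flattening and
    the pooled sigma absorbs the BSV (both expected and documented).

``fit_two_stage``
    An iterated two-stage refinement targeting the *typical* (median)
    values: a pooled log-scale fit is followed by alternating per-subject
    nonlinear least squares for the well-individualised parameters (V1 and
    CL1 from plasma, Q1 from CSF) and a global refit of the shared ones
    (V3, Q2, PC), with an analytic correction for the mean of the
    log-transformed proportional error.  Typical values are the medians of
    the per-subject estimates.

Parameters are always handled on the log scale (positivity by
construction); the CSF volume V2 is fixed (0.13 L by default), as in the
final published model.  Fits are warm-started by least squares and
multi-started from 0.5x/1x/2x the initial values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .params import (NumericalError, PKParameters, PopulationSpec,
                     ValidationError)
from .population import cv_pct_to_omega
from .study import CMT_CSF, CMT_PLASMA, StudyDataset, nominal_sampling_times

__all__ = [
    "StudyPredictor",
    "FitResult",
    "BootstrapResult",
    "fit_pooled",
    "fit_two_stage",
    "bootstrap_ci",
    "vpc",
]

_ESTIMATED = ("v1_l", "v3_l", "cl1_l_per_h", "q1_l_per_h", "q2_l_per_h", "pc")
_PENALTY = 1e12
#: concentration floor (mg/L) standing in for an assay quantification limit
#: when observations are log-transformed
_LOG_FLOOR = 1e-3


# ---------------------------------------------------------------------------
# Batched exact predictions
# ---------------------------------------------------------------------------

class StudyPredictor:
    """Exact concentrations at each subject's observation times, batched.

    One instance captures the *design*: per-subject dosing (dose, interval,
    infusion duration, number of doses before sampling), drainage covariate
    and observation times.  :meth:`concentrations` then evaluates any
    parameter vector (scalars for a pooled fit, per-subject arrays for
    simulation) by eigendecomposition of the stacked rate matrices.
    """

    def __init__(self, tau_h: np.ndarray, tinf_h: np.ndarray,
                 rate_mg_h: np.ndarray, n_doses: np.ndarray,
                 obs_times: list[np.ndarray],
                 drainage_l_day: np.ndarray,
                 drainage_as_rate_constant: bool = False) -> None:
        self.n_subjects = len(tau_h)
        self.tau = np.asarray(tau_h, float)
        self.tinf = np.asarray(tinf_h, float)
        self.rate = np.asarray(rate_mg_h, float)
        self.n_doses = np.asarray(n_doses, int)
        self.drainage_l_day = np.asarray(drainage_l_day, float)
        self.drainage_as_rate_constant = drainage_as_rate_constant
        if np.any(self.tinf > self.tau + 1e-12):
            raise ValidationError("infusion duration exceeds dosing interval")
        k = max(len(t) for t in obs_times)
        self.times = np.zeros((self.n_subjects, k))
        self.valid = np.zeros((self.n_subjects, k), dtype=bool)
        for i, t in enumerate(obs_times):
            t = np.asarray(t, float)
            if np.any(t < 0) or np.any(t > self.tau[i] + 1e-9):
                raise ValidationError(
                    "observation times must lie within one dosing interval")
            self.times[i, :len(t)] = t
            self.valid[i, :len(t)] = True

    def subset(self, indices: Sequence[int]) -> "StudyPredictor":
        idx = list(indices)
        return StudyPredictor(
            self.tau[idx], self.tinf[idx], self.rate[idx], self.n_doses[idx],
            [self.times[i][self.valid[i]] for i in idx],
            self.drainage_l_day[idx], self.drainage_as_rate_constant)

    # -- linear algebra helpers (complex-safe) ------------------------------
    @staticmethod
    def _phi_apply(v, vinv, w, t, x):
        """e^{A t} x for stacked eigendecompositions; t is (n,) per subject."""
        c = (vinv @ x[:, :, None])[:, :, 0]
        return (v @ ((np.exp(w * t[:, None]) * c)[:, :, None]))[:, :, 0]

    def _system(self, v1, v2, v3, cl1, q1, q2, pc):
        n = self.n_subjects
        ones = np.ones(n)
        v1, v2, v3, cl1, q1, q2, pc = [np.asarray(p, float) * ones
                                       for p in (v1, v2, v3, cl1, q1, q2, pc)]
        k10 = cl1 / v1
        k12 = q1 * pc / v1
        k21 = q1 / v2
        k13 = q2 / v1
        k31 = q2 / v3
        if self.drainage_as_rate_constant:
            k20 = self.drainage_l_day / 24.0
        else:
            k20 = (self.drainage_l_day / 24.0) / v2
        a = np.zeros((n, 3, 3))
        a[:, 0, 0] = -(k10 + k12 + k13)
        a[:, 0, 1] = k21
        a[:, 0, 2] = k31
        a[:, 1, 0] = k12
        a[:, 1, 1] = -(k21 + k20)
        a[:, 2, 0] = k13
        a[:, 2, 2] = -k31
        return a, v1, v2

    def amounts(self, v1, v2, v3, cl1, q1, q2, pc) -> np.ndarray:
        """Amounts (n_subjects, n_times, 3) at the stored observation times."""
        a, _, _ = self._system(v1, v2, v3, cl1, q1, q2, pc)
        w, vmat = np.linalg.eig(a)
        w = w.astype(complex)
        vmat = vmat.astype(complex)
        vinv = np.linalg.inv(vmat)
        b = np.zeros((self.n_subjects, 3))
        b[:, 0] = self.rate
        xp = np.linalg.solve(a, -b[:, :, None])[:, :, 0].astype(complex)

        # one-interval map: x(tau) = P2 (P1 x + (I - P1) xp)
        def through_interval(x):
            x1 = self._phi_apply(vmat, vinv, w, self.tinf, x - xp) + xp
            return self._phi_apply(vmat, vinv, w, self.tau - self.tinf, x1)

        x = np.zeros((self.n_subjects, 3), dtype=complex)
        max_prev = int(self.n_doses.max()) - 1
        for k in range(max_prev):
            nxt = through_interval(x)
            upd = (self.n_doses - 1) > k
            x[upd] = nxt[upd]

        x_end = self._phi_apply(vmat, vinv, w, self.tinf, x - xp) + xp
        out = np.empty((self.n_subjects, self.times.shape[1], 3))
        for j in range(self.times.shape[1]):
            t = self.times[:, j]
            on = self._phi_apply(vmat, vinv, w, np.minimum(t, self.tinf),
                                 x - xp) + xp
            off = self._phi_apply(vmat, vinv, w,
                                  np.maximum(t - self.tinf, 0.0), x_end)
            out[:, j, :] = np.where((t <= self.tinf)[:, None], on, off).real
        return out

    def concentrations(self, v1, v2, v3, cl1, q1, q2, pc
                       ) -> tuple[np.ndarray, np.ndarray]:
        """(plasma, csf) concentration arrays, each (n_subjects, n_times)."""
        amt = self.amounts(v1, v2, v3, cl1, q1, q2, pc)
        ones = np.ones(self.n_subjects)
        v1 = np.asarray(v1, float) * ones
        v2 = np.asarray(v2, float) * ones
        return amt[:, :, 0] / v1[:, None], amt[:, :, 1] / v2[:, None]

    @classmethod
    def from_observations(cls, observations: pd.DataFrame,
                          drainage_as_rate_constant: bool = False
                          ) -> tuple["StudyPredictor", pd.DataFrame]:
        """Reconstruct the design from a rectangular dataset.

        The dosing regimen of each subject is read off its dose rows (amount,
        inter-dose spacing, AMT/RATE ratio) and observation times are taken
        relative to the last dose.  Returns the predictor plus the
        observation rows annotated with (subject index, time index).
        """
        df = observations
        if "DRAIN_ML_DAY" not in df.columns:
            raise ValidationError("dataset lacks the DRAIN_ML_DAY covariate "
                                  "column required for fitting")
        tau, tinf, rate, ndose, times, drain = [], [], [], [], [], []
        obs_parts = []
        for s_ix, (sid, sub) in enumerate(df.groupby("ID", sort=True)):
            doses = sub[sub["EVID"] == 1].sort_values("TIME")
            obs = sub[sub["EVID"] == 0].sort_values(["TIME", "CMT"]).copy()
            if len(doses) < 2 or len(obs) == 0:
                raise ValidationError(
                    f"subject {sid}: need >= 2 dose events and >= 1 observation")
            gaps = np.diff(doses["TIME"].to_numpy())
            if np.ptp(gaps) > 1e-6:
                raise ValidationError(f"subject {sid}: uneven dosing intervals")
            tau_i = float(gaps[0])
            amt = float(doses["AMT"].iloc[0])
            rate_i = float(doses["RATE"].iloc[0])
            if rate_i <= 0:
                raise ValidationError(f"subject {sid}: dose rows need RATE > 0")
            t_last = float(doses["TIME"].max())
            t_rel = obs["TIME"].to_numpy(float) - t_last
            uniq = np.unique(t_rel)
            obs["_subj_ix"] = s_ix
            obs["_time_ix"] = np.searchsorted(uniq, t_rel)
            obs["_t_rel"] = t_rel
            obs_parts.append(obs)
            tau.append(tau_i)
            tinf.append(amt / rate_i)
            rate.append(rate_i)
            ndose.append(len(doses))
            times.append(uniq)
            drain.append(float(sub["DRAIN_ML_DAY"].iloc[0]) / 1000.0)
        predictor = cls(np.array(tau), np.array(tinf), np.array(rate),
                        np.array(ndose), times, np.array(drain),
                        drainage_as_rate_constant)
        return predictor, pd.concat(obs_parts, ignore_index=True)

    @classmethod
    def from_subjects(cls, subjects: pd.DataFrame, n_doses: int,
                      drainage_as_rate_constant: bool = False
                      ) -> "StudyPredictor":
        """Build the predictor from a per-subject design table (VPC use)."""
        from .params import DosingRegimen
        times = []
        for _, row in subjects.iterrows():
            regimen = DosingRegimen(row["dose_mg"], row["interval_h"],
                                    row["infusion_h"])
            times.append(nominal_sampling_times(regimen, int(row["group"])))
        return cls(subjects["interval_h"].to_numpy(float),
                   subjects["infusion_h"].to_numpy(float),
                   (subjects["dose_mg"] / subjects["infusion_h"]
                    ).to_numpy(float),
                   np.full(len(subjects), n_doses),
                   times,
                   subjects["DRAIN_ML_DAY"].to_numpy(float) / 1000.0,
                   drainage_as_rate_constant)


# ---------------------------------------------------------------------------
# Proportional-error log-noise moments
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(101)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2 * np.pi)


def _lognoise_moments(sigma: float) -> tuple[float, float]:
    """Mean and variance of ln(max(1 + eps, eps_floor)), eps ~ N(0, sigma^2).

    For proportional error y = f (1 + eps), the log-transformed observation
    is ln y = ln f + ln(1 + eps), whose mean is about -sigma^2/2 rather than
    zero; log-scale fitting must subtract this offset or it biases
    predictions low.  The floor mirrors the quantification floor applied to
    the data.
    """
    vals = np.log(np.maximum(1.0 + sigma * _GH_NODES, 0.02))
    mean = float(np.sum(_GH_WEIGHTS * vals))
    var = float(np.sum(_GH_WEIGHTS * (vals - mean) ** 2))
    return mean, var


def _sigma_from_logvar(s2: float) -> float:
    """Invert Var[ln(1+eps)] = s2 for the proportional-error sigma."""
    if s2 <= 0:
        return 0.0
    try:
        return float(optimize.brentq(
            lambda s: _lognoise_moments(s)[1] - s2, 1e-6, 1.5))
    except ValueError:
        return float(np.sqrt(s2))


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a structural-model fit."""

    params: PKParameters
    residual_cv_pct: float
    objective: float                  # -2 log-likelihood at the optimum
    converged: bool
    n_function_evals: int
    gradient_norm: float
    fixed_v2_l: float
    method: str = "pooled"
    polish: bool = True
    start_objectives: list[float] = field(default_factory=list)
    objective_history: list[float] = field(default_factory=list)
    message: str = ""
    individual_estimates: pd.DataFrame | None = None

    def estimates(self) -> dict[str, float]:
        out = {name: getattr(self.params, name) for name in _ESTIMATED}
        out["v2_l"] = self.fixed_v2_l
        out["residual_cv_pct"] = self.residual_cv_pct
        return out

    def to_json(self, path: str | Path | None = None, **extra) -> str:
        payload = {
            "method": self.method,
            "estimates": self.estimates(),
            "objective": self.objective,
            "converged": self.converged,
            "n_function_evals": self.n_function_evals,
            "gradient_norm": self.gradient_norm,
            "start_objectives": self.start_objectives,
            "message": self.message,
            **extra,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


class _PooledObjective:
    """-2LL of the pooled proportional-error model on one dataset."""

    def __init__(self, predictor: StudyPredictor, obs: pd.DataFrame,
                 fixed_v2_l: float) -> None:
        self.predictor = predictor
        self.fixed_v2_l = fixed_v2_l
        self.subj_ix = obs["_subj_ix"].to_numpy(int)
        self.time_ix = obs["_time_ix"].to_numpy(int)
        self.is_plasma = (obs["CMT"].to_numpy(int) == CMT_PLASMA)
        self.y = obs["DV"].to_numpy(float)
        self.n_obs = len(self.y)
        self.n_evals = 0

    def predict(self, theta: np.ndarray) -> np.ndarray:
        """Predicted concentrations for structural log-params theta (6,)."""
        v1, v3, cl1, q1, q2, pc = np.exp(theta)
        plasma, csf = self.predictor.concentrations(
            v1, self.fixed_v2_l, v3, cl1, q1, q2, pc)
        return np.where(self.is_plasma,
                        plasma[self.subj_ix, self.time_ix],
                        csf[self.subj_ix, self.time_ix])

    def rel_residuals(self, theta: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):
            f = self.predict(theta)
        if not np.all(np.isfinite(f)):
            return np.full(self.n_obs, 1e6)
        f = np.maximum(f, 1e-12)
        return (self.y - f) / f

    def log_residuals(self, theta: np.ndarray, offset: float = 0.0
                      ) -> np.ndarray:
        with np.errstate(all="ignore"):
            f = self.predict(theta)
        if not np.all(np.isfinite(f)):
            return np.full(self.n_obs, 1e6)
        return (np.log(np.maximum(self.y, _LOG_FLOOR))
                - np.log(np.maximum(f, 1e-12)) - offset)

    def neg2ll(self, z: np.ndarray) -> float:
        """z = log([v1, v3, cl1, q1, q2, pc, sigma])."""
        self.n_evals += 1
        if np.any(np.abs(z) > 50):
            return _PENALTY
        sigma = np.exp(z[-1])
        with np.errstate(all="ignore"):
            f = self.predict(z[:-1])
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            return _PENALTY
        r = (self.y - f) / f
        val = (self.n_obs * np.log(2 * np.pi)
               + 2 * np.sum(np.log(sigma * f))
               + np.sum(r ** 2) / sigma ** 2)
        return float(val) if np.isfinite(val) else _PENALTY


def _numeric_grad_norm(fun, z: np.ndarray, h: float = 1e-5) -> float:
    g = np.zeros_like(z)
    for i in range(len(z)):
        zp, zm = z.copy(), z.copy()
        zp[i] += h
        zm[i] -= h
        g[i] = (fun(zp) - fun(zm)) / (2 * h)
    return float(np.linalg.norm(g))


def _build_objective(dataset: StudyDataset | pd.DataFrame, fixed_v2_l: float,
                     drainage_as_rate_constant: bool) -> _PooledObjective:
    obs_df = (dataset.observations if isinstance(dataset, StudyDataset)
              else dataset)
    predictor, obs = StudyPredictor.from_observations(
        obs_df, drainage_as_rate_constant)
    cmt = obs["CMT"].to_numpy(int)
    if not (np.any(cmt == CMT_PLASMA) and np.any(cmt == CMT_CSF)):
        raise ValidationError("dataset must contain both plasma and CSF "
                              "observations")
    return _PooledObjective(predictor, obs, fixed_v2_l)


# ---------------------------------------------------------------------------
# Naive-pooled maximum likelihood
# ---------------------------------------------------------------------------

def fit_pooled(dataset: StudyDataset | pd.DataFrame,
               init: PKParameters | None = None,
               fixed_v2_l: float = 0.13,
               n_starts: int = 3,
               sigma_init: float = 0.3,
               drainage_as_rate_constant: bool = False,
               polish: bool = True,
               ls_max_nfev: int = 4000,
               ls_tol: float = 1e-13,
               nm_maxiter: int = 6000) -> FitResult:
    """Pooled proportional-error ML fit of the structural model plus sigma.

    Multi-start: the structural initial values are scaled by 1x, 0.5x, 2x
    (first ``n_starts`` of these); each start is warm-started by
    relative-residual least squares, and the best start is polished by
    Nelder-Mead on the exact -2LL (skipped when ``polish`` is false, e.g.
    inside bootstrap loops).  Non-convergence is flagged on the result,
    never silently ignored.
    """
    objective = _build_objective(dataset, fixed_v2_l,
                                 drainage_as_rate_constant)
    init = init or PKParameters()
    z_init = np.log([getattr(init, name) for name in _ESTIMATED])

    multipliers = (1.0, 0.5, 2.0)[:max(1, n_starts)]
    start_objs: list[float] = []
    best_z, best_val = None, np.inf
    for mult in multipliers:
        z0 = z_init + np.log(mult)
        ls = optimize.least_squares(objective.rel_residuals, z0,
                                    xtol=ls_tol, ftol=ls_tol, gtol=ls_tol,
                                    max_nfev=ls_max_nfev)
        sigma_hat = max(np.sqrt(np.mean(ls.fun ** 2)), 1e-10)
        z_full = np.append(ls.x, np.log(sigma_hat))
        val = objective.neg2ll(z_full)
        if not np.isfinite(val):
            z_full = np.append(z0, np.log(sigma_init))
            val = objective.neg2ll(z_full)
        start_objs.append(val)
        if val < best_val:
            best_val, best_z = val, z_full
    if best_z is None or not np.isfinite(best_val):
        raise NumericalError("all optimizer starts failed")

    history: list[float] = [best_val]
    message = "least-squares warm start"
    if polish:
        def tracked(z):
            val = objective.neg2ll(z)
            if val < history[-1]:
                history.append(val)
            return val

        nm = optimize.minimize(tracked, best_z, method="Nelder-Mead",
                               options={"maxiter": nm_maxiter, "xatol": 1e-9,
                                        "fatol": 1e-9})
        if nm.fun <= best_val:
            best_z, best_val = nm.x, float(nm.fun)
        message = str(nm.message)

    grad_norm = _numeric_grad_norm(objective.neg2ll, best_z)
    converged = bool(np.isfinite(best_val) and best_val < _PENALTY)
    theta = np.exp(best_z)
    params = PKParameters(
        v1_l=theta[0], v2_l=fixed_v2_l, v3_l=theta[1], cl1_l_per_h=theta[2],
        q1_l_per_h=theta[3], q2_l_per_h=theta[4], pc=theta[5],
        drainage_as_rate_constant=drainage_as_rate_constant)
    return FitResult(
        params=params,
        residual_cv_pct=float(100 * theta[6]),
        objective=best_val,
        converged=converged,
        n_function_evals=objective.n_evals,
        gradient_norm=grad_norm,
        fixed_v2_l=fixed_v2_l,
        method="pooled",
        polish=polish,
        start_objectives=start_objs,
        objective_history=history,
        message=message,
    )


# ---------------------------------------------------------------------------
# Iterated two-stage estimation
# ---------------------------------------------------------------------------

def fit_two_stage(dataset: StudyDataset | pd.DataFrame,
                  init: PKParameters | None = None,
                  fixed_v2_l: float = 0.13,
                  n_iter: int = 2,
                  drainage_as_rate_constant: bool = False) -> FitResult:
    """Iterated two-stage fit targeting the typical (median) parameters.

    Stage 1 is a pooled log-scale least-squares fit of all structural
    parameters.  Each subsequent iteration then (a) refits V1 and CL1 per
    subject on that subject's plasma observations, (b) refits Q1 per subject
    on its CSF observations, and (c) refits the shared parameters V3, Q2 and
    PC globally, everything on the log scale with an analytic offset
    ``E[ln(1+eps)]`` whose sigma is estimated from the within-subject plasma
    residual spread (within one subject the plasma residuals contain
    measurement noise only, because V1 and CL1 absorb that subject's
    between-subject deviations).  Typical V1, CL1 and Q1 are the medians of
    the per-subject estimates; the iteration count is deliberately small
    because Q1 (per-subject) and PC (global) are only jointly weakly
    identified from sparse CSF data and prolonged alternation drifts along
    that ridge.

    Returns a :class:`FitResult` with ``individual_estimates`` holding the
    per-subject values; ``objective`` is the offset-corrected log-scale sum
    of squares (not comparable with the pooled -2LL).
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    objective = _build_objective(dataset, fixed_v2_l,
                                 drainage_as_rate_constant)
    pred = objective.predictor
    init = init or PKParameters()
    z_init = np.log([getattr(init, name) for name in _ESTIMATED])

    ls = optimize.least_squares(objective.log_residuals, z_init,
                                xtol=1e-12, ftol=1e-12, max_nfev=2000)
    zp = ls.x  # order: v1, v3, cl1, q1, q2, pc
    n = pred.n_subjects
    v1s = np.full(n, np.exp(zp[0]))
    cl1s = np.full(n, np.exp(zp[2]))
    q1s = np.full(n, np.exp(zp[3]))
    z_glob = zp[[1, 4, 5]]  # v3, q2, pc
    offset = 0.0
    sigma = 0.0

    subs = [pred.subset([i]) for i in range(n)]
    six, tix, ispl = objective.subj_ix, objective.time_ix, objective.is_plasma
    logy = np.log(np.maximum(objective.y, _LOG_FLOOR))

    for _ in range(n_iter):
        v3, q2, pc = np.exp(z_glob)
        ss_plasma, dof = 0.0, 0
        for si in range(n):
            mp = (six == si) & ispl
            mc = (six == si) & ~ispl
            sp = subs[si]

            def r_plasma(zf, si=si, mp=mp, sp=sp):
                v1c, cl1c = np.exp(zf)
                with np.errstate(all="ignore"):
                    pl, _ = sp.concentrations(v1c, fixed_v2_l, v3, cl1c,
                                              q1s[si], q2, pc)
                f = np.maximum(pl[0, tix[mp]], 1e-12)
                return logy[mp] - np.log(f) - offset

            if mp.sum() >= 2:
                lsp = optimize.least_squares(
                    r_plasma, np.log([v1s[si], cl1s[si]]), max_nfev=200)
                v1s[si], cl1s[si] = np.exp(lsp.x)
                ss_plasma += float(np.sum(lsp.fun ** 2))
                dof += int(mp.sum()) - 2

            def r_csf(zf, si=si, mc=mc, sp=sp):
                with np.errstate(all="ignore"):
                    _, cs = sp.concentrations(v1s[si], fixed_v2_l, v3,
                                              cl1s[si], np.exp(zf[0]), q2, pc)
                f = np.maximum(cs[0, tix[mc]], 1e-12)
                return logy[mc] - np.log(f) - offset

            if mc.sum() >= 1:
                lsc = optimize.least_squares(r_csf, np.log([q1s[si]]),
                                             max_nfev=200)
                q1s[si] = np.exp(lsc.x[0])
        if dof > 0:
            sigma = _sigma_from_logvar(ss_plasma / dof)
            offset = _lognoise_moments(sigma)[0]

        def r_global(zg):
            v3g, q2g, pcg = np.exp(zg)
            with np.errstate(all="ignore"):
                pl, cs = pred.concentrations(v1s, fixed_v2_l, v3g, cl1s, q1s,
                                             q2g, pcg)
            f = np.where(ispl, pl[six, tix], cs[six, tix])
            if not np.all(np.isfinite(f)):
                return np.full(objective.n_obs, 1e6)
            return logy - np.log(np.maximum(f, 1e-12)) - offset

        lg = optimize.least_squares(r_global, z_glob, max_nfev=800)
        z_glob = lg.x

    v3, q2, pc = np.exp(z_glob)
    params = PKParameters(
        v1_l=float(np.median(v1s)), v2_l=fixed_v2_l, v3_l=float(v3),
        cl1_l_per_h=float(np.median(cl1s)), q1_l_per_h=float(np.median(q1s)),
        q2_l_per_h=float(q2), pc=float(pc),
        drainage_as_rate_constant=drainage_as_rate_constant)
    individuals = pd.DataFrame({
        "subject_index": np.arange(n), "v1_l": v1s, "cl1_l_per_h": cl1s,
        "q1_l_per_h": q1s})
    final_ss = float(np.sum(r_global(z_glob) ** 2))
    return FitResult(
        params=params,
        residual_cv_pct=float(100 * sigma),
        objective=final_ss,
        converged=bool(np.isfinite(final_ss)),
        n_function_evals=objective.n_evals,
        gradient_norm=float("nan"),
        fixed_v2_l=fixed_v2_l,
        method="two-stage",
        message="iterated two-stage (log scale, noise-offset corrected)",
        individual_estimates=individuals,
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    intervals: pd.DataFrame      # parameter, p2.5, p50, p97.5
    replicates: pd.DataFrame     # one row per successful refit
    n_boot: int
    n_failed: int
    seed: int

    def contains(self, estimates: Mapping[str, float]) -> dict[str, bool]:
        """Whether each point estimate lies inside its percentile interval."""
        out = {}
        for _, row in self.intervals.iterrows():
            name = row["parameter"]
            if name in estimates:
                out[name] = bool(row["p2.5"] <= estimates[name]
                                 <= row["p97.5"])
        return out


def bootstrap_ci(dataset: StudyDataset | pd.DataFrame, fit: FitResult,
                 n_boot: int = 1000, seed: int = 0,
                 n_starts: int = 1, polish: bool | None = None
                 ) -> BootstrapResult:
    """Subject-level nonparametric bootstrap percentile intervals.

    Subjects are resampled with replacement; each replicate is refitted from
    the point estimate (single-start — appropriate because the refits start
    at the optimum of a very similar dataset).  ``polish`` defaults to
    whatever the point fit used, so the bootstrap distribution is that of
    the same estimator.  Replicates that fail are dropped and counted.
    """
    if polish is None:
        polish = fit.polish
    obs_df = (dataset.observations if isinstance(dataset, StudyDataset)
              else dataset)
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(obs_df["ID"].unique()))
    by_id = {sid: obs_df[obs_df["ID"] == sid] for sid in ids}
    rows = []
    n_failed = 0
    for _ in range(n_boot):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for new_id, sid in enumerate(chosen, start=1):
            sub = by_id[sid].copy()
            sub["ID"] = new_id
            parts.append(sub)
        boot_df = pd.concat(parts, ignore_index=True)
        try:
            # reduced optimizer budgets: each refit starts at the optimum of
            # a very similar dataset, so few iterations are needed
            refit = fit_pooled(boot_df, init=fit.params,
                               fixed_v2_l=fit.fixed_v2_l, n_starts=n_starts,
                               polish=polish, ls_max_nfev=500, ls_tol=1e-10,
                               nm_maxiter=1500,
                               drainage_as_rate_constant=
                               fit.params.drainage_as_rate_constant)
        except (NumericalError, ValidationError):
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        rows.append(refit.estimates())
    if not rows:
        raise NumericalError("every bootstrap refit failed")
    replicates = pd.DataFrame(rows)
    intervals = pd.DataFrame({
        "parameter": replicates.columns,
        "p2.5": replicates.quantile(0.025).to_numpy(),
        "p50": replicates.quantile(0.5).to_numpy(),
        "p97.5": replicates.quantile(0.975).to_numpy(),
    })
    return BootstrapResult(intervals=intervals, replicates=replicates,
                           n_boot=n_boot, n_failed=n_failed, seed=seed)


# ---------------------------------------------------------------------------
# Visual predictive check
# ---------------------------------------------------------------------------

def vpc(dataset: StudyDataset, spec: PopulationSpec, n_sim: int = 1000,
        seed: int = 0,
        percentiles: Sequence[float] = (5.0, 50.0, 95.0)) -> pd.DataFrame:
    """Simulation-based percentile bands versus observed percentiles.

    ``n_sim`` replicate studies are simulated under the dataset's own design
    (same regimens, sampling groups and drainage covariates) from ``spec``,
    with between-subject variability and proportional residual error.  For
    each matrix and nominal time-after-dose bin the observed percentile is
    reported together with the across-replicate median and 95% CI of the
    simulated percentile.
    """
    if n_sim < 1:
        raise ValidationError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = dataset.subjects
    n = len(subjects)
    predictor = StudyPredictor.from_subjects(
        subjects, dataset.design.n_doses_before_sampling,
        spec.typical.drainage_as_rate_constant)

    # observed values binned by (matrix, nominal time after the sampled dose)
    obs = dataset.observations
    obs = obs[obs["EVID"] == 0].copy()
    tau_by_id = subjects.set_index("ID")["interval_h"]
    nd = dataset.design.n_doses_before_sampling
    obs["t_rel"] = (obs["TIME"]
                    - (nd - 1) * obs["ID"].map(tau_by_id)).round(6)

    omega = {name: cv_pct_to_omega(cv)
             for name, cv in spec.bsv_cv_pct.items() if cv > 0}
    typ = spec.typical
    sigma = spec.residual_cv_pct / 100.0
    bin_keys = sorted(set(zip(obs["CMT"].astype(int), obs["t_rel"])))
    bin_rows = {key: (obs["CMT"].to_numpy(int) == key[0])
                & (obs["t_rel"].to_numpy() == key[1]) for key in bin_keys}
    quantile_store = {key: np.empty((n_sim, len(percentiles)))
                      for key in bin_keys}
    tix = _time_index(obs, predictor)
    six = obs["ID"].to_numpy(int) - 1
    is_plasma_row = obs["CMT"].to_numpy(int) == CMT_PLASMA
    for s in range(n_sim):
        draw = {}
        for name in ("v1_l", "v2_l", "v3_l", "cl1_l_per_h", "q1_l_per_h",
                     "q2_l_per_h", "pc"):
            tv = getattr(typ, name)
            if name in omega:
                draw[name] = tv * np.exp(rng.normal(0, omega[name], n))
            else:
                draw[name] = np.full(n, tv)
        plasma, csf = predictor.concentrations(
            draw["v1_l"], draw["v2_l"], draw["v3_l"], draw["cl1_l_per_h"],
            draw["q1_l_per_h"], draw["q2_l_per_h"], draw["pc"])
        eps_p = rng.normal(0, sigma, plasma.shape)
        eps_c = rng.normal(0, sigma, csf.shape)
        plasma_obs = np.maximum(plasma * (1 + eps_p), 0.0)
        csf_obs = np.maximum(csf * (1 + eps_c), 0.0)
        sim_dv = np.where(is_plasma_row, plasma_obs[six, tix],
                          csf_obs[six, tix])
        for key in bin_keys:
            vals = sim_dv[bin_rows[key]]
            quantile_store[key][s] = np.percentile(vals, percentiles)

    rows = []
    for key in bin_keys:
        cmt, t_rel = key
        observed = np.percentile(obs.loc[bin_rows[key], "DV"], percentiles)
        sims = quantile_store[key]
        for j, p in enumerate(percentiles):
            rows.append({
                "matrix": "plasma" if cmt == CMT_PLASMA else "csf",
                "time_h": t_rel,
                "percentile": p,
                "observed": float(observed[j]),
                "sim_median": float(np.median(sims[:, j])),
                "sim_lo": float(np.percentile(sims[:, j], 2.5)),
                "sim_hi": float(np.percentile(sims[:, j], 97.5)),
            })
    return pd.DataFrame(rows)


def _time_index(obs: pd.DataFrame, predictor: StudyPredictor) -> np.ndarray:
    """Column index of each observation row's time in the predictor grid."""
    t_rel = obs["t_rel"].to_numpy(float)
    subj = obs["ID"].to_numpy(int) - 1
    out = np.empty(len(obs), dtype=int)
    for i in range(len(obs)):
        row_times = predictor.times[subj[i], predictor.valid[subj[i]]]
        out[i] = int(np.argmin(np.abs(row_times - t_rel[i])))
    return out
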