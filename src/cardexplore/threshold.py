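"""Piecewise logistic model of approach-vs-avoid exploration.

The influence of Delta-uncertainty on choice is allowed to change above a free
overall-uncertainty threshold tau (nats):

    logit P(right) = b_side + b_rep * r + s(U) * z(Delta-uncertainty)
    s(U) = beta_low + beta_int * max(0, U - tau)        (hinge form, default)
    s(U) = beta_low + beta_int * 1[U > tau]             (step form)

tau is estimated by maximizing the ridge-penalized profile likelihood over a
grid (the likelihood is non-smooth in tau, so a grid keeps the optimum
reproducible).  A negative beta_int means the tendency to approach the more
uncertain table reverses into avoidance when overall uncertainty is high; the
magnitude of that avoidance is summarized by the area between the
below-threshold slope and the declining segment, a triangle for the hinge
form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import observer as obs
from .inference import ridge_logit

__all__ = [
    "default_tau_grid",
    "PiecewiseFit",
    "fit_piecewise",
    "AvoidanceScore",
    "avoidance_score",
    "fraction_above_threshold",
    "ApproachAvoidResult",
    "approach_avoid_individuals",
]

log = logging.getLogger(__name__)

PIECEWISE_COEF_NAMES = ("side", "repeat", "dv_low", "dv_int")


def default_tau_grid(step: float = 0.005, lo: float = 0.30,
                     hi: float = obs.MAX_OVERALL_UNCERTAINTY) -> np.ndarray:
    """Threshold grid in nats; default 0.30 to 2 ln 2 in 0.005 steps."""
    if not (0.0 < lo < hi <= obs.MAX_OVERALL_UNCERTAINTY + 1e-12):
        raise ValueError(f"tau grid must lie inside (0, 2 ln 2], got [{lo}, {hi}]")
    grid = np.arange(lo, hi, step)
    return np.append(grid, hi)


@dataclass
class PiecewiseFit:
    """Fitted piecewise model: threshold, slopes, profile, derived quantities."""

    tau_hat: float
    beta_low: float
    beta_int: float
    beta_side: float
    beta_rep: float
    se: dict[str, float]
    profile: pd.DataFrame            # columns: tau, objective (penalized log-lik)
    frac_above: float                # fraction of trials with U > tau_hat
    form: str
    ridge: float
    n_trials: int
    beta_int_identifiable: bool
    loglik: float                    # unpenalized log-likelihood at the optimum
    null_loglik: float               # same model without the threshold term

    @property
    def coef(self) -> dict[str, float]:
        return {"side": self.beta_side, "repeat": self.beta_rep,
                "dv_low": self.beta_low, "dv_int": self.beta_int}

    def effective_slope(self, u: np.ndarray) -> np.ndarray:
        """s(U): slope on z(Delta-uncertainty) as a function of overall uncertainty."""
        u = np.asarray(u, dtype=float)
        if self.form == "hinge":
            return self.beta_low + self.beta_int * np.maximum(0.0, u - self.tau_hat)
        return self.beta_low + self.beta_int * (u > self.tau_hat)


def _piecewise_design(design: pd.DataFrame, tau: float, form: str) -> np.ndarray:
    u = design["overall_uncertainty"].to_numpy(dtype=float)
    z = design["z_delta_uncertainty"].to_numpy(dtype=float)
    if form == "hinge":
        extra = np.maximum(0.0, u - tau) * z
    else:
        extra = (u > tau).astype(float) * z
    return np.column_stack([
        np.ones(len(design)), design["r"].to_numpy(dtype=float), z, extra,
    ])


def fit_piecewise(design: pd.DataFrame, tau_grid: np.ndarray | None = None,
                  ridge: float = 1.0, form: str = "hinge") -> PiecewiseFit:
    """Profile the penalized likelihood over the tau grid and fit at the argmax.

    If no trials lie above the profiled optimum (the threshold term has no
    support) beta_int is unidentifiable; it is fixed at 0 and flagged.
    """
    if form not in ("hinge", "step"):
        raise ValueError(f"form must be 'hinge' or 'step', got {form!r}")
    if tau_grid is None:
        tau_grid = default_tau_grid()
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.ndim != 1 or len(tau_grid) < 1:
        raise ValueError("tau_grid must be a nonempty 1-d array")
    if tau_grid.min() <= 0 or tau_grid.max() > obs.MAX_OVERALL_UNCERTAINTY + 1e-9:
        raise ValueError("tau_grid values must lie in (0, 2 ln 2]")

    y = design["y"].to_numpy(dtype=float)
    u = design["overall_uncertainty"].to_numpy(dtype=float)

    # null model (no threshold term) for the nesting comparison
    X0 = _piecewise_design(design, float(tau_grid.max()), form)[:, :3]
    null_res = ridge_logit(X0, y, lam=ridge)

    beta0 = np.append(null_res.coef, 0.0)
    objectives = np.empty(len(tau_grid))
    coefs = np.empty((len(tau_grid), 4))
    z = design["z_delta_uncertainty"].to_numpy(dtype=float)
    Xg = _piecewise_design(design, float(tau_grid[0]), form)
    for i, tau in enumerate(tau_grid):
        if form == "hinge":
            Xg[:, 3] = np.maximum(0.0, u - tau) * z
        else:
            Xg[:, 3] = (u > tau) * z
        res = ridge_logit(Xg, y, lam=ridge, beta0=beta0, tol=1e-7, light=True)
        objectives[i] = res.objective
        coefs[i] = res.coef
        beta0 = res.coef  # warm start the neighbouring grid point

    i_hat = int(np.argmax(objectives))
    tau_hat = float(tau_grid[i_hat])
    X = _piecewise_design(design, tau_hat, form)
    res = ridge_logit(X, y, lam=ridge, beta0=coefs[i_hat])
    frac_above = float(np.mean(u > tau_hat))

    identifiable = bool(np.any(u > tau_hat))
    if not identifiable:
        log.warning("no trials above tau_hat=%.3f; beta_int fixed at 0", tau_hat)
        coef = np.append(null_res.coef, 0.0)
        se = dict(zip(PIECEWISE_COEF_NAMES, np.append(null_res.se, np.nan)))
        loglik = null_res.loglik
    else:
        coef = res.coef
        se = dict(zip(PIECEWISE_COEF_NAMES, res.se))
        loglik = res.loglik

    return PiecewiseFit(
        tau_hat=tau_hat, beta_side=float(coef[0]), beta_rep=float(coef[1]),
        beta_low=float(coef[2]), beta_int=float(coef[3]), se=se,
        profile=pd.DataFrame({"tau": tau_grid, "objective": objectives}),
        frac_above=frac_above, form=form, ridge=ridge, n_trials=len(design),
        beta_int_identifiable=identifiable, loglik=loglik,
        null_loglik=null_res.loglik,
    )


@dataclass
class AvoidanceScore:
    """Area above the declining segment of the piecewise effect curve."""

    area: float
    tau_hat: float
    beta_int: float
    u_max: float

    def __float__(self) -> float:
        return self.area


def avoidance_score(fit: PiecewiseFit, u_max: float = obs.MAX_OVERALL_UNCERTAINTY) -> AvoidanceScore:
    """Integrated shortfall of s(U) below beta_low on (tau_hat, u_max].

    For the hinge form with beta_int < 0 this is the triangular area
    ``|beta_int| * (u_max - tau)^2 / 2``; for the step form it is the rectangle
    ``|beta_int| * (u_max - tau)``.  Zero when beta_int >= 0 or tau >= u_max.
    """
    width = u_max - fit.tau_hat
    if fit.beta_int >= 0.0 or width <= 0.0:
        area = 0.0
    elif fit.form == "hinge":
        area = 0.5 * abs(fit.beta_int) * width ** 2
    else:
        area = abs(fit.beta_int) * width
    return AvoidanceScore(area=area, tau_hat=fit.tau_hat,
                          beta_int=fit.beta_int, u_max=u_max)


def fraction_above_threshold(design: pd.DataFrame, tau: float) -> float:
    """Fraction of trials whose overall uncertainty exceeds tau."""
    if len(design) == 0:
        raise ValueError("empty design")
    return float(np.mean(design["overall_uncertainty"].to_numpy() > tau))


@dataclass
class ApproachAvoidResult:
    """Per-participant approach slopes and avoidance scores, with their correlation."""

    table: pd.DataFrame      # participant_id, tau_hat, beta_low, beta_int, avoidance
    correlation: float       # Pearson r between beta_low and avoidance
    p_value: float           # two-sided permutation p-value
    group_fit: PiecewiseFit
    excluded: list = field(default_factory=list)


def approach_avoid_individuals(design: pd.DataFrame,
                               tau_grid: np.ndarray | None = None,
                               ridge: float = 1.0, form: str = "hinge",
                               prior_weight: float | None = None,
                               min_trials: int = 100, n_perm: int = 2000,
                               rng: np.random.Generator | None = None) -> ApproachAvoidResult:
    """Individual piecewise fits with group shrinkage on the threshold.

    Each participant's tau is profiled on the shared grid with the pooled
    profile added as a log-prior (scaled by ``prior_weight``, default
    1/n_participants, i.e. one average participant's worth of pooled
    evidence), which stabilizes individuals with few high-uncertainty trials.
    Participants with fewer than ``min_trials`` trials or with no trials above
    their profiled threshold are excluded and logged.
    """
    rng = rng or np.random.default_rng(0)
    if tau_grid is None:
        tau_grid = default_tau_grid(step=0.02)
    tau_grid = np.asarray(tau_grid, dtype=float)

    group_fit = fit_piecewise(design, tau_grid=tau_grid, ridge=ridge, form=form)
    pids = design["participant_id"].to_numpy()
    uniq = np.unique(pids)
    w = prior_weight if prior_weight is not None else 1.0 / len(uniq)
    gobj = group_fit.profile["objective"].to_numpy()
    log_prior = w * (gobj - gobj.max())

    rows, excluded = [], []
    for pid in uniq:
        sub = design[pids == pid]
        if len(sub) < min_trials:
            excluded.append((pid, "too few trials"))
            log.info("participant %s excluded: %d < %d trials", pid, len(sub), min_trials)
            continue
        y = sub["y"].to_numpy(dtype=float)
        u = sub["overall_uncertainty"].to_numpy(dtype=float)
        objectives = np.empty(len(tau_grid))
        coefs = np.empty((len(tau_grid), 4))
        beta0 = None
        for i, tau in enumerate(tau_grid):
            X = _piecewise_design(sub, float(tau), form)
            res = ridge_logit(X, y, lam=ridge, beta0=beta0, tol=1e-7, light=True)
            objectives[i] = res.objective
            coefs[i] = res.coef
            beta0 = res.coef
        i_hat = int(np.argmax(objectives + log_prior))
        tau_i = float(tau_grid[i_hat])
        if not np.any(u > tau_i):
            excluded.append((pid, "beta_int unidentifiable"))
            log.info("participant %s excluded: no trials above tau=%.3f", pid, tau_i)
            continue
        b = coefs[i_hat]
        fit_i = PiecewiseFit(
            tau_hat=tau_i, beta_side=float(b[0]), beta_rep=float(b[1]),
            beta_low=float(b[2]), beta_int=float(b[3]), se={},
            profile=pd.DataFrame({"tau": tau_grid, "objective": objectives}),
            frac_above=float(np.mean(u > tau_i)), form=form, ridge=ridge,
            n_trials=len(sub), beta_int_identifiable=True, loglik=np.nan,
            null_loglik=np.nan,
        )
        rows.append({
            "participant_id": pid, "n_trials": len(sub), "tau_hat": tau_i,
            "beta_low": fit_i.beta_low, "beta_int": fit_i.beta_int,
            "avoidance": avoidance_score(fit_i).area,
            "frac_above": fit_i.frac_above,
        })

    table = pd.DataFrame(rows)
    if len(table) >= 3:
        x = table["beta_low"].to_numpy()
        z = table["avoidance"].to_numpy()
        if x.std() > 0 and z.std() > 0:
            r_obs = float(np.corrcoef(x, z)[0, 1])
            perm = np.empty(n_perm)
            for k in range(n_perm):
                perm[k] = np.corrcoef(x, rng.permutation(z))[0, 1]
            p = float((np.sum(np.abs(perm) >= abs(r_obs)) + 1) / (n_perm + 1))
        else:
            r_obs, p = np.nan, np.nan
    else:
        r_obs, p = np.nan, np.nan

    return ApproachAvoidResult(table=table, correlation=r_obs, p_value=p,
                               group_fit=group_fit, excluded=excluded)
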