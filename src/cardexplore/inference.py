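"""Logistic strategy inference: which decision variable explains exploratory choice.

For each candidate strategy (Delta-EIG, Delta-uncertainty, Delta-exposure) a
logistic choice model ``logit P(right) = b_side + b_rep * r + b_dv * z(DV)`` is
fitted by ridge-penalized maximum likelihood per participant, with a
precision-weighted population summary (a deterministic two-stage stand-in for
a multilevel model; the default ridge lambda = 1 on the standardized scale
plays the role of a standard-normal regularizing prior).  Models are compared
by exact stratified k-fold cross-validated log predictive density, the same
comparison semantics as an expected-log-predictive-density score, and the
whole procedure is validated by model-recovery simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import observer as obs
from .agents import SimDataset, DatasetSpec, simulate_dataset

__all__ = [
    "ridge_logit",
    "RidgeLogitResult",
    "prepare_predictors",
    "LogisticFit",
    "fit_choice_model",
    "ModelComparison",
    "compare_strategies",
    "RecoveryMatrix",
    "recover_models",
    "exposure_epiphenomenon_check",
]

#: tie-break order for model comparison: simpler strategies first
STRATEGY_COMPLEXITY = {"exposure": 0, "uncertainty": 1, "eig": 2}


@dataclass
class RidgeLogitResult:
    coef: np.ndarray
    se: np.ndarray | None
    cov: np.ndarray | None
    loglik: float          # unpenalized Bernoulli log-likelihood at the optimum
    objective: float       # penalized log-likelihood (profile value)
    n_iter: int
    converged: bool


def ridge_logit(X: np.ndarray, y: np.ndarray, lam: float = 1.0,
                beta0: np.ndarray | None = None, max_iter: int = 100,
                tol: float = 1e-10, light: bool = False) -> RidgeLogitResult:
    """Newton solver for logistic regression with an L2 penalty on all coefficients.

    Maximizes sum(y log p + (1-y) log(1-p)) - lam/2 * ||beta||^2.  The penalty
    guarantees a finite optimum even under perfect separation.  Standard errors
    come from the inverse penalized Hessian.  ``light=True`` skips the final
    covariance/log-likelihood pass (used when profiling over a grid).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    beta = np.zeros(d) if beta0 is None else np.array(beta0, dtype=float)
    eye = lam * np.eye(d)

    def objective(b):
        eta = X @ b
        # stable log-likelihood: sum(y*eta - log(1+exp(eta)))
        ll = float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))
        return ll - 0.5 * lam * float(b @ b)

    obj = objective(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        grad = X.T @ (y - p) - lam * beta
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (X.T * w) @ X + eye
        step = np.linalg.solve(H, grad)
        # step-halving line search on the penalized objective
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                break
            scale *= 0.5
        beta, obj = cand, cand_obj
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    if not converged and it == max_iter:
        # Newton with ridge is strictly concave; reaching max_iter without
        # satisfying the step tolerance still yields usable estimates
        converged = np.max(np.abs(step)) < 1e-6
    if light:
        return RidgeLogitResult(beta, None, None, np.nan, obj, it, bool(converged))
    p = expit(X @ beta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = (X.T * w) @ X + eye
    cov = np.linalg.inv(H)
    eta = X @ beta
    loglik = float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))
    return RidgeLogitResult(beta, np.sqrt(np.diag(cov)), cov, loglik,
                            obj, it, bool(converged))


def prepare_predictors(data: SimDataset | pd.DataFrame,
                       scaling: dict[str, float] | None | str = "stored",
                       drop_practice: bool = True,
                       max_overall_uncertainty: float | None = None) -> pd.DataFrame:
    """Build the trial-level design table for the choice models.

    ``scaling``: "stored" uses the dataset's generation-time constants when
    available (so generation and fitting share the same scale); None z-scores
    empirically within the dataset; a dict divides by the given constants.
    Overall uncertainty is kept raw (nats) and also z-scored empirically.
    Practice rounds are excluded by default, as in the analysis.
    """
    if isinstance(data, SimDataset):
        trials = data.trials
        stored = data.scaling
    else:
        trials = data
        stored = None
    if scaling == "stored":
        scaling = stored  # may still be None -> empirical
    if drop_practice and "is_practice" in trials:
        trials = trials[~trials["is_practice"].astype(bool)]
    if len(trials) == 0:
        raise ValueError("no trials left after filtering")
    if max_overall_uncertainty is not None:
        trials = trials[trials["overall_uncertainty"] <= max_overall_uncertainty]

    out = pd.DataFrame({
        "participant_id": trials["participant_id"].to_numpy(),
        "session": trials["session"].to_numpy(),
        "round_id": trials["round_id"].to_numpy(),
        "y": trials["choice_side"].to_numpy(dtype=float),
        "r": trials["repeat_side"].to_numpy(dtype=float),
        "overall_uncertainty": trials["overall_uncertainty"].to_numpy(dtype=float),
    })
    used_scaling: dict[str, float] = {}
    for kind in obs.DV_KINDS:
        raw = trials[f"delta_{kind}"].to_numpy(dtype=float)
        if isinstance(scaling, dict):
            out[f"z_delta_{kind}"] = raw / scaling[kind]
            used_scaling[kind] = float(scaling[kind])
        else:
            sd = raw.std()
            if sd == 0.0:
                warnings.warn(
                    f"delta_{kind} has zero variance; left unscaled", RuntimeWarning
                )
                out[f"z_delta_{kind}"] = raw - raw.mean()
                used_scaling[kind] = 1.0
            else:
                out[f"z_delta_{kind}"] = (raw - raw.mean()) / sd
                used_scaling[kind] = float(sd)
    u = out["overall_uncertainty"].to_numpy()
    u_sd = u.std()
    out["z_overall_uncertainty"] = (u - u.mean()) / u_sd if u_sd > 0 else u - u.mean()
    out.attrs["scaling"] = used_scaling
    return out.reset_index(drop=True)


COEF_NAMES = ("side", "repeat", "dv")


def _design_matrix(design: pd.DataFrame, dv_kind: str) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack([
        np.ones(len(design)),
        design["r"].to_numpy(),
        design[f"z_delta_{dv_kind}"].to_numpy(),
    ])
    return X, design["y"].to_numpy(dtype=float)


@dataclass
class LogisticFit:
    """Fitted choice model for one candidate strategy."""

    dv_kind: str
    population: pd.DataFrame          # index: coef name; columns: estimate, se
    pooled: pd.DataFrame              # same layout, from the all-trials fit
    per_participant: pd.DataFrame     # one row per participant with coefs and SEs
    n_trials: int
    ridge: float

    @property
    def dv_slope(self) -> float:
        return float(self.population.loc["dv", "estimate"])

    @property
    def dv_slope_se(self) -> float:
        return float(self.population.loc["dv", "se"])


def fit_choice_model(design: pd.DataFrame, dv_kind: str, ridge: float = 1.0,
                     min_trials: int = 20) -> LogisticFit:
    """Per-participant ridge logistic fits with a precision-weighted population summary.

    Participants with fewer than ``min_trials`` trials are excluded from the
    per-participant stage (the pooled fit always uses everyone).
    """
    if dv_kind not in obs.DV_KINDS:
        raise ValueError(f"unknown dv_kind {dv_kind!r}; expected one of {obs.DV_KINDS}")
    X, y = _design_matrix(design, dv_kind)
    pooled_res = ridge_logit(X, y, lam=ridge)
    pooled = pd.DataFrame({"estimate": pooled_res.coef, "se": pooled_res.se},
                          index=list(COEF_NAMES))

    rows = []
    pids = design["participant_id"].to_numpy()
    for pid in np.unique(pids):
        mask = pids == pid
        if mask.sum() < min_trials:
            continue
        res = ridge_logit(X[mask], y[mask], lam=ridge, beta0=pooled_res.coef)
        row = {"participant_id": pid, "n_trials": int(mask.sum()),
               "loglik": res.loglik, "converged": res.converged}
        for j, name in enumerate(COEF_NAMES):
            row[name] = res.coef[j]
            row[f"{name}_se"] = res.se[j]
        rows.append(row)
    per_part = pd.DataFrame(rows)

    if len(per_part) > 0:
        est, se = [], []
        for name in COEF_NAMES:
            w = 1.0 / per_part[f"{name}_se"].to_numpy() ** 2
            b = per_part[name].to_numpy()
            est.append(float(np.sum(w * b) / np.sum(w)))
            se.append(float(np.sqrt(1.0 / np.sum(w))))
        population = pd.DataFrame({"estimate": est, "se": se}, index=list(COEF_NAMES))
    else:
        population = pooled.copy()

    return LogisticFit(dv_kind=dv_kind, population=population, pooled=pooled,
                       per_participant=per_part, n_trials=len(design), ridge=ridge)


def _fold_assignment(design: pd.DataFrame, k_folds: int, seed: int) -> np.ndarray:
    """Participant-stratified folds: each participant's trials spread over all folds."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(design), dtype=int)
    pids = design["participant_id"].to_numpy()
    for pid in np.unique(pids):
        idx = np.flatnonzero(pids == pid)
        perm = rng.permutation(len(idx))
        folds[idx[perm]] = np.arange(len(idx)) % k_folds
    return folds


@dataclass
class ModelComparison:
    """Cross-validated comparison of the candidate strategies."""

    scores: dict[str, float]               # total held-out log predictive density
    fold_scores: pd.DataFrame              # fold x model
    pairwise: pd.DataFrame                 # model_a, model_b, diff, se
    ranking: list[str]                     # best model first
    k_folds: int
    n_trials: int
    fold_assignment: np.ndarray = field(repr=False, default=None)

    @property
    def best(self) -> str:
        return self.ranking[0]


def compare_strategies(design: pd.DataFrame, k_folds: int = 10,
                       dv_kinds: tuple[str, ...] = obs.DV_KINDS,
                       ridge: float = 1.0, seed: int = 0,
                       min_trials: int = 20) -> ModelComparison:
    """Exact k-fold cross-validated log predictive density per candidate model.

    Folds are stratified by participant; held-out trials are scored with that
    participant's training-fold coefficients (pooled coefficients if the
    participant has too few training trials).  Pairwise differences carry a
    standard error computed over fold-level differences.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    folds = _fold_assignment(design, k_folds, seed)
    y_all = design["y"].to_numpy(dtype=float)
    # merge any fold whose held-out responses are single-class into its neighbor
    k = k_folds
    merged = True
    while merged and k > 2:
        merged = False
        for f in range(k):
            yf = y_all[folds == f]
            if len(yf) == 0 or yf.min() == yf.max():
                folds[folds == f] = (f + 1) % k
                folds[folds > f] -= 1
                k -= 1
                merged = True
                break

    pids = design["participant_id"].to_numpy()
    uniq_pids = np.unique(pids)
    fold_rows = []
    for f in range(k):
        test_mask = folds == f
        train_mask = ~test_mask
        row = {"fold": f, "n_test": int(test_mask.sum())}
        for kind in dv_kinds:
            X, y = _design_matrix(design, kind)
            pooled = ridge_logit(X[train_mask], y[train_mask], lam=ridge)
            logdens = 0.0
            for pid in uniq_pids:
                pm = pids == pid
                tr = pm & train_mask
                te = pm & test_mask
                if te.sum() == 0:
                    continue
                if tr.sum() >= min_trials:
                    res = ridge_logit(X[tr], y[tr], lam=ridge, beta0=pooled.coef)
                    coef = res.coef
                else:
                    coef = pooled.coef
                p = expit(X[te] @ coef)
                p = np.clip(p, 1e-12, 1.0 - 1e-12)
                yt = y[te]
                logdens += float(np.sum(yt * np.log(p) + (1.0 - yt) * np.log(1.0 - p)))
            row[kind] = logdens
        fold_rows.append(row)

    fold_df = pd.DataFrame(fold_rows).set_index("fold")
    scores = {kind: float(fold_df[kind].sum()) for kind in dv_kinds}
    ranking = sorted(dv_kinds,
                     key=lambda m: (-scores[m], STRATEGY_COMPLEXITY.get(m, 99)))
    pairs = []
    for i, a in enumerate(dv_kinds):
        for b in dv_kinds[i + 1:]:
            d = fold_df[a].to_numpy() - fold_df[b].to_numpy()
            pairs.append({
                "model_a": a, "model_b": b,
                "diff": float(d.sum()),
                "se": float(np.sqrt(k) * d.std(ddof=1)) if k > 1 else np.nan,
            })
    return ModelComparison(scores=scores, fold_scores=fold_df,
                           pairwise=pd.DataFrame(pairs), ranking=ranking,
                           k_folds=k, n_trials=len(design),
                           fold_assignment=folds)


@dataclass
class RecoveryMatrix:
    """Generating-model x winning-model counts over replicate simulations."""

    counts: pd.DataFrame    # index: generator, columns: winner
    n_replicates: int

    @property
    def diagonal_rate(self) -> dict[str, float]:
        return {g: float(self.counts.loc[g, g]) / self.n_replicates
                for g in self.counts.index if g in self.counts.columns}

    def diagonal_dominates(self) -> bool:
        for g in self.counts.index:
            row = self.counts.loc[g]
            diag = row.get(g, 0)
            if any(row[c] >= diag for c in row.index if c != g):
                return False
        return True


def recover_models(population_specs: dict[str, DatasetSpec], n_replicates: int,
                   rng: np.random.Generator, k_folds: int = 10,
                   dv_kinds: tuple[str, ...] = obs.DV_KINDS,
                   ridge: float = 1.0) -> RecoveryMatrix:
    """Simulate from each generating population, fit all candidates, count winners."""
    counts = pd.DataFrame(0, index=list(population_specs), columns=list(dv_kinds))
    for gen_name, spec in population_specs.items():
        for rep in range(n_replicates):
            ds = simulate_dataset(spec, rng)
            design = prepare_predictors(ds)
            cv_seed = int(rng.integers(2 ** 31))
            comp = compare_strategies(design, k_folds=k_folds, dv_kinds=dv_kinds,
                                      ridge=ridge, seed=cv_seed)
            counts.loc[gen_name, comp.best] += 1
    return RecoveryMatrix(counts=counts, n_replicates=n_replicates)


def exposure_epiphenomenon_check(design: pd.DataFrame,
                                 ridge: float = 1.0) -> tuple[float, float]:
    """Population Delta-exposure slope and its SE on the given dataset.

    The exposure predictor is oriented so the least-exposure heuristic
    predicts a positive slope.  On data generated by uncertainty-guided agents
    the fitted slope is expected to be negative: such agents keep returning to
    harder-to-learn tables, so the table they choose is typically the one they
    have already seen *more* of — the opposite of the exposure heuristic.
    """
    fit = fit_choice_model(design, "exposure", ridge=ridge)
    return fit.dv_slope, fit.dv_slope_se
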