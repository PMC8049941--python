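"""Fitting the explanatory item-response model from response data.

The observation model for respondent p answering item i is

    P(correct) = c + (d - c) * logistic(x_i' beta + u_p),   u_p ~ Normal(0, sigma^2)

i.e. a logistic mixed-effects regression squeezed between a guessing floor c
and an inattention ceiling d.  The marginal likelihood integrates the random
participant intercept out by Gauss-Hermite quadrature (one latent dimension
per participant), maximized with L-BFGS-B using an analytic gradient.  This
fit is written here rather than delegated because no installed mixed-model
routine accepts the floor/ceiling-modified link; the c=0, d=1, sigma=0
limiting case is cross-checked against an ordinary logistic regression in the
test suite.

On top of the core fit sit the calibration-pipeline steps: profile search
over the asymptotes (c, d), random-forest permutation-importance screening of
candidate predictors, exhaustive best-subset search under BIC, and k-fold
cross-validated classification accuracy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, train_test_split
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "FitResult",
    "build_design",
    "fit_model",
    "optimize_asymptotes",
    "screen_predictors",
    "subset_search",
    "cv_accuracy",
    "fit_split_then_joint",
    "DEFAULT_C_GRID",
    "DEFAULT_D_GRID",
]

#: Default profile grids for the guessing floor and inattention ceiling.
DEFAULT_C_GRID = tuple(np.round(np.arange(0.0, 0.501, 0.05), 2))
DEFAULT_D_GRID = tuple(np.round(np.arange(0.80, 1.001, 0.05), 2))

#: Map from coefficient-style feature names to tabular column names.
_FEATURE_COLUMNS = {
    "probability_probe_last_heard": "ProbabilityProbe_LastHeard",
    "level": "Level",
    "probe_trueim_absdiff": "ProbeTrueIm_AbsDiff",
    "heard_range": "Heard_Range",
    "probability_probe": "Probability_Probe",
    "probe_is_startnote": "ProbeNote_is_StartNote",
}


class DegenerateDataError(ValueError):
    """All responses identical: the model is not identifiable."""


@dataclass
class FitResult:
    """A fitted explanatory response model."""

    coefficients: dict[str, float]
    guessing: float
    inattention: float
    participant_effect_sd: float
    log_likelihood: float
    bic: float
    n_obs: int
    n_params: int
    converged: bool
    message: str = ""
    standard_errors: dict[str, float] = field(default_factory=dict)
    participant_effects: dict = field(default_factory=dict)
    feature_subset: tuple[str, ...] = ()

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        beta = np.array(
            [self.coefficients[n] for n in ("intercept", *self.feature_subset)]
        )
        return X @ beta


def _column_values(features: pd.DataFrame, name: str) -> np.ndarray:
    base = name.split(":", 1)[-1]
    col = _FEATURE_COLUMNS.get(base, base)
    if col not in features.columns:
        raise KeyError(f"feature {name!r}: column {col!r} not found")
    return features[col].to_numpy(dtype=float)


def build_design(
    merged: pd.DataFrame, feature_subset: Sequence[str]
) -> np.ndarray:
    """Design matrix (intercept first) for a merged response+feature table.

    Names may be plain features (``"level"`` or ``"Level"``: a main effect)
    or probe-accuracy interaction terms (``"correct:level"`` /
    ``"incorrect:level"``: the feature masked to correct- or incorrect-probe
    rows, matching the joint-model parameterization).
    """
    n = len(merged)
    cols = [np.ones(n)]
    acc = merged["Probe_Accuracy"].to_numpy(dtype=float) if "Probe_Accuracy" in merged else None
    for name in feature_subset:
        v = _column_values(merged, name)
        if name.startswith(("correct:", "incorrect:")):
            if acc is None:
                raise KeyError("interaction terms require a Probe_Accuracy column")
            mask = acc if name.startswith("correct:") else 1.0 - acc
            v = v * mask
        cols.append(v)
    return np.column_stack(cols)


def _merge(data: pd.DataFrame, features: pd.DataFrame | None) -> pd.DataFrame:
    required = {"participant_id", "item_id", "correct"}
    if not required <= set(data.columns):
        raise ValueError(f"response table must have columns {sorted(required)}")
    if features is not None:
        data = data.merge(features, on="item_id", how="left", validate="m:1")
        if data.isna().any().any():
            missing = data.loc[data.isna().any(axis=1), "item_id"].unique()[:5]
            raise ValueError(f"items without features, e.g. {list(missing)}")
    return data


def _marginal_loglik_and_grad(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    pid: np.ndarray,
    n_pid: int,
    c: float,
    d: float,
    nodes: np.ndarray,
    log_w: np.ndarray,
    free_sigma: bool,
):
    """Negative marginal log-likelihood and gradient (Gauss-Hermite)."""
    if free_sigma:
        beta, sigma = params[:-1], params[-1]
    else:
        beta, sigma = params, 0.0
    eta = X @ beta
    u = np.sqrt(2.0) * sigma * nodes  # latent intercept at each node
    z = eta[:, None] + u[None, :]  # (n_obs, K)
    s = expit(z)
    p = c + (d - c) * s
    lp = y[:, None] * np.log(p) + (1.0 - y[:, None]) * np.log1p(-p)
    S = np.zeros((n_pid, lp.shape[1]))
    np.add.at(S, pid, lp)
    A = S + log_w[None, :]
    per_pid = logsumexp(A, axis=1)
    loglik = float(per_pid.sum())
    # posterior node weights per participant
    R = np.exp(A - per_pid[:, None])
    Robs = R[pid]  # (n_obs, K)
    g = (y[:, None] - p) / (p * (1.0 - p)) * (d - c) * s * (1.0 - s)
    w_obs = Robs * g
    grad_beta = X.T @ w_obs.sum(axis=1)
    if free_sigma:
        grad_sigma = float((w_obs * (np.sqrt(2.0) * nodes)[None, :]).sum())
        grad = np.append(grad_beta, grad_sigma)
    else:
        grad = grad_beta
    return -loglik, -grad


def fit_model(
    data: pd.DataFrame,
    feature_subset: Sequence[str] = (),
    c: float = 0.3,
    d: float = 0.95,
    features: pd.DataFrame | None = None,
    sigma_zero: bool = False,
    n_quadrature: int = 15,
    start: np.ndarray | None = None,
    compute_se: bool = True,
    maxiter: int = 500,
) -> FitResult:
    """Maximize the approximate marginal likelihood of the explanatory model.

    Parameters
    ----------
    data:
        Long-format responses (participant_id, item_id, correct), optionally
        already carrying the feature columns; otherwise pass ``features``
        (one row per item_id) to merge.
    feature_subset:
        Predictor names (see :func:`build_design`); empty fits the null model
        (intercept + participant effect).
    c, d:
        Guessing floor and inattention ceiling, fixed for this call.
    sigma_zero:
        Force the participant-effect SD to zero (plain fixed-effects fit).

    Notes
    -----
    Deterministic: no randomness enters the optimizer.  Non-convergence is
    reported on the result (``converged=False`` with the optimizer message),
    never silently.
    """
    merged = _merge(data, features)
    y = merged["correct"].to_numpy(dtype=float)
    if len(y) == 0:
        raise ValueError("empty response table")
    if y.min() == y.max():
        raise DegenerateDataError("all responses identical (all 0 or all 1)")
    if not 0.0 <= c < d <= 1.0:
        raise ValueError("asymptotes must satisfy 0 <= c < d <= 1")
    X = build_design(merged, feature_subset)
    pids, pid_codes = np.unique(merged["participant_id"].to_numpy(), return_inverse=True)
    n_pid = len(pids)
    free_sigma = not sigma_zero
    if free_sigma:
        t, w = np.polynomial.hermite.hermgauss(n_quadrature)
        log_w = np.log(w) - 0.5 * np.log(np.pi)
    else:
        t = np.zeros(1)
        log_w = np.zeros(1)
    p_fixed = X.shape[1]
    if start is None:
        x0 = np.zeros(p_fixed + (1 if free_sigma else 0))
        if free_sigma:
            x0[-1] = 0.5
    else:
        x0 = np.asarray(start, dtype=float)
    bounds = [(None, None)] * p_fixed + ([(0.0, 10.0)] if free_sigma else [])
    args = (X, y, pid_codes, n_pid, c, d, t, log_w, free_sigma)
    res = minimize(
        _marginal_loglik_and_grad,
        x0,
        args=args,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    beta = res.x[:p_fixed]
    sigma = float(res.x[-1]) if free_sigma else 0.0
    loglik = -float(res.fun)
    n_params = p_fixed + (1 if free_sigma else 0)
    n_obs = len(y)
    names = ("intercept", *feature_subset)
    se: dict[str, float] = {}
    if compute_se:
        try:
            H = approx_hess(res.x, lambda v: _marginal_loglik_and_grad(v, *args)[0])
            cov = np.linalg.pinv(H)
            diag = np.clip(np.diag(cov), 0.0, None)
            se = {n: float(np.sqrt(diag[i])) for i, n in enumerate(names)}
        except Exception:  # pragma: no cover - SEs are advisory
            se = {}
    # posterior-mean participant effects (used for within-sample prediction)
    eta = X @ beta
    u = np.sqrt(2.0) * sigma * t
    z = eta[:, None] + u[None, :]
    p = c + (d - c) * expit(z)
    lp = y[:, None] * np.log(p) + (1.0 - y[:, None]) * np.log1p(-p)
    S = np.zeros((n_pid, lp.shape[1]))
    np.add.at(S, pid_codes, lp)
    A = S + log_w[None, :]
    R = np.exp(A - logsumexp(A, axis=1)[:, None])
    u_hat = R @ u
    return FitResult(
        coefficients={n: float(b) for n, b in zip(names, beta)},
        guessing=c,
        inattention=d,
        participant_effect_sd=sigma,
        log_likelihood=loglik,
        bic=-2.0 * loglik + n_params * np.log(n_obs),
        n_obs=n_obs,
        n_params=n_params,
        converged=bool(res.success),
        message=str(res.message),
        standard_errors=se,
        participant_effects={pid: float(u) for pid, u in zip(pids, u_hat)},
        feature_subset=tuple(feature_subset),
    )


def optimize_asymptotes(
    data: pd.DataFrame,
    feature_subset: Sequence[str] = (),
    grid: tuple[Sequence[float], Sequence[float]] | None = None,
    features: pd.DataFrame | None = None,
    **fit_kwargs,
) -> FitResult:
    """Profile the likelihood over the (c, d) asymptote grid.

    Fits the mixed model at every admissible grid point (c < d) and returns
    the best fit by profile likelihood, with the two searched asymptotes
    counted as parameters in its BIC.
    """
    c_grid, d_grid = grid if grid is not None else (DEFAULT_C_GRID, DEFAULT_D_GRID)
    merged = _merge(data, features)
    best: FitResult | None = None
    warm: np.ndarray | None = None
    for c in c_grid:
        for d in d_grid:
            if not c < d:
                continue
            fit = fit_model(
                merged, feature_subset, c=float(c), d=float(d),
                start=warm, compute_se=False, **fit_kwargs,
            )
            warm = np.array(
                [fit.coefficients[n] for n in ("intercept", *fit.feature_subset)]
                + ([fit.participant_effect_sd] if not fit_kwargs.get("sigma_zero") else [])
            )
            if best is None or fit.log_likelihood > best.log_likelihood:
                best = fit
    assert best is not None
    best.n_params += 2  # searched asymptotes
    best.bic = -2.0 * best.log_likelihood + best.n_params * np.log(best.n_obs)
    return best


def screen_predictors(
    data: pd.DataFrame,
    all_features: Sequence[str],
    n_keep: int | None = None,
    rng: int | np.random.Generator = 0,
    features: pd.DataFrame | None = None,
    n_estimators: int = 300,
    n_repeats: int = 10,
) -> list[str]:
    """Rank candidate predictors by held-out permutation importance.

    A random-forest classifier of response correctness is trained on 70% of
    the observations; importance is the mean decrease in held-out accuracy
    when a feature column is permuted.  Returns the top ``n_keep`` feature
    names (all, ranked, when ``n_keep`` is None).
    """
    if len(all_features) < 2:
        raise ValueError("need at least 2 candidate features to screen")
    merged = _merge(data, features)
    cols = {name: _column_values(merged, name) for name in all_features}
    Xf = pd.DataFrame(cols)
    y = merged["correct"].to_numpy(dtype=int)
    seed = int(rng.integers(2**31)) if isinstance(rng, np.random.Generator) else int(rng)
    X_tr, X_te, y_tr, y_te = train_test_split(
        Xf, y, test_size=0.3, random_state=seed, stratify=y
    )
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    ).fit(X_tr, y_tr)
    imp = permutation_importance(
        forest, X_te, y_te, n_repeats=n_repeats, random_state=seed, n_jobs=1
    )
    order = np.argsort(-imp.importances_mean)
    ranked = [list(all_features)[i] for i in order]
    return ranked if n_keep is None else ranked[:n_keep]


def subset_search(
    data: pd.DataFrame,
    candidate_features: Sequence[str],
    max_size: int | None = None,
    c: float = 0.3,
    d: float = 0.95,
    features: pd.DataFrame | None = None,
    search_asymptotes: bool = False,
    budget: int = 4096,
    **fit_kwargs,
) -> tuple[FitResult, pd.DataFrame]:
    """Exhaustive best-subset search under BIC.

    Fits every subset of the candidates (null model included), optionally
    re-profiling the asymptotes per subset, and returns the minimal-BIC fit
    plus the full per-subset table.
    """
    k = len(candidate_features)
    sizes = range(0, (max_size if max_size is not None else k) + 1)
    n_subsets = sum(1 for s in sizes for _ in itertools.combinations(range(k), s))
    if n_subsets > budget:
        raise ValueError(
            f"{n_subsets} subsets exceed the budget of {budget}; pass max_size"
        )
    merged = _merge(data, features)
    rows = []
    best: FitResult | None = None
    for size in sizes:
        for combo in itertools.combinations(candidate_features, size):
            if search_asymptotes:
                fit = optimize_asymptotes(merged, combo, **fit_kwargs)
            else:
                fit = fit_model(
                    merged, combo, c=c, d=d, compute_se=False, **fit_kwargs
                )
            rows.append(
                {
                    "subset": combo,
                    "size": size,
                    "c": fit.guessing,
                    "d": fit.inattention,
                    "log_likelihood": fit.log_likelihood,
                    "bic": fit.bic,
                    "n_params": fit.n_params,
                }
            )
            if best is None or fit.bic < best.bic:
                best = fit
    assert best is not None
    return best, pd.DataFrame(rows)


def _predict_probability(
    fit: FitResult, merged: pd.DataFrame, use_effects: bool
) -> np.ndarray:
    X = build_design(merged, fit.feature_subset)
    eta = fit.linear_predictor(X)
    if use_effects:
        eff = merged["participant_id"].map(fit.participant_effects).fillna(0.0)
        eta = eta + eff.to_numpy(dtype=float)
    return fit.guessing + (fit.inattention - fit.guessing) * expit(eta)


def cv_accuracy(
    data: pd.DataFrame,
    feature_subset: Sequence[str],
    k_folds: int = 10,
    with_participant_effects: bool = False,
    rng: int | np.random.Generator = 0,
    c: float = 0.3,
    d: float = 0.95,
    features: pd.DataFrame | None = None,
    **fit_kwargs,
) -> float:
    """Mean held-out 0/1 classification accuracy (threshold 0.5).

    Folds are stratified on the response.  When participant effects are used,
    the held-out prediction adds the posterior-mean effect fitted for that
    participant on the training folds (0 for unseen participants).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    merged = _merge(data, features).reset_index(drop=True)
    y = merged["correct"].to_numpy(dtype=int)
    if min(np.bincount(y, minlength=2)) < k_folds:
        raise ValueError("a fold would contain a single response class")
    seed = int(rng.integers(2**31)) if isinstance(rng, np.random.Generator) else int(rng)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(merged, y):
        fit = fit_model(
            merged.iloc[train_idx], feature_subset, c=c, d=d,
            compute_se=False, **fit_kwargs,
        )
        p = _predict_probability(fit, merged.iloc[test_idx], with_participant_effects)
        accs.append(float(np.mean((p >= 0.5).astype(int) == y[test_idx])))
    return float(np.mean(accs))


def fit_split_then_joint(
    data: pd.DataFrame,
    correct_subset: Sequence[str] = ("probability_probe_last_heard", "level"),
    incorrect_subset: Sequence[str] = ("probe_trueim_absdiff", "heard_range"),
    c: float = 0.3,
    d: float = 0.95,
    features: pd.DataFrame | None = None,
    **fit_kwargs,
) -> dict[str, FitResult]:
    """Fit correct-probe and incorrect-probe models separately, then the
    joint interaction model over the full data (the canonical output)."""
    merged = _merge(data, features)
    acc = merged["Probe_Accuracy"].astype(bool)
    out = {
        "correct": fit_model(
            merged[acc], correct_subset, c=c, d=d, **fit_kwargs
        ),
        "incorrect": fit_model(
            merged[~acc], incorrect_subset, c=c, d=d, **fit_kwargs
        ),
    }
    joint = [f"correct:{n}" for n in correct_subset]
    joint += [f"incorrect:{n}" for n in correct_subset]
    joint += [f"incorrect:{n}" for n in incorrect_subset if f"incorrect:{n}" not in joint]
    joint += [
        f"correct:{n}" for n in incorrect_subset
        if n != "probe_trueim_absdiff" and f"correct:{n}" not in joint
    ]
    out["joint"] = fit_model(merged, joint, c=c, d=d, **fit_kwargs)
    return out
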