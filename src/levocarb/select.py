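"""Adjusted adaptive LASSO covariate selection.

Candidate covariate-parameter relations enter a full model as linear
effects on standardised covariates (zero mean, unit SD across subjects).
The L1 constraint is adaptive: each standardised coefficient β_j is
weighted by w_j = |SE(β̂_j,ML)/β̂_j,ML| from a single unpenalised fit, and
the fit maximises the population likelihood subject to Σ w_j·|β_j| ≤ t.
Null covariates have small |β̂| relative to their SE, hence large weights,
and are effectively priced out of the active set.  The constraint size t
is chosen by k-fold cross-validation with folds stratified on study
association; the prediction error of a held-out fold is its Laplace OFV
under the training estimates with only the etas re-estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .estimate import (
    FitSettings,
    FreeSpec,
    _Objective,
    _pack_model,
    evaluate_ofv,
    fit_population,
)
from .model_core import CovariateEffect, PopulationModel
from .popsim import PKDataset

__all__ = [
    "LassoResult",
    "standardize_covariates",
    "adaptive_weights",
    "fit_constrained",
    "cv_select_t",
    "stratified_folds",
]

_COV_COLUMN = {"wt": "WT", "age": "AGE", "sex": "SEX", "hy": "HY",
               "cd_dose": "CDOSE", "years_ld": "YRSLD"}
_ZERO = 1e-8


@dataclass
class LassoResult:
    """Outcome of the cross-validated adaptive LASSO."""

    t_grid: np.ndarray
    cv_error: np.ndarray
    t_star: float
    coefficients_std: dict      # (parameter, covariate) -> standardised beta
    coefficients: dict          # (parameter, covariate) -> natural-scale beta
    weights: dict               # (parameter, covariate) -> adaptive weight
    folds: dict                 # subject id -> fold index
    scaling: dict               # covariate -> (mean, sd)
    ml_coefficients_std: dict = field(default_factory=dict)
    model: PopulationModel | None = None
    ofv: float = np.nan

    @property
    def active_set(self) -> list:
        return [k for k, v in self.coefficients_std.items() if abs(v) > _ZERO]


def standardize_covariates(dataset: PKDataset, covariates: list[str]):
    """Standardise subject-level covariates to mean 0, SD 1 (ddof=1).

    Returns ``(table, scaling)`` where ``table`` is indexed by subject ID
    and ``scaling`` maps each covariate to its ``(mean, sd)`` so that
    coefficients can be back-transformed exactly.  Zero-variance covariates
    are dropped with a warning.
    """
    subj = dataset.df.groupby("ID").first()
    out = {}
    scaling = {}
    for cov in covariates:
        col = _COV_COLUMN.get(cov)
        if col is None or col not in subj.columns:
            raise KeyError(f"unknown covariate {cov!r}")
        x = subj[col].astype(float)
        sd = float(x.std(ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            warnings.warn(f"covariate {cov!r} has zero variance; excluded",
                          stacklevel=2)
            continue
        mean = float(x.mean())
        out[cov] = (x - mean) / sd
        scaling[cov] = (mean, sd)
    return pd.DataFrame(out), scaling


def _model_with_candidates(model, candidates, scaling, coef_std=None):
    """Full covariate model: linear effects on (natural-scale) covariates.

    A standardised coefficient β_j on z = (x - mean)/sd is identical to a
    natural coefficient β_j/sd centred at the covariate mean, so the
    candidates are expressed in the model's own linear-effect form.
    """
    m = model.copy()
    effects = list(m.covariate_effects)
    for j, (par, cov) in enumerate(candidates):
        mean, sd = scaling[cov]
        beta_std = 0.0 if coef_std is None else float(coef_std[j])
        effects.append(
            CovariateEffect(parameter=par, covariate=cov, kind="linear",
                            coefficient=beta_std / sd, reference=mean)
        )
    m.covariate_effects = effects
    return m


def adaptive_weights(fit, candidates, se_std, clip=1e6):
    """w_j = |SE(β̂)/β̂| on the standardised scale, clipped to ``clip``.

    The ratio is scale-invariant, so natural-scale estimates and SEs give
    the same weights.  Near-zero ML coefficients receive the (large,
    finite) clip value and are thereby effectively excluded.
    """
    w = {}
    for (par, cov) in candidates:
        beta = fit[(par, cov)]
        se = se_std[(par, cov)]
        if abs(beta) < _ZERO or not np.isfinite(se):
            w[(par, cov)] = clip
        else:
            w[(par, cov)] = float(min(abs(se / beta), clip))
    return w


def _coef_se_std(dataset, model_hat, candidates, scaling, settings):
    """Block central-difference Hessian over the coefficients only."""
    free = FreeSpec(coefficients=list(candidates))
    x0, setter, _ = _pack_model(model_hat, free)
    obj = _Objective(dataset, model_hat, free, settings)
    h = settings.hessian_step * 10  # coefficients are O(0.1) on the std scale
    p = len(x0)
    f0 = obj(x0, setter)
    H = np.empty((p, p))
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = h
        fp[i] = obj(x0 + e, setter)
        fm[i] = obj(x0 - e, setter)
        H[i, i] = (fp[i] + fm[i] - 2 * f0) / h**2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ei[i] = h
            ej = np.zeros(p)
            ej[j] = h
            fpp = obj(x0 + ei + ej, setter)
            fmm = obj(x0 - ei - ej, setter)
            H[i, j] = H[j, i] = (fpp + fmm - fp[i] - fm[i] - fp[j] - fm[j]
                                 + 2 * f0) / (2 * h**2)
    try:
        cov = 2.0 * np.linalg.inv(H)
        se_nat = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_nat = np.full(p, np.nan)
    out = {}
    for (par, covname), se in zip(candidates, se_nat):
        _, sd = scaling[covname]
        out[(par, covname)] = se * sd  # natural SE -> standardised SE
    return out


@dataclass
class ConstrainedFit:
    model: PopulationModel
    coefficients_std: dict
    coefficients: dict
    ofv: float
    x: np.ndarray
    converged: bool


def fit_constrained(
    dataset: PKDataset,
    model: PopulationModel,
    candidates: list[tuple[str, str]],
    weights: dict,
    t: float,
    scaling: dict,
    free: FreeSpec | None = None,
    settings: FitSettings | None = None,
    x0: np.ndarray | None = None,
) -> ConstrainedFit:
    """Penalised fit under the adaptive L1 constraint Σ w_j·|β_j| ≤ t.

    Each scaled coefficient ``b_j = w_j·β_j`` is split into a positive and
    a negative part, turning the constraint into a smooth linear inequality
    over non-negative variables (solved with SLSQP); inactive coefficients
    sit exactly at zero.  ``free`` lists the structural parameters
    re-estimated alongside the coefficients.
    """
    if t < 0:
        raise ValueError("the tuning parameter t must be >= 0")
    if any(w <= 0 for w in weights.values()):
        raise ValueError("adaptive weights must be positive")
    settings = settings or FitSettings()
    free = free or FreeSpec.default(model, dataset)
    J = len(candidates)
    wvec = np.array([weights[c] for c in candidates])
    sdvec = np.array([scaling[c[1]][1] for c in candidates])

    base = _model_with_candidates(model, candidates, scaling)
    free_full = FreeSpec(theta=free.theta, omega=free.omega, sigma=free.sigma,
                         coefficients=list(free.coefficients) + list(candidates))
    xs0, setter, _ = _pack_model(base, free_full)
    n_struct = len(xs0) - J
    obj = _Objective(dataset, base, free_full, settings)

    def assemble(z):
        b = (z[n_struct:n_struct + J] - z[n_struct + J:]) / wvec  # beta_std
        x = np.concatenate([z[:n_struct], b / sdvec])  # natural coefficients
        return x

    def fun(z):
        return obj(assemble(z), setter)

    if x0 is None:
        z0 = np.concatenate([xs0[:n_struct], np.zeros(2 * J)])
    else:
        z0 = x0.copy()
    # keep every linear factor positive in-sample: |beta_nat| bounded
    from .estimate import coef_feasible_limit

    lim = np.array(
        [coef_feasible_limit(base, c, obj.arr["cov"]) for c in candidates]
    )
    b_cap = wvec * sdvec * lim  # bound on the split variables b±
    bounds = [(None, None)] * n_struct + [
        (0.0, float(c)) for c in np.concatenate([b_cap, b_cap])
    ]
    cons = [{"type": "ineq",
             "fun": lambda z: t - np.sum(z[n_struct:]),
             "jac": lambda z: np.concatenate([np.zeros(n_struct),
                                              -np.ones(2 * J)])}]
    res = optimize.minimize(
        fun, z0, method="SLSQP", bounds=bounds, constraints=cons,
        options={"maxiter": 120, "ftol": settings.constr_ftol,
                 "eps": settings.outer_eps},
    )
    z = res.x.copy()
    # collapse any positive/negative overlap, then enforce the constraint
    bp, bm = z[n_struct:n_struct + J], z[n_struct + J:]
    b = bp - bm
    # clear solver residue: anything below a sliver of the budget is zero
    b[np.abs(b) < max(1e-6 * t, 1e-10)] = 0.0
    z[n_struct:n_struct + J] = np.maximum(b, 0.0)
    z[n_struct + J:] = np.maximum(-b, 0.0)
    total = np.sum(np.abs(b))
    if total > t:
        # project any solver infeasibility back onto the constraint
        scale = t / total if total > 0 else 0.0
        z[n_struct:] *= scale
        b = z[n_struct:n_struct + J] - z[n_struct + J:]
    beta_std = b / wvec
    beta_std[np.abs(beta_std) < _ZERO] = 0.0
    ofv = obj(assemble(z), setter)
    model_hat = setter(assemble(z))
    coef_std = dict(zip(candidates, beta_std))
    coef_nat = dict(zip(candidates, beta_std / sdvec))
    return ConstrainedFit(model=model_hat, coefficients_std=coef_std,
                          coefficients=coef_nat, ofv=float(ofv), x=z,
                          converged=bool(res.success))


def _strip_candidates(model, candidates):
    """Remove the candidate linear effects, keeping fitted structural values."""
    m = model.copy()
    cand = set(candidates)
    m.covariate_effects = [
        e for e in m.covariate_effects
        if not (e.kind == "linear" and (e.parameter, e.covariate) in cand)
    ]
    return m


def stratified_folds(dataset: PKDataset, k: int, seed: int) -> dict:
    """Assign subjects to k folds, stratified on study association."""
    subj = dataset.df.groupby("ID").first()
    rng = np.random.default_rng(seed)
    folds = {}
    for _, grp in subj.groupby("STUDY"):
        ids = np.array(grp.index)
        rng.shuffle(ids)
        for pos, sid in enumerate(ids):
            folds[sid] = pos % k
    return folds


def _subset(dataset, ids):
    return PKDataset(dataset.df[dataset.df["ID"].isin(ids)].copy(),
                     validate=False)


def cv_select_t(
    dataset: PKDataset,
    model: PopulationModel,
    candidates: list[tuple[str, str]],
    k: int = 5,
    seed: int = 0,
    t_grid: np.ndarray | None = None,
    n_grid: int = 20,
    free: FreeSpec | None = None,
    settings: FitSettings | None = None,
    weights: dict | None = None,
    refit_structural: str = "always",
) -> LassoResult:
    """Choose the constraint size t by study-stratified cross-validation.

    The grid spans 0 to 1.2 × Σ w_j·|β̂_j,ML| (the constraint value at
    which the unpenalised optimum becomes feasible); the selected t is the
    prediction-error minimum, and the reported coefficients come from a
    full-data constrained fit at that t.  Deterministic for a fixed seed.

    ``refit_structural`` controls how much each training fit re-estimates:
    ``"always"`` re-estimates structural parameters at every t,
    ``"first"`` re-estimates them once per fold (at the loosest t) and then
    moves only the coefficients along the t-path — much cheaper and, with a
    fitted structural model, nearly indistinguishable for selection.
    """
    if refit_structural not in ("always", "first"):
        raise ValueError("refit_structural must be 'always' or 'first'")
    settings = settings or FitSettings()
    free = free or FreeSpec.default(model, dataset)
    covnames = sorted({c for _, c in candidates})
    _, scaling = standardize_covariates(dataset, covnames)
    candidates = [c for c in candidates if c[1] in scaling]

    # 1) unpenalised full model: ML coefficients and their SEs -> weights
    full = _model_with_candidates(model, candidates, scaling)
    free_ml = FreeSpec(theta=free.theta, omega=free.omega, sigma=free.sigma,
                       coefficients=list(candidates))
    ml_fit = fit_population(dataset, full, free=free_ml, settings=settings)
    beta_ml_nat = {c: ml_fit.coefficients[c] for c in candidates}
    beta_ml_std = {c: beta_ml_nat[c] * scaling[c[1]][1] for c in candidates}
    if weights is None:
        se_std = _coef_se_std(dataset, ml_fit.model, candidates, scaling,
                              settings)
        weights = adaptive_weights(beta_ml_std, candidates, se_std)

    wvec = np.array([weights[c] for c in candidates])
    bvec = np.array([beta_ml_std[c] for c in candidates])
    t_max = 1.2 * float(np.sum(wvec * np.abs(bvec)))
    if t_grid is None:
        if t_max <= 0:
            t_grid = np.array([0.0])
        else:
            t_grid = np.concatenate(
                [[0.0], np.geomspace(t_max / 50.0, t_max, n_grid - 1)]
            )
    t_grid = np.asarray(t_grid, dtype=float)

    folds = stratified_folds(dataset, k, seed)
    all_ids = list(folds)
    order = np.argsort(t_grid)[::-1]  # warm-start from the loosest fit
    cv_err = np.zeros(len(t_grid))
    for fold in range(k):
        test_ids = [s for s in all_ids if folds[s] == fold]
        train_ids = [s for s in all_ids if folds[s] != fold]
        if not test_ids or not train_ids:
            raise ValueError(f"fold {fold} is empty; reduce k")
        train = _subset(dataset, train_ids)
        test = _subset(dataset, test_ids)
        warm = None
        fold_model = model
        fold_free = free
        if refit_structural == "first":
            # one unconstrained re-estimation per fold (structural +
            # coefficients, quasi-Newton, warm-started at the full-data
            # ML estimates), then coefficient-only L1 fits
            ml_fold = fit_population(train, ml_fit.model, free=free_ml,
                                     settings=settings)
            fold_model = _strip_candidates(ml_fold.model, candidates)
            fold_free = FreeSpec()
        for idx in order:
            cf = fit_constrained(train, fold_model, candidates, weights,
                                 float(t_grid[idx]), scaling, free=fold_free,
                                 settings=settings, x0=warm)
            warm = cf.x
            cv_err[idx] += evaluate_ofv(test, cf.model, settings) / k
    i_star = int(np.argmin(cv_err))
    t_star = float(t_grid[i_star])

    warm = None
    final = None
    full_model = model
    full_free = free
    if refit_structural == "first":
        # the full-data unpenalised fit already provides the structural fit
        full_model = _strip_candidates(ml_fit.model, candidates)
        full_free = FreeSpec()
    for idx in order:
        final_t = fit_constrained(dataset, full_model, candidates, weights,
                                  float(t_grid[idx]), scaling, free=full_free,
                                  settings=settings, x0=warm)
        warm = final_t.x
        if idx == i_star:
            final = final_t
            break

    return LassoResult(
        t_grid=t_grid,
        cv_error=cv_err,
        t_star=t_star,
        coefficients_std=final.coefficients_std,
        coefficients=final.coefficients,
        weights=weights,
        folds=folds,
        scaling=scaling,
        ml_coefficients_std=beta_ml_std,
        model=final.model,
        ofv=final.ofv,
    )
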