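"""Cohort-level vectorised evaluation: covariates + etas -> profiles.

These helpers mirror :func:`levocarb.model_core.individual_parameters` and
:func:`levocarb.model_core.predict_concentration` but operate on arrays with
a leading subject axis, which is what the simulator, the likelihood and the
VPC machinery all iterate over.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

from . import _num
from .model_core import PopulationModel

__all__ = [
    "CovariateSignError",
    "individual_params_arrays",
    "batch_profiles",
    "prepare_drug_arrays",
]


class CovariateSignError(ValueError):
    """A linear covariate effect drove a parameter non-positive.

    ``violation`` quantifies how far below zero the worst factor went, so
    penalised objectives can slope back toward the feasible region.
    """

    def __init__(self, message, violation=0.0):
        super().__init__(message)
        self.violation = float(violation)


def individual_params_arrays(
    model: PopulationModel,
    cov: dict,
    etas: np.ndarray | None = None,
    eta_names: list[str] | None = None,
) -> dict:
    """Realised parameters for a batch of subjects.

    ``cov`` maps covariate keys (``wt``, ``age``, ...) to arrays ``(N,)``;
    ``etas`` is ``(N, d)`` aligned with ``eta_names`` (default
    ``model.eta_names``).  Returns a dict of ``(N,)`` arrays for every
    theta entry.
    """
    n = len(np.atleast_1d(next(iter(cov.values())))) if cov else 1
    p = {k: np.full(n, float(v)) for k, v in model.theta.items()}

    for kind in ("allometric", "linear", "interaction"):
        for eff in model.covariate_effects:
            if eff.kind != kind:
                continue
            value = np.asarray(cov[eff.covariate], dtype=float)
            if kind == "allometric":
                factor = (value / eff.reference) ** eff.coefficient
            elif kind == "linear":
                factor = 1.0 + eff.coefficient * (value - eff.reference)
                if np.any(factor <= 0.0):
                    raise CovariateSignError(
                        f"linear effect of covariate {eff.covariate!r} on "
                        f"{eff.parameter!r} drives the parameter non-positive",
                        violation=float(np.sum(np.minimum(factor, 0.0) ** 2)),
                    )
            else:
                factor = 1.0 / (1.0 + value / eff.coefficient)
            p[eff.parameter] = p[eff.parameter] * factor

    if etas is not None:
        if eta_names is None:
            eta_names = model.eta_names
        etas = np.atleast_2d(np.asarray(etas, dtype=float))
        with np.errstate(all="ignore"):
            for j, name in enumerate(eta_names):
                dist = model.omega[name].dist
                e = etas[:, j]
                if dist == "lognormal":
                    p[name] = p[name] * np.exp(e)
                elif dist == "normal":
                    p[name] = p[name] + e
                else:
                    p[name] = expit(logit(p[name]) + e)
    return p


def batch_profiles(model: PopulationModel, params: dict, times, dose_t, dose_a):
    """Concentration matrix ``(N, T)`` for realised parameter arrays."""
    return _num.profile_conc(
        times,
        dose_t,
        dose_a,
        params,
        model.transit.n1,
        model.transit.n2,
        model.n_disposition_compartments == 2,
    )


def _pad(rows, fill=0.0):
    width = max((len(r) for r in rows), default=0)
    out = np.full((len(rows), max(width, 1)), fill, dtype=float)
    mask = np.zeros_like(out, dtype=bool)
    for i, r in enumerate(rows):
        out[i, : len(r)] = r
        mask[i, : len(r)] = True
    return out, mask


def prepare_drug_arrays(dataset, drug: str) -> dict:
    """Extract padded per-subject arrays for one drug from a dataset.

    Returns a dict with ``ids``, observation ``times``/``dv``/``mask``
    (``(N, T)``), dose ``dose_t``/``dose_a`` (``(N, D)``), a covariate dict
    and a boolean ``patient`` flag (Hoehn & Yahr >= 1).
    """
    from .popsim import DRUG_DVID  # local import to avoid a cycle

    dvid = DRUG_DVID[drug]
    df = dataset.df
    ids = sorted(df["ID"].unique())
    t_rows, y_rows, dt_rows, da_rows = [], [], [], []
    cov_rows = {k: [] for k in ("wt", "age", "sex", "hy", "cd_dose")}
    patient = []
    col = {"wt": "WT", "age": "AGE", "sex": "SEX", "hy": "HY", "cd_dose": "CDOSE"}
    for sid in ids:
        sub = df[df["ID"] == sid]
        obs = sub[(sub["EVID"] == 0) & (sub["DVID"] == dvid)].sort_values("TIME")
        dose = sub[(sub["EVID"] == 1) & (sub["DVID"] == dvid)].sort_values("TIME")
        t_rows.append(obs["TIME"].to_numpy(dtype=float))
        y_rows.append(obs["DV"].to_numpy(dtype=float))
        dt_rows.append(dose["TIME"].to_numpy(dtype=float))
        da_rows.append(dose["AMT"].to_numpy(dtype=float))
        first = sub.iloc[0]
        for k in cov_rows:
            cov_rows[k].append(float(first[col[k]]))
        patient.append(float(first["HY"]) >= 1.0)
    times, mask = _pad(t_rows)
    dv, _ = _pad(y_rows)
    dose_t, dose_mask = _pad(dt_rows)
    dose_a, _ = _pad(da_rows)
    dose_a[~dose_mask] = 0.0
    # padded dose slots must not perturb the first-dose time used by the
    # pre-dose baseline term
    dose_t = np.where(dose_mask, dose_t, dose_t[:, :1])
    return {
        "ids": ids,
        "times": times,
        "mask": mask,
        "dv": dv,
        "dose_t": dose_t,
        "dose_a": dose_a,
        "cov": {k: np.asarray(v) for k, v in cov_rows.items()},
        "patient": np.asarray(patient, dtype=bool),
    }
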