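"""Structural and covariate model for levodopa/carbidopa population PK.

The structural model has two parallel transit-compartment absorption chains
(producing the double-peak concentration profiles seen after dissolved
microtablet dosing), one- or two-compartment disposition, and a pre-dose
baseline concentration that decays at the individual terminal slope.  The
covariate model composes, in order, allometric bodyweight scaling, linear
covariate effects and a nonlinear carbidopa-dose interaction, before the
subject's random effects are applied on each parameter's own scale.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.special import expit, gammaln, logit

from . import _num

__all__ = [
    "SubjectCovariates",
    "PKParameters",
    "TransitConfig",
    "CovariateEffect",
    "OmegaEntry",
    "ResidualSpec",
    "PopulationModel",
    "individual_parameters",
    "terminal_slope",
    "transit_input_rate",
    "predict_concentration",
    "predict_amounts",
    "load_model",
    "save_model",
    "load_packaged_model",
    "COVARIATE_FIELDS",
]

# dataset/config covariate keys -> SubjectCovariates attributes
COVARIATE_FIELDS = {
    "wt": "weight",
    "age": "age",
    "sex": "sex",
    "hy": "hy",
    "cd_dose": "cd_dose",
    "years_ld": "years_ld_treatment",
    "t_diagnosis": "time_since_diagnosis",
}


@dataclass(frozen=True)
class SubjectCovariates:
    """One subject's covariate vector.

    ``sex`` is 0 for male, 1 for female; ``hy`` is the Hoehn & Yahr stage
    (0 for healthy volunteers); ``cd_dose`` is the total carbidopa dose in
    mg used for the clearance interaction.
    """

    weight: float
    age: float
    sex: int = 0
    hy: int = 0
    cd_dose: float = 0.0
    study: str = ""
    years_ld_treatment: float = 0.0
    time_since_diagnosis: float = 0.0

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.hy not in (0, 1, 2, 3, 4, 5):
            raise ValueError("Hoehn & Yahr stage must be an integer in 0..5")
        if self.cd_dose < 0:
            raise ValueError("carbidopa dose must be non-negative")


@dataclass(frozen=True)
class PKParameters:
    """Realised structural parameters of one subject.

    Rates are per minute, volumes in litres, concentrations in µg/mL.
    ``q_f``/``vp_f`` are ``None`` for one-compartment disposition.
    """

    cl_f: float
    vc_f: float
    mtt1: float
    mtt2: float
    fa1: float
    f_rel: float = 1.0
    c0: float = 0.0
    q_f: float | None = None
    vp_f: float | None = None

    def __post_init__(self):
        for name in ("cl_f", "vc_f", "mtt1", "mtt2", "f_rel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.fa1 < 1.0:
            raise ValueError("fa1 must lie strictly between 0 and 1")
        if self.c0 < 0:
            raise ValueError("pre-dose concentration must be non-negative")
        if (self.q_f is None) != (self.vp_f is None):
            raise ValueError("q_f and vp_f must be given together")
        if self.q_f is not None and (self.q_f <= 0 or self.vp_f <= 0):
            raise ValueError("q_f and vp_f must be positive")

    @property
    def n_compartments(self) -> int:
        return 1 if self.q_f is None else 2

    @property
    def lambda_z(self) -> float:
        """Terminal slope (1/min) implied by the disposition parameters."""
        return terminal_slope(self, self.n_compartments)


@dataclass(frozen=True)
class TransitConfig:
    """Transit-compartment counts for the fast (n1) and slow (n2) chain."""

    n1: int
    n2: int

    def __post_init__(self):
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("transit compartment counts must be >= 1")


LD_TRANSIT = TransitConfig(5, 6)
CD_TRANSIT = TransitConfig(3, 10)


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relation.

    kind:
      * ``allometric`` — multiplicative power of (cov/reference); the
        coefficient is the fixed exponent (0.75 for clearances, 1 for
        volumes) and is never estimated.
      * ``linear`` — multiplicative factor ``1 + coefficient·(cov - reference)``
        with the reference being the centring mean.
      * ``interaction`` — divisor ``1 + cov/coefficient`` where the
        coefficient is the interaction potency in covariate units.
    """

    parameter: str
    covariate: str
    kind: str
    coefficient: float
    reference: float = 0.0

    def __post_init__(self):
        if self.kind not in ("allometric", "linear", "interaction"):
            raise ValueError(f"unknown covariate effect kind {self.kind!r}")
        if self.kind == "interaction" and self.coefficient <= 0:
            raise ValueError("interaction potency must be positive")
        if self.covariate not in COVARIATE_FIELDS:
            raise ValueError(f"unknown covariate {self.covariate!r}")

    def factor(self, value: float) -> float:
        if self.kind == "allometric":
            return (value / self.reference) ** self.coefficient
        if self.kind == "linear":
            return 1.0 + self.coefficient * (value - self.reference)
        return 1.0 / (1.0 + value / self.coefficient)


@dataclass(frozen=True)
class OmegaEntry:
    """Inter-individual variability on one parameter.

    ``sd`` is the standard deviation of the random effect on the scale set
    by ``dist``: multiplicative (``lognormal``), additive (``normal``) or on
    the logit of the parameter (``logitnormal``, used for fa1).
    """

    sd: float
    dist: str = "lognormal"

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("omega standard deviation must be >= 0")
        if self.dist not in ("lognormal", "normal", "logitnormal"):
            raise ValueError(f"unknown IIV distribution {self.dist!r}")

    @property
    def variance(self) -> float:
        return self.sd**2


@dataclass(frozen=True)
class ResidualSpec:
    """Combined proportional+additive residual error, by population.

    ``shared_fraction`` is the correlation between the levodopa and
    carbidopa residuals of the same physical sample (both drugs are
    measured in one specimen, so part of the error is common).
    """

    prop_healthy: float = 0.0
    prop_patient: float = 0.0
    add_healthy: float = 0.0
    add_patient: float = 0.0
    shared_fraction: float = 0.0

    def __post_init__(self):
        for name in ("prop_healthy", "prop_patient", "add_healthy", "add_patient"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")

    def sd(self, pred, patient: bool):
        prop = self.prop_patient if patient else self.prop_healthy
        add = self.add_patient if patient else self.add_healthy
        return np.sqrt((prop * np.asarray(pred)) ** 2 + add**2)


_KIND_ORDER = {"allometric": 0, "linear": 1, "interaction": 2}


@dataclass
class PopulationModel:
    """Typical values, covariate effects and variability for one drug."""

    drug: str
    n_disposition_compartments: int
    theta: dict[str, float]
    transit: TransitConfig
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    omega: dict[str, OmegaEntry] = field(default_factory=dict)
    sigma: ResidualSpec = field(default_factory=ResidualSpec)
    fixed: tuple[str, ...] = ("f_rel",)

    def __post_init__(self):
        if self.n_disposition_compartments not in (1, 2):
            raise ValueError("disposition must have 1 or 2 compartments")
        required = {"cl_f", "vc_f", "mtt1", "mtt2", "fa1", "f_rel", "c0"}
        if self.n_disposition_compartments == 2:
            required |= {"q_f", "vp_f"}
        missing = required - set(self.theta)
        if missing:
            raise ValueError(f"theta is missing {sorted(missing)}")
        for eff in self.covariate_effects:
            if eff.parameter not in self.theta:
                raise ValueError(
                    f"covariate effect targets unknown parameter {eff.parameter!r}"
                )
        for name in self.omega:
            if name not in self.theta:
                raise ValueError(f"omega entry targets unknown parameter {name!r}")

    @property
    def eta_names(self) -> list[str]:
        """Parameters carrying a random effect, in declaration order."""
        return [k for k, v in self.omega.items() if v.sd > 0]

    def copy(self) -> "PopulationModel":
        return PopulationModel(
            drug=self.drug,
            n_disposition_compartments=self.n_disposition_compartments,
            theta=dict(self.theta),
            transit=self.transit,
            covariate_effects=list(self.covariate_effects),
            omega=dict(self.omega),
            sigma=self.sigma,
            fixed=self.fixed,
        )


def _covariate_value(cov: SubjectCovariates, key: str) -> float:
    return float(getattr(cov, COVARIATE_FIELDS[key]))


def individual_parameters(
    model: PopulationModel,
    cov: SubjectCovariates,
    eta: Mapping[str, float] | Sequence[float] | None = None,
) -> PKParameters:
    """Realise one subject's structural parameters.

    Covariate effects are applied in the order allometric → linear →
    interaction (linear effects commute among themselves); the random
    effect is then applied on the scale given by the parameter's IIV
    distribution tag.  ``eta`` maps parameter names to random-effect
    values, or is a sequence aligned with ``model.eta_names``; omitted
    entries are 0.
    """
    if eta is None:
        eta = {}
    if not isinstance(eta, Mapping):
        eta = dict(zip(model.eta_names, eta, strict=True))

    p = dict(model.theta)
    for eff in sorted(model.covariate_effects, key=lambda e: _KIND_ORDER[e.kind]):
        value = _covariate_value(cov, eff.covariate)
        factor = eff.factor(value)
        if eff.kind == "linear" and factor <= 0.0:
            raise ValueError(
                f"linear effect of covariate {eff.covariate!r} on "
                f"{eff.parameter!r} drives the parameter non-positive "
                f"(covariate value {value}, factor {factor:.4g})"
            )
        p[eff.parameter] = p[eff.parameter] * factor

    for name, entry in model.omega.items():
        e = float(eta.get(name, 0.0))
        if e == 0.0:
            continue
        if entry.dist == "lognormal":
            p[name] = p[name] * math.exp(e)
        elif entry.dist == "normal":
            p[name] = p[name] + e
        else:  # logitnormal
            p[name] = float(expit(logit(p[name]) + e))

    kwargs = {k: p[k] for k in ("cl_f", "vc_f", "mtt1", "mtt2", "fa1", "f_rel", "c0")}
    if model.n_disposition_compartments == 2:
        kwargs["q_f"] = p["q_f"]
        kwargs["vp_f"] = p["vp_f"]
    return PKParameters(**kwargs)


def terminal_slope(params: PKParameters, n_compartments: int | None = None) -> float:
    """Terminal elimination slope λ_z (1/min).

    One compartment: ``cl_f/vc_f``.  Two compartments: the smaller root of
    ``λ² − (k10+k12+k21)·λ + k10·k21 = 0``.
    """
    if n_compartments is None:
        n_compartments = params.n_compartments
    if n_compartments == 1:
        return params.cl_f / params.vc_f
    lams, _ = _num.disposition_terms(
        params.cl_f, params.vc_f, params.q_f, params.vp_f
    )
    return float(lams[..., -1])


def transit_input_rate(t, dose: float, frac: float, mtt: float, n: int, f_rel: float = 1.0):
    """Drug mass rate (mg/min) entering the central compartment from one chain.

    ``rate(t) = f_rel·frac·dose·ktr·(ktr·t)^n·e^(−ktr·t)/n!`` with
    ``ktr = (n+1)/mtt`` — the Erlang density of shape ``n+1`` scaled by the
    chain's share of the dose.  Vectorised over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if n < 1:
        raise ValueError("transit compartment count must be >= 1")
    if mtt <= 0:
        raise ValueError("mean transit time must be positive")
    ktr = (n + 1) / mtt
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rate = n * np.log(ktr * t) - ktr * t
    rate = np.where(t > 0, ktr * np.exp(log_rate - gammaln(n + 1)), 0.0)
    return f_rel * frac * dose * rate


def _params_dict(model: PopulationModel, params: PKParameters) -> dict:
    d = {
        "cl_f": params.cl_f,
        "vc_f": params.vc_f,
        "mtt1": params.mtt1,
        "mtt2": params.mtt2,
        "fa1": params.fa1,
        "f_rel": params.f_rel,
        "c0": params.c0,
    }
    if model.n_disposition_compartments == 2:
        d["q_f"] = params.q_f
        d["vp_f"] = params.vp_f
    return d


def predict_concentration(
    model: PopulationModel,
    params: PKParameters,
    doses: Sequence[tuple[float, float]],
    times,
    method: str = "analytic",
) -> np.ndarray:
    """Concentration (µg/mL) at ``times`` for one subject.

    ``doses`` is a sequence of ``(time, amount_mg)``.  The profile is the
    superposition of both chains' transit input over all doses plus the
    pre-dose baseline ``c0·exp(-λ_z·(t - t_first_dose))``.  ``method`` is
    ``"analytic"`` (exact closed form, default) or ``"ode"`` (LSODA at
    rtol 1e-8 / atol 1e-10, kept as an independent cross-check).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim and np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    if not doses:
        doses = [(0.0, 0.0)]
    dose_t = np.array([d[0] for d in doses], dtype=float)
    dose_a = np.array([d[1] for d in doses], dtype=float)
    if np.any(dose_a < 0):
        raise ValueError("dose amounts must be non-negative")
    if method == "analytic":
        return _num.profile_conc(
            times,
            dose_t,
            dose_a,
            _params_dict(model, params),
            model.transit.n1,
            model.transit.n2,
            model.n_disposition_compartments == 2,
        )
    if method == "ode":
        return _ode_profile(model, params, dose_t, dose_a, times)["conc"]
    raise ValueError(f"unknown method {method!r}")


def predict_amounts(
    model: PopulationModel,
    params: PKParameters,
    doses: Sequence[tuple[float, float]],
    times,
) -> dict:
    """ODE solution with full state: compartment amounts and cumulative
    elimination, for mass-balance checking."""
    dose_t = np.array([d[0] for d in doses], dtype=float)
    dose_a = np.array([d[1] for d in doses], dtype=float)
    return _ode_profile(model, params, dose_t, dose_a, np.asarray(times, dtype=float))


def _ode_profile(model, params, dose_t, dose_a, times):
    from scipy.integrate import solve_ivp

    n1, n2 = model.transit.n1, model.transit.n2
    m1, m2 = n1 + 1, n2 + 1
    two = model.n_disposition_compartments == 2
    ktr1 = m1 / params.mtt1
    ktr2 = m2 / params.mtt2
    k10 = params.cl_f / params.vc_f
    k12 = params.q_f / params.vc_f if two else 0.0
    k21 = params.q_f / params.vp_f if two else 0.0
    nstate = m1 + m2 + (2 if two else 1) + 1  # + cumulative elimination

    def rhs(t, y):
        dy = np.empty_like(y)
        a1 = y[:m1]
        a2 = y[m1 : m1 + m2]
        dy[:m1] = -ktr1 * a1
        dy[1:m1] += ktr1 * a1[:-1]
        dy[m1 : m1 + m2] = -ktr2 * a2
        dy[m1 + 1 : m1 + m2] += ktr2 * a2[:-1]
        ac = y[m1 + m2]
        inflow = ktr1 * a1[-1] + ktr2 * a2[-1]
        if two:
            ap = y[m1 + m2 + 1]
            dy[m1 + m2] = inflow - (k10 + k12) * ac + k21 * ap
            dy[m1 + m2 + 1] = k12 * ac - k21 * ap
        else:
            dy[m1 + m2] = inflow - k10 * ac
        dy[-1] = k10 * ac
        return dy

    order = np.argsort(dose_t)
    dose_t = dose_t[order]
    dose_a = dose_a[order]
    t0 = dose_t[0] if len(dose_t) else 0.0
    breakpoints = sorted(set(np.concatenate([dose_t, times[times > min(t0, times.min(initial=t0))]])))

    y = np.zeros(nstate)
    t_cur = min(t0, times.min(initial=t0))
    conc = np.zeros_like(times)
    states = np.zeros((len(times), nstate))
    # times before the first event: only baseline contributes
    done = times <= t_cur
    events = {}
    for t, a in zip(dose_t, dose_a):
        events.setdefault(t, 0.0)
        events[t] += a

    for t_next in breakpoints:
        if t_next > t_cur:
            sol = solve_ivp(
                rhs,
                (t_cur, t_next),
                y,
                method="LSODA",
                rtol=1e-8,
                atol=1e-10,
                dense_output=True,
            )
            if not sol.success:
                raise RuntimeError(f"ODE solver failed: {sol.message}")
            sel = (times > t_cur) & (times <= t_next)
            if np.any(sel):
                ys = sol.sol(times[sel])
                states[sel] = ys.T
                conc[sel] = ys[m1 + m2] / params.vc_f
            y = sol.y[:, -1]
            t_cur = t_next
        if t_next in events:
            a = events[t_next] * params.f_rel
            y[0] += a * params.fa1
            y[m1] += a * (1.0 - params.fa1)

    lam_z = terminal_slope(params, model.n_disposition_compartments)
    conc = conc + params.c0 * np.exp(-lam_z * (times - t0))
    return {
        "conc": conc,
        "states": states,
        "eliminated": states[:, -1],
        "state_names": (
            [f"transit1_{i}" for i in range(m1)]
            + [f"transit2_{i}" for i in range(m2)]
            + (["central", "peripheral"] if two else ["central"])
            + ["eliminated"]
        ),
    }


# ---------------------------------------------------------------------------
# model specification files


def _effects_to_yaml(effects):
    return [
        {
            "parameter": e.parameter,
            "covariate": e.covariate,
            "kind": e.kind,
            "coefficient": float(e.coefficient),
            "reference": float(e.reference),
        }
        for e in effects
    ]


def save_model(model: PopulationModel, path) -> None:
    doc = {
        "drug": model.drug,
        "n_disposition_compartments": model.n_disposition_compartments,
        "transit": {"n1": model.transit.n1, "n2": model.transit.n2},
        "theta": {k: float(v) for k, v in model.theta.items()},
        "fixed": list(model.fixed),
        "covariate_effects": _effects_to_yaml(model.covariate_effects),
        "omega": {
            k: {"sd": float(v.sd), "dist": v.dist} for k, v in model.omega.items()
        },
        "sigma": {
            "prop_healthy": model.sigma.prop_healthy,
            "prop_patient": model.sigma.prop_patient,
            "add_healthy": model.sigma.add_healthy,
            "add_patient": model.sigma.add_patient,
            "shared_fraction": model.sigma.shared_fraction,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _model_from_doc(doc: dict) -> PopulationModel:
    return PopulationModel(
        drug=doc["drug"],
        n_disposition_compartments=int(doc["n_disposition_compartments"]),
        theta={k: float(v) for k, v in doc["theta"].items()},
        transit=TransitConfig(int(doc["transit"]["n1"]), int(doc["transit"]["n2"])),
        covariate_effects=[
            CovariateEffect(
                parameter=e["parameter"],
                covariate=e["covariate"],
                kind=e["kind"],
                coefficient=float(e["coefficient"]),
                reference=float(e.get("reference", 0.0)),
            )
            for e in doc.get("covariate_effects", [])
        ],
        omega={
            k: OmegaEntry(sd=float(v["sd"]), dist=v.get("dist", "lognormal"))
            for k, v in doc.get("omega", {}).items()
        },
        sigma=ResidualSpec(**doc.get("sigma", {})),
        fixed=tuple(doc.get("fixed", ("f_rel",))),
    )


def load_model(path, variant: str | None = None) -> PopulationModel:
    """Read a model specification file (YAML).

    ``variant`` selects an alternative parameter column stored under the
    file's ``variants`` key (e.g. the re-estimated covariate-coefficient
    column of the reference model files); ``None`` uses the base values.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _apply_variant(doc, variant)


def _apply_variant(doc, variant):
    variants = doc.pop("variants", {}) or {}
    if variant:
        if variant not in variants:
            raise KeyError(f"model file has no variant {variant!r}")
        patch = variants[variant]
        for key in ("theta", "omega", "sigma"):
            if key in patch:
                doc.setdefault(key, {}).update(patch[key])
        if "covariate_effects" in patch:
            doc["covariate_effects"] = patch["covariate_effects"]
    return _model_from_doc(doc)


def load_packaged_model(name: str, variant: str | None = None) -> PopulationModel:
    """Load one of the models shipped with the package.

    Available: ``"reference_ld"`` and ``"reference_cd"`` — the final joint
    levodopa/carbidopa reference models (fixed-coefficient column by
    default; ``variant="reestimated"`` selects the column with unfixed
    covariate coefficients).
    """
    ref = importlib.resources.files("levocarb") / "data" / f"{name}.yaml"
    with ref.open() as fh:
        doc = yaml.safe_load(fh)
    return _apply_variant(doc, variant)
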