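"""Synthetic study generation: designs, population simulation, BLQ, I/O.

Emulates three microtablet studies: a dense single-dose study in healthy
volunteers, an individualised single-dose study in patients with advanced
Parkinson's disease (non-zero pre-dose concentrations after overnight
washout) and a sparse multiple-dose study in healthy volunteers used for
external evaluation.  Datasets are NONMEM-style event-record tables.

Random-number contract: one seed spawns three named substreams (covariates,
etas, residuals), each further split per subject, so enlarging a cohort
leaves the first subjects' draws unchanged.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import _batch
from .model_core import PopulationModel, ResidualSpec  # noqa: F401  (re-export)

__all__ = [
    "StudyDesign",
    "PKDataset",
    "ResidualSpec",
    "load_design",
    "load_packaged_design",
    "sample_population",
    "simulate_on_dataset",
    "apply_blq_m6",
    "write_dataset",
    "read_dataset",
    "DRUG_DVID",
]

DRUG_DVID = {"levodopa": 1, "carbidopa": 2}
DVID_DRUG = {v: k for k, v in DRUG_DVID.items()}

MANDATORY_COLUMNS = [
    "ID", "TIME", "AMT", "DV", "EVID", "MDV", "DVID", "BLQ", "LOD",
    "WT", "AGE", "SEX", "HY", "CDOSE", "STUDY",
]
OPTIONAL_COLUMNS = ["YRSLD", "TDIAG"]


@dataclass
class StudyDesign:
    """One study arm: dosing rule, sampling schedule, covariate marginals.

    ``dosing`` holds ``times`` (min) and either fixed per-occasion
    ``ld_amounts`` (mg levodopa) or an ``individualized`` rule with an
    ``ld_range`` drawn uniformly and rounded to the microtablet strength;
    carbidopa is co-administered at ``1/cd_ratio`` of the levodopa amount.
    ``covariates`` maps covariate keys to marginal specs: ``{value: v}``,
    ``{p_female: p}`` or a truncated normal ``{mean, sd, min, max}`` with
    optional ``integer: true``.
    """

    label: str
    n_subjects: int
    dosing: dict
    sampling_times: list[float]
    covariates: dict = field(default_factory=dict)
    pre_dose_positive: bool = False
    lod: dict = field(default_factory=dict)

    def __post_init__(self):
        st = np.asarray(self.sampling_times, dtype=float)
        if st.size == 0:
            raise ValueError("sampling schedule is empty")
        if np.any(np.diff(st) < 0):
            raise ValueError("sampling times must be sorted ascending")
        self.sampling_times = [float(t) for t in st]

    @property
    def dose_times(self) -> np.ndarray:
        return np.asarray(self.dosing["times"], dtype=float)


def load_design(path) -> StudyDesign:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return StudyDesign(
        label=doc["label"],
        n_subjects=int(doc["n_subjects"]),
        dosing=doc["dosing"],
        sampling_times=doc["sampling_times"],
        covariates=doc.get("covariates", {}),
        pre_dose_positive=bool(doc.get("pre_dose_positive", False)),
        lod=doc.get("lod", {}),
    )


def load_packaged_design(name: str) -> StudyDesign:
    """Load a shipped design: ``study1``, ``study2`` or ``study3``."""
    ref = importlib.resources.files("levocarb") / "data" / "designs" / f"{name}.yaml"
    with ref.open() as fh:
        doc = yaml.safe_load(fh)
    return StudyDesign(
        label=doc["label"],
        n_subjects=int(doc["n_subjects"]),
        dosing=doc["dosing"],
        sampling_times=doc["sampling_times"],
        covariates=doc.get("covariates", {}),
        pre_dose_positive=bool(doc.get("pre_dose_positive", False)),
        lod=doc.get("lod", {}),
    )


class PKDataset:
    """Event-record dataset (doses + observations) for a cohort.

    Thin wrapper over a :class:`pandas.DataFrame` in NONMEM-style long
    format; one row per dose or observation event, covariates repeated on
    every row.  ``DVID`` is 1 for levodopa and 2 for carbidopa.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self):
        missing = [c for c in MANDATORY_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset is missing mandatory columns {missing}")
        for sid, sub in self.df.groupby("ID"):
            if not (sub["EVID"] == 1).any():
                raise ValueError(f"subject {sid} has no dose record")
        obs = self.observations()
        if (obs["DV"] < 0).any():
            raise ValueError("negative observed concentrations")

    def observations(self, drug: str | None = None) -> pd.DataFrame:
        out = self.df[self.df["EVID"] == 0]
        if drug is not None:
            out = out[out["DVID"] == DRUG_DVID[drug]]
        return out

    def doses(self, drug: str | None = None) -> pd.DataFrame:
        out = self.df[self.df["EVID"] == 1]
        if drug is not None:
            out = out[out["DVID"] == DRUG_DVID[drug]]
        return out

    def subject_table(self) -> pd.DataFrame:
        cols = ["WT", "AGE", "SEX", "HY", "CDOSE", "STUDY"] + [
            c for c in OPTIONAL_COLUMNS if c in self.df.columns
        ]
        return self.df.groupby("ID").first()[cols]

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    def copy(self) -> "PKDataset":
        return PKDataset(self.df.copy(), validate=False)

    def equals(self, other: "PKDataset") -> bool:
        return self.df.equals(other.df)


def _draw_truncnorm(rng, spec, integer=False):
    lo, hi = float(spec["min"]), float(spec["max"])
    for _ in range(1000):
        x = rng.normal(spec["mean"], spec["sd"])
        if lo <= x <= hi:
            return int(round(x)) if integer else float(x)
    return float(np.clip(spec["mean"], lo, hi))


def _draw_covariates(design: StudyDesign, rng) -> dict:
    """One subject's covariates plus the dose schedule, in a fixed order."""
    out = {}
    for key in ("wt", "age", "sex", "hy", "years_ld", "t_diagnosis"):
        spec = design.covariates.get(key)
        if spec is None:
            out[key] = 0.0
        elif "value" in spec:
            out[key] = float(spec["value"])
        elif "p_female" in spec:
            out[key] = float(rng.random() < float(spec["p_female"]))
        else:
            out[key] = _draw_truncnorm(rng, spec, integer=bool(spec.get("integer")))
    dosing = design.dosing
    times = np.asarray(dosing["times"], dtype=float)
    if "individualized" in dosing:
        rule = dosing["individualized"]
        lo, hi = rule["ld_range"]
        step = float(rule.get("round_to", 5.0))
        amount = step * round(rng.uniform(lo, hi) / step)
        ld_amounts = np.full(times.shape, amount)
    else:
        ld_amounts = np.asarray(dosing["ld_amounts"], dtype=float)
    cd_amounts = ld_amounts / float(dosing.get("cd_ratio", 4.0))
    out["dose_times"] = times
    out["ld_amounts"] = ld_amounts
    out["cd_amounts"] = cd_amounts
    out["cd_dose"] = float(cd_amounts.sum())
    return out


def _correlated_residuals(rng, n, rho):
    z = rng.standard_normal((n, 2))
    return z[:, 0], rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]


def sample_population(
    design: StudyDesign,
    model_ld: PopulationModel,
    model_cd: PopulationModel,
    seed: int,
) -> PKDataset:
    """Simulate a full cohort under a study design.

    Draws covariates from the design's truncated marginals, per-subject
    random effects from each model's IIV, predicts both drugs at the
    design's sampling times, and adds combined proportional+additive
    residual error in which the levodopa/carbidopa pair measured in the
    same sample is correlated with the shared-error fraction.  When the
    design declares ``pre_dose_positive: false`` the pre-dose baseline is
    zeroed (washed-out cohort).  Deterministic for a fixed seed.
    """
    ss = np.random.SeedSequence(seed)
    cov_ss, eta_ss, res_ss = ss.spawn(3)
    n = design.n_subjects
    cov_children = cov_ss.spawn(n)
    eta_children = eta_ss.spawn(n)
    res_children = res_ss.spawn(n)

    subjects = [_draw_covariates(design, np.random.default_rng(c)) for c in cov_children]

    names_ld = model_ld.eta_names
    names_cd = model_cd.eta_names
    sd_ld = np.array([model_ld.omega[k].sd for k in names_ld])
    sd_cd = np.array([model_cd.omega[k].sd for k in names_cd])
    etas_ld = np.empty((n, len(names_ld)))
    etas_cd = np.empty((n, len(names_cd)))
    for i, child in enumerate(eta_children):
        rng = np.random.default_rng(child)
        etas_ld[i] = rng.standard_normal(len(names_ld)) * sd_ld
        etas_cd[i] = rng.standard_normal(len(names_cd)) * sd_cd

    cov_arrays = {
        k: np.array([s[k] for s in subjects])
        for k in ("wt", "age", "sex", "hy", "cd_dose")
    }
    times = np.asarray(design.sampling_times, dtype=float)
    dose_t = np.stack([s["dose_times"] for s in subjects])
    ld_amt = np.stack([s["ld_amounts"] for s in subjects])
    cd_amt = np.stack([s["cd_amounts"] for s in subjects])

    f_by_drug = {}
    for drug, model, etas, names, amt in (
        ("levodopa", model_ld, etas_ld, names_ld, ld_amt),
        ("carbidopa", model_cd, etas_cd, names_cd, cd_amt),
    ):
        params = _batch.individual_params_arrays(model, cov_arrays, etas, names)
        if not design.pre_dose_positive:
            params["c0"] = np.zeros(n)
        f_by_drug[drug] = _batch.batch_profiles(model, params, times, dose_t, amt)

    rho = model_ld.sigma.shared_fraction
    records = []
    for i, subj in enumerate(subjects):
        rng = np.random.default_rng(res_children[i])
        z_ld, z_cd = _correlated_residuals(rng, len(times), rho)
        patient = subj["hy"] >= 1
        base = {
            "ID": i + 1,
            "WT": subj["wt"],
            "AGE": subj["age"],
            "SEX": int(subj["sex"]),
            "HY": int(subj["hy"]),
            "CDOSE": subj["cd_dose"],
            "STUDY": design.label,
            "YRSLD": subj["years_ld"],
            "TDIAG": subj["t_diagnosis"],
        }
        for drug, amounts in (("levodopa", ld_amt[i]), ("carbidopa", cd_amt[i])):
            for t, a in zip(subj["dose_times"], amounts):
                records.append(
                    base
                    | {
                        "TIME": t, "AMT": a, "DV": np.nan, "EVID": 1, "MDV": 1,
                        "DVID": DRUG_DVID[drug], "BLQ": 0,
                        "LOD": design.lod.get(drug, 0.0),
                    }
                )
        for drug, z in (("levodopa", z_ld), ("carbidopa", z_cd)):
            f = f_by_drug[drug][i]
            model = model_ld if drug == "levodopa" else model_cd
            sd = model.sigma.sd(f, patient)
            y = np.maximum(f + sd * z, 0.0)
            for t, v in zip(times, y):
                records.append(
                    base
                    | {
                        "TIME": t, "AMT": np.nan, "DV": v, "EVID": 0, "MDV": 0,
                        "DVID": DRUG_DVID[drug], "BLQ": 0,
                        "LOD": design.lod.get(drug, 0.0),
                    }
                )

    df = pd.DataFrame.from_records(records)
    df = df.sort_values(["ID", "TIME", "EVID", "DVID"], kind="stable")
    cols = MANDATORY_COLUMNS + OPTIONAL_COLUMNS
    return PKDataset(df[cols])


def draw_individual_parameters(
    design: StudyDesign,
    model: PopulationModel,
    seed: int,
) -> pd.DataFrame:
    """Realised structural parameters for a simulated cohort (no residuals).

    Uses the same covariate and eta substreams as :func:`sample_population`
    with the same seed, so the returned parameters are exactly those
    underlying the corresponding dataset.
    """
    ss = np.random.SeedSequence(seed)
    cov_ss, eta_ss, _ = ss.spawn(3)
    n = design.n_subjects
    subjects = [
        _draw_covariates(design, np.random.default_rng(c)) for c in cov_ss.spawn(n)
    ]
    names = model.eta_names
    sd = np.array([model.omega[k].sd for k in names])
    etas = np.stack(
        [
            np.random.default_rng(c).standard_normal(len(names)) * sd
            for c in eta_ss.spawn(n)
        ]
    )
    cov_arrays = {
        k: np.array([s[k] for s in subjects])
        for k in ("wt", "age", "sex", "hy", "cd_dose")
    }
    params = _batch.individual_params_arrays(model, cov_arrays, etas, names)
    out = pd.DataFrame(params)
    out.index = pd.RangeIndex(1, n + 1, name="ID")
    return out


def simulate_on_dataset(
    dataset: PKDataset,
    model_ld: PopulationModel,
    model_cd: PopulationModel,
    seed: int,
    zero_baseline: bool = False,
    ld_cl_per_dose: np.ndarray | None = None,
) -> PKDataset:
    """Re-simulate observations on an existing dataset's design matrix.

    Doses, covariates and observation times are reused verbatim; only the
    random effects and residual errors are redrawn.  This is the replicate
    generator behind the visual predictive checks.

    ``ld_cl_per_dose`` optionally replaces the covariate-derived levodopa
    clearance with a per-(subject, dose) array (before the subject's
    clearance random effect), expressing dose-specific carbidopa exposure.
    ``seed`` may be an int or a pre-spawned :class:`numpy.random.SeedSequence`.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    eta_ss, res_ss = ss.spawn(2)
    out = dataset.copy()
    rho = model_ld.sigma.shared_fraction

    arr = {d: _batch.prepare_drug_arrays(dataset, d) for d in DRUG_DVID}
    n = len(arr["levodopa"]["ids"])
    eta_children = eta_ss.spawn(n)
    res_children = res_ss.spawn(n)

    sims = {}
    for drug, model in (("levodopa", model_ld), ("carbidopa", model_cd)):
        a = arr[drug]
        names = model.eta_names
        sd = np.array([model.omega[k].sd for k in names])
        etas = np.stack(
            [
                np.random.default_rng(c).standard_normal(len(names)) * sd
                for c in eta_children
            ]
        )
        params = _batch.individual_params_arrays(model, a["cov"], etas, names)
        if drug == "levodopa" and ld_cl_per_dose is not None:
            eta_cl = np.zeros(n)
            if "cl_f" in names:
                eta_cl = etas[:, names.index("cl_f")]
            params["cl_f"] = ld_cl_per_dose * np.exp(eta_cl)[:, None]
        if zero_baseline:
            params["c0"] = np.zeros(n)
        sims[drug] = _batch.batch_profiles(
            model, params, a["times"], a["dose_t"], a["dose_a"]
        )

    # residuals, correlated where both drugs are sampled at the same time
    dv_new = out.df["DV"].to_numpy(dtype=float).copy()
    obs_index = {
        drug: out.df.index[(out.df["EVID"] == 0) & (out.df["DVID"] == DRUG_DVID[drug])]
        for drug in DRUG_DVID
    }
    for i in range(n):
        rng = np.random.default_rng(res_children[i])
        a_ld, a_cd = arr["levodopa"], arr["carbidopa"]
        t_ld = a_ld["times"][i][a_ld["mask"][i]]
        t_cd = a_cd["times"][i][a_cd["mask"][i]]
        z_ld = np.empty(len(t_ld))
        z_cd = np.empty(len(t_cd))
        shared = np.intersect1d(t_ld, t_cd)
        zl, zc = _correlated_residuals(rng, len(shared), rho)
        z_ld[np.isin(t_ld, shared)] = zl
        z_cd[np.isin(t_cd, shared)] = zc
        only_ld = ~np.isin(t_ld, shared)
        only_cd = ~np.isin(t_cd, shared)
        z_ld[only_ld] = rng.standard_normal(only_ld.sum())
        z_cd[only_cd] = rng.standard_normal(only_cd.sum())
        patient = a_ld["patient"][i]
        for drug, tvec, z in (("levodopa", t_ld, z_ld), ("carbidopa", t_cd, z_cd)):
            model = model_ld if drug == "levodopa" else model_cd
            f = sims[drug][i][arr[drug]["mask"][i]]
            y = np.maximum(f + model.sigma.sd(f, patient) * z, 0.0)
            sid = arr[drug]["ids"][i]
            idx = obs_index[drug]
            sel = idx[out.df.loc[idx, "ID"] == sid]
            dv_new[sel] = y
    out.df["DV"] = dv_new
    return out


def apply_blq_m6(dataset: PKDataset, lod: dict | None = None) -> PKDataset:
    """Censor below-LOD observations with the M6 rule.

    Within each subject-by-drug series, every maximal consecutive run of
    observations below the limit of detection keeps only its first record,
    re-assigned the value LOD/2 and flagged BLQ; the rest of the run is
    deleted.  ``lod`` maps drug names to limits; when omitted, the
    dataset's LOD column is used.
    """
    if lod is not None:
        for drug, v in lod.items():
            if v <= 0:
                raise ValueError(f"LOD for {drug} must be positive")
    df = dataset.df.copy()
    drop = []
    for (sid, dvid), sub in df[df["EVID"] == 0].groupby(["ID", "DVID"]):
        sub = sub.sort_values("TIME")
        if lod is not None:
            limit = float(lod[DVID_DRUG[int(dvid)]])
        else:
            limit = float(sub["LOD"].iloc[0])
        if limit <= 0:
            continue
        below = sub["DV"].to_numpy() < limit
        run_start = True
        for idx, b in zip(sub.index, below):
            if not b:
                run_start = True
                continue
            if run_start:
                df.loc[idx, "DV"] = limit / 2.0
                df.loc[idx, "BLQ"] = 1
                df.loc[idx, "LOD"] = limit
                run_start = False
            else:
                drop.append(idx)
    df = df.drop(index=drop)
    return PKDataset(df, validate=False)


def write_dataset(dataset: PKDataset, path) -> None:
    """Write a dataset as NONMEM-style CSV; missing numerics become ``"."``."""
    df = dataset.df.copy()
    out = df.astype(object).where(~df.isna(), ".")
    out.to_csv(path, index=False)


def read_dataset(path) -> PKDataset:
    """Read a NONMEM-style CSV dataset written by :func:`write_dataset`."""
    df = pd.read_csv(path, na_values=["."], dtype=object)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file is missing mandatory columns {missing}")
    unknown = [
        c for c in df.columns if c not in MANDATORY_COLUMNS + OPTIONAL_COLUMNS
    ]
    if unknown:
        warnings.warn(f"ignoring unknown dataset columns {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    for c in df.columns:
        if c == "STUDY":
            df[c] = df[c].astype(str)
        elif c in ("ID", "EVID", "MDV", "DVID", "BLQ", "SEX", "HY"):
            df[c] = df[c].astype(float).astype(int)
        else:
            df[c] = df[c].astype(float)
    return PKDataset(df)
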