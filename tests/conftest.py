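import warnings

import numpy as np
import pytest

import levocarb as lc

warnings.filterwarnings("ignore", message="estimation did not converge")


@pytest.fixture(scope="session")
def ld_model():
    return lc.load_packaged_model("reference_ld")


@pytest.fixture(scope="session")
def cd_model():
    return lc.load_packaged_model("reference_cd")


@pytest.fixture(scope="session")
def study1():
    return lc.load_packaged_design("study1")


@pytest.fixture(scope="session")
def study2():
    return lc.load_packaged_design("study2")


@pytest.fixture(scope="session")
def study3():
    return lc.load_packaged_design("study3")


@pytest.fixture(scope="session")
def small_patient_dataset(ld_model, cd_model):
    """12 patients on the individualized single-dose design."""
    d = lc.load_packaged_design("study2")
    d.n_subjects = 12
    return lc.sample_population(d, ld_model, cd_model, seed=101)


@pytest.fixture(scope="session")
def reference_covariates():
    """Covariate vector at every reference value of the levodopa model:
    70 kg, pooled-mean age, zero carbidopa, and (synthetic) Hoehn & Yahr
    forced to its pooled mean so each linear factor is exactly 1."""
    return lc.SubjectCovariates(weight=70.0, age=48.7, sex=0, hy=0, cd_dose=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
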