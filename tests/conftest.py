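import numpy as np
import pytest

from penguinperf import preprocess
from penguinperf.imputation import survey_summary
from penguinperf.joint import JointModel, fit_joint
from penguinperf.mcmc import PosteriorDraws, SamplerConfig
from penguinperf.synthetic import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def study():
    """One seeded synthetic study shared by read-only tests."""
    return generate_study(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def prepared(study):
    """(analysis, exclusions, predictors) from the shared study."""
    perf = preprocess.apply_parameter_transform(study.performance)
    perf = preprocess.standardize_performance(perf)
    predictors = preprocess.build_predictors(
        study.climate, study.survey, study.catch, study.config.years
    )
    analysis, exclusions = preprocess.match_and_pool(perf, predictors)
    return analysis, exclusions, predictors


@pytest.fixture(scope="session")
def joint_model(prepared):
    analysis, _, predictors = prepared
    return JointModel(analysis, predictors, survey_summary(predictors))


@pytest.fixture(scope="session")
def fitted(joint_model):
    """A short joint fit shared by scenario / diagnostics integration tests."""
    cfg = SamplerConfig(
        n_chains=2, n_adapt=1500, n_burnin=3000, n_keep_iterations=3000, thin=3, seed=42
    )
    return fit_joint(joint_model, cfg)


def make_draws(**arrays) -> PosteriorDraws:
    """Build a PosteriorDraws from named (chains, draws) or flat arrays."""
    names = list(arrays)
    arrs = []
    for v in arrays.values():
        a = np.asarray(v, float)
        if a.ndim == 1:
            a = a[None, :]
        arrs.append(a)
    stacked = np.stack(arrs, axis=-1)
    return PosteriorDraws(names, stacked)


def _anova_draws(alpha, beta=None, sigma=None, omega=None, n=None):
    """Constructed posterior-draw set with full ANOVA naming."""
    n = n if n is not None else np.asarray(alpha).size
    alpha = np.broadcast_to(np.asarray(alpha, float), (n,))
    beta = beta if beta is not None else np.zeros((5, n))
    sigma = sigma if sigma is not None else np.ones(n)
    omega = omega if omega is not None else np.ones(n)
    kw = {"alpha": alpha}
    for i in range(5):
        kw[f"beta{i + 1}"] = np.broadcast_to(np.asarray(beta[i], float), (n,))
    kw["sigma"] = np.broadcast_to(np.asarray(sigma, float), (n,))
    kw["omega"] = np.broadcast_to(np.asarray(omega, float), (n,))
    return make_draws(**kw)


@pytest.fixture
def anova_draws_factory():
    return _anova_draws
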