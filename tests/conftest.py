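import numpy as np
import pytest

from sanpop import (
    PopulationConfig,
    SurrogatePacemaker,
    SurrogateSpec,
    classify,
    default_model,
    default_transforms,
    filter_physiological,
    reference_triplet,
    run_population,
    sample_scalings,
    simulate,
)


@pytest.fixture(scope="session")
def san_model():
    return default_model()


@pytest.fixture(scope="session")
def transforms():
    return default_transforms()


@pytest.fixture(scope="session")
def condition_rates(san_model, transforms):
    """Steady firing rate of the default (unscaled) cell per condition.

    Session-scoped: the three stiff simulations run once and are shared by
    the model-level and acceptance-level direction checks.
    """
    out = {}
    for cond in ("baseline", "ISO", "CCh"):
        res = simulate(
            san_model, transform=transforms[cond], duration=20.0, analysis_window=8.0
        )
        assert res.status == "ok"
        out[cond] = res
    return out


@pytest.fixture(scope="session")
def surrogate_population():
    """A classified 2,000-variant surrogate population with its comparison inputs."""
    surr = SurrogatePacemaker(SurrogateSpec(noise_sd=0.02))
    cfg = PopulationConfig(
        varied_params=tuple(surr.varied_params), n_variants=2000, sigma=0.26, seed=7
    )
    records = run_population(surr, sample_scalings(cfg), noise_seed=cfg.seed)
    filter_physiological(records)
    classify(records, reference_triplet(surr))
    return cfg, records
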