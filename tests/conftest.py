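import dataclasses

import pytest

from cc_organotrait.design import StudyDesign, default_design
from cc_organotrait.simulate import (
    IpgttShape,
    TraitFamilyParams,
    default_params,
    generate_cohort,
)
from cc_organotrait.traits import derive_traits


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def params42():
    return default_params(seed=42)


@pytest.fixture(scope="session")
def cohort207(design, params42):
    return generate_cohort(design, params42)


@pytest.fixture(scope="session")
def trait_table(cohort207):
    return derive_traits(cohort207)


@pytest.fixture(scope="session")
def small_design():
    """Two lines, 3 animals per cell: cheap cohorts for unit tests."""
    lines = ("LA", "LB")
    sizes = {
        (line, sex, diet): 3
        for line in lines for sex in ("F", "M") for diet in ("CHD", "HFD")
    }
    return StudyDesign(lines=lines, group_sizes=sizes)


def noiseless_params():
    """All variance knobs at zero, diet effects off: fully deterministic."""
    zero = dict(sigma_line=0.0, sigma_int=0.0, sigma_e=0.0, diet_effect=0.0)
    return dataclasses.replace(
        default_params(seed=0),
        body_weight=TraitFamilyParams(mu=20.0, sex_effect=4.0, **zero),
        glucose=TraitFamilyParams(mu=110.0, sex_effect=5.0, **zero),
        liver=TraitFamilyParams(mu=1.4, sex_effect=0.1, **zero),
        spleen=TraitFamilyParams(mu=0.09, sex_effect=0.05, **zero),
        heart=TraitFamilyParams(mu=0.15, sex_effect=0.06, **zero),
        hfd_growth_per_week=0.0,
        growth_sigma_line=0.0,
        growth_sigma_int=0.0,
        growth_sigma_e=0.0,
        ipgtt=IpgttShape(measurement_sd=0.0, hfd_multiplier=1.0),
    )


@pytest.fixture()
def zero_noise_params():
    return noiseless_params()


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the default design and protocols."""
    from cc_organotrait.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("fullrun")
    manifest = run_pipeline(RunConfig(out_dir=out, seed=42))
    return out, manifest
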