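import pytest

from litterdecay import default_study_config, generate_bags
from litterdecay.data_model import BagRecord


@pytest.fixture(scope="session")
def study_bags():
    """One seeded realization of the field design (site dropout applied)."""
    return generate_bags(default_study_config(seed=11))


@pytest.fixture(scope="session")
def noiseless_bags():
    return generate_bags(default_study_config(seed=0, ln_noise_sd=0.0))


@pytest.fixture
def mono_bag():
    return BagRecord(site="1", plot="1-2", proliferation=True, exclusion=False,
                     species="maple", mesh="L", replicate=1, removal_day=90,
                     initial_mass_g=3.0, final_mass_g=2.268)


@pytest.fixture
def mixed_bag():
    return BagRecord(site="5", plot="5-2", proliferation=False, exclusion=False,
                     species="mixed", mesh="M", replicate=2, removal_day=90,
                     initial_mass_g=3.0, final_mass_g=2.7,
                     maple_final_mass_g=1.35, beech_final_mass_g=1.35)
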