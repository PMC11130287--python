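import pytest

from ldhairpin import synthetic as syn


@pytest.fixture(scope="session")
def deep_v_spec():
    """Noise-free bilayer (deep-V) accessibility ground truth."""
    return syn.GroundTruthSpec(conformation="deep_V", noise_sd_fraction=0.0, seed=11)


@pytest.fixture(scope="session")
def open_shallow_spec():
    """Noise-free LD-monolayer (open-shallow) accessibility ground truth."""
    return syn.GroundTruthSpec(conformation="open_shallow", noise_sd_fraction=0.0, seed=12)


@pytest.fixture(scope="session")
def deep_v_records(deep_v_spec):
    return syn.gen_accessibility_profile(deep_v_spec)


@pytest.fixture(scope="session")
def open_shallow_records(open_shallow_spec):
    return syn.gen_accessibility_profile(open_shallow_spec)


@pytest.fixture(scope="session")
def deep_v_frame():
    return syn.gen_hairpin_structure(syn.HairpinGeometrySpec.deep_v(seed=2))


@pytest.fixture(scope="session")
def open_shallow_frame():
    return syn.gen_hairpin_structure(syn.HairpinGeometrySpec.open_shallow(seed=2))
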