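import pytest

import dpdshear as d


@pytest.fixture(scope="session")
def ff():
    return d.default_forcefield()


@pytest.fixture(scope="session")
def small_lipid_system(ff):
    """A tiny lipid+water box (all-pairs regime) shared by force tests."""
    spec = d.SystemSpec(
        box_length=4.0,
        density=3.0,
        n_lipids=6,
        lipid_I=d.lipid_type_I(4),
        lipid_II=d.lipid_type_II(6),
        seed=3,
    )
    system, topo = d.build_system(spec, ff)
    return spec, system, topo


@pytest.fixture(scope="session")
def classifier_spec():
    return d.SystemSpec(
        box_length=16.0,
        n_lipids=600,
        lipid_I=d.lipid_type_I(4),
        lipid_II=d.lipid_type_II(4),
        seed=2,
    )
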