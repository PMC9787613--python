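import numpy as np
import pytest

import transleaf as tl


@pytest.fixture(scope="session")
def trait_table():
    return tl.packaged_traits()


@pytest.fixture(scope="session")
def eq2_spec():
    return tl.ModelSpec.equation("eq2")


def make_joined(n=400, seed=7, **cfg_kwargs):
    """Simulated joined (record, traits) pairs from the packaged eq2 set."""
    cfg = tl.SimConfig(n_trees=n, seed=seed, **cfg_kwargs)
    records, truth = tl.simulate_dataset(cfg)
    joined = tl.attach_traits(records, tl.packaged_traits())
    return joined, truth


@pytest.fixture(scope="session")
def sim_joined():
    """Medium simulated dataset shared by read-only tests."""
    joined, truth = make_joined(n=800, seed=11)
    return joined, truth


@pytest.fixture()
def tiny_csv(tmp_path):
    """A 3-row valid tree table CSV on disk."""
    path = tmp_path / "trees.csv"
    path.write_text(
        "tree_id,species,dbh_cm,lcr,crown_class,sg_obs,leaf_mass_kg,mat_c,map_mm,study_id\n"
        "a1,Pinus taeda,20,0.45,codominant,0.46,9.5,15.2,1200,s1\n"
        "a2,Acer rubrum,31.5,0.60,dominant,,12.1,11.0,980,s1\n"
        "a3,Abies balsamea,12.0,0.72,overtopped,0.35,4.2,3.4,820,s2\n"
    )
    return path
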