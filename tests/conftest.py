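import numpy as np
import pytest

from pocketmorph import synthetic


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    """Directory with one PDB file per synthetic fixture preset."""
    out = tmp_path_factory.mktemp("toy_complexes")
    for preset in synthetic.TOY_PRESETS:
        synthetic.write_toy_complex(preset, out / f"{preset}.pdb", seed=0)
    return out


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic two-group cohort (study-condition defaults)."""
    return synthetic.sample_cohort(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
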