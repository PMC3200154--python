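import pytest

from enscon.contacts import extract_contacts
from enscon.synthetic import EnsembleSpec, make_ensemble, make_reference

from helpers import ENS_SEED, REF_SEED


@pytest.fixture(scope="session")
def bundle_ref():
    """Frozen 80-residue helical-bundle reference."""
    return make_reference(80, motif="helix_bundle", seed=REF_SEED)


@pytest.fixture(scope="session")
def frozen_ensemble(bundle_ref):
    """The frozen study conditions: 50 models, 1.0 A noise, 20% corrupted."""
    spec = EnsembleSpec(
        n_res=80, n_models=50, noise_sigma=1.0,
        corrupt_fraction=0.2, corrupt_shift=15.0, seed=ENS_SEED,
    )
    return make_ensemble(bundle_ref, spec)


@pytest.fixture(scope="session")
def frozen_maps(frozen_ensemble):
    models, _, _ = frozen_ensemble
    return [extract_contacts(m) for m in models]
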