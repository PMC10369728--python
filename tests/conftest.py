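import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ORIGINAL_37MER = "TKEQKEQIAKATGLTTKQVRNWYVQLNASIKVMLTSI"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230726)


@pytest.fixture(scope="session")
def training_features():
    """Composition features for default synthetic training classes (n=60)."""
    from pepmine.composition_features import composition_vector
    from pepmine.synthetic_data import (acp_profile, amp_negative_profile,
                                        random_profile, simulate_training_sets)

    sets = simulate_training_sets(
        [acp_profile(), amp_negative_profile(), random_profile()], 60, seed=11)
    return {label: np.array([composition_vector(p) for p in peps])
            for label, peps in sets.items()}


@pytest.fixture(scope="session")
def tiny_hmm():
    from pepmine.profile_hmm import build_from_alignment

    return build_from_alignment(["KKLLA", "KKLIA", "KRLLA"], name="toy")
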