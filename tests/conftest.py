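import numpy as np
import pytest

from ddrsim.model import build_default_model


@pytest.fixture(scope="session")
def mrc5():
    return build_default_model("MRC5")


@pytest.fixture(scope="session")
def mrc5_one_site():
    return build_default_model("MRC5", n_dna_sites=1)


def zeroed_overlay(model, keep=()):
    """Overlay setting every rate constant to 0 except `keep` and thresholds."""
    overlay = {}
    for name, entry in model.parameters.items():
        if name in keep:
            continue
        if name.startswith("k_") or name in ("dsb_yield",):
            overlay[name] = 0.0
    return overlay
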