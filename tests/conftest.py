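import numpy as np
import pytest

from foldkin import synthetic as syn


@pytest.fixture(scope="session")
def lh_chemical_curve():
    """Noise-free urea denaturation curve for the Lh preset (CD probe)."""
    spec = syn.default_scenario("chemical_curve", "Lh")
    curve, truth = syn.generate(spec)
    return curve, truth


@pytest.fixture(scope="session")
def lh_chevron():
    spec = syn.default_scenario("chevron", "Lh")
    return syn.generate(spec)


def assert_sig_figs(value, truth, n):
    """Agreement to at least n significant figures (relative error)."""
    assert truth != 0
    rel = abs(value - truth) / abs(truth)
    assert rel < 0.5 * 10.0 ** (-n + 1), (
        f"{value!r} vs {truth!r}: relative error {rel:.2e} exceeds {n} sig figs"
    )


@pytest.fixture(scope="session")
def sig_figs():
    return assert_sig_figs
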