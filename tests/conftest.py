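import pytest

from rsnalab import PRESETS, RSNAModel, generate_subject, standard_protocol


@pytest.fixture(scope="session")
def wky_baroreflex_record():
    """One normotensive subject with the full vasodilator+pressor protocol."""
    preset = PRESETS["WKY"]
    protocol, duration = standard_protocol(preset, "baroreflex")
    return generate_subject(preset, protocol, seed=11, duration=duration)


@pytest.fixture(scope="session")
def wky_results(wky_baroreflex_record):
    return RSNAModel(wky_baroreflex_record).fit()


@pytest.fixture(scope="session")
def basal_record():
    """Undisturbed 180-s normotensive recording."""
    preset = PRESETS["WKY"]
    protocol, duration = standard_protocol(preset, "basal")
    return generate_subject(preset, protocol, seed=7, duration=duration)
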