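import pytest

from gdf15mr.summary_data import harmonized_reference, reference_instruments


@pytest.fixture(scope="session")
def ukb_instruments():
    return harmonized_reference("ukb")


@pytest.fixture(scope="session")
def finngen_instruments():
    return harmonized_reference("finngen")


@pytest.fixture(scope="session")
def exposure_dataset():
    return reference_instruments("ukb")[0]
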