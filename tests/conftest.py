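import pytest

from mutscan import synthetic as sd


@pytest.fixture(scope="session")
def small_cds():
    """A 10-codon CDS used by library-enumeration tests."""
    return sd.random_cds(10, seed=42)


@pytest.fixture(scope="session")
def tiny_library(small_cds):
    return sd.enumerate_snv_library(small_cds)
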