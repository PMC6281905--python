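import pytest

from esterkin import synthetic_data as sd

ALL_SPECIES = [
    ("As", "1A", "mono"), ("P", "1A", "mono"),
    ("As", "1A", "di"), ("P", "1A", "di"),
    ("As", "1B", "mono"), ("P", "1B", "mono"),
    ("As", "1B", "di"), ("P", "1B", "di"),
    ("As", "2", "mono"), ("P", "2", "mono"),
]


@pytest.fixture(scope="session")
def ts_bundles():
    """Paired reactant/TS fixtures for every modelled species."""
    return {key: sd.make_ts_like(*key, seed=101) for key in ALL_SPECIES}


@pytest.fixture(scope="session")
def strand_bundle():
    """Four-residue mock strand with three phosphate bridges."""
    return sd.make_mock_strand(4, ["P", "P", "P"], seed=42)
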