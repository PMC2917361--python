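import pytest

from htsupersage import (
    NLAIII,
    load_barcode_table,
    simulate_expression,
    simulate_transcriptome,
)
from htsupersage.demux import REFERENCE_INDEXES


@pytest.fixture(scope="session")
def toy_transcriptome():
    """60 random transcripts carrying all three built-in sites, plus weights."""
    transcripts, ledger = simulate_transcriptome(
        60, length_range=(200, 600), seed=101
    )
    weights = simulate_expression(60, lognormal_sigma=1.0, seed=102)
    return transcripts, ledger, weights


@pytest.fixture(scope="session")
def reference_table():
    """Barcode table over the 27 demonstration-run indexes, all NlaIII."""
    rows = [(f"lib{i:02d}", idx, "NlaIII") for i, idx in enumerate(REFERENCE_INDEXES)]
    return load_barcode_table(rows)


@pytest.fixture
def three_sample_table():
    return load_barcode_table(
        [("a", "GCCC", "NlaIII"), ("b", "GCCA", "NlaIII"), ("c", "GCCT", "NlaIII")]
    )
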