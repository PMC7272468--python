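import pytest

from promvar.alignment import AlignmentRecord, PromoterAlignment
from promvar.synthetic import PanelConfig, simulate_promoter_panel


@pytest.fixture(scope="session")
def default_panel():
    """The default synthetic promoter panel (105 accessions + 4 wild)."""
    return simulate_promoter_panel(PanelConfig(seed=20))


@pytest.fixture
def toy_alignment():
    """4 records x 12 columns: 1 SNP column, one 2-bp gap run, ATG at column 9.

    REF    ACGTACGTG ATG
    S1     ACGTACGTG ATG   (identical to reference)
    S2     ACG--CGTG ATG   (2-bp deletion)
    S3     ACGTACTTG ATG   (SNP at column 6)
    """
    rows = [
        ("REF", "temperate_japonica", "ACGTACGTGATG"),
        ("S1", "temperate_japonica", "ACGTACGTGATG"),
        ("S2", "indica", "ACG--CGTGATG"),
        ("S3", "indica", "ACGTACTTGATG"),
    ]
    records = [AlignmentRecord(*r) for r in rows]
    return PromoterAlignment(records, reference_id="REF", atg_column=9)
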