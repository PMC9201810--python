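import pandas as pd
import pytest

from quadseg import load_band_table, load_chromosome_table
from quadseg.karyotype import Breakpoint, ReciprocalTranslocation
from quadseg.reference import ChromosomeRecord


@pytest.fixture(scope="session")
def chrom_table():
    return load_chromosome_table()


@pytest.fixture(scope="session")
def band_table():
    return load_band_table()


@pytest.fixture(scope="session")
def toy_table():
    """Two synthetic chromosomes with round-number geometry."""
    return {
        "4": ChromosomeRecord("4", 100_000_000, 40_000_000, 45_000_000),
        "13": ChromosomeRecord("13", 60_000_000, 10_000_000, 13_000_000),
    }


@pytest.fixture()
def toy_translocation(toy_table):
    """t(4;13) with q breakpoints at 80 Mb and 30 Mb on the toy genome."""
    return ReciprocalTranslocation(
        carrier_id="T1",
        carrier_sex="female",
        bp1=Breakpoint(chromosome="4", arm="q", position_bp=80_000_000),
        bp2=Breakpoint(chromosome="13", arm="q", position_bp=30_000_000),
    )


@pytest.fixture(scope="session")
def real_translocation(band_table):
    from quadseg import parse_iscn_karyotype

    return parse_iscn_karyotype(
        "46,XX,t(2;5)(q21;q13)", band_table, carrier_id="R1"
    )
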