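import pandas as pd
import pytest

from dminc.refdata import reference_counts_frame
from dminc.synth import write_fixture_suite


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The hand-built fixture suite written to a session temp dir."""
    outdir = tmp_path_factory.mktemp("fixtures")
    write_fixture_suite(outdir)
    return outdir


@pytest.fixture(scope="session")
def fixture_ledger(fixture_dir) -> pd.DataFrame:
    return pd.read_csv(fixture_dir / "fixture_ledger.csv",
                       dtype={"person_id": str})


@pytest.fixture(scope="session")
def fixture_claims(fixture_dir) -> pd.DataFrame:
    return pd.read_csv(fixture_dir / "fixture_claims.csv",
                       dtype={"person_id": str, "code": str})


@pytest.fixture(scope="session")
def reference_agg() -> pd.DataFrame:
    """Published stratified cumulative counts (fixed denominators), long form."""
    return reference_counts_frame()
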