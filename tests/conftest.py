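import pandas as pd
import pytest
from importlib import resources

from cinv_audit import run_audit
from cinv_audit.risk import Guideline, load_guideline_table


@pytest.fixture(scope="session")
def jsco():
    return load_guideline_table(Guideline.JSCO)


@pytest.fixture(scope="session")
def fixture_paths():
    fx = resources.files("cinv_audit.data").joinpath("fixtures")
    return {"registry": fx / "registry.csv", "claims": fx / "claims.csv",
            "procedures": fx / "procedures.csv", "expected": fx / "expected.csv"}


@pytest.fixture(scope="session")
def fixture_result(fixture_paths):
    """The audit run once over the packaged 30-patient fixture."""
    return run_audit(fixture_paths["registry"], fixture_paths["claims"],
                     fixture_paths["procedures"])


@pytest.fixture(scope="session")
def fixture_expected(fixture_paths):
    return pd.read_csv(fixture_paths["expected"], dtype=str).fillna("")
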