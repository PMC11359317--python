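import pandas as pd
import pytest

from pvsignal.meddra import TermDictionary, bundled_path, load_pathogen_rules, load_term_groups
from pvsignal.synth import make_fixture


@pytest.fixture(scope="session")
def dictionary() -> TermDictionary:
    return TermDictionary.from_tsv(bundled_path("synthetic_pt_dictionary.tsv"))


@pytest.fixture(scope="session")
def groups():
    return load_term_groups()


@pytest.fixture(scope="session")
def pathogen_rules():
    return load_pathogen_rules()


@pytest.fixture(scope="session")
def tiny_bundle():
    bundle, _ = make_fixture("tiny-hand-checked")
    return bundle


@pytest.fixture(scope="session")
def messy_bundle():
    bundle, _ = make_fixture("messy-dates")
    return bundle


def universe_from(pairs) -> pd.DataFrame:
    """Build a (CASEID, event) incidence frame from (case, event) tuples."""
    return pd.DataFrame(pairs, columns=["CASEID", "event"])
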