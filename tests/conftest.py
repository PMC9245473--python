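from pathlib import Path

import pytest

from q2arc.fixtures import FixtureRecord, standard_suite

SUITE_SEED = 2021


@pytest.fixture(scope="session")
def suite_dir(tmp_path_factory) -> Path:
    return tmp_path_factory.mktemp("fixtures")


@pytest.fixture(scope="session")
def suite(suite_dir) -> dict[str, FixtureRecord]:
    """The canonical fixture set, keyed by artifact file name."""
    records = standard_suite(suite_dir, seed=SUITE_SEED)
    return {record.artifact_path.name: record for record in records}


@pytest.fixture(scope="session")
def good_records(suite) -> list[FixtureRecord]:
    return [r for r in suite.values() if r.corruption is None]


@pytest.fixture
def html_dir(tmp_path) -> Path:
    """A small static site for the maker tests."""
    site = tmp_path / "site"
    (site / "css").mkdir(parents=True)
    (site / "img").mkdir()
    (site / "index.html").write_text(
        "<!doctype html>\n<html><body><h1>Report</h1></body></html>\n"
    )
    (site / "css" / "style.css").write_text("h1 { color: teal; }\n")
    (site / "img" / "logo.svg").write_text("<svg></svg>\n")
    (site / ".hidden").write_text("editor droppings\n")
    return site
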