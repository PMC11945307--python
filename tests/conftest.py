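import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from dagenrich import (
    build_graph,
    load_annotations,
    parse_obo,
    propagate_true_path,
)

DATA = Path(__file__).parent / "data" / "worked"


@pytest.fixture(scope="session")
def worked_terms():
    return parse_obo(DATA / "worked.obo")


@pytest.fixture(scope="session")
def worked_graph(worked_terms):
    return build_graph(worked_terms, "T:01")


@pytest.fixture(scope="session")
def worked_annotations(worked_graph):
    table = load_annotations(DATA / "annotations.tsv", worked_graph)
    return propagate_true_path(table, worked_graph)


@pytest.fixture(scope="session")
def worked_interest():
    return [line.strip() for line in (DATA / "interest.txt").read_text().splitlines() if line.strip()]
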