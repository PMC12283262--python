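import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from stachelhaus import ScaffoldSpec, make_scaffold, paper_catalogue


@pytest.fixture(scope="session")
def scaffold():
    """A seed-fixed synthetic scaffold and its derived reference profile."""
    return make_scaffold(ScaffoldSpec(length=530, seed=7))


@pytest.fixture(scope="session")
def profile(scaffold):
    return scaffold[1]


@pytest.fixture(scope="session")
def cat():
    """The packaged catalogue of published codes."""
    return paper_catalogue()


TOY_TSV = """\
code\tsubstrate\tmodifications\tn\tspecies\titerative\tsource
DAQDLGVVDK\tGlu\t\t3\t\tfalse\ttoy
DAQDLGVVDK\tGln\t\t2\t\tfalse\ttoy
DAWFLGNVVK\tLeu\t\t5\tBacillus subtilis\ttrue\ttoy
"""


@pytest.fixture
def toy_catalogue_path(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text(TOY_TSV)
    return p
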