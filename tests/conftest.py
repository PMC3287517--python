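import numpy as np
import pytest

from amplitag import sim
from amplitag.pipeline import default_sample_sheet


@pytest.fixture(scope="session")
def sheet():
    """The four-species tag layout (shared TCAG key, species MIDs)."""
    return default_sample_sheet()


@pytest.fixture(scope="session")
def sheet_by_sample(sheet):
    return {r.sample: r for r in sheet}


@pytest.fixture(scope="session")
def references():
    return sim.synthetic_references()


@pytest.fixture(scope="session")
def templates(references):
    return {r["accession"]: r["bases"] for r in references}


@pytest.fixture(scope="session")
def clade_reps(references):
    """One accession per synthetic clade plus a second Rickettsia-like one —
    mutually divergent templates for mixed communities."""
    groups: dict[str, list[str]] = {}
    for r in references:
        groups.setdefault(r["group"], []).append(r["accession"])
    return [v[0] for v in groups.values()] + [groups["Rickettsia-like"][1]]


@pytest.fixture()
def rng():
    return np.random.default_rng(20120118)
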