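import pytest

from ptmpanel import ProteinRecord, default_protease_panel
from ptmpanel.synthetic import histone_h3_tail_protein


@pytest.fixture(scope="session")
def panel():
    return default_protease_panel()


@pytest.fixture(scope="session")
def rules(panel):
    """Panel rules indexed by name."""
    return {r.name: r for r in panel}


@pytest.fixture(scope="session")
def h3_tail():
    """Histone H3 N-terminal tail, mature (Met-removed) numbering."""
    return histone_h3_tail_protein()


@pytest.fixture
def simple_protein():
    return ProteinRecord(id="p1", sequence="AKAKA")


def brute_force_digest(sequence: str, cut_positions: list[int], max_missed: int):
    """Independent digestion oracle: every substring whose boundaries are
    termini or cut sites and which contains at most ``max_missed`` cut sites
    strictly inside it. Returns a set of (start, end, n_internal) with
    1-based inclusive coordinates."""
    bounds = [0] + list(cut_positions) + [len(sequence)]
    out = set()
    for i, a in enumerate(bounds):
        for b in bounds[i + 1 :]:
            internal = sum(1 for c in cut_positions if a < c < b)
            if internal <= max_missed:
                out.add((a + 1, b, internal))
    return out
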