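import re

import pytest

import xenotrace as xt


def brute_force_digest(sequence: str, max_missed: int, proline_rule: bool = True):
    """Independent position-scan digestion oracle.

    Finds cleavage positions by regex, builds 0-missed fragments, and
    concatenates up to ``max_missed`` adjacent fragments.  Returns a list of
    (sequence, start, n_missed).
    """
    pat = r"(?<=[KR])(?!P)" if proline_rule else r"(?<=[KR])"
    cuts = [m.start() for m in re.finditer(pat, sequence) if 0 < m.start() < len(sequence)]
    bounds = [0] + cuts + [len(sequence)]
    frags = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    out = []
    for i in range(len(frags)):
        for k in range(max_missed + 1):
            if i + k >= len(frags):
                break
            a, b = frags[i][0], frags[i + k][1]
            out.append((sequence[a:b], a, k))
    return sorted(out, key=lambda t: (t[1], t[2]))


@pytest.fixture
def toy_proteomes():
    """Two tiny two-species proteomes: shared core, one substitution, and a
    species-specific protein each."""
    human = xt.Proteome(
        "human",
        [
            ("H1", "MAGIKWTESTRAEPTIDEKGGR"),
            ("H2", "SSSSKFFFFRQQQQK"),
            ("Hs", "WWYYKNNNNNRMMMMK"),
        ],
    )
    mouse = xt.Proteome(
        "mouse",
        [
            ("M1", "MAGIKWTESTRAEPTADEKGGR"),  # one substitution (I->A) in one peptide
            ("M2", "SSSSKFFFFRQQQQK"),
            ("Ms", "DDCCKEEEEERHHHHK"),
        ],
    )
    return human, mouse


@pytest.fixture
def toy_library(toy_proteomes):
    human, mouse = toy_proteomes
    return xt.build_libraries(
        human, mouse, max_missed=2, length_window=(1, 50), mass_window=(0.0, 1e6)
    )
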