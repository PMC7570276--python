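import pytest

from gipctools.chem import CeramideSpec, GipcComposition

A_RESIDUES = ("HexA", "Hex")


def make_a(r1: str, lcb: str, fa: str) -> GipcComposition:
    return GipcComposition("A", A_RESIDUES, r1, CeramideSpec.resolved(lcb, fa))


@pytest.fixture
def a_oh_t181_h240() -> GipcComposition:
    """The reference species A-OH-t18:1/h24:0 (sum level A-OH-q42:1)."""
    return make_a("OH", "t18:1", "h24:0")


@pytest.fixture
def ipc_t181_h240() -> GipcComposition:
    return GipcComposition("0", (), None, CeramideSpec.resolved("t18:1", "h24:0"))
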