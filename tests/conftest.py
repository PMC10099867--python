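import pytest

from cqtkit import ArrheniusReaction, IncubationRecord


@pytest.fixture
def toy_incubations():
    """Three exactly collinear (q10, ln_r0) records: corr at 0°C is -1."""
    return [
        IncubationRecord("a", "toy", 2.0, 1.0),
        IncubationRecord("b", "toy", 3.0, 0.0),
        IncubationRecord("c", "toy", 4.0, -1.0),
    ]


@pytest.fixture
def toy_reactions():
    """Four uncatalysed + four catalysed reactions with resolvable pairing."""
    uncat = [
        ArrheniusReaction(id=f"u{i}", catalysed=False, ea=ea, ln_k25=lnk)
        for i, (ea, lnk) in enumerate(
            [(50.0, -10.0), (90.0, -20.0), (130.0, -32.0), (170.0, -44.0)]
        )
    ]
    cat = [
        ArrheniusReaction(id=f"c{i}", catalysed=True, pair_id=f"u{i}", ea=ea)
        for i, ea in enumerate([45.0, 55.0, 60.0, 68.0])
    ]
    return uncat + cat
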