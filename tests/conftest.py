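import pytest

import pairled as pl


@pytest.fixture()
def worked_example():
    """Hand-computable 3-fragment case.

    el_prep = (4, 2, 0), epsilon = (-2, -6, -2) for pairs (1,2), (1,3),
    (2,3).  With |epsilon|-proportional weights: w(1->2) = 2/8, w(1->3) =
    6/8, w(2->1) = w(2->3) = 1/2, so the distributed pairs are (2.0, 3.0,
    1.0) and the fp entries (0.0, -3.0, -1.0), summing to -4.0.
    """
    labels = ("F1", "F2", "F3")
    eps = pl.PairMatrix.from_pairs(labels, {
        ("F1", "F2"): -2.0, ("F1", "F3"): -6.0, ("F2", "F3"): -2.0,
    })
    prep = {"F1": 4.0, "F2": 2.0, "F3": 0.0}
    return labels, prep, eps


@pytest.fixture()
def two_fragment_dataset():
    """Minimal valid 2-fragment dataset: E = -10, intra (-4, -5), pair -1."""
    scheme = pl.FragmentScheme(("X", "Y"), {"X": "A", "Y": "B"})
    return pl.LEDDataset(
        scheme=scheme,
        total_energy=-10.0,
        intra={"X": -4.0, "Y": -5.0},
        inter={("X", "Y"): pl.EnergyChannels(elstat=-0.6, exch=0.2,
                                             disp=-0.4, no_disp=-0.2)},
        method_label="test",
    ).validate()
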