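"""Core decomposition engine: building blocks, exactness, and properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pairled as pl
from pairled.decomposition import distribution_weights
from pairled.model import ValidationError


def _refs_for(super_ds, per_sub_data):
    """Build a SubsystemReferenceSet from {sub: (total, intra, inter)}."""
    refs = {}
    for sub, (total, intra, inter) in per_sub_data.items():
        scheme = super_ds.scheme.restricted(sub)
        refs[sub] = pl.LEDDataset(scheme=scheme, total_energy=total,
                                  intra=intra, inter=inter).validate()
    return pl.SubsystemReferenceSet(parent_scheme=super_ds.scheme,
                                    references=refs).validate()


class TestInteractionEnergy:
    def test_two_subsystems(self, two_fragment_dataset):
        refs = _refs_for(two_fragment_dataset, {
            "A": (-60.0 + 60.0 - 4.5, {"X": -4.5}, {}),
            "B": (-4.5, {"Y": -4.5}, {}),
        })
        # E = -10, refs total -9 -> dE_int = -1
        assert pl.interaction_energy(two_fragment_dataset, refs) == -1.0

    def test_no_interaction_gives_zero(self, two_fragment_dataset):
        refs = _refs_for(two_fragment_dataset, {
            "A": (-5.0, {"X": -5.0}, {}),
            "B": (-5.0, {"Y": -5.0}, {}),
        })
        assert pl.interaction_energy(two_fragment_dataset, refs) == 0.0

    def test_three_subsystems(self):
        scheme = pl.FragmentScheme(("a", "b", "c"),
                                   {"a": "A", "b": "B", "c": "C"})
        zero = pl.EnergyChannels()
        super_ds = pl.LEDDataset(
            scheme=scheme, total_energy=-20.0,
            intra={"a": -6.2, "b": -7.2, "c": -6.6},
            inter={("a", "b"): zero, ("a", "c"): zero, ("b", "c"): zero},
        ).validate()
        refs = _refs_for(super_ds, {
            "A": (-6.0, {"a": -6.0}, {}),
            "B": (-7.0, {"b": -7.0}, {}),
            "C": (-6.5, {"c": -6.5}, {}),
        })
        assert pl.interaction_energy(super_ds, refs) == pytest.approx(-0.5)

    def test_fragment_set_mismatch(self, two_fragment_dataset):
        other = pl.FragmentScheme(("P", "Q"), {"P": "A", "Q": "B"})
        refs = pl.SubsystemReferenceSet(parent_scheme=other, references={})
        with pytest.raises(ValidationError, match="mismatch"):
            pl.interaction_energy(two_fragment_dataset, refs)


class TestElPrepVector:
    def test_is_intra_difference(self, two_fragment_dataset):
        refs = _refs_for(two_fragment_dataset, {
            "A": (-4.01, {"X": -4.01}, {}),
            "B": (-5.0, {"Y": -5.0}, {}),
        })
        prep = pl.el_prep_vector(two_fragment_dataset, refs)
        assert prep["X"] == pytest.approx(0.01)
        assert prep["Y"] == 0.0

    def test_compressed_trimer_all_positive(self):
        # polarization cost is 1/2 alpha |F|^2 >= 0 for monomer subsystems
        system = pl.charged_trimer(scale=0.8)
        prep = pl.el_prep_vector(system.supersystem, system.references)
        assert all(v > 0 for v in prep.values())


class TestEpsilonMatrix:
    def _mixed_system(self):
        scheme = pl.FragmentScheme(("a", "b", "c"),
                                   {"a": "A", "b": "A", "c": "B"})
        ch = pl.EnergyChannels
        super_ds = pl.LEDDataset(
            scheme=scheme, total_energy=-30.0 - 3.0 - 3.0 - 1.0,
            intra={"a": -10.0, "b": -10.0, "c": -10.0},
            inter={("a", "b"): ch(elstat=-3.0),
                   ("a", "c"): ch(elstat=-3.0),
                   ("b", "c"): ch(elstat=-1.0)},
        ).validate()
        refs = _refs_for(super_ds, {
            "A": (-20.0 - 2.5, {"a": -10.0, "b": -10.0},
                  {("a", "b"): ch(elstat=-2.5)}),
            "B": (-10.0, {"c": -10.0}, {}),
        })
        return super_ds, refs

    def test_same_subsystem_is_binding_induced_change(self):
        super_ds, refs = self._mixed_system()
        eps = pl.epsilon_matrix(super_ds, refs)
        assert eps.get("a", "b") == pytest.approx(-0.5)   # -3.0 - (-2.5)
        assert eps.get("a", "c") == -3.0                  # cross: pass-through
        assert eps.get("b", "c") == -1.0

    def test_single_fragment_subsystems_pass_through(self):
        system = pl.charged_trimer()
        eps = pl.epsilon_matrix(system.supersystem, system.references)
        assert eps.allclose(system.supersystem.inter_matrix(), atol=0.0)


class TestDistributeElPrep:
    def test_two_fragments_forced_by_normalization(self):
        eps = pl.PairMatrix.from_pairs(("a", "b"), {("a", "b"): -7.0})
        for mode in ("abs_epsilon", "squared_epsilon", "equal"):
            d = pl.distribute_el_prep({"a": 1.25, "b": -0.25}, eps,
                                      pl.WeightConfig(mode=mode))
            assert d.get("a", "b") == 1.0

    def test_worked_three_fragment_example(self, worked_example):
        labels, prep, eps = worked_example
        d = pl.distribute_el_prep(prep, eps)
        assert d.get("F1", "F2") == pytest.approx(2.0)
        assert d.get("F1", "F3") == pytest.approx(3.0)
        assert d.get("F2", "F3") == pytest.approx(1.0)
        assert d.total() == pytest.approx(6.0)

    def test_zero_el_prep_gives_zero_matrix(self, worked_example):
        labels, _, eps = worked_example
        d = pl.distribute_el_prep({x: 0.0 for x in labels}, eps)
        assert np.all(d.values == 0.0)

    def test_zero_row_policies(self):
        labels = ("a", "b", "c")
        eps = pl.PairMatrix.from_pairs(labels, {("b", "c"): -1.0})
        prep = {"a": 0.3, "b": 0.0, "c": 0.0}
        d = pl.distribute_el_prep(prep, eps)  # default: equal split
        assert d.get("a", "b") == pytest.approx(0.15)
        assert d.get("a", "c") == pytest.approx(0.15)
        with pytest.raises(ValidationError, match="all-zero"):
            pl.distribute_el_prep(prep, eps,
                                  pl.WeightConfig(zero_row_policy="error"))

    def test_single_fragment_is_an_error(self):
        eps = pl.PairMatrix(("a",))
        with pytest.raises(ValidationError, match="no pairs"):
            pl.distribute_el_prep({"a": 1.0}, eps)

    @pytest.mark.parametrize("mode", ["abs_epsilon", "squared_epsilon", "equal"])
    def test_row_weights_normalize(self, worked_example, mode):
        _, _, eps = worked_example
        W = distribution_weights(eps, pl.WeightConfig(mode=mode))
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-15)


class TestFpMap:
    def test_two_fragment_limit_single_entry_is_binding_energy(self):
        system = pl.canonical_dimer()
        res = pl.fp_map(system.supersystem, system.references)
        de = pl.interaction_energy(system.supersystem, system.references)
        assert res.fp_map.get("W1", "W2") == pytest.approx(de, abs=1e-12)
        assert res.delta_e_int == de

    def test_worked_example_entries(self, worked_example):
        labels, prep, eps = worked_example
        d = pl.distribute_el_prep(prep, eps)
        fp = eps + d
        assert fp.get("F1", "F2") == pytest.approx(0.0)
        assert fp.get("F1", "F3") == pytest.approx(-3.0)
        assert fp.get("F2", "F3") == pytest.approx(-1.0)
        assert fp.total() == pytest.approx(-4.0)

    def test_result_carries_consistent_intermediates(self):
        system = pl.random_system(5, 2, seed=3)
        res = pl.fp_map(system.supersystem, system.references)
        recomposed = res.epsilon + res.el_prep_pairs
        assert recomposed.allclose(res.fp_map, atol=0.0)
        assert abs(res.el_prep_pairs.total() - res.el_prep_sum()) < 1e-10
        assert abs(res.fp_map.total() - res.delta_e_int) < 1e-10


class TestChannelMaps:
    def test_channels_sum_to_fp_map(self):
        system = pl.random_system(6, 3, seed=9)
        res = pl.fp_map(system.supersystem, system.references)
        acc = pl.PairMatrix(res.scheme.fragment_labels)
        for m in res.channel_maps.values():
            acc = acc + m
        assert np.max(np.abs(acc.values - res.fp_map.values)) < 1e-10

    def test_channel_pass_through_on_one_pair(self, two_fragment_dataset):
        refs = _refs_for(two_fragment_dataset, {
            "A": (-4.0, {"X": -4.0}, {}), "B": (-5.0, {"Y": -5.0}, {}),
        })
        res = pl.fp_map(two_fragment_dataset, refs)
        assert res.channel_maps["elstat"].get("X", "Y") == -0.6
        assert res.channel_maps["exch"].get("X", "Y") == 0.2
        assert res.channel_maps["disp"].get("X", "Y") == -0.4
        assert res.channel_maps["no_disp"].get("X", "Y") == -0.2
        assert res.epsilon.get("X", "Y") == pytest.approx(-1.0)

    def test_channel_sum_mismatch_rejected(self):
        system = pl.canonical_dimer()
        res = pl.fp_map(system.supersystem, system.references)
        bad = {"only": pl.PairMatrix.from_pairs(("W1", "W2"),
                                                {("W1", "W2"): 123.0})}
        with pytest.raises(ValidationError, match="do not sum"):
            pl.channel_fp_maps(res, bad)


class TestAggregateMap:
    @pytest.fixture()
    def map4(self):
        labels = ("L", "R1", "R2", "R3")
        return pl.PairMatrix.from_pairs(labels, {
            ("L", "R1"): -1.0, ("L", "R2"): -2.0, ("L", "R3"): -3.0,
            ("R1", "R2"): 0.5, ("R1", "R3"): 0.25, ("R2", "R3"): 0.125,
        })

    def test_identity_grouping_is_unchanged(self, map4):
        df = pl.aggregate_map(map4, {x: x for x in map4.labels})
        assert np.allclose(df.to_numpy(), map4.values)

    def test_single_group_collapses_to_total(self, map4):
        df = pl.aggregate_map(map4, {x: "all" for x in map4.labels})
        assert df.shape == (1, 1)
        assert df.loc["all", "all"] == pytest.approx(map4.total())

    def test_rest_lumping(self, map4):
        df = pl.aggregate_map(
            map4, {"L": "L", "R1": "R1", "R2": "R2", "R3": "R3"},
            explicit_groups=["L", "R1"])
        assert df.loc["L", "rest"] == pytest.approx(-5.0)  # (L,R2)+(L,R3)
        assert df.loc["rest", "rest"] == pytest.approx(0.125)
        assert pl.aggregate_total(df) == pytest.approx(map4.total())

    def test_unknown_fragment_rejected(self, map4):
        with pytest.raises(ValidationError):
            pl.aggregate_map(map4, {"L": "L"})


class TestLinearityDiagnostic:
    def test_exact_line_recovers_slope_and_unit_r2(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0 * v for v in x]
        fit = pl.el_prep_linearity(y, x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert not fit.degenerate

    def test_constant_response_flagged_zero_r2(self):
        fit = pl.el_prep_linearity([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert fit.r_squared == 0.0 and fit.degenerate

    def test_input_errors(self):
        with pytest.raises(ValidationError, match="at least 3"):
            pl.el_prep_linearity([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValidationError, match="zero variance"):
            pl.el_prep_linearity([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])

    def test_emulator_dimer_scan_is_strongly_linear(self):
        xs, ys = [], []
        for _, system in pl.dimer_scan_systems(20):
            res = pl.fp_map(system.supersystem, system.references)
            xs.append(res.epsilon.get("W1", "W2"))
            ys.append(res.el_prep["W1"] + res.el_prep["W2"])
        fit = pl.el_prep_linearity(ys, xs)
        assert fit.r_squared >= 0.95


# ---------------------------------------------------------------------------
# Property tests over random emulator systems
# ---------------------------------------------------------------------------

@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1),
       n=st.integers(2, 7), m=st.integers(1, 3),
       mode=st.sampled_from(["abs_epsilon", "squared_epsilon", "equal"]))
def test_exactness_and_conservation_properties(seed, n, m, mode):
    """Pair sums reproduce the binding energy and conserve el-prep, all modes."""
    m = min(m, n)
    system = pl.random_system(n, m, seed=seed)
    cfg = pl.WeightConfig(mode=mode)
    res = pl.fp_map(system.supersystem, system.references, cfg)
    assert abs(res.fp_map.total() - res.delta_e_int) < 1e-10
    assert abs(res.el_prep_pairs.total() - res.el_prep_sum()) < 1e-10
    oracle = pl.oracle_totals(system.fragments, system.scheme)
    assert res.delta_e_int == pytest.approx(oracle.delta_e_int, abs=1e-10)


@settings(max_examples=10, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_permutation_equivariance(seed):
    """Relabelling fragments permutes every map consistently."""
    system = pl.random_system(5, 2, seed=seed)
    res = pl.fp_map(system.supersystem, system.references)
    labels = list(system.scheme.fragment_labels)
    rng = np.random.default_rng(seed)
    perm = [labels[i] for i in rng.permutation(len(labels))]

    order = {x: i for i, x in enumerate(system.scheme.fragment_labels)}
    permuted_scheme = pl.FragmentScheme(
        tuple(perm), dict(system.scheme.subsystem_of))
    permuted_super = pl.LEDDataset(
        scheme=permuted_scheme,
        total_energy=system.supersystem.total_energy,
        intra=dict(system.supersystem.intra),
        inter={k: v for k, v in system.supersystem.inter.items()},
        completeness_tol=system.supersystem.completeness_tol,
    ).validate()
    permuted_refs = pl.SubsystemReferenceSet(
        parent_scheme=permuted_scheme,
        references=system.references.references)
    res_p = pl.fp_map(permuted_super, permuted_refs)
    assert res_p.fp_map.permuted(system.scheme.fragment_labels).allclose(
        res.fp_map, atol=1e-12)
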