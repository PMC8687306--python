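import json

import numpy as np
import pytest

from fluctid import (
    ReactionNetwork,
    build_epo_receptor,
    build_gene_expression,
    build_immigration_death,
    propensities,
    simulate_ssa,
    TimeGrid,
)

EPO_MOIETY = {"Epo": 1, "EpoEpoR": 1, "EpoEpoR_i": 1, "Epo_i": 1, "Epo_e": 1}


class TestValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            build_immigration_death(-1.0, 0.1, 10)
        with pytest.raises(ValueError):
            build_gene_expression(kr=-5)
        with pytest.raises(ValueError):
            build_epo_receptor(kon=-0.1)

    def test_unknown_rate_param_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            ReactionNetwork(["X"], [((0,), (1,), "missing")], {"k": 1.0}, [0])

    def test_stoichiometry_length_checked(self):
        with pytest.raises(ValueError):
            ReactionNetwork(["A", "B"], [((1,), (0,), "k")], {"k": 1.0}, [0, 0])

    def test_negative_initial_state_rejected(self):
        with pytest.raises(ValueError):
            ReactionNetwork(["X"], [((1,), (0,), "k")], {"k": 1.0}, [-1])

    def test_noninteger_initial_state_warns_and_rounds(self):
        with pytest.warns(UserWarning, match="rounded"):
            net = ReactionNetwork(["X"], [((1,), (0,), "k")], {"k": 1.0}, [9.7])
        assert net.initial_state[0] == 10
        assert net.initial_state_real[0] == 9.7


class TestPropensities:
    def test_immigration_death_at_zero(self, id_net):
        assert propensities(id_net, [0]).tolist() == [1.0, 0.0]

    def test_total_propensity_at_steady_state(self, id_net):
        assert propensities(id_net, [10]).sum() == pytest.approx(2.0)

    def test_translation_propensity(self):
        net = build_gene_expression()
        a = propensities(net, [16, 230])
        # reactions: transcription, translation, mRNA decay, protein decay
        assert a[1] == pytest.approx(10 * 16)

    def test_epo_binding_propensity(self):
        net, _ = build_epo_receptor()
        a = propensities(net, net.initial_state)
        assert a[0] == pytest.approx(0.017 * 300 * 170)

    def test_bimolecular_and_homodimer_combinatorics(self):
        net = ReactionNetwork(
            ["A", "B"],
            [((1, 1), (0, 0), "k"), ((2, 0), (0, 1), "k2")],
            {"k": 2.0, "k2": 3.0},
            [4, 5],
        )
        a = propensities(net, [4, 5])
        assert a[0] == pytest.approx(2.0 * 4 * 5)
        assert a[1] == pytest.approx(3.0 * 4 * 3 / 2)

    def test_zero_when_substrate_insufficient(self):
        net = ReactionNetwork(["A"], [((2,), (0,), "k")], {"k": 1.0}, [1])
        assert propensities(net, [1])[0] == 0.0

    def test_rate_scaling_scales_only_its_reaction(self, id_net):
        scaled = id_net.with_parameters(theta2=0.2)
        a0, a1 = propensities(id_net, [10]), propensities(scaled, [10])
        assert a1[0] == a0[0]
        assert a1[1] == pytest.approx(2 * a0[1])


class TestEpoStructure:
    def test_initial_state(self):
        net, obs = build_epo_receptor()
        state = dict(zip(net.species_names, net.initial_state))
        assert state["Epo"] == 300 and state["EpoR"] == 170
        assert sum(state.values()) == 470

    def test_moiety_conserved_per_reaction(self):
        net, _ = build_epo_receptor()
        m = np.array([EPO_MOIETY.get(s, 0) for s in net.species_names])
        for r in net.reactions:
            change = np.array(r.products) - np.array(r.substrates)
            assert m @ change == 0

    def test_moiety_conserved_along_ssa_trajectory(self):
        net, _ = build_epo_receptor()
        traj = simulate_ssa(net, TimeGrid(0.0, 50, 0.2), seed=5)
        m = np.array([EPO_MOIETY.get(s, 0) for s in net.species_names])
        totals = traj.values @ m
        assert np.all(totals == totals[0])

    def test_receptor_synthesis_is_constant_kt_bmax(self):
        net, _ = build_epo_receptor(Bmax=200, kt=0.2)
        a = propensities(net, np.zeros(6, dtype=int))
        labels = [r.rate_param for r in net.reactions]
        assert a[labels.index("kt_Bmax")] == pytest.approx(0.2 * 200)


class TestObservables:
    def test_y1_scale(self):
        net, obs = build_epo_receptor()
        y = obs.apply(net.initial_state[None, :])
        assert y[0, 0] == pytest.approx(9.12 * 300)
        assert y[0, 1] == 0.0

    def test_unknown_species_rejected(self):
        from fluctid import ObservableMap

        with pytest.raises(KeyError):
            ObservableMap(["A"], [("y", {"B": 1.0}, 1.0)])


def test_json_round_trip():
    net = build_gene_expression(mrna0=3, pro0=7)
    clone = ReactionNetwork.from_json(net.to_json())
    assert clone.species_names == net.species_names
    assert clone.parameters == net.parameters
    assert np.array_equal(clone.initial_state, net.initial_state)
    assert [r for r in clone.reactions] == [r for r in net.reactions]
    # non-integer initial values survive serialisation exactly
    with pytest.warns(UserWarning):
        net2, _ = build_epo_receptor(Epo0=176.47)
    clone2 = ReactionNetwork.from_json(net2.to_json())
    assert clone2.initial_state_real[0] == 176.47
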