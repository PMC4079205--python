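"""Origination-fixation model: stationarity, transition matrices, ensembles."""

import numpy as np
import pytest

from splicesel.selection import fixation_ratio
from splicesel.simulate import (
    DEFAULT_PANEL_DISTANCES,
    SimParams,
    hky_mutation_matrix,
    normalize_mutation_matrix,
    rate_matrix,
    simulate_panel,
    simulate_triplet_ensemble,
    stationary_frequencies,
    substitution_matrix,
)
from splicesel.sites import NUC_INDEX, invariant_bases, site_offsets


def uniform_mu():
    mu = np.full((4, 4), 1.0)
    np.fill_diagonal(mu, 0.0)
    return normalize_mutation_matrix(mu)


class TestStationaryFrequencies:
    def test_neutral_symmetric_is_uniform(self):
        pi = stationary_frequencies(uniform_mu(), None)
        assert np.allclose(pi, 0.25, atol=1e-12)

    def test_selected_ratio_matches_long_run_simulation(self):
        # two alleles with a fitness gap S: detailed balance predicts
        # freq(favored)/freq(other) = e^S; check against an independent
        # time-average of an explicitly simulated jump process
        mu = uniform_mu()
        S = 2.0
        f = np.array([S, 0.0, 0.0, 0.0])
        pi = stationary_frequencies(mu, f)
        assert pi[0] / pi[1] == pytest.approx(np.exp(S), rel=1e-9)

        q = rate_matrix(mu, f)
        rng = np.random.default_rng(2024)
        state, t_acc = 0, np.zeros(4)
        for _ in range(200_000):
            out_rate = -q[state, state]
            t_acc[state] += rng.exponential(1.0 / out_rate)
            probs = q[state].copy()
            probs[state] = 0.0
            state = rng.choice(4, p=probs / probs.sum())
        emp = t_acc / t_acc.sum()
        assert emp[0] / emp[1] == pytest.approx(np.exp(S), rel=0.06)
        assert np.allclose(emp, pi, atol=0.01)

    def test_asymmetric_mutation_balance(self):
        # target-dependent rates mu[Z, X] = w[X] give stationary pi = w
        w = np.array([1.0, 2.0, 3.0, 4.0])
        mu = np.tile(w, (4, 1)).astype(float)
        np.fill_diagonal(mu, 0.0)
        pi = stationary_frequencies(normalize_mutation_matrix(mu), None)
        assert pi[0] / pi[1] == pytest.approx(0.5, rel=1e-9)
        assert np.allclose(pi, w / w.sum(), atol=1e-9)

    def test_detailed_balance_for_symmetric_mutation(self):
        mu = hky_mutation_matrix(2.0)
        f = np.array([0.5, -1.0, 0.0, 2.0])
        pi = stationary_frequencies(mu, f)
        q = rate_matrix(mu, f)
        for z in range(4):
            for x in range(4):
                if z != x:
                    assert pi[z] * q[z, x] == pytest.approx(pi[x] * q[x, z], rel=1e-9)

    def test_disconnected_matrix_rejected(self):
        mu = uniform_mu()
        mu[:, 3] = 0.0
        mu[3, :] = 0.0
        with pytest.raises(ValueError):
            stationary_frequencies(mu, None)


class TestSubstitutionMatrix:
    def test_zero_branch_is_identity(self):
        assert np.array_equal(
            substitution_matrix(0.0, hky_mutation_matrix(), None), np.eye(4)
        )

    def test_constant_fitness_reduces_to_neutral(self):
        mu = hky_mutation_matrix(2.0)
        p_neutral = substitution_matrix(0.1, mu, None)
        p_shifted = substitution_matrix(0.1, mu, np.full(4, 3.0))
        assert np.allclose(p_neutral, p_shifted, atol=1e-12)

    def test_rate_ratio_under_selection(self):
        # advantage S=2 of A over G: rate(G->A)/rate(A->G) = r(2)/r(-2)
        mu = hky_mutation_matrix(2.0)
        f = np.zeros(4)
        f[NUC_INDEX["A"]] = 2.0
        q = rate_matrix(mu, f)
        a, g = NUC_INDEX["A"], NUC_INDEX["G"]
        expected = (mu[g, a] * fixation_ratio(2.0)) / (mu[a, g] * fixation_ratio(-2.0))
        assert q[g, a] / q[a, g] == pytest.approx(expected, rel=1e-12)
        assert fixation_ratio(2.0) == pytest.approx(2.3130, abs=1e-4)
        assert fixation_ratio(-2.0) == pytest.approx(0.31304, abs=1e-5)

    @pytest.mark.parametrize("t", [0.001, 0.05, 0.5, 5.0])
    def test_rows_are_distributions(self, t):
        p = substitution_matrix(t, hky_mutation_matrix(), [0.0, -2.0, 1.0, 0.0])
        assert np.all(p >= 0) and np.all(p <= 1)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            substitution_matrix(-0.1, hky_mutation_matrix(), None)


class TestTripletEnsemble:
    def test_zero_branches_make_species_identical(self):
        p = SimParams(n_sites=200, t_sister=0.0, t_outgroup=0.0, seed=1)
        ens = simulate_triplet_ensemble(p)
        assert np.array_equal(ens.ref, ens.sister)
        assert np.array_equal(ens.ref, ens.outgroup)
        assert np.array_equal(ens.ref, ens.anc_true)

    def test_strong_selection_fixes_consensus(self):
        p = SimParams(n_sites=300, site_type="donor", S_profile=-50.0, seed=2)
        ens = simulate_triplet_ensemble(p)
        for j, off in enumerate(ens.offsets):
            cn = ens.consensus.cn("donor", off)
            if cn is None or len(cn) != 1:
                continue
            code = NUC_INDEX[next(iter(cn))]
            for arr in (ens.ref, ens.sister, ens.outgroup):
                assert np.all(arr[:, j] == code)

    def test_invariant_dinucleotides_never_mutate(self):
        for site_type in ("donor", "acceptor"):
            p = SimParams(n_sites=500, site_type=site_type, S_profile=0.0, seed=3)
            ens = simulate_triplet_ensemble(p)
            offs = site_offsets(site_type)
            for off, base in invariant_bases(site_type).items():
                j = offs.index(off)
                code = NUC_INDEX[base]
                for arr in (ens.ref, ens.sister, ens.outgroup, ens.anc_true):
                    assert np.all(arr[:, j] == code)

    def test_neutral_divergence_matches_transition_matrix(self):
        p = SimParams(
            n_sites=20000, site_type="donor", S_profile=0.0,
            t_sister=0.1, t_outgroup=0.2, seed=4,
        )
        ens = simulate_triplet_ensemble(p)
        P = substitution_matrix(0.05, p.mutation_matrix, None)
        pi = stationary_frequencies(p.mutation_matrix, None)
        expected = 1.0 - float(pi @ np.diag(P))
        variable = [j for j, off in enumerate(ens.offsets) if off not in (1, 2)]
        changed = (ens.ref[:, variable] != ens.anc_true[:, variable]).mean()
        n = ens.n_sites * len(variable)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(changed - expected) < 3 * se

    def test_deterministic_for_fixed_seed(self):
        p1 = SimParams(n_sites=500, site_specific_fraction=0.2, seed=9)
        p2 = SimParams(n_sites=500, site_specific_fraction=0.2, seed=9)
        e1, e2 = simulate_triplet_ensemble(p1), simulate_triplet_ensemble(p2)
        for name in ("ref", "sister", "outgroup", "anc_true", "favored"):
            assert np.array_equal(getattr(e1, name), getattr(e2, name))
        for prov in e1.controls:
            assert np.array_equal(e1.controls[prov].ref, e2.controls[prov].ref)
            assert np.array_equal(e1.controls[prov].score, e2.controls[prov].score)
        e3 = simulate_triplet_ensemble(SimParams(n_sites=500, seed=10))
        assert not np.array_equal(e1.ref, e3.ref)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SimParams(n_sites=0)
        with pytest.raises(ValueError):
            SimParams(n_sites=10, site_specific_fraction=1.5)
        with pytest.raises(ValueError):
            SimParams(n_sites=10, t_sister=-0.1)


class TestPanel:
    def test_zero_distance_species_matches_reference(self):
        p = SimParams(n_sites=100, seed=5, panel_distances=(0.0,))
        panel = simulate_panel(p)
        assert np.array_equal(panel.sites.states[:, 0], panel.sites.ref)

    def test_large_distance_approaches_stationarity(self):
        p = SimParams(
            n_sites=3000, site_type="donor", S_profile=0.0, seed=6,
            panel_distances=(50.0,),
        )
        panel = simulate_panel(p)
        match = (panel.sites.states[:, 0] == panel.sites.ref).mean()
        pi = stationary_frequencies(p.mutation_matrix, None)
        n = panel.sites.ref.size
        se = np.sqrt(0.25 * 0.75 / n)
        # far species is an independent draw from the stationary law
        assert abs(match - float(pi @ pi)) < 4 * se

    def test_favored_nc_more_conserved_than_controls(self):
        p = SimParams(
            n_sites=2000, site_type="donor", S_profile=-2.0,
            site_specific_fraction=1.0, seed=7, panel_distances=(0.5, 1.0),
        )
        panel = simulate_panel(p)
        fav = panel.sites.favored
        sel = fav >= 0
        obs = (panel.sites.states[sel, 0] == panel.sites.ref[sel])[
            panel.sites.ref[sel] == fav[sel]
        ].mean()
        ctrl = (panel.controls.states[:, 0] == panel.controls.ref).mean()
        assert obs > ctrl + 0.05

    def test_empty_distances_rejected(self):
        with pytest.raises(ValueError):
            simulate_panel(SimParams(n_sites=10, seed=1), distances=[])

    def test_decreasing_distances_rejected(self):
        with pytest.raises(ValueError):
            simulate_panel(SimParams(n_sites=10, seed=1), distances=[0.5, 0.1])
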