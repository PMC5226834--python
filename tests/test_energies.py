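"""Energy functionals: trivial anchors, brute-force oracles, kernel geometry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mapalign as ma
from mapalign.energies import (axon_correlation_kernel, chemoaffinity_kernel,
                               retinal_kernel, synaptic_weight,
                               synaptic_weight_matrix)
from mapalign.annealer import Move

from conftest import random_state


# ---------------------------------------------------------------------------
# Independent brute-force implementations (the oracles)
# ---------------------------------------------------------------------------

def brute_chemo(state, params):
    total = 0.0
    g = state.grid
    for s in range(g.n_sites):
        xs, ys = g.sc_coords[s]
        for l in range(g.n_sites):
            n = state.counts[s, l]
            if n == 0:
                continue
            xl, yl = g.v1_coords[l]
            term = (params.alpha_a * (np.exp(xs) - 1) * np.exp(-xl)
                    - params.beta_a * (np.exp(ys) - 1) * (np.exp(yl) - 1))
            total += n * term
    return total


def brute_competition(state, params):
    g = state.grid
    total = 0.0
    for l in range(g.n_sites):
        nA = int(state.counts[:, l].sum())
        total += params.beta_c * nA ** 2 - params.alpha_c * nA
    for s in range(g.n_sites):
        nD = int(state.counts[s, :].sum())
        total += params.gamma_c * nD ** 2
    return total


def brute_retinal(xs, ys, xl, yl, params):
    if params.genotype == "WT":
        d = np.hypot(xs - xl, ys - yl)
        return np.exp(-d / params.beta_u)
    kb = params.kappa_u * params.beta_u
    dy = (ys - yl) / params.beta_u
    d1 = np.sqrt(((xs - xl / 2) / kb) ** 2 + dy ** 2)
    d2 = np.sqrt(((xs - xl / 2 - 0.5) / kb) ** 2 + dy ** 2)
    if params.kernel_form == "gaussian":
        d1, d2 = d1 ** 2, d2 ** 2
    return params.alpha_u * np.exp(-d1) + np.exp(-d2)


def brute_activity(state, params):
    g = state.grid
    total = 0.0
    for s in range(g.n_sites):
        xs, ys = g.sc_coords[s]
        for l in range(g.n_sites):
            n = state.counts[s, l]
            if n == 0:
                continue
            xl, yl = g.v1_coords[l]
            R = brute_retinal(xs, ys, xl, yl, params)
            if params.model_kind == "correlational":
                total += n * R
                continue
            num = den = 0.0
            for q in range(g.n_sites):
                if q == l or state.counts[s, q] == 0:
                    continue
                xq, yq = g.v1_coords[q]
                D = np.exp(-((xs - xq) ** 2 + (ys - yq) ** 2)
                           / (4 * params.nu_u ** 2))
                K = np.exp(-np.hypot(xl - xq, yl - yq) / params.beta_u)
                num += D * state.counts[s, q] * K
                den += D * state.counts[s, q]
            axon = num / den if den > 0 else 0.0
            total += n * (axon + params.xi_u * R)
    return -params.gamma_u * total


# ---------------------------------------------------------------------------
# Chemoaffinity and competition
# ---------------------------------------------------------------------------

class TestChemoaffinity:
    def test_empty_state_is_zero(self, grid6):
        s = ma.init_connectivity(grid6, "empty")
        p = ma.genotype_params("correlational", "WT")
        assert ma.chemoaffinity_energy(s, p) == 0.0

    def test_single_contact_and_linearity(self, grid6):
        p = ma.genotype_params("correlational", "WT")
        s = ma.init_connectivity(grid6, "empty")
        s.add_contact(7, 22)
        g = chemoaffinity_kernel(grid6.sc_coords[7:8], grid6.v1_coords[22:23], p)
        e1 = ma.chemoaffinity_energy(s, p)
        assert e1 == pytest.approx(float(g[0, 0]), rel=1e-12)
        s.add_contact(7, 22)
        assert ma.chemoaffinity_energy(s, p) == pytest.approx(2 * e1, rel=1e-12)

    def test_matches_brute_force(self, grid6):
        p = ma.genotype_params("correlational", "WT")
        s = random_state(grid6, mean=3, seed=11)
        assert ma.chemoaffinity_energy(s, p) == pytest.approx(
            brute_chemo(s, p), rel=1e-9)


class TestCompetition:
    def test_empty_state_is_zero(self, grid6):
        s = ma.init_connectivity(grid6, "empty")
        p = ma.genotype_params("correlational", "WT")
        assert ma.competition_energy(s, p) == 0.0

    def test_single_contact_hand_value(self, grid6):
        # one contact: 1 - 450 + 1 with the canonical coefficients
        p = ma.genotype_params("correlational", "WT")
        s = ma.init_connectivity(grid6, "empty")
        s.add_contact(0, 5)
        assert ma.competition_energy(s, p) == pytest.approx(-448.0)

    def test_matches_brute_force(self, grid6):
        p = ma.genotype_params("correlational", "WT")
        s = random_state(grid6, mean=4, seed=5)
        assert ma.competition_energy(s, p) == brute_competition(s, p)


# ---------------------------------------------------------------------------
# Activity energy
# ---------------------------------------------------------------------------

class TestActivityCorrelational:
    def test_zero_distance_contact_contributes_minus_gamma(self, grid6):
        p = ma.genotype_params("correlational", "WT")
        s = ma.init_connectivity(grid6, "empty")
        s.add_contact(14, 14)  # same site index => same coordinates
        assert ma.activity_energy(s, p) == pytest.approx(-p.gamma_u)

    def test_kernel_at_one_correlation_length(self):
        p = ma.genotype_params("correlational", "WT")
        sc = np.array([[0.5, 0.5]])
        v1 = np.array([[0.5 + p.beta_u, 0.5]])
        assert retinal_kernel(sc, v1, p)[0, 0] == pytest.approx(np.e ** -1)

    def test_kernel_monotone_decay(self):
        p = ma.genotype_params("correlational", "WT")
        d = np.linspace(0, 1.4, 200)
        sc = np.column_stack([np.zeros(200), np.zeros(200)])
        v1 = np.column_stack([d, np.zeros(200)])
        vals = np.array([retinal_kernel(sc[i:i+1], v1[i:i+1], p)[0, 0]
                         for i in range(200)])
        assert (np.diff(vals) < 0).all()

    @pytest.mark.parametrize("genotype", ["WT", "Isl2EphA3", "Isl2EphA3_b2KO"])
    def test_matches_brute_force(self, grid6, genotype):
        p = ma.genotype_params("correlational", genotype)
        s = random_state(grid6, mean=3, seed=2)
        assert ma.activity_energy(s, p) == pytest.approx(
            brute_activity(s, p), rel=1e-9)


class TestActivityIntegrational:
    def test_two_axon_toy_hand_value(self):
        # one SC site with contacts from two distinct axons l and q:
        # each contact's axon-axon term is the correlation with the single
        # other axon, K(l, q); the retinal term adds xi_u * R.
        grid = ma.build_grid(4)
        p = ma.genotype_params("integrational", "WT")
        s = ma.init_connectivity(grid, "empty")
        sc, l, q = 5, 5, 10
        s.add_contact(sc, l)
        s.add_contact(sc, q)
        K = axon_correlation_kernel(grid.v1_coords, p)[l, q]
        R_l = retinal_kernel(grid.sc_coords[sc:sc+1], grid.v1_coords[l:l+1], p)[0, 0]
        R_q = retinal_kernel(grid.sc_coords[sc:sc+1], grid.v1_coords[q:q+1], p)[0, 0]
        expected = -p.gamma_u * ((K + p.xi_u * R_l) + (K + p.xi_u * R_q))
        assert ma.activity_energy(s, p) == pytest.approx(expected, rel=1e-12)

    def test_single_axon_site_has_zero_axon_term(self):
        # with no other axon converging the 0/0 ratio is defined as 0
        grid = ma.build_grid(4)
        p = ma.genotype_params("integrational", "WT")
        s = ma.init_connectivity(grid, "empty")
        s.add_contact(3, 9)
        s.add_contact(3, 9)
        R = retinal_kernel(grid.sc_coords[3:4], grid.v1_coords[9:10], p)[0, 0]
        assert ma.activity_energy(s, p) == pytest.approx(
            -p.gamma_u * 2 * p.xi_u * R)

    @pytest.mark.parametrize("genotype", ["WT", "Isl2EphA3", "Isl2EphA3_b2KO"])
    def test_matches_brute_force(self, grid6, genotype):
        p = ma.genotype_params("integrational", genotype)
        s = random_state(grid6, mean=3, seed=8)
        assert ma.activity_energy(s, p) == pytest.approx(
            brute_activity(s, p), rel=1e-9)

    def test_strong_retinal_drive_limit_recovers_correlational(self, grid6):
        # bracket / xi_u -> retinal kernel as xi_u -> infinity
        s = random_state(grid6, mean=3, seed=4)
        corr = ma.genotype_params("correlational", "WT")
        big = 1e6
        integ = ma.genotype_params("integrational", "WT", xi_u=big)
        assert ma.activity_energy(s, integ) / big == pytest.approx(
            ma.activity_energy(s, corr), rel=1e-5)


class TestSynapticWeight:
    def test_unit_at_zero_distance(self):
        assert synaptic_weight((0.3, 0.4), (0.3, 0.4), 0.15) == 1.0

    def test_value_at_two_nu(self):
        assert synaptic_weight((0.0, 0.0), (0.3, 0.0), 0.15) == pytest.approx(
            np.e ** -1)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_symmetry(self, x1, y1, x2, y2):
        assert synaptic_weight((x1, y1), (x2, y2), 0.15) == pytest.approx(
            synaptic_weight((x2, y2), (x1, y1), 0.15))

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            synaptic_weight((0, 0), (1, 1), 0.0)


# ---------------------------------------------------------------------------
# Mutant kernel geometry
# ---------------------------------------------------------------------------

class TestDuplicatedKernelGeometry:
    @pytest.mark.parametrize("xl", [0.0, 0.2, 0.5, 0.8, 1.0])
    def test_peak_positions(self, xl):
        p = ma.genotype_params("correlational", "Isl2EphA3")
        x = np.linspace(-0.2, 1.2, 2801)
        sc = np.column_stack([x, np.full_like(x, 0.5)])
        v1 = np.array([[xl, 0.5]])
        vals = retinal_kernel(sc, v1, p)[:, 0]
        # two local maxima, at xl/2 and xl/2 + 1/2
        i1 = np.argmin(np.abs(x - xl / 2))
        i2 = np.argmin(np.abs(x - (xl / 2 + 0.5)))
        assert vals[i1] >= vals[max(i1 - 5, 0)] and vals[i1] >= vals[i1 + 5]
        assert vals[i2] >= vals[i2 - 5] and vals[i2] >= vals[min(i2 + 5, len(x) - 1)]

    def test_amplitude_ratio_is_alpha_u(self):
        p = ma.genotype_params("correlational", "Isl2EphA3")
        v1 = np.array([[0.5, 0.5]])
        peak1 = retinal_kernel(np.array([[0.25, 0.5]]), v1, p)[0, 0]
        peak2 = retinal_kernel(np.array([[0.75, 0.5]]), v1, p)[0, 0]
        # small cross-talk from the opposite peak shifts the ratio slightly
        assert peak1 / peak2 == pytest.approx(p.alpha_u, rel=0.02)

    @pytest.mark.parametrize("kappa", [1.0, 2.0, 4.0])
    def test_azimuthal_width_scales_with_kappa(self, kappa):
        # suppress the anterior peak (alpha_u -> 0) to isolate one peak:
        # the azimuthal e-folding distance must be exactly kappa * beta_u
        p = ma.genotype_params("correlational", "Isl2EphA3",
                               alpha_u=1e-12, kappa_u=kappa)
        v1 = np.array([[1.0, 0.5]])
        peak = np.array([[1.0, 0.5]])
        off = np.array([[1.0 - kappa * p.beta_u, 0.5]])
        ratio = (retinal_kernel(off, v1, p)[0, 0]
                 / retinal_kernel(peak, v1, p)[0, 0])
        assert ratio == pytest.approx(np.e ** -1, rel=1e-9)

    def test_gaussian_variant_differs_only_off_peak(self):
        pe = ma.genotype_params("correlational", "Isl2EphA3")
        pg = ma.genotype_params("correlational", "Isl2EphA3",
                                kernel_form="gaussian")
        v1 = np.array([[0.5, 0.5]])
        on_peak = np.array([[0.75, 0.5]])
        off = np.array([[0.6, 0.5]])
        assert retinal_kernel(on_peak, v1, pg)[0, 0] == pytest.approx(
            retinal_kernel(on_peak, v1, pe)[0, 0], rel=0.02)
        assert retinal_kernel(off, v1, pg)[0, 0] != pytest.approx(
            retinal_kernel(off, v1, pe)[0, 0], rel=0.02)


# ---------------------------------------------------------------------------
# Totals, additivity, incremental deltas
# ---------------------------------------------------------------------------

class TestTotalEnergy:
    def test_empty_state_all_zero(self, grid6):
        p = ma.genotype_params("correlational", "WT")
        eb = ma.total_energy(ma.init_connectivity(grid6, "empty"), p)
        assert (eb.E_a, eb.E_c, eb.E_u, eb.E_total) == (0, 0, 0, 0)

    @pytest.mark.parametrize("kind", ["correlational", "integrational"])
    def test_total_is_sum_and_matches_brute_force(self, grid6, kind):
        p = ma.genotype_params(kind, "WT")
        s = random_state(grid6, mean=3, seed=13)
        eb = ma.total_energy(s, p)
        assert eb.E_total == pytest.approx(eb.E_a + eb.E_c + eb.E_u, rel=1e-12)
        brute = brute_chemo(s, p) + brute_competition(s, p) + brute_activity(s, p)
        assert eb.E_total == pytest.approx(brute, rel=1e-9)

    def test_additivity_of_linear_components(self, grid6):
        # E_a and correlational E_u are linear in counts; E_c is not
        p = ma.genotype_params("correlational", "WT")
        a = random_state(grid6, mean=2, seed=1)
        b = random_state(grid6, mean=2, seed=2)
        both = ma.ConnectivityState(grid6, a.counts + b.counts)
        assert ma.chemoaffinity_energy(both, p) == pytest.approx(
            ma.chemoaffinity_energy(a, p) + ma.chemoaffinity_energy(b, p),
            rel=1e-9)
        assert ma.activity_energy(both, p) == pytest.approx(
            ma.activity_energy(a, p) + ma.activity_energy(b, p), rel=1e-9)
        assert ma.competition_energy(both, p) != pytest.approx(
            ma.competition_energy(a, p) + ma.competition_energy(b, p), rel=1e-6)


class TestDeltaEnergy:
    def test_add_then_remove_cancels(self, grid8):
        p = ma.genotype_params("integrational", "Isl2EphA3")
        s = random_state(grid8, mean=2, seed=3)
        d1 = ma.delta_energy(s, Move(add_pair=(10, 20)), p)
        s.add_contact(10, 20)
        d2 = ma.delta_energy(s, Move(remove_pair=(10, 20)), p)
        s.remove_contact(10, 20)
        assert d1 + d2 == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_first_contact(self, grid6):
        # adding one aligned contact to an empty correlational WT state
        p = ma.genotype_params("correlational", "WT")
        s = ma.init_connectivity(grid6, "empty")
        g = chemoaffinity_kernel(grid6.sc_coords[21:22], grid6.v1_coords[21:22], p)
        expected = float(g[0, 0]) + (1 - p.alpha_c + 1) - p.gamma_u
        assert ma.delta_energy(s, Move(add_pair=(21, 21)), p) == pytest.approx(
            expected, rel=1e-12)

    def test_invalid_removal_rejected(self, grid6):
        p = ma.genotype_params("correlational", "WT")
        s = ma.init_connectivity(grid6, "empty")
        with pytest.raises(ValueError):
            ma.delta_energy(s, Move(remove_pair=(0, 0)), p)

    def test_state_left_unchanged(self, grid6):
        p = ma.genotype_params("integrational", "WT")
        s = random_state(grid6, mean=2, seed=9)
        before = s.counts.copy()
        ma.delta_energy(s, Move(add_pair=(1, 2), remove_pair=(0, 0)), p) \
            if s.counts[0, 0] else \
            ma.delta_energy(s, Move(add_pair=(1, 2)), p)
        assert np.array_equal(before, s.counts)
        assert s.marginals_consistent()

    @pytest.mark.parametrize("kind,genotype", [
        (m, g) for m in ("correlational", "integrational")
        for g in ("WT", "Isl2EphA3", "Isl2EphA3_b2KO")])
    def test_matches_full_recompute(self, grid8, kind, genotype):
        p = ma.genotype_params(kind, genotype)
        s = random_state(grid8, mean=2, seed=17)
        rng = np.random.default_rng(23)
        n_checked = 0
        while n_checked < 60:
            mv = ma.propose_move(s, rng)
            d = ma.delta_energy(s, mv, p)
            e0 = ma.total_energy(s, p).E_total
            if mv.add_pair:
                s.add_contact(*mv.add_pair)
            if mv.remove_pair:
                s.remove_contact(*mv.remove_pair)
            e1 = ma.total_energy(s, p).E_total
            assert d == pytest.approx(e1 - e0, abs=1e-9)
            n_checked += 1


# ---------------------------------------------------------------------------
# Energy fields
# ---------------------------------------------------------------------------

class TestEnergyField:
    def test_wt_activity_minimum_at_source(self):
        grid = ma.build_grid(50)
        p = ma.genotype_params("correlational", "WT")
        f = ma.energy_field(p, (0.5, 0.5), "activity", grid)
        best = grid.sc_coords[np.argmin(f.values)]
        assert np.linalg.norm(best - [0.5, 0.5]) < grid.spacing

    def test_duplicated_map_has_two_minima(self):
        grid = ma.build_grid(50)
        p = ma.genotype_params("correlational", "Isl2EphA3")
        f = ma.energy_field(p, (0.5, 0.5), "activity", grid)
        m = f.as_matrix()
        row = m[25, :]  # elevation 0.51: adjacent to the source elevation
        minima = [i for i in range(1, 49) if row[i] < row[i-1] and row[i] < row[i+1]]
        xs = np.unique(grid.sc_coords[:, 0])[minima]
        assert len(xs) == 2
        assert np.allclose(sorted(xs), [0.25, 0.75], atol=grid.spacing)

    def test_chemoaffinity_field_graded_along_both_axes(self):
        grid = ma.build_grid(20)
        p = ma.genotype_params("correlational", "WT")
        f = ma.energy_field(p, (0.5, 0.5), "chemoaffinity", grid).as_matrix()
        assert (np.diff(f, axis=1) > 0).all()   # increases with SC azimuth
        assert (np.diff(f, axis=0) < 0).all()   # decreases with SC elevation

    def test_source_outside_unit_square_rejected(self):
        grid = ma.build_grid(10)
        p = ma.genotype_params("correlational", "WT")
        with pytest.raises(ValueError):
            ma.energy_field(p, (1.5, 0.5), "activity", grid)
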