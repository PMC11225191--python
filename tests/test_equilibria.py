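"""Closed-form equilibria, stability conditions and phase-map classification."""

import numpy as np
import pytest

from hgtgames import (
    EffectivePayoffs,
    FixedRates,
    classify_region,
    classify_symbiosis,
    coexistence_abundance,
    coexistence_conditions_oscillating,
    coexistence_fixed_gamma_window,
    effective_rates,
    equilibria,
    rhs_replicator,
    stability_boundary,
    synergy,
)
from hgtgames.equilibria import (
    NotApplicableError,
    UnboundedGrowthError,
    jacobian_counts,
)


def kinds(eqs):
    return {e.kind: e for e in eqs}


class TestEquilibria:
    def test_exclusion_geometry(self, base_rates):
        eqs = kinds(equilibria(base_rates))
        assert set(eqs) == {"trivial", "A_only", "B_only"}
        assert not eqs["trivial"].stable
        assert eqs["A_only"].N_star == pytest.approx(18.0) and eqs["A_only"].stable
        assert eqs["B_only"].N_star == pytest.approx(10.0) and not eqs["B_only"].stable

    def test_neutral_case_reported_as_degenerate_line(self):
        eqs = kinds(equilibria(FixedRates.symmetric(1.2, 1.2, 0.3)))
        assert "degenerate_line" in eqs
        assert eqs["degenerate_line"].N_star == pytest.approx(1.2 / 0.3)
        assert "interior" not in eqs

    def test_parallel_nullclines_give_no_interior_point(self, base_rates):
        # equal competition, unequal reproduction: denominator vanishes but
        # the nullclines do not coincide
        eqs = kinds(equilibria(base_rates))
        assert "interior" not in eqs and "degenerate_line" not in eqs

    def test_region_II_effective_rates_interior(self, base_rates):
        eff = effective_rates(base_rates, EffectivePayoffs(0.08, -0.08))
        eqs = kinds(equilibria(eff))
        interior = eqs["interior"]
        assert interior.stable
        assert interior.N_star == pytest.approx(0.224 / 0.0096)
        assert interior.p_A_star == pytest.approx(5.0 / 7.0)
        # both monocultures destabilised
        assert not eqs["A_only"].stable and not eqs["B_only"].stable
        # rest point: replicator RHS residual vanishes
        dp, dN = rhs_replicator(interior.p_A_star, interior.N_star, eff)
        assert abs(dp) < 1e-9 and abs(dN) < 1e-9

    def test_closed_forms_are_roots_and_verdicts_match_jacobian(self, rng):
        """Randomized cross-check: each equilibrium is a root of the dynamics
        and the stability verdict agrees with the dominant eigenvalue of a
        numerically differentiated count-space Jacobian."""
        for _ in range(200):
            rates = FixedRates(
                r_A=rng.uniform(0.2, 2.0),
                r_B=rng.uniform(0.2, 2.0),
                a_AA=rng.uniform(0.05, 0.6),
                a_AB=rng.uniform(0.05, 0.6),
                a_BA=rng.uniform(0.05, 0.6),
                a_BB=rng.uniform(0.05, 0.6),
                gamma=rng.uniform(-0.3, 0.3),
            )
            for eq in equilibria(rates):
                if eq.kind in ("trivial", "degenerate_line"):
                    continue
                dp, dN = rhs_replicator(eq.p_A_star, eq.N_star, rates)
                assert abs(dp) < 1e-9 and abs(dN) < 1e-9
                n_A = eq.p_A_star * eq.N_star
                n_B = eq.N_star - n_A
                # finite-difference Jacobian of the count-space field
                # (one-sided at the non-negativity boundary)
                from hgtgames import rhs_counts

                h = 1e-6 * max(1.0, eq.N_star)

                def column(dx, dy):
                    lo_A, lo_B = max(n_A - dx, 0.0), max(n_B - dy, 0.0)
                    hi = np.asarray(rhs_counts((n_A + dx, n_B + dy), rates))
                    lo = np.asarray(rhs_counts((lo_A, lo_B), rates))
                    return (hi - lo) / ((n_A + dx - lo_A) + (n_B + dy - lo_B))

                J = np.column_stack([column(h, 0.0), column(0.0, h)])
                assert np.allclose(J, jacobian_counts(n_A, n_B, rates), atol=1e-4)
                top = np.max(np.linalg.eigvals(J).real)
                if eq.stable is not None and abs(top) > 1e-6:
                    assert eq.stable == (top < 0)


class TestStabilityBoundary:
    def test_exclusion_parameters(self, base_rates):
        assert stability_boundary(base_rates) == (True, False)

    def test_bistable_configuration(self):
        # both monoculture conditions hold and the product condition exceeds 1
        rates = FixedRates(r_A=1.0, r_B=1.0, a_AA=0.1, a_AB=0.25, a_BA=0.25, a_BB=0.1)
        assert stability_boundary(rates) == (True, True)
        eqs = kinds(equilibria(rates))
        assert "interior" in eqs and not eqs["interior"].stable

    def test_gamma_driven_coexistence(self):
        # within the gamma window both monocultures destabilise
        lo, hi = coexistence_fixed_gamma_window(1.8, 1.0, 0.1)
        g = 0.5 * (lo + hi)
        rates = FixedRates.symmetric(1.8, 1.0, 0.1, gamma=g)
        assert stability_boundary(rates) == (False, False)
        eqs = kinds(equilibria(rates))
        assert eqs["interior"].stable


class TestGammaWindow:
    def test_symmetric_rates_empty_window(self):
        lo, hi = coexistence_fixed_gamma_window(1.0, 1.0, 0.1)
        assert lo == hi == 0.0

    def test_printed_parameterisation(self):
        lo, hi = coexistence_fixed_gamma_window(1.8, 1.0, 0.1)
        assert lo == pytest.approx(-0.08)
        assert hi == pytest.approx(0.1 * (1 / 1.8 - 1))
        assert hi < 0  # the slower reproducer must be the net beneficiary

    def test_balanced_transfer_is_outside_window(self):
        lo, hi = coexistence_fixed_gamma_window(1.8, 1.0, 0.1)
        assert not lo < 0.0 < hi  # gamma = 0 -> exclusion


class TestCoexistenceConditions:
    def test_region_II_point(self):
        exist, stab = coexistence_conditions_oscillating(1.8, 1.0, 0.1, 0.0, 0.08, -0.08)
        assert exist and stab

    def test_no_oscillation_no_coexistence(self):
        exist, _ = coexistence_conditions_oscillating(1.8, 1.0, 0.1, 0.0, 0.0, 0.0)
        assert not exist

    def test_na_region_existence_without_stability(self):
        # deep below the divergence curve: composition exists, abundance diverges
        xi, kappa = 0.3, -0.5
        assert 0.1 * (xi - kappa) + xi * kappa <= 0
        exist, stab = coexistence_conditions_oscillating(1.8, 1.0, 0.1, 0.0, xi, kappa)
        assert exist and not stab

    def test_unbalanced_transfer_uses_shifted_conditions(self):
        # gamma folds into both existence inequalities
        exist, _ = coexistence_conditions_oscillating(1.8, 1.0, 0.1, -0.06, 0.0, 0.0)
        assert exist  # gamma alone inside the fixed-environment window


class TestCoexistenceAbundance:
    def test_xi_zero_recovers_fixed_environment_abundance(self):
        N_c, p_A = coexistence_abundance(1.8, 1.0, 0.1, 0.0, -0.08)
        assert N_c == pytest.approx(18.0)
        # composition reduces to (a/|kappa|)(1 - r_B/r_A) on the xi = 0 line
        assert p_A == pytest.approx((0.1 / 0.08) * (1 - 1.0 / 1.8))

    def test_region_III_values(self):
        N_c, p_A = coexistence_abundance(1.8, 1.0, 0.1, 0.11, -0.11)
        assert N_c == pytest.approx(0.308 / 0.0099)
        assert p_A == pytest.approx(0.19 / 0.308)

    def test_region_I_below_fixed_abundance(self):
        N_c, _ = coexistence_abundance(1.8, 1.0, 0.1, -0.01, -0.08)
        assert N_c < 18.0

    def test_divergent_denominator_raises(self):
        with pytest.raises(UnboundedGrowthError):
            coexistence_abundance(1.8, 1.0, 0.1, 0.3, -0.5)

    def test_outside_coexistence_raises(self):
        with pytest.raises(NotApplicableError):
            coexistence_abundance(1.8, 1.0, 0.1, 0.05, 0.02)

    def test_monotone_increasing_in_xi(self):
        kappa = -0.08
        xis = np.linspace(-0.05, 0.3, 60)
        Ns = [coexistence_abundance(1.8, 1.0, 0.1, x, kappa)[0] for x in xis]
        assert np.all(np.diff(Ns) > 0)


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "xi,kappa,region,symb,syn",
        [
            (-0.01, -0.08, "I", "pure_competition", False),
            (0.08, -0.08, "II", "pure_competition", True),
            (0.11, -0.11, "III", "mutualism", True),
            (0.05, 0.02, "IV", "pure_competition", False),
            (-0.12, -0.08, "VI", "pure_competition", False),
        ],
    )
    def test_named_points(self, xi, kappa, region, symb, syn):
        rep = classify_region(1.8, 1.0, 0.1, xi, kappa)
        assert rep.region == region
        assert rep.symbiosis == symb
        assert rep.synergy is syn

    def test_fixed_environment_limit_reproduces_exclusion(self):
        # vanishing emergent payoffs: A wins, exactly as in the fixed environment
        assert classify_region(1.8, 1.0, 0.1, 0.0, 0.0).region == "IV"

    def test_bistable_region(self):
        rep = classify_region(1.8, 1.0, 0.1, -0.12, 0.02)
        assert rep.region == "V"
        assert rep.diagnostics["A_only_stable"] and rep.diagnostics["B_only_stable"]

    def test_na_region_subcodes(self):
        rep = classify_region(1.8, 1.0, 0.1, 0.3, -0.5)
        assert rep.region == "NA_unbounded"
        assert rep.na_subcode == "negative_abundance"

    def test_relabeling_when_B_reproduces_faster(self):
        # swapping populations maps (xi, kappa) -> (-kappa, -xi)
        direct = classify_region(1.8, 1.0, 0.1, 0.08, -0.08)
        swapped = classify_region(1.0, 1.8, 0.1, 0.08, -0.08)
        assert swapped.swapped and not direct.swapped
        assert swapped.region == direct.region
        assert swapped.N_c_star == pytest.approx(direct.N_c_star)

    def test_partition_is_exhaustive_and_exclusive(self):
        """Every grid point receives exactly one region label."""
        labels = {"I", "II", "III", "IV", "V", "VI", "NA_unbounded", "boundary"}
        count = 0
        for xi in np.linspace(-0.1, 0.3, 41):
            for kappa in np.linspace(-0.3, 0.1, 41):
                rep = classify_region(1.8, 1.0, 0.1, float(xi), float(kappa))
                assert rep.region in labels
                count += 1
        assert count == 41 * 41

    def test_exclusion_principle_random_draws(self, rng):
        """Balanced transfer + equal competition: no stable interior point."""
        for _ in range(1000):
            r_A, r_B = rng.uniform(0.3, 2.5, 2)
            if abs(r_A - r_B) < 1e-3:
                continue
            a = rng.uniform(0.02, 0.5)
            eqs = equilibria(FixedRates.symmetric(r_A, r_B, a))
            assert not any(e.kind == "interior" and e.stable for e in eqs)
            A_st, B_st = stability_boundary(FixedRates.symmetric(r_A, r_B, a))
            assert (A_st, B_st) == ((r_A > r_B), (r_B > r_A))


class TestSymbiosisAndSynergy:
    @pytest.mark.parametrize(
        "xi,kappa,label",
        [
            (0.08, -0.08, "pure_competition"),
            (0.11, -0.11, "mutualism"),
            (0.12, -0.08, "A_parasitizes_B"),
            (-0.01, -0.12, "B_parasitizes_A"),
            (0.1, -0.05, "boundary"),
        ],
    )
    def test_cross_derivative_signs(self, xi, kappa, label):
        assert classify_symbiosis(0.1, xi, kappa) == label

    def test_synergy_from_abundances(self):
        assert synergy(1.8, 1.0, 0.1, 0.08, -0.08)
        assert not synergy(1.8, 1.0, 0.1, -0.01, -0.08)
        assert not synergy(1.8, 1.0, 0.1, 0.0, -0.08)  # N_c* = N_f* exactly

    def test_synergy_outside_coexistence_raises(self):
        with pytest.raises(NotApplicableError):
            synergy(1.8, 1.0, 0.1, 0.05, 0.02)
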