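"""Exact competition equilibrium: solver, signal model, and fitting."""

import io
import math

import numpy as np
import pytest

from hydromap import (
    BindingParameters,
    TitrationCurve,
    TitrationPoint,
    fit_titration,
    fit_titrations_global,
    predicted_anisotropy,
    read_titration_tsv,
    solve_equilibrium,
    write_titration_tsv,
)
from hydromap.synth import default_titration_design, simulate_titration


def bisect_bracket(ptot, dtot, ctot, kp, kc, tol=1e-15):
    """Independent bisection oracle for the free-protein root of
    g(p) = p (1 + D/(Kp+p) + C/(Kc+p)) - P on [0, P].

    Returns the final (lo, hi) bracket of width <= tol; the unique root is
    guaranteed inside it because g is strictly increasing."""

    def g(p):
        return p * (1.0 + dtot / (kp + p) + ctot / (kc + p)) - ptot

    lo, hi = 0.0, ptot
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
    return lo, hi


def bisect_free_protein(ptot, dtot, ctot, kp, kc, tol=1e-15):
    lo, hi = bisect_bracket(ptot, dtot, ctot, kp, kc, tol)
    return 0.5 * (lo + hi)


def species_from_free_protein(p, dtot, ctot, kp, kc):
    """All five species implied by a free-protein value (each monotone in p)."""
    pd = p * dtot / (kp + p)
    pc = p * ctot / (kc + p)
    return np.array([p, dtot - pd, ctot - pc, pd, pc])


def assert_species_match_oracle(st, ptot, dtot, ctot, kp, kc, rel=1e-6):
    """Solver species must lie within the oracle bracket's species interval,
    widened by the stated relative tolerance."""
    lo, hi = bisect_bracket(ptot, dtot, ctot, kp, kc)
    s_lo = species_from_free_protein(lo, dtot, ctot, kp, kc)
    s_hi = species_from_free_protein(hi, dtot, ctot, kp, kc)
    lower = np.minimum(s_lo, s_hi)
    upper = np.maximum(s_lo, s_hi)
    got = np.array(
        [
            st.free_protein,
            st.free_probe,
            st.free_competitor,
            st.protein_probe,
            st.protein_competitor,
        ]
    )
    pad = rel * np.maximum(np.abs(lower), np.abs(upper))
    assert np.all(got >= lower - pad), (got, lower, upper)
    assert np.all(got <= upper + pad), (got, lower, upper)


class TestSolveEquilibrium:
    def test_trace_probe_no_competitor_half_saturation(self):
        """At protein_total = K_probe and trace probe, half the probe is bound."""
        st = solve_equilibrium(1e-9, 1e-15, 0.0, 1e-9, 1e-9)
        assert st.fraction_bound(1e-15) == pytest.approx(0.5, rel=1e-5)
        assert st.free_protein == pytest.approx(1e-9, rel=1e-5)

    def test_infinitely_weak_competitor_is_absent(self):
        args = dict(protein_total=5e-9, probe_total=1e-9, K_probe=1e-9)
        a = solve_equilibrium(competitor_total=0.0, K_comp=1e-9, **args)
        b = solve_equilibrium(competitor_total=5e-9, K_comp=1e6, **args)
        assert b.fraction_bound(1e-9) == pytest.approx(
            a.fraction_bound(1e-9), rel=1e-6
        )

    def test_matches_bisection_oracle_worked_case(self):
        """All five species agree with the 1e-15 M bisection oracle."""
        ptot, dtot, ctot, kp, kc = 10e-9, 2e-9, 5e-9, 1e-9, 2e-9
        p = bisect_free_protein(ptot, dtot, ctot, kp, kc)
        st = solve_equilibrium(ptot, dtot, ctot, kp, kc)
        assert st.free_protein == pytest.approx(p, rel=1e-6)
        assert st.protein_probe == pytest.approx(p * dtot / (kp + p), rel=1e-6)
        assert st.protein_competitor == pytest.approx(p * ctot / (kc + p), rel=1e-6)
        assert st.free_probe == pytest.approx(dtot - p * dtot / (kp + p), rel=1e-6)
        assert st.free_competitor == pytest.approx(
            ctot - p * ctot / (kc + p), rel=1e-6
        )

    def test_oracle_agreement_random_draws(self, rng):
        """Solver matches bisection on 100 random parameter draws; mass
        balance and both binding laws hold at the stated tolerances."""
        for _ in range(100):
            ptot = 10.0 ** rng.uniform(-10, -7)
            dtot = 10.0 ** rng.uniform(-10, -8)
            ctot = 10.0 ** rng.uniform(-11, -6)
            kp = 10.0 ** rng.uniform(-10, -8)
            kc = 10.0 ** rng.uniform(-11, -7)
            st = solve_equilibrium(ptot, dtot, ctot, kp, kc)
            assert_species_match_oracle(st, ptot, dtot, ctot, kp, kc, rel=1e-6)
            # mass balances to 1e-9 relative
            assert (
                st.free_protein + st.protein_probe + st.protein_competitor
            ) == pytest.approx(ptot, rel=1e-9)
            assert st.free_probe + st.protein_probe == pytest.approx(dtot, rel=1e-9)
            assert st.free_competitor + st.protein_competitor == pytest.approx(
                ctot, rel=1e-9
            )
            # mass action to 1e-6 relative
            assert st.free_protein * st.free_probe == pytest.approx(
                kp * st.protein_probe, rel=1e-6
            )
            assert st.free_protein * st.free_competitor == pytest.approx(
                kc * st.protein_competitor, rel=1e-6
            )

    def test_root_bracketing_signs(self):
        """g(0) < 0 <= g(P_t): the physical root is bracketed and unique."""
        ptot, dtot, ctot, kp, kc = 5e-9, 1e-9, 3e-9, 1e-9, 0.5e-9

        def g(p):
            return p * (1 + dtot / (kp + p) + ctot / (kc + p)) - ptot

        assert g(0.0) < 0
        assert g(ptot) >= 0

    def test_fraction_bound_monotone_in_competitor(self):
        fbs = [
            solve_equilibrium(5e-9, 1e-9, ct, 1e-9, 0.5e-9).fraction_bound(1e-9)
            for ct in np.logspace(-12, -6, 25)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(fbs, fbs[1:]))

    def test_probe_competitor_role_swap_symmetry(self):
        """Swapping probe/competitor identities (with their K values) leaves
        the free protein unchanged."""
        a = solve_equilibrium(8e-9, 2e-9, 5e-9, 1e-9, 3e-9)
        b = solve_equilibrium(8e-9, 5e-9, 2e-9, 3e-9, 1e-9)
        assert a.free_protein == pytest.approx(b.free_protein, rel=1e-9)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(protein_total=-1e-9),
            dict(probe_total=float("nan")),
            dict(competitor_total=-1.0),
            dict(K_probe=0.0),
            dict(K_comp=-2e-9),
            dict(K_probe=float("inf")),
        ],
    )
    def test_domain_errors(self, bad):
        kwargs = dict(
            protein_total=1e-9,
            probe_total=1e-9,
            competitor_total=1e-9,
            K_probe=1e-9,
            K_comp=1e-9,
        )
        kwargs.update(bad)
        with pytest.raises(ValueError):
            solve_equilibrium(**kwargs)


class TestPredictedAnisotropy:
    @pytest.mark.parametrize(
        "fb, expected", [(0.0, 0.10), (1.0, 0.30), (0.5, 0.20)]
    )
    def test_limits_and_midpoint(self, fb, expected):
        dtot = 1e-9
        st = solve_equilibrium(0.0, dtot, 0.0, 1e-9, 1e-9)  # all free
        # construct a state with the requested bound fraction directly
        from hydromap.equilibria import EquilibriumState

        st = EquilibriumState(0.0, dtot * (1 - fb), 0.0, dtot * fb, 0.0)
        assert predicted_anisotropy(st, dtot, 0.10, 0.30) == pytest.approx(expected)

    def test_zero_probe_total_rejected(self):
        from hydromap.equilibria import EquilibriumState

        st = EquilibriumState(0.0, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            predicted_anisotropy(st, 0.0, 0.1, 0.3)


class TestFitTitration:
    def test_self_consistency_on_exact_data(self, wt_truth):
        """Noise-free data regenerates the generating parameters."""
        design = default_titration_design(wt_truth.K_comp, noise_sd=0.0)
        curve = simulate_titration(design, wt_truth)
        fit = fit_titration(curve, fixed={"K_probe": wt_truth.K_probe})
        assert fit.converged and fit.identifiable
        assert fit.residual_sum_squares < 1e-12
        assert fit.estimates.K_comp == pytest.approx(wt_truth.K_comp, rel=1e-4)
        assert fit.estimates.r0 == pytest.approx(wt_truth.r0, rel=1e-4)
        assert fit.estimates.r1 == pytest.approx(wt_truth.r1, rel=1e-4)

    def test_noisy_recovery_wt_affinity(self, wt_truth):
        """sigma = 0.002 noise on 12 points recovers log10 K within 0.15."""
        design = default_titration_design(wt_truth.K_comp, seed=42, noise_sd=0.002)
        curve = simulate_titration(design, wt_truth)
        fit = fit_titration(curve, fixed={"K_probe": wt_truth.K_probe})
        assert fit.converged
        assert abs(math.log10(fit.estimates.K_comp / wt_truth.K_comp)) < 0.15
        assert fit.standard_errors["K_comp"] > 0

    def test_bootstrap_errors_comparable_to_jacobian(self, wt_truth):
        """Residual-resampling bootstrap SEs land in the same decade as the
        Jacobian-based ones and are seed-reproducible."""
        design = default_titration_design(wt_truth.K_comp, seed=13, noise_sd=0.002)
        curve = simulate_titration(design, wt_truth)
        fixed = {"K_probe": wt_truth.K_probe}
        jac = fit_titration(curve, fixed=fixed)
        boot1 = fit_titration(curve, fixed=fixed, bootstrap=25, bootstrap_seed=5)
        boot2 = fit_titration(curve, fixed=fixed, bootstrap=25, bootstrap_seed=5)
        assert boot1.standard_errors == boot2.standard_errors
        ratio = boot1.standard_errors["K_comp"] / jac.standard_errors["K_comp"]
        assert 0.2 < ratio < 5.0

    def test_flat_curve_flagged_unidentifiable(self):
        points = tuple(
            TitrationPoint(competitor_total=c, anisotropy=0.18)
            for c in np.logspace(-11, -7, 8)
        )
        curve = TitrationCurve(
            points=points, probe_total=1e-9, protein_total=5e-9, osmolality=0.3
        )
        fit = fit_titration(curve)
        assert not fit.identifiable
        assert not fit.converged

    def test_global_fit_shares_probe_affinity(self, wt_truth):
        designs = [
            default_titration_design(k, seed=i, noise_sd=0.0)
            for i, k in enumerate([0.34e-9, 2e-9])
        ]
        curves = [simulate_titration(d, BindingParameters(
            K_probe=wt_truth.K_probe, K_comp=d.competitor_concentrations[5],
            r0=wt_truth.r0, r1=wt_truth.r1)) for d in designs]
        results = fit_titrations_global(curves, K_probe_initial=2e-9)
        kps = {round(math.log10(r.estimates.K_probe), 6) for r in results}
        assert len(kps) == 1  # one shared probe affinity

    def test_validation_errors(self, wt_truth):
        design = default_titration_design(1e-9, noise_sd=0.0)
        curve = simulate_titration(design, wt_truth)
        with pytest.raises(ValueError):
            fit_titration(curve, fixed={"bogus": 1.0})
        with pytest.raises(ValueError):
            fit_titration(
                curve, fixed={p: 1e-9 for p in ("K_probe", "K_comp")} | {"r0": 0.1, "r1": 0.2}
            )


class TestRecoveryProperty:
    def test_median_log_error_across_affinity_range(self, wt_truth):
        """Over 50 seeded curves spanning K_comp 0.1-100 nM at sigma=0.002,
        median |log10(Khat/K)| < 0.1."""
        rng = np.random.default_rng(7)
        errors = []
        for i in range(50):
            k_true = 10.0 ** rng.uniform(-10, -7)
            truth = BindingParameters(
                K_probe=wt_truth.K_probe, K_comp=k_true,
                r0=wt_truth.r0, r1=wt_truth.r1,
            )
            design = default_titration_design(k_true, seed=1000 + i, noise_sd=0.002)
            fit = fit_titration(
                simulate_titration(design, truth), fixed={"K_probe": truth.K_probe}
            )
            errors.append(abs(math.log10(fit.estimates.K_comp / k_true)))
        assert np.median(errors) < 0.1


class TestTitrationIO:
    def test_tsv_round_trip(self, tmp_path, wt_truth):
        design = default_titration_design(0.5e-9, seed=5)
        curve = simulate_titration(design, wt_truth)
        path = tmp_path / "curve.tsv"
        write_titration_tsv(curve, path)
        back = read_titration_tsv(path)
        assert back.probe_total == pytest.approx(curve.probe_total, rel=1e-9)
        assert back.protein_total == pytest.approx(curve.protein_total, rel=1e-9)
        assert back.osmolality == curve.osmolality
        np.testing.assert_allclose(
            back.competitor_totals, curve.competitor_totals, rtol=1e-9
        )
        np.testing.assert_allclose(back.anisotropies, curve.anisotropies, atol=1e-7)

    def test_nanomolar_units_normalized(self):
        text = (
            "# probe_total=1\n# protein_total=5\n# osmolality=0.3\n# units=nM\n"
            "competitor_total\tanisotropy\n"
            + "\n".join(f"{c}\t0.2" for c in [1, 2, 4, 8, 16, 32])
        )
        curve = read_titration_tsv(io.StringIO(text))
        assert curve.probe_total == pytest.approx(1e-9)
        assert curve.points[-1].competitor_total == pytest.approx(32e-9)

    def test_missing_metadata_rejected(self):
        text = "competitor_total\tanisotropy\n" + "\n".join(
            f"{c}\t0.2" for c in range(6)
        )
        with pytest.raises(ValueError, match="probe_total"):
            read_titration_tsv(io.StringIO(text))


class TestCurveValidation:
    def test_too_few_points(self):
        pts = tuple(TitrationPoint(c * 1e-9, 0.2) for c in range(5))
        with pytest.raises(ValueError, match="6 points"):
            TitrationCurve(points=pts, probe_total=1e-9, protein_total=1e-9, osmolality=0.3)

    def test_decreasing_doses_rejected(self):
        pts = tuple(TitrationPoint(c * 1e-9, 0.2) for c in [1, 2, 3, 2, 5, 6])
        with pytest.raises(ValueError, match="non-decreasing"):
            TitrationCurve(points=pts, probe_total=1e-9, protein_total=1e-9, osmolality=0.3)

    def test_unphysical_anisotropy_bounds(self):
        with pytest.raises(ValueError):
            BindingParameters(K_probe=1e-9, K_comp=1e-9, r0=0.1, r1=0.45)
        with pytest.raises(ValueError):
            BindingParameters(K_probe=1e-9, K_comp=1e-9, r0=0.2, r1=0.2)
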