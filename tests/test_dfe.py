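import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.stats import binom

from pollenselect import dfe
from pollenselect.diversity import SFSPair, fold_sfs
from pollenselect.synthetic_data import simulate_sfs_pair


class TestSelectedWeights:
    def test_neutral_limit_is_one_over_i(self):
        n = 40
        w = dfe.selected_weights(0.0, n)
        assert np.allclose(w, 1.0 / np.arange(1, n), rtol=1e-12)

    @pytest.mark.parametrize("S", [0.5, 5.0, 50.0, 500.0])
    def test_quadrature_against_adaptive_integration(self, S):
        """Independent oracle: scipy adaptive quadrature of the sampling
        integrand per frequency class."""
        n = 20
        w = dfe.selected_weights(S, n)
        for i in (1, 2, 10, 19):
            f = lambda x: (
                binom.pmf(i, n, x)
                * np.exp(-S * x) * np.expm1(-S * (1 - x)) / np.expm1(-S)
                / (x * (1 - x))
            )
            ref, _ = integrate.quad(f, 0, 1, limit=200)
            assert w[i - 1] == pytest.approx(ref, rel=1e-5)

    def test_weights_decrease_with_selection(self):
        n = 40
        w_weak = dfe.selected_weights(1.0, n)
        w_strong = dfe.selected_weights(100.0, n)
        assert np.all(w_strong < w_weak)


class TestExpectedSFS:
    def test_neutral_spectrum_proportional_to_synonymous(self):
        n = 20
        e_n = dfe.expected_sfs(0.3, 0.0, theta=0.01, r=None, n=n, L=1000, fold=False)
        e_s = dfe.expected_sfs(0.3, 0.0, theta=0.01, r=None, n=n, L=250, fold=False)
        assert np.allclose(e_n / e_s, 4.0)

    def test_neutral_class_weight_is_theta_L_over_i(self):
        n = 12
        e = dfe.expected_sfs(1.0, 0.0, theta=0.02, r=None, n=n, L=500, fold=False)
        assert np.allclose(e, 0.02 * 500 / np.arange(1, n))

    def test_matches_generator_sampling_at_n20(self, rng):
        """Monte-Carlo totals from the generator agree with the expectation
        within 3 SE per frequency class."""
        n, L_n, L_s, theta = 20, 5e4, 5e4, 0.01
        shape, mean_S = 0.5, 50.0
        reps = 40
        tot = np.zeros(n // 2)
        for _ in range(reps):
            pair = simulate_sfs_pair(shape, mean_S, theta, n, L_n, L_s, rng)
            tot += pair.sfs_n
        expected = dfe.expected_sfs(shape, mean_S, theta, None, n, L_n, fold=True)
        se = np.sqrt(expected / reps)
        assert np.all(np.abs(tot / reps - expected) < 3.5 * se)

    def test_continuity_in_parameters(self):
        n = 30
        base = dfe.gamma_weights(0.3, 100.0, n).sum()
        near = dfe.gamma_weights(0.3001, 100.1, n).sum()
        assert near == pytest.approx(base, rel=1e-2)
        assert np.isfinite(base)


class TestFitGammaDFE:
    def test_parameter_recovery(self, rng):
        b, ms, theta, Ln, Ls, n = 0.3, 400.0, 0.01, 2e6, 5e5, 80
        errs = []
        for _ in range(3):
            pair = simulate_sfs_pair(b, ms, theta, n, Ln, Ls, rng)
            fit = dfe.fit_gamma_dfe(pair)
            errs.append(abs(fit.shape - b))
        assert np.median(errs) < 0.05

    def test_neutral_data_puts_mass_below_nes_one(self):
        n = 40
        v = fold_sfs(1.0 / np.arange(1, n), n)
        pair = SFSPair(
            n=n, folded=True,
            sfs_n=np.round(4000 * v), sfs_s=np.round(1000 * v),
            L_n=4e5, L_s=1e5,
        )
        fit = dfe.fit_gamma_dfe(pair)
        below_one = dfe.discretize(fit, (0.0, 1.0, math.inf))[0]
        assert below_one >= 0.95

    def test_fix_r_consistent_on_equilibrium_data(self, rng):
        b, ms, theta, Ln, Ls, n = 0.4, 100.0, 0.01, 1e6, 2.5e5, 60
        pair = simulate_sfs_pair(b, ms, theta, n, Ln, Ls, rng)
        free = dfe.fit_gamma_dfe(pair)
        fixed = dfe.fit_gamma_dfe(pair, fix_r=True)
        assert fixed.shape == pytest.approx(free.shape, abs=0.05)
        assert np.all(fixed.r == 1.0)

    def test_r_first_class_is_one(self, rng):
        pair = simulate_sfs_pair(0.3, 100.0, 0.01, 40, 1e5, 5e4, rng)
        fit = dfe.fit_gamma_dfe(pair)
        assert fit.r[0] == 1.0

    def test_likelihood_peak_near_generating_parameters(self, rng):
        """On large data the generating parameters beat ±50% perturbations."""
        b, ms, theta, n = 0.3, 200.0, 0.02, 60
        pair = simulate_sfs_pair(b, ms, theta, n, 5e6, 1.5e6, rng)
        data = dfe._prepare_data(pair, True)
        at = lambda bb, mm: -dfe._profile(np.log([bb, mm]), data)
        ll0 = at(b, ms)
        for bb, mm in ((b * 1.5, ms), (b * 0.5, ms), (b, ms * 1.5), (b, ms * 0.5)):
            assert ll0 > at(bb, mm)

    def test_folding_then_fitting_equals_folded_fit(self, rng):
        n = 30
        un = simulate_sfs_pair(0.3, 50.0, 0.01, n, 2e5, 5e4, rng, fold=False)
        folded = SFSPair(
            n=n, folded=True,
            sfs_n=fold_sfs(un.sfs_n, n), sfs_s=fold_sfs(un.sfs_s, n),
            L_n=un.L_n, L_s=un.L_s,
        )
        f1 = dfe.fit_gamma_dfe(un, fold=True)
        f2 = dfe.fit_gamma_dfe(folded, fold=True)
        assert f1.shape == pytest.approx(f2.shape, rel=1e-9)
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, rel=1e-12)


class TestDiscretize:
    def _fit(self, shape, mean_nes):
        return dfe.DFEFit(
            shape=shape, mean_S=mean_nes * dfe.S_PER_NES, theta_hat=0.01,
            r=np.ones(1), log_likelihood=0.0, n=20, folded=True,
        )

    def test_exponential_closed_form(self):
        props = dfe.discretize(self._fit(1.0, 10.0), (0.0, 2.0, 10.0, math.inf))
        expected = (1 - math.exp(-0.2), math.exp(-0.2) - math.exp(-1), math.exp(-1))
        assert props == pytest.approx(expected, rel=1e-9)

    def test_near_point_mass(self):
        props = dfe.discretize(self._fit(500.0, 5.0), (0.0, 2.0, 10.0, math.inf))
        assert props[1] > 0.999

    def test_quadrature_oracle(self):
        shape, mean_nes = 0.3, 25.0
        edges = (0.0, 2.0, 10.0, 100.0, math.inf)
        props = dfe.discretize(self._fit(shape, mean_nes), edges)
        pdf = stats.gamma(shape, scale=mean_nes / shape).pdf
        for k in range(len(edges) - 1):
            hi = edges[k + 1] if math.isfinite(edges[k + 1]) else np.inf
            ref, _ = integrate.quad(pdf, edges[k], hi)
            assert props[k] == pytest.approx(ref, abs=1e-6)
        assert props.sum() == pytest.approx(1.0)


class TestAlpha:
    def test_neutral_equal_rates_gives_zero(self):
        fit = dfe.DFEFit(
            shape=1.0, mean_S=0.0, theta_hat=0.01, r=np.ones(1),
            log_likelihood=0.0, n=20, folded=True,
        )
        pair = SFSPair(
            n=20, folded=True, sfs_n=np.zeros(10), sfs_s=np.zeros(10),
            L_n=1000, L_s=250, D_n=100, D_s=25,
        )
        assert dfe.estimate_alpha(fit, pair) == pytest.approx(0.0)

    def test_strong_selection_pushes_alpha_to_one(self):
        fit = dfe.DFEFit(
            shape=5.0, mean_S=1e5, theta_hat=0.01, r=np.ones(1),
            log_likelihood=0.0, n=20, folded=True,
        )
        pair = SFSPair(
            n=20, folded=True, sfs_n=np.zeros(10), sfs_s=np.zeros(10),
            L_n=1000, L_s=250, D_n=50, D_s=25,
        )
        assert dfe.estimate_alpha(fit, pair) > 0.99

    def test_no_nonsynonymous_divergence_flagged(self):
        fit = dfe.DFEFit(
            shape=1.0, mean_S=10.0, theta_hat=0.01, r=np.ones(1),
            log_likelihood=0.0, n=20, folded=True,
        )
        pair = SFSPair(
            n=20, folded=True, sfs_n=np.zeros(10), sfs_s=np.zeros(10),
            L_n=1000, L_s=250, D_n=0, D_s=25,
        )
        with pytest.raises(ValueError, match="alpha undefined"):
            dfe.estimate_alpha(fit, pair)

    def test_alpha_recovery_with_known_adaptive_fraction(self, rng):
        b, ms, theta, n = 0.3, 200.0, 0.01, 80
        pair = simulate_sfs_pair(
            b, ms, theta, n, 2e6, 5e5, rng, div_ds=0.15, adaptive_fraction=0.3
        )
        fit = dfe.fit_gamma_dfe(pair)
        alpha = dfe.estimate_alpha(fit, pair)
        assert alpha == pytest.approx(0.3, abs=0.05)


class TestBootstrap:
    def _genes(self, rng, G=40, n=40):
        return [
            simulate_sfs_pair(0.3, 100.0, 0.01, n, 2e4, 5e3, rng) for _ in range(G)
        ]

    def test_seed_reproducibility(self, rng):
        genes = self._genes(rng)
        r1 = dfe.bootstrap(genes, B=10, seed=7)
        r2 = dfe.bootstrap(genes, B=10, seed=7)
        assert r1.intervals == r2.intervals

    def test_identity_resample_degenerate_interval(self, rng):
        genes = self._genes(rng)
        res = dfe.bootstrap(genes, B=1, seed=0, resample=False)
        lo, hi = res.intervals["shape"]
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(res.point.shape, rel=1e-6)
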