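"""Mechanistic nascent-fluorescence model: samplers, detection rule, Gamma likelihood."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from burstfish.nascent import (
    GeneModel,
    InfeasibleParameterError,
    PolymeraseConfiguration,
    _simulate_batch,
    exon_fluorescence,
    gamma_intensity_loglik,
    intron_signal_present,
    mean_active_ts_intensity,
    sample_gamma_intensity,
    sample_polymerase_positions,
    sample_promoter_trajectory,
)
from burstfish.telegraph import TelegraphParams

ALWAYS_ON = TelegraphParams(lam=1e6, gam=1e-6, mu=200.0, delta=1.0, beta=1.0)


class TestGeneModel:
    def test_valid_model_window(self, gene_two_introns):
        assert gene_two_introns.window_s == pytest.approx(40.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(exon_probe_positions=()),  # no exon probes
            dict(intron_probe_positions=()),  # no intron probes
            dict(intron_probe_positions=(100,)),  # probe outside any intron
            dict(intron_intervals=((500, 600), (550, 700)), intron_probe_positions=(560,)),
            dict(exon_probe_positions=(2500,)),  # beyond gene end
        ],
    )
    def test_invariant_violations(self, kwargs):
        base = dict(
            length_bp=2000,
            exon_probe_positions=(50, 900),
            intron_probe_positions=(520,),
            intron_intervals=((500, 600),),
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            GeneModel(**base)

    def test_config_round_trip(self, gene_two_introns):
        assert GeneModel.from_config(gene_two_introns.to_config()) == gene_two_introns


class TestTrajectory:
    def test_same_seed_identical(self, params_std):
        t1 = sample_promoter_trajectory(params_std, 100.0, np.random.default_rng(5))
        t2 = sample_promoter_trajectory(params_std, 100.0, np.random.default_rng(5))
        assert t1 == t2

    def test_stationary_on_fraction(self, rng):
        params = TelegraphParams(2.0, 1.0, 1.0, 1.0, 1.0)
        n, window = 4000, 1800.0
        fracs = [
            sample_promoter_trajectory(params, window, rng).on_time() / window
            for _ in range(n)
        ]
        se = np.std(fracs, ddof=1) / math.sqrt(n)
        assert abs(np.mean(fracs) - 2.0 / 3.0) < 3 * se

    def test_always_on_limit_single_segment(self, rng):
        traj = sample_promoter_trajectory(ALWAYS_ON, 100.0, rng)
        assert len(traj.segments) == 1 and traj.segments[0][0] == "ON"

    def test_invalid_window(self, params_std, rng):
        with pytest.raises(ValueError):
            sample_promoter_trajectory(params_std, 0.0, rng)


class TestPolymerasePositions:
    def test_always_on_count_is_poisson(self, gene_single_intron, rng):
        # Little's law: mean occupancy = initiation rate x traversal time
        n = 10_000
        mu = 300.0
        expected = (mu / 3600.0) * gene_single_intron.window_s
        counts = []
        for _ in range(n):
            traj = sample_promoter_trajectory(ALWAYS_ON, gene_single_intron.window_s, rng)
            cfg = sample_polymerase_positions(traj, mu, gene_single_intron, rng)
            counts.append(len(cfg.positions_bp))
        se = math.sqrt(expected / n)  # Poisson variance = mean
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_mu_zero_limit(self, gene_single_intron, rng):
        traj = sample_promoter_trajectory(ALWAYS_ON, gene_single_intron.window_s, rng)
        cfg = sample_polymerase_positions(traj, 1e-9, gene_single_intron, rng)
        assert cfg.positions_bp == ()

    def test_positions_in_range(self, gene_single_intron, rng):
        traj = sample_promoter_trajectory(ALWAYS_ON, gene_single_intron.window_s, rng)
        cfg = sample_polymerase_positions(traj, 2000.0, gene_single_intron, rng)
        pos = np.array(cfg.positions_bp)
        assert np.all((pos > 0) & (pos <= gene_single_intron.length_bp))

    def test_window_too_short(self, params_std, gene_single_intron, rng):
        traj = sample_promoter_trajectory(params_std, 1.0, rng)
        with pytest.raises(ValueError):
            sample_polymerase_positions(traj, 100.0, gene_single_intron, rng)


class TestIntronSignal:
    @pytest.mark.parametrize(
        "pos,expected",
        [(550.0, True), (510.0, False), (650.0, False)],
    )
    def test_single_polymerase(self, gene_two_introns, pos, expected):
        # intron [500, 600) carries its probe at 520: signal requires the
        # polymerase inside the intron at or past the probe target
        cfg = PolymeraseConfiguration(positions_bp=(pos,))
        assert intron_signal_present(cfg, gene_two_introns) is expected

    def test_probe_downstream_of_polymerase(self):
        gene = GeneModel(
            length_bp=1000,
            exon_probe_positions=(50,),
            intron_probe_positions=(580,),
            intron_intervals=((500, 600),),
        )
        assert not intron_signal_present(PolymeraseConfiguration((550.0,)), gene)

    def test_empty_configuration(self, gene_two_introns):
        assert not intron_signal_present(PolymeraseConfiguration(()), gene_two_introns)


class TestExonFluorescence:
    def test_partial_transcript(self):
        gene = GeneModel(
            length_bp=1000,
            exon_probe_positions=(100, 200, 300, 400),
            intron_probe_positions=(520,),
            intron_intervals=((500, 600),),
        )
        assert exon_fluorescence(PolymeraseConfiguration((250.0,)), gene) == pytest.approx(0.5)
        assert exon_fluorescence(PolymeraseConfiguration((1000.0,)), gene) == pytest.approx(1.0)
        assert exon_fluorescence(PolymeraseConfiguration(()), gene) == 0.0

    def test_additive_and_monotone(self, gene_two_introns):
        z1 = exon_fluorescence(PolymeraseConfiguration((500.0,)), gene_two_introns)
        z2 = exon_fluorescence(PolymeraseConfiguration((1500.0,)), gene_two_introns)
        both = exon_fluorescence(PolymeraseConfiguration((500.0, 1500.0)), gene_two_introns)
        assert both == pytest.approx(z1 + z2)
        assert z2 >= z1


class TestMeanActiveTSIntensity:
    def test_single_intron_closed_form(self, gene_single_intron):
        # single whole-gene intron probed at 0: acceptance = 1 - exp(-mu L / v)
        # and the accepted-sample mean has a Poisson closed form
        mu = 200.0
        est = mean_active_ts_intensity(
            TelegraphParams(1e6, 1e-6, mu, 1.0, 1.0),
            gene_single_intron,
            n_samples=10_000,
            rng=np.random.default_rng(42),
        )
        L, v, P = 1000.0, 50.0, 4
        xs = np.array(gene_single_intron.exon_probe_positions)
        mu_s = mu / 3600.0
        p_acc = 1 - math.exp(-mu_s * L / v)
        cond_mean = (mu_s / v) * np.sum(L - xs) / P / p_acc
        # 3 SE of the conditional mean, conservatively using the sample itself
        se = cond_mean / math.sqrt(est.n_accepted)
        assert abs(est.mean_intensity - cond_mean) < 3 * se
        assert abs(est.acceptance_rate - p_acc) < 0.02

    def test_same_seed_identical(self, params_std, gene_single_intron):
        a = mean_active_ts_intensity(params_std, gene_single_intron, n_samples=500,
                                     rng=np.random.default_rng(3))
        b = mean_active_ts_intensity(params_std, gene_single_intron, n_samples=500,
                                     rng=np.random.default_rng(3))
        assert a == b

    def test_monotone_in_mu(self, gene_single_intron):
        means = []
        for mu in (50.0, 200.0, 800.0):
            params = TelegraphParams(1.0, 1.0, mu, 1.0, 1.0)
            est = mean_active_ts_intensity(
                params, gene_single_intron, n_samples=4000, rng=np.random.default_rng(9)
            )
            means.append(est.mean_intensity)
        assert means[0] < means[1] < means[2]

    def test_acceptance_increasing_in_active_fraction(self, gene_single_intron):
        rates = []
        for lam in (0.2, 1.0, 5.0):
            params = TelegraphParams(lam, 1.0, 100.0, 1.0, 1.0)
            est = mean_active_ts_intensity(
                params, gene_single_intron, n_samples=3000, rng=np.random.default_rng(4)
            )
            rates.append(est.acceptance_rate)
        assert rates[0] < rates[1] < rates[2]

    def test_infeasible_parameters(self, gene_single_intron):
        params = TelegraphParams(1.0, 1.0, 1e-7, 1.0, 1.0)
        with pytest.raises(InfeasibleParameterError):
            mean_active_ts_intensity(
                params,
                gene_single_intron,
                n_samples=100,
                rng=np.random.default_rng(0),
                max_proposals=50_000,
            )

    def test_batch_matches_object_api_statistics(self, gene_single_intron):
        # the vectorized batch path and the explicit per-sample path describe
        # the same process: compare unconditional mean fluorescence
        mu = 300.0
        params = TelegraphParams(1e6, 1e-6, mu, 1.0, 1.0)
        rng = np.random.default_rng(11)
        z_batch, _ = _simulate_batch(params, gene_single_intron, 20_000, rng)
        zs = []
        for _ in range(3000):
            traj = sample_promoter_trajectory(params, gene_single_intron.window_s, rng)
            cfg = sample_polymerase_positions(traj, mu, gene_single_intron, rng)
            zs.append(exon_fluorescence(cfg, gene_single_intron))
        se = np.std(zs, ddof=1) / math.sqrt(len(zs))
        assert abs(z_batch.mean() - np.mean(zs)) < 4 * se


class TestGammaIntensity:
    def test_exponential_special_case(self):
        # nu=2, beta=4 -> shape 1, scale 2: density at z=2 is e^-1/2
        assert gamma_intensity_loglik(2.0, 2.0, 4.0) == pytest.approx(
            math.log(0.5 * math.exp(-1.0)), abs=1e-12
        )

    def test_density_normalizes(self):
        nu, beta = 0.7, 0.15
        val, _ = integrate.quad(
            lambda z: math.exp(gamma_intensity_loglik(z, nu, beta)), 0, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_moment_matching(self, rng):
        nu, beta, n = 1.3, 0.4, 100_000
        draws = sample_gamma_intensity(nu, beta, n, rng)
        assert abs(draws.mean() - nu) < 3 * math.sqrt(beta / n)
        # SE of the sample variance of a Gamma via its fourth moment
        shape = nu**2 / beta
        kurt_excess = 6.0 / shape
        se_var = beta * math.sqrt((kurt_excess + 2.0) / n)
        assert abs(draws.var(ddof=1) - beta) < 3 * se_var

    def test_matches_scipy_density(self):
        z = np.array([0.2, 0.9, 2.7])
        nu, beta = 0.8, 0.3
        ref = stats.gamma.logpdf(z, a=nu**2 / beta, scale=beta / nu)
        np.testing.assert_allclose(gamma_intensity_loglik(z, nu, beta), ref, atol=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gamma_intensity_loglik(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            gamma_intensity_loglik(1.0, -1.0, 1.0)
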