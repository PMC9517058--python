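"""Langevin/metadynamics sampler and PLUMED-dialect file I/O."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import integrate, stats

from hostguest import landscapes as L
from hostguest import sampler as S
from hostguest.constants import KB_KCAL_MOL_K, beta

kT = KB_KCAL_MOL_K * 300.0


def _flat_potential(lo=-500.0, hi=500.0):
    return L.PotentialSpec(kind="reaction", lo=lo, hi=hi, periodic=False,
                           terms=(), offset=0.0, basins={})


def _gaussian_well(amplitude=200.0, width=2.0, lo=-8.0, hi=8.0):
    return L.PotentialSpec(kind="reaction", lo=lo, hi=hi, periodic=False,
                           terms=(L.GaussianTerm(-amplitude, 0.0, width),),
                           offset=amplitude, basins={"w": (-2.0, 2.0)})


class TestLangevin:
    def test_free_diffusion_msd(self):
        D, dt, stride = 1.0, 1e-3, 10
        params = S.RunParams(dt=dt, diffusion=D, n_steps=100_000, seed=1,
                             save_stride=stride)
        traj = S.run_langevin(_flat_potential(), params, s0=0.0)
        incr = np.diff(traj.cv_values)
        assert incr.var() == pytest.approx(2 * D * stride * dt, rel=0.10)

    def test_confined_variance_matches_boltzmann(self):
        # oracle: quadrature variance of exp(-beta F) in the well
        pot = _gaussian_well()
        b = beta()
        z0 = integrate.quad(lambda s: np.exp(-b * pot.energy(s)), -3, 3)[0]
        z2 = integrate.quad(lambda s: s * s * np.exp(-b * pot.energy(s)), -3, 3)[0]
        var_expected = z2 / z0
        params = S.RunParams(dt=1e-4, n_steps=600_000, seed=2, save_stride=20)
        traj = S.run_langevin(pot, params, s0=0.0)
        assert traj.cv_values.var() == pytest.approx(var_expected, rel=0.05)

    def test_seed_determinism(self, free_amide_potential):
        params = S.RunParams(dt=2e-4, n_steps=20_000, seed=9, save_stride=10)
        a = S.run_langevin(free_amide_potential, params)
        b = S.run_langevin(free_amide_potential, params)
        assert np.array_equal(a.cv_values, b.cv_values)

    def test_step_divergence_raises(self):
        steep = L.PotentialSpec(kind="reaction", lo=0.0, hi=1.0, periodic=False,
                                terms=(L.GaussianTerm(-500.0, 0.5, 0.02),),
                                offset=0.0, basins={})
        params = S.RunParams(dt=0.05, n_steps=10_000, seed=0, save_stride=0)
        with pytest.raises(S.StepSizeError):
            S.run_langevin(steep, params, s0=0.45)

    def test_stationary_histogram_matches_boltzmann(self):
        """Chi-square goodness of fit of the sampled density against
        exp(-beta F) on a double well with a 4 kBT barrier."""
        pot = L.make_dihedral_potential(0.6, 4.0 * kT)
        params = S.RunParams(dt=1e-3, n_steps=6_000_000, seed=5,
                             save_stride=10_000)
        traj = S.run_langevin(pot, params)
        edges = np.linspace(-math.pi, math.pi, 25)
        b = beta()
        p = np.array([
            np.trapezoid(np.exp(-b * pot.energy(np.linspace(e0, e1, 200))),
                         np.linspace(e0, e1, 200))
            for e0, e1 in zip(edges[:-1], edges[1:])])
        p /= p.sum()
        counts, _ = np.histogram(traj.cv_values, bins=edges)
        expected = p * counts.sum()
        pool = expected < 5  # pool sparsely populated barrier bins
        if pool.any():
            counts = np.concatenate([counts[~pool], [counts[pool].sum()]])
            expected = np.concatenate([expected[~pool], [expected[pool].sum()]])
        chi2, pval = stats.chisquare(counts,
                                     expected * counts.sum() / expected.sum())
        assert pval > 0.01


@pytest.fixture(scope="module")
def short_run(free_amide_potential):
    params = S.RunParams(dt=2e-4, n_steps=300_000, seed=3, save_stride=100)
    metad = S.MetaDParams(hill_height0=1.2, hill_sigma=0.35,
                          deposit_stride=500, bias_factor=15.0)
    return S.run_wtmetad(free_amide_potential, params, metad), metad


class TestWTMetaD:
    def test_tempering_law_for_hill_heights(self, short_run):
        """Each deposited height equals h0*exp(-V(center, t-)/ (kB dT))."""
        (_, hills), metad = short_run
        kbdT = KB_KCAL_MOL_K * (metad.bias_factor - 1.0) * 300.0
        for i in [0, 1, 5, 50, 200, len(hills) - 1]:
            v_before = S.evaluate_bias(hills, float(hills.centers[i]),
                                       t=float(hills.times[i]) - 1e-12)
            expected = metad.hill_height0 * math.exp(-v_before / kbdT)
            # deposition reads the bias off the integration grid, so the
            # comparison is only exact to grid-interpolation accuracy
            assert hills.heights[i] == pytest.approx(expected, rel=1e-3)

    def test_bias_grows_monotonically_at_fixed_point(self, short_run):
        (_, hills), _ = short_run
        ts = np.linspace(0, float(hills.times[-1]), 20)
        vals = [S.evaluate_bias(hills, math.pi, t=t) for t in ts]
        assert np.all(np.diff(vals) >= 0)

    def test_total_bias_bounded(self, short_run, free_amide_potential):
        (_, hills), metad = short_run
        g = free_amide_potential.grid(256)
        vmax = np.max(S.evaluate_bias(hills, g))
        assert vmax <= metad.bias_factor * (22.3 + 5.0)

    def test_untempered_limit_keeps_heights_constant(self, free_amide_potential):
        params = S.RunParams(dt=2e-4, n_steps=50_000, seed=4, save_stride=0)
        metad = S.MetaDParams(hill_height0=0.3, hill_sigma=0.35,
                              deposit_stride=500, bias_factor=1e9)
        _, hills = S.run_wtmetad(free_amide_potential, params, metad)
        assert np.allclose(hills.heights, 0.3, rtol=1e-6)

    def test_double_well_dg_recovery(self):
        """WT-MetaD recovers a 1 kcal/mol basin offset to 0.2 over 3 seeds."""
        pot = L.make_dihedral_potential(1.0, 4.0)
        from hostguest import thermo as T
        recs = []
        for seed in (21, 22, 23):
            params = S.RunParams(dt=5e-4, n_steps=400_000, seed=seed,
                                 save_stride=0)
            metad = S.MetaDParams(hill_height0=0.2, hill_sigma=0.35,
                                  deposit_stride=500, bias_factor=8.0)
            _, hills = S.run_wtmetad(pot, params, metad)
            prof = T.fes_from_hills(hills, basins=pot.basins)
            recs.append(T.basin_free_energy_difference(prof, "trans", "cis"))
        # oracle: quadrature basin dG of the analytic landscape
        b = beta()
        g = pot.grid(8192)
        from hostguest.thermo import FreeEnergyProfile
        truth = FreeEnergyProfile(grid=g, F=pot.energy(g), temperature=300.0,
                                  periodic=True, basins=pot.basins)
        from hostguest.thermo import basin_free_energy_difference
        dg_true = basin_free_energy_difference(truth, "trans", "cis")
        assert np.mean(recs) == pytest.approx(dg_true, abs=0.2)


class TestInfrequent:
    def test_barrierless_exit_has_unrescaled_time(self):
        pot = L.make_reaction_profile(-2.0, 0.15)
        params = S.RunParams(dt=5e-5, n_steps=200_000, seed=6, save_stride=0)
        metad = S.MetaDParams(hill_height0=0.15, hill_sigma=0.05,
                              deposit_stride=50_000, bias_factor=6.0)
        events = S.run_infrequent_ensemble(pot, params, metad, "R", "TI", 8,
                                           commit_margin=0.05)
        for e in events:
            assert not e.censored
            assert e.rescaled_time == pytest.approx(e.physical_time, rel=1e-9)

    def test_rescaled_time_never_below_physical(self):
        pot = L.make_reaction_profile(0.0, 6.0 * kT)
        params = S.RunParams(dt=5e-5, n_steps=2_000_000, seed=8, save_stride=0)
        metad = S.MetaDParams(hill_height0=0.15, hill_sigma=0.05,
                              deposit_stride=1000, bias_factor=6.0)
        events = S.run_infrequent_ensemble(pot, params, metad, "R", "TI", 10,
                                           commit_margin=0.05)
        for e in events:
            assert e.rescaled_time >= e.physical_time - 1e-12

    def test_mean_rescaled_time_matches_brute_force(self):
        """Infrequent rescaled times vs unbiased first-passage, factor 2."""
        pot = L.make_reaction_profile(0.0, 6.0 * kT)
        metad = S.MetaDParams(hill_height0=0.15, hill_sigma=0.05,
                              deposit_stride=1000, bias_factor=6.0)
        p1 = S.RunParams(dt=5e-5, n_steps=2_000_000, seed=30, save_stride=0)
        biased = S.run_infrequent_ensemble(pot, p1, metad, "R", "TI", 20,
                                           commit_margin=0.05)
        p2 = S.RunParams(dt=5e-5, n_steps=8_000_000, seed=31, save_stride=0)
        unbiased = S.run_infrequent_ensemble(pot, p2, None, "R", "TI", 20,
                                             commit_margin=0.05)
        tb = np.mean([e.rescaled_time for e in biased if not e.censored])
        tu = np.mean([e.physical_time for e in unbiased if not e.censored])
        assert 0.5 < tb / tu < 2.0

    def test_event_set_determinism(self):
        pot = L.make_reaction_profile(0.0, 4.0 * kT)
        params = S.RunParams(dt=5e-5, n_steps=500_000, seed=12, save_stride=0)
        metad = S.MetaDParams(hill_height0=0.15, hill_sigma=0.05,
                              deposit_stride=500, bias_factor=6.0)
        a = S.run_infrequent_ensemble(pot, params, metad, "R", "TI", 6,
                                      commit_margin=0.05)
        b = S.run_infrequent_ensemble(pot, params, metad, "R", "TI", 6,
                                      commit_margin=0.05)
        assert a == b

    def test_fast_deposition_rejected(self):
        pot = L.make_reaction_profile(0.0, 2.0)
        params = S.RunParams(n_steps=1000, seed=0)
        metad = S.MetaDParams(hill_height0=0.1, hill_sigma=0.05,
                              deposit_stride=10, bias_factor=5.0)
        with pytest.raises(ValueError, match="floor"):
            S.run_infrequent_ensemble(pot, params, metad, "R", "TI", 2)

    def test_same_basin_rejected(self):
        pot = L.make_reaction_profile(0.0, 2.0)
        with pytest.raises(ValueError):
            S.run_infrequent_ensemble(pot, S.RunParams(n_steps=10, seed=0),
                                      None, "R", "R", 2)


class TestBiasEvaluation:
    def test_empty_log_is_zero(self):
        hills = S.HillsLog(times=np.array([]), centers=np.array([]),
                           sigmas=np.array([]), heights=np.array([]),
                           bias_factor=10.0, lo=-math.pi, hi=math.pi,
                           periodic=True)
        assert S.evaluate_bias(hills, 0.3) == 0.0

    def test_single_hill_peak_value(self):
        hills = S.HillsLog(times=np.array([1.0]), centers=np.array([0.0]),
                           sigmas=np.array([0.35]), heights=np.array([1.0]),
                           bias_factor=10.0, lo=-math.pi, hi=math.pi,
                           periodic=True)
        assert S.evaluate_bias(hills, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_periodic_image_wrapping(self):
        hills = S.HillsLog(times=np.array([1.0]),
                           centers=np.array([math.pi - 0.1]),
                           sigmas=np.array([0.35]), heights=np.array([1.0]),
                           bias_factor=10.0, lo=-math.pi, hi=math.pi,
                           periodic=True)
        across = S.evaluate_bias(hills, -math.pi + 0.1)
        direct = S.evaluate_bias(hills, math.pi - 0.1 + 0.2)
        assert across == pytest.approx(direct, rel=1e-12)
        assert across == pytest.approx(math.exp(-0.5 * (0.2 / 0.35) ** 2),
                                       rel=1e-9)


class TestHillsIO:
    def _hills(self, n=7):
        rng = np.random.default_rng(0)
        return S.HillsLog(times=np.arange(1.0, n + 1),
                          centers=rng.uniform(-3, 3, n),
                          sigmas=np.full(n, 0.35),
                          heights=rng.uniform(0.1, 1.2, n),
                          bias_factor=15.0, lo=-math.pi, hi=math.pi,
                          periodic=True, cv_name="omega")

    def test_round_trip(self, tmp_path):
        hills = self._hills()
        path = tmp_path / "HILLS"
        S.write_hills(hills, path)
        back = S.read_hills(path)
        assert back == hills
        assert back.cv_name == "omega"

    def test_interleaved_comments_skipped(self, tmp_path):
        hills = self._hills(3)
        path = tmp_path / "HILLS"
        S.write_hills(hills, path)
        lines = path.read_text().splitlines()
        lines.insert(2, "# restart marker")
        path.write_text("\n".join(lines) + "\n")
        assert S.read_hills(path) == hills

    def test_ragged_row_reports_line_number(self, tmp_path):
        path = tmp_path / "HILLS"
        S.write_hills(self._hills(3), path)
        path.write_text(path.read_text() + "1.0 2.0\n")
        with pytest.raises(S.HillsParseError, match="line 5"):
            S.read_hills(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "HILLS"
        path.write_text("#! FIELDS time cv height biasf\n1 2 3 4\n")
        with pytest.raises(S.HillsParseError):
            S.read_hills(path)

    def test_colvar_round_trip(self, tmp_path):
        params = S.RunParams(dt=1e-3, n_steps=2_000, seed=1, save_stride=100)
        traj = S.run_langevin(_flat_potential(), params, s0=0.0)
        path = tmp_path / "COLVAR"
        S.write_colvar(traj, path)
        t, cv, bias = S.read_colvar(path)
        assert np.allclose(cv, traj.cv_values)
        assert np.allclose(t, traj.times)


class TestParamValidation:
    def test_invalid_run_params(self):
        with pytest.raises(ValueError):
            S.RunParams(dt=-1.0)
        with pytest.raises(ValueError):
            S.RunParams(n_steps=0)
        with pytest.raises(ValueError):
            S.RunParams(boundary="absorbing")

    def test_invalid_metad_params(self):
        with pytest.raises(ValueError):
            S.MetaDParams(bias_factor=1.0)
        with pytest.raises(ValueError):
            S.MetaDParams(hill_height0=-0.1)

    def test_boundary_mismatch(self, free_amide_potential):
        params = S.RunParams(n_steps=100, boundary="reflecting")
        with pytest.raises(ValueError):
            S.run_langevin(free_amide_potential, params)
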