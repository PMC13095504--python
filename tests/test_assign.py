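"""Bayesian assignment surfaces: oracles, joint posteriors, QA, site spread."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from isodrift.assign import (ProbabilitySurface, joint_posterior,
                             odds_ratio_region, posterior_surface,
                             qa_known_origin, site_spread)
from isodrift.calibrate import CalibrationFit
from isodrift.isoscape import Isoscape
from isodrift.synth import sample_known_origin_moths

from conftest import tiny_raster


def make_iso(mean, sigma):
    mean = np.atleast_2d(np.asarray(mean, float))
    sigma = np.broadcast_to(np.asarray(sigma, float), mean.shape).copy()
    grid = tiny_raster(mean)
    return Isoscape(mean=grid, sigma=grid.like(sigma),
                    valid_mask=grid.like(np.isfinite(mean).astype(float)))


def surface_from(probs):
    probs = np.atleast_2d(np.asarray(probs, float))
    return ProbabilitySurface(probs=tiny_raster(probs))


class TestPosterior:
    def test_symmetric_cells_split_evenly(self):
        iso = make_iso([[5.0, 5.0]], 1.0)
        s = posterior_surface(123.4, iso)
        assert np.allclose(s.probs.values, [[0.5, 0.5]])

    def test_density_ratio_matches_closed_form(self):
        """Means (0, 10), σ 1, obs 0: ratio is exp(−50)."""
        iso = make_iso([[0.0, 10.0]], 1.0)
        s = posterior_surface(0.0, iso)
        e50 = np.exp(-50.0)
        assert s.probs.values[0, 0] == pytest.approx(1.0 / (1.0 + e50))
        assert s.probs.values[0, 1] == pytest.approx(e50, rel=1e-9)
        assert s.probs.values[0, 1] == pytest.approx(1.93e-22, rel=1e-2)

    def test_far_observation_still_normalizes(self):
        iso = make_iso(np.zeros((5, 5)), 0.5)
        s = posterior_surface(500.0, iso)
        assert s.probs.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_normal_density(self):
        """Equivalence with the direct per-cell formula to machine precision."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            shape = tuple(rng.integers(3, 21, size=2))
            mean = rng.normal(5, 4, shape)
            sigma = rng.uniform(0.5, 3.0, shape)
            mean[rng.random(shape) < 0.15] = np.nan
            obs = rng.normal(5, 4)
            iso = make_iso(mean, sigma)
            s = posterior_surface(obs, iso, sigma_floor=0.0)
            valid = np.isfinite(mean)
            dens = stats.norm.pdf(obs, mean[valid], sigma[valid])
            expect = dens / dens.sum()
            assert np.allclose(s.probs.values[valid], expect, rtol=1e-12, atol=0)

    def test_sigma_floor_applied(self):
        iso = make_iso([[3.0, 3.0]], [[0.0, 0.1]])
        s = posterior_surface(3.0, iso, sigma_floor=0.1)
        assert np.allclose(s.probs.values, 0.5)

    def test_fully_masked_isoscape_rejected(self):
        iso = make_iso([[1.0]], 1.0)
        iso.valid_mask.values[:] = 0.0
        with pytest.raises(ValueError, match="masked"):
            posterior_surface(0.0, iso)


class TestJoint:
    def test_single_surface_identity(self):
        s = surface_from([[0.8, 0.2]])
        assert joint_posterior([s]) is s

    def test_two_copies_product_hand_value(self):
        s = surface_from([[0.8, 0.2]])
        j = joint_posterior([s, s])
        assert np.allclose(j.probs.values, [[0.64 / 0.68, 0.04 / 0.68]])
        assert np.allclose(j.probs.values, [[0.9412, 0.0588]], atol=1e-4)

    def test_uniform_surface_is_neutral(self):
        s = surface_from([[0.7, 0.2, 0.1]])
        u = surface_from([[1 / 3] * 3])
        j = joint_posterior([s, u])
        assert np.allclose(j.probs.values, s.probs.values)

    def test_product_sharpens_with_copies(self):
        """Max probability of n identical unimodal surfaces is
        non-decreasing in n."""
        s = surface_from([[0.5, 0.3, 0.2]])
        peaks = [joint_posterior([s] * n).probs.values.max() for n in (1, 2, 4, 8)]
        assert np.all(np.diff(peaks) >= 0)

    def test_grid_mismatch_rejected(self):
        a = surface_from([[0.5, 0.5]])
        b = ProbabilitySurface(probs=tiny_raster(np.array([[0.5, 0.5]]), lat0=48.0))
        with pytest.raises(ValueError, match="congruent"):
            joint_posterior([a, b])

    def test_mean_rule_averages(self):
        a = surface_from([[1.0, 0.0]])
        b = surface_from([[0.0, 1.0]])
        j = joint_posterior([a, b], rule="mean")
        assert np.allclose(j.probs.values, 0.5)


class TestOddsRegion:
    def test_uniform_ties_all_retained(self):
        s = surface_from([[0.25] * 4])
        region = odds_ratio_region(s, odds=1.0)
        assert region.values.sum() == 4

    def test_dominant_cell_only(self):
        s = surface_from([[0.9, 0.1]])
        region = odds_ratio_region(s, odds=2.0)   # needs cum ≥ 2/3
        assert region.values.tolist() == [[1.0, 0.0]]

    def test_huge_odds_keeps_all_nonzero(self):
        s = surface_from([[0.6, 0.4, 0.0]])
        region = odds_ratio_region(s, odds=1e12)
        assert region.values[0, 0] == 1 and region.values[0, 1] == 1

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(2, 40), st.integers(0, 2**31 - 1),
           st.floats(0.2, 10.0))
    def test_region_mass_reaches_target_minimally(self, n, seed, odds):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(n))
        s = surface_from(p[None, :])
        region = odds_ratio_region(s, odds=odds)
        inside = region.values[0] > 0.5
        target = odds / (odds + 1)
        assert p[inside].sum() >= target - 1e-9
        # minimality up to ties: dropping the whole lowest-probability tier
        # inside the region must fall below the target
        if inside.any():
            cut = p[inside].min()
            trimmed = p[inside & (p > cut + 1e-15)].sum()
            assert trimmed < target


class TestQA:
    def test_informative_isoscape_beats_random(self, noiseless_landscape,
                                               truth_isoscape):
        covs, true = noiseless_landscape
        moths = sample_known_origin_moths(true, covs, 12, 3, (-0.08, 0.94),
                                          seed=13, intra_site_sd=0.59)
        foliar = None  # iso supplied directly
        qa = qa_known_origin(moths, foliar, covs, seed=13, n_random=50,
                             iso=truth_isoscape)
        assert qa.odds_ratio > 1.0
        assert np.all(np.diff(qa.granularity) >= -1e-12)

    def test_flat_isoscape_is_uninformative(self, noiseless_landscape,
                                            truth_isoscape):
        covs, true = noiseless_landscape
        rng = np.random.default_rng(0)
        near_flat = 5.0 + rng.normal(0, 1e-6, truth_isoscape.mean.shape)
        flat = Isoscape(
            mean=truth_isoscape.mean.like(
                np.where(truth_isoscape.valid, near_flat, np.nan)),
            sigma=truth_isoscape.sigma,
            valid_mask=truth_isoscape.valid_mask)
        moths = sample_known_origin_moths(true, covs, 10, 3, (0.0, 1.0),
                                          seed=14, intra_site_sd=0.3)
        moths = moths.assign(d34S=5.0 + (moths["d34S"] - moths["d34S"].mean()) * 0.01)
        qa = qa_known_origin(moths, None, covs, seed=14, n_random=100, iso=flat)
        assert qa.odds_ratio == pytest.approx(1.0, abs=0.05)

    def test_noiseless_pipeline_modes_at_true_origin(self, default_landscape):
        """Exact moths on an exact isoscape: the posterior mode is the
        true-origin cell for every moth."""
        covs, true = default_landscape
        land = true.mask
        iso = Isoscape(mean=true,
                       sigma=true.like(np.where(land, 1.0, np.nan)),
                       valid_mask=true.like(land.astype(float)))
        moths = sample_known_origin_moths(true, covs, 8, 2, (0.0, 1.0),
                                          seed=15, intra_site_sd=0.0)
        for _, rec in moths.iterrows():
            s = posterior_surface(rec["d34S"], iso)
            r, c = np.unravel_index(np.nanargmax(s.probs.values), s.probs.shape)
            assert (r, c) == (rec["row"], rec["col"])

    def test_too_few_sites_rejected(self, noiseless_landscape, truth_isoscape):
        covs, true = noiseless_landscape
        moths = sample_known_origin_moths(true, covs, 4, 3, (0.0, 1.0), seed=16)
        with pytest.raises(ValueError, match="5"):
            qa_known_origin(moths, None, covs, iso=truth_isoscape)


class TestSiteSpread:
    @staticmethod
    def _samples(rng, sds, group, n_sites=20, n_rep=5, offset=0):
        rows = []
        for i in range(n_sites):
            mu = rng.normal(5, 3)
            for v in rng.normal(mu, sds, size=n_rep):
                rows.append({"site_id": f"{group}{i + offset}", "lat": 46.0,
                             "lon": -63.0, "tissue": "moth", "species": "x",
                             "d34S": v, "n_replicates": 1, "group": group})
        return pd.DataFrame(rows)

    def test_recovers_generator_sds(self):
        """Generators at 0.59‰ and 1.74‰ (known-origin vs trap-caught
        locals): group-mean SDs recover within Monte-Carlo error."""
        rng = np.random.default_rng(1)
        df = pd.concat([self._samples(rng, 0.59, "known", 60),
                        self._samples(rng, 1.74, "local", 60)])
        per_site, summary = site_spread(df, "group")
        # E[sample SD] = c4(n)·σ; c4(5) = sqrt(2/4)·Γ(2.5)/Γ(2) ≈ 0.9400
        from scipy.special import gamma
        c4 = np.sqrt(2 / 4) * gamma(2.5) / gamma(2.0)
        assert summary["mean_sd"]["known"] == pytest.approx(0.59 * c4, abs=0.06)
        assert summary["mean_sd"]["local"] == pytest.approx(1.74 * c4, abs=0.17)
        assert summary["p_value"] < 1e-6

    def test_equal_generators_rarely_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = pd.concat([self._samples(rng, 0.8, "a", 10),
                            self._samples(rng, 0.8, "b", 10)])
            _, summary = site_spread(df, "group")
            hits += summary["p_value"] <= 0.05
        assert hits <= 2   # ≥ 90% of null runs non-significant

    def test_degenerate_identical_values_rejected(self):
        df = pd.DataFrame({"site_id": ["a", "a", "b", "b", "c", "c", "d", "d"],
                           "d34S": [5.0] * 8,
                           "group": ["g1", "g1", "g1", "g1", "g2", "g2", "g2", "g2"]})
        with pytest.raises(ValueError, match="identical"):
            site_spread(df, "group")

    def test_insufficient_replication_rejected(self):
        df = pd.DataFrame({"site_id": ["a", "b", "b", "c", "c", "d", "d"],
                           "d34S": [5.0, 1, 2, 3, 4, 5, 6],
                           "group": ["g1"] * 3 + ["g2"] * 4})
        with pytest.raises(ValueError, match="fewer than 2"):
            site_spread(df, "group")
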