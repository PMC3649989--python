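"""Haplotype-copying HMM: exhaustive path-enumeration oracle, limit cases,
population aggregation, time profiling, jackknife correction."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from introscan.ancestry_hmm import (
    CopyingParams,
    copying_posterior,
    correct_track,
    haplotype_posteriors,
    jackknife_reference_baseline,
    profile_admixture_time,
    scan_population,
)
from introscan.io_formats import HaplotypePanel
from introscan.synthetic_data import (
    SimConfig,
    contaminate_reference,
    simulate_admixed_population,
    simulate_ancestral_panels,
)


def tiny_sites(n, spacing_cm=0.5):
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "bp": np.arange(1, n + 1) * 100_000,
            "cM": np.arange(n) * spacing_cm,
            "ref": ["A"] * n,
            "alt": ["G"] * n,
        }
    )


def enumerate_path_posteriors(query, hap_r, hap_d, cm, params):
    """Literal sum over all (ancestry, copied haplotype) state paths.

    Same model definition as the forward–backward implementation, computed
    by brute force: state s in [0, kr) copies recipient haplotype s, state
    s in [kr, kr+kd) copies donor haplotype s-kr.
    """
    kr, kd = hap_r.shape[0], hap_d.shape[0]
    S = kr + kd
    panel = np.vstack([hap_r, hap_d])
    m, mu = params.mix_prior, params.miscopy_rate
    prior = np.array([(1 - m) / kr] * kr + [m / kd] * kd)
    n = len(cm)
    d = np.diff(cm) / 100.0
    pa = 1 - np.exp(-params.generations_T * d)
    ps = 1 - np.exp(-params.panel_switch_rate * d)

    def emit(t, s):
        if query[t] < 0:
            return 1.0
        return 1.0 - mu if query[t] == panel[s, t] else mu

    def trans(t, s, s2):
        same_panel = (s < kr) == (s2 < kr)
        k_panel = kr if s < kr else kd
        p = pa[t] * prior[s2]
        if same_panel:
            p += (1 - pa[t]) * ps[t] / k_panel
            if s == s2:
                p += (1 - pa[t]) * (1 - ps[t])
        return p

    total = 0.0
    donor_mass = np.zeros(n)
    for path in itertools.product(range(S), repeat=n):
        p = prior[path[0]] * emit(0, path[0])
        for t in range(1, n):
            p *= trans(t - 1, path[t - 1], path[t]) * emit(t, path[t])
        total += p
        for t in range(n):
            if path[t] >= kr:
                donor_mass[t] += p
    return donor_mass / total, np.log(total)


def panels_from_arrays(sites, hap_r, hap_d):
    return (
        HaplotypePanel(sites, hap_r, "maize"),
        HaplotypePanel(sites, hap_d, "mexicana"),
    )


class TestCopyingPosterior:
    def test_matches_exhaustive_path_enumeration(self):
        """Forward–backward equals the brute-force path sum on an 8-site toy."""
        rng = np.random.default_rng(31)
        n = 8
        sites = tiny_sites(n)
        hap_r = rng.integers(0, 2, size=(2, n)).astype(np.int8)
        hap_d = rng.integers(0, 2, size=(2, n)).astype(np.int8)
        params = CopyingParams(generations_T=50, mix_prior=0.2,
                               miscopy_rate=0.01, panel_switch_rate=5.0)
        pr, pd_ = panels_from_arrays(sites, hap_r, hap_d)
        for trial in range(3):
            query = rng.integers(0, 2, size=n).astype(np.int8)
            post, ll = haplotype_posteriors(query[None, :], pr, pd_, sites, params)
            oracle_post, oracle_ll = enumerate_path_posteriors(
                query, hap_r, hap_d, sites["cM"].to_numpy(), params
            )
            np.testing.assert_allclose(post[0], oracle_post, atol=1e-8)
            assert ll[0] == pytest.approx(oracle_ll, abs=1e-8)

    def test_oracle_with_missing_query_alleles(self):
        rng = np.random.default_rng(32)
        n = 6
        sites = tiny_sites(n)
        hap_r = rng.integers(0, 2, size=(2, n)).astype(np.int8)
        hap_d = rng.integers(0, 2, size=(2, n)).astype(np.int8)
        query = rng.integers(0, 2, size=n).astype(np.int8)
        query[2] = -1
        params = CopyingParams()
        pr, pd_ = panels_from_arrays(sites, hap_r, hap_d)
        post, ll = haplotype_posteriors(query[None, :], pr, pd_, sites, params)
        oracle_post, oracle_ll = enumerate_path_posteriors(
            query, hap_r, hap_d, sites["cM"].to_numpy(), params
        )
        np.testing.assert_allclose(post[0], oracle_post, atol=1e-8)

    def test_verbatim_donor_copy_detected(self):
        rng = np.random.default_rng(33)
        n = 200
        sites = tiny_sites(n, spacing_cm=0.1)
        hap_r = rng.integers(0, 2, size=(6, n)).astype(np.int8)
        hap_d = rng.integers(0, 2, size=(6, n)).astype(np.int8)
        pr, pd_ = panels_from_arrays(sites, hap_r, hap_d)
        ind = np.vstack([hap_d[0], hap_d[1]])
        dosage, _ = copying_posterior(
            ind, pr, pd_, CopyingParams(miscopy_rate=0.002)
        )
        assert dosage.mean() > 1.9

    def test_posterior_vanishes_with_prior(self):
        """Donor posterior decreases monotonically as the prior shrinks."""
        rng = np.random.default_rng(34)
        n = 100
        sites = tiny_sites(n, spacing_cm=0.1)
        hap_r = rng.integers(0, 2, size=(4, n)).astype(np.int8)
        hap_d = rng.integers(0, 2, size=(4, n)).astype(np.int8)
        pr, pd_ = panels_from_arrays(sites, hap_r, hap_d)
        query = hap_r[0].copy()
        means = []
        for prior in (0.3, 0.1, 0.01, 0.001):
            post, _ = haplotype_posteriors(
                query[None, :], pr, pd_, sites,
                CopyingParams(mix_prior=prior),
            )
            means.append(post.mean())
        assert means[0] > means[1] > means[2] > means[3]
        assert means[-1] < 0.01

    def test_empty_panel_errors(self):
        sites = tiny_sites(4)
        hap = np.zeros((2, 4), dtype=np.int8)
        pr = HaplotypePanel(sites, hap, "maize")
        pd_empty = HaplotypePanel(sites, np.zeros((0, 4), dtype=np.int8), "mexicana")
        with pytest.raises(ValueError, match="empty reference panel"):
            haplotype_posteriors(hap[:1], pr, pd_empty, sites, CopyingParams())

    def test_loglik_decreases_toward_random_emission(self):
        """On data matched to the panel, likelihood degrades as the miscopy
        rate approaches 1/2."""
        rng = np.random.default_rng(35)
        n = 120
        sites = tiny_sites(n, spacing_cm=0.1)
        hap_r = rng.integers(0, 2, size=(4, n)).astype(np.int8)
        hap_d = rng.integers(0, 2, size=(4, n)).astype(np.int8)
        pr, pd_ = panels_from_arrays(sites, hap_r, hap_d)
        query = hap_r[2][None, :]
        lls = []
        for mu in (0.002, 0.05, 0.2, 0.45):
            _, ll = haplotype_posteriors(
                query, pr, pd_, sites, CopyingParams(miscopy_rate=mu)
            )
            lls.append(ll[0])
        assert all(a >= b for a, b in zip(lls, lls[1:]))


class TestScanPopulation:
    def test_unadmixed_population_low_track(self):
        cfg = SimConfig(
            n_chromosomes=1, chromosome_length_bp=30_000_000,
            n_reference_haplotypes=12, n_individuals=8,
            admixture_proportion={"mexicana": 0.0, "maize": 0.0},
            shared_tract_spec=[], seed=36,
        )
        panels = simulate_ancestral_panels(cfg)
        pop = simulate_admixed_population(panels, cfg, 0, "maize")
        track = scan_population(pop.haplotypes, panels[0], panels[1],
                                CopyingParams(mix_prior=0.2))
        assert (track.mean < 0.1).mean() >= 0.95

    def test_forced_tract_high_track(self, small_cfg, small_panels,
                                      small_population):
        track = scan_population(
            small_population.haplotypes, small_panels[0], small_panels[1],
            CopyingParams(mix_prior=0.2),
        )
        sel = (
            (small_panels[0].sites["bp"] >= 10_000_000)
            & (small_panels[0].sites["bp"] < 18_000_000)
        ).to_numpy()
        assert (track.mean[sel] > 0.5).mean() > 0.9

    def test_single_individual_mean_is_dosage_half(self, small_cfg, small_panels):
        cfg = SimConfig(**{
            **{f: getattr(small_cfg, f) for f in (
                "n_chromosomes", "chromosome_length_bp", "n_reference_haplotypes",
                "shared_tract_spec")},
            "n_individuals": 1,
        }, seed=37)
        pop = simulate_admixed_population(small_panels, cfg, 0, "maize")
        track = scan_population(pop.haplotypes, small_panels[0], small_panels[1],
                                CopyingParams(mix_prior=0.2))
        np.testing.assert_allclose(track.mean, track.dosage[:, 0] / 2.0)


class TestProfileAdmixtureTime:
    def test_single_value_grid(self, small_panels, small_population):
        prof = profile_admixture_time(
            small_population.haplotypes, small_panels[0], small_panels[1],
            [100.0], CopyingParams(mix_prior=0.2),
        )
        assert prof.T_hat == 100.0

    def test_grid_order_invariance(self, small_panels, small_population):
        grid = [500.0, 10.0, 100.0]
        p1 = profile_admixture_time(
            small_population.haplotypes, small_panels[0], small_panels[1],
            grid, CopyingParams(mix_prior=0.2),
        )
        p2 = profile_admixture_time(
            small_population.haplotypes, small_panels[0], small_panels[1],
            sorted(grid), CopyingParams(mix_prior=0.2),
        )
        np.testing.assert_array_equal(p1.T_grid, p2.T_grid)
        np.testing.assert_array_equal(p1.loglik, p2.loglik)
        assert p1.T_hat == p2.T_hat

    def test_grid_outside_bounds_rejected(self, small_panels, small_population):
        with pytest.raises(ValueError, match="1, 5000"):
            profile_admixture_time(
                small_population.haplotypes, small_panels[0], small_panels[1],
                [0.5, 100.0],
            )


class TestJackknife:
    def test_clean_panels_low_baseline(self):
        # study-size panels (24 haplotypes): the baseline bound is a property
        # of the study design, not of arbitrarily small panels
        cfg = SimConfig(
            n_chromosomes=1, chromosome_length_bp=40_000_000,
            n_reference_haplotypes=24, shared_tract_spec=[], seed=39,
        )
        panels = simulate_ancestral_panels(cfg)
        base = jackknife_reference_baseline(
            panels[0], panels[1], CopyingParams(mix_prior=0.2)
        )
        assert (base < 0.05).mean() >= 0.95

    def test_contaminated_panel_elevated_inside_tracts(self, small_cfg,
                                                       small_panels):
        rng = np.random.default_rng(38)
        cont, truth = contaminate_reference(
            small_panels[0], 0.3, small_panels[1], small_cfg, rng
        )
        base = jackknife_reference_baseline(
            cont, small_panels[1], CopyingParams(mix_prior=0.2)
        )
        frac = truth.site_donor_indicator(
            small_panels[0].sites, "mexicana"
        ).mean(axis=1)
        inside, outside = base[frac > 0], base[frac == 0]
        assert inside.mean() > outside.mean()

    def test_identical_haplotype_panel_finite(self):
        sites = tiny_sites(20, 0.2)
        hap = np.tile(np.array([0, 1] * 10, dtype=np.int8), (8, 1))
        pr = HaplotypePanel(sites, hap, "maize")
        pd_ = HaplotypePanel(
            sites, 1 - hap, "mexicana"
        )
        base = jackknife_reference_baseline(pr, pd_, CopyingParams())
        assert np.all(np.isfinite(base))

    def test_small_panel_errors(self):
        sites = tiny_sites(4)
        hap = np.zeros((4, 4), dtype=np.int8)  # only 2 individuals
        pr = HaplotypePanel(sites, hap, "maize")
        with pytest.raises(ValueError, match=">=3"):
            jackknife_reference_baseline(pr, pr, CopyingParams())


class TestCorrectTrack:
    def test_identity_floor_and_alignment(self, small_panels, small_population):
        track = scan_population(
            small_population.haplotypes, small_panels[0], small_panels[1],
            CopyingParams(mix_prior=0.2),
        )
        same = correct_track(track, np.zeros_like(track.mean))
        np.testing.assert_array_equal(same.mean, track.mean)
        floored = correct_track(track, np.ones_like(track.mean))
        assert np.all(floored.mean == 0.0)
        assert floored.corrected and not track.corrected
        np.testing.assert_array_equal(floored.dosage, track.dosage)
        with pytest.raises(ValueError, match="aligned"):
            correct_track(track, np.zeros(3))
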