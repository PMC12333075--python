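"""The synthetic study generator: determinism, realism contrasts, and the
statistical structure the downstream analysis assumes."""

import math

import numpy as np
import pandas as pd
import pytest

from peatspec.community import estimate_cover, shannon_index
from peatspec.errors import ConfigError, GenerationError
from peatspec.preprocess import harmonize
from peatspec.spectral_io import Spectrum
from peatspec.synthetic_data import (
    DEFAULT_SPECIES_PARAMS,
    FULL_GRID,
    SimulationConfig,
    SpeciesSpectralParams,
    gen_communities,
    gen_endmember_library,
    gen_grid_observation,
    gen_plot_spectrum,
    gen_study,
)
from peatspec.unmixing import EndmemberSet, unmix_trophic_level


class TestEndmemberLibrary:
    def test_deterministic_given_seed(self):
        a = gen_endmember_library(seed=5)
        b = gen_endmember_library(seed=5)
        assert np.array_equal(a.data.to_numpy(), b.data.to_numpy())
        c = gen_endmember_library(seed=6)
        assert not np.array_equal(a.data.to_numpy(), c.data.to_numpy())

    def test_full_grid(self):
        lib = gen_endmember_library(seed=0)
        assert np.array_equal(lib.wavelengths_nm, FULL_GRID)
        rf = lib.data.to_numpy()
        assert rf.min() > 0 and rf.max() < 1

    def test_vascular_greener_than_moss(self):
        """Vascular species reflect more in the green (530-570 nm) and have
        a steeper red edge than Sphagnum mosses."""
        green = (FULL_GRID >= 530) & (FULL_GRID <= 570)
        red_edge = (FULL_GRID >= 670) & (FULL_GRID <= 760)
        vasc, moss = [], []
        vasc_slope, moss_slope = [], []
        for sp, prm in DEFAULT_SPECIES_PARAMS.items():
            rf = prm.template()
            peak = rf[green].mean() - rf[FULL_GRID == 500][0]
            slope = np.max(np.diff(rf[red_edge]))
            if prm.functional_type == "vascular":
                vasc.append(peak)
                vasc_slope.append(slope)
            elif prm.functional_type == "moss":
                moss.append(peak)
                moss_slope.append(slope)
        assert min(vasc) > max(moss)
        assert min(vasc_slope) > max(moss_slope)

    def test_litter_monotone_through_visible(self):
        rf = DEFAULT_SPECIES_PARAMS["Litter"].template()
        at = lambda nm: rf[FULL_GRID == nm][0]
        assert at(700) > at(550) > at(450)

    def test_impossible_params_raise(self):
        bad = SpeciesSpectralParams("vascular", 0.5, 0.9, 710, 15, 0.9, 0.0, 0.0)
        with pytest.raises(GenerationError):
            bad.template()


class TestCommunities:
    def test_high_alpha_near_uniform(self):
        cfg = SimulationConfig(seed=0, n_plots=40, dirichlet_alpha=100.0)
        comms = gen_communities(cfg, "minerotrophic")
        h = np.mean([shannon_index(c) for c in comms])
        assert h == pytest.approx(math.log(6), abs=0.05)

    def test_low_alpha_sparse(self):
        cfg = SimulationConfig(seed=0, n_plots=200, dirichlet_alpha=0.3)
        comms = gen_communities(cfg, "minerotrophic")
        assert np.mean([c.richness for c in comms]) < 6

    def test_sum_to_100_always(self):
        cfg = SimulationConfig(seed=3, n_plots=100, dirichlet_alpha=0.3)
        for c in gen_communities(cfg, "ombrotrophic"):
            assert sum(c.cover.values()) == pytest.approx(100.0, abs=1e-9)


class TestPlotSpectrum:
    def test_noiseless_is_exact_mixture(self):
        cfg = SimulationConfig(seed=0, noise_sd=0.0, brightness_cv=0.0)
        lib = gen_endmember_library(seed=0)
        comms = gen_communities(cfg, "minerotrophic")
        c = comms[0]
        s = gen_plot_spectrum(c, lib, cfg)
        expected = sum(
            (f / 100.0) * lib.data[sp].to_numpy() for sp, f in c.cover.items() if f > 0
        )
        assert np.allclose(s.rf, expected, atol=1e-12)

    def test_single_species_plot_equals_endmember(self):
        from peatspec.community import PlotCommunity

        cfg = SimulationConfig(seed=0, noise_sd=0.0, brightness_cv=0.0)
        lib = gen_endmember_library(seed=0)
        c = PlotCommunity("p", "minerotrophic", {"Litter": 100.0})
        s = gen_plot_spectrum(c, lib, cfg)
        assert np.allclose(s.rf, lib.data["Litter"].to_numpy(), atol=1e-12)

    def test_ensemble_mean_near_exact_mixture(self):
        """Noise on: the mean spectrum over 1000 replicate plots of one
        fixed community is within 3 SE of the exact mixture everywhere."""
        cfg = SimulationConfig(seed=0)
        lib = harmonize(gen_endmember_library(seed=0))
        comms = gen_communities(cfg, "ombrotrophic")
        c = comms[0]
        rng = np.random.default_rng(99)
        reps = np.stack([gen_plot_spectrum(c, lib, cfg, rng).rf for _ in range(1000)])
        exact = sum(
            (f / 100.0) * lib.data[sp].to_numpy() for sp, f in c.cover.items() if f > 0
        )
        se = reps.std(axis=0, ddof=1) / np.sqrt(1000)
        assert np.all(np.abs(reps.mean(axis=0) - exact) <= 3.5 * se)

    def test_missing_endmember_raises(self):
        from peatspec.community import PlotCommunity

        cfg = SimulationConfig(seed=0)
        lib = gen_endmember_library(seed=0)
        c = PlotCommunity("p", "minerotrophic", {"Unknown species": 100.0})
        with pytest.raises(ConfigError):
            gen_plot_spectrum(c, lib, cfg)


class TestGridObservation:
    def test_single_species_all_labels(self):
        from peatspec.community import PlotCommunity

        c = PlotCommunity("p", "minerotrophic", {"Litter": 100.0})
        g = gen_grid_observation(c, seed=0)
        assert g.labels == ["Litter"] * 100

    def test_binomial_moments(self):
        """f=(50,50): counts are Binomial(100, 0.5) -> mean ~50, sd ~5."""
        from peatspec.community import PlotCommunity

        c = PlotCommunity("p", "minerotrophic", {"a": 50.0, "b": 50.0})
        rng = np.random.default_rng(1)
        counts = np.array(
            [gen_grid_observation(c, seed=rng).labels.count("a") for _ in range(5000)]
        )
        assert counts.mean() == pytest.approx(50.0, abs=0.3)
        assert counts.std() == pytest.approx(5.0, abs=0.3)

    def test_estimate_cover_unbiased_for_community(self):
        from peatspec.community import PlotCommunity

        c = PlotCommunity("p", "minerotrophic", {"a": 70.0, "b": 20.0, "c": 10.0})
        rng = np.random.default_rng(2)
        est = {"a": 0.0, "b": 0.0, "c": 0.0}
        n_rep = 3000
        for _ in range(n_rep):
            cov = estimate_cover(gen_grid_observation(c, seed=rng), "minerotrophic")
            for sp in est:
                est[sp] += cov.cover.get(sp, 0.0)
        for sp, truth in c.cover.items():
            p = truth / 100
            se_mean = 100 * math.sqrt(p * (1 - p) / 100) / math.sqrt(n_rep)
            assert abs(est[sp] / n_rep - truth) <= 3 * se_mean


class TestStudy:
    def test_end_to_end_smoke(self, small_study):
        assert len(small_study.communities) == 12
        assert len(small_study.plots) == 12
        assert set(small_study.diversity.columns) >= {"plot_id", "shannon", "simpson"}

    def test_determinism(self, small_study):
        again = gen_study(SimulationConfig(seed=7, n_plots=6))
        assert np.array_equal(
            small_study.plots.data.to_numpy(), again.plots.data.to_numpy()
        )
        for a, b in zip(small_study.grid_observations, again.grid_observations):
            assert a.labels == b.labels

    def test_fixture_files_regenerate_bit_identically(self, small_study):
        """The committed fixture CSVs equal a fresh regeneration from the
        recorded seed."""
        from peatspec.band_sim import gaussian_bandset, resample_library

        covers = pd.read_csv("tests/data/fixture_covers.csv", dtype={"plot_id": str})
        rows = [
            {"plot_id": c.plot_id, "species": sp, "cover_percent": f,
             "trophic_level": c.trophic_level}
            for c in small_study.communities
            for sp, f in c.cover.items()
        ]
        fresh = pd.DataFrame(rows)
        assert covers["plot_id"].tolist() == fresh["plot_id"].tolist()
        assert np.allclose(covers["cover_percent"], fresh["cover_percent"], atol=1e-9)

        bands = pd.read_csv("tests/data/fixture_plot_bands.csv")
        regenerated = resample_library(harmonize(small_study.plots), gaussian_bandset())
        assert np.allclose(
            bands.set_index("wavelength_nm").to_numpy(),
            regenerated.data.to_numpy(),
            atol=1e-9,
        )

    def test_noise_degrades_unmixing_monotonically(self):
        """Mean unmixing R2 decreases as rf noise grows (three levels)."""
        means = []
        for noise in (0.002, 0.01, 0.03):
            study = gen_study(SimulationConfig(seed=11, n_plots=25, noise_sd=noise))
            plots_h = harmonize(study.plots)
            em_h = harmonize(study.endmembers)
            r2 = []
            for level in ("minerotrophic", "ombrotrophic"):
                comms = study.communities_of(level)
                E = EndmemberSet.from_library(
                    em_h, sorted({sp for c in comms for sp in c.species}), level
                )
                ids = [c.plot_id for c in comms]
                res = unmix_trophic_level(plots_h.subset(ids), E, comms)
                r2.extend(res.per_species_metrics()["r2"].tolist())
            means.append(np.mean(r2))
        assert means[0] > means[1] > means[2]
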