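"""Synthetic peatland spectral studies for end-to-end testing.

Real endmember libraries and plot spectra live in external repositories;
this module generates stand-ins with the statistical structure the
analysis assumes, so every pipeline stage can be exercised without a
download.  The generative model is deliberately the one under which NNLS
unmixing is correctly specified:

    y(l) = sum_s (f_s / 100) * b_ps * E_s(l) + eps(l)

with per-plot-per-species brightness jitter ``b_ps ~ LogNormal(0, cv)``,
iid Gaussian noise ``eps``, and optionally a per-plot shade factor (an
unmodelled dark endmember) that post-hoc normalization must absorb.

Endmember templates are parametric reflectance curves with the
qualitative contrasts of real peatland vegetation — vascular plants with
a pronounced green peak and steep red edge, Sphagnum mosses flatter and
wetter (deeper water-absorption dips), litter brightening monotonically
through the visible with high SWIR reflectance.  All numeric parameter
values are synthetic: they mimic shapes, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, GenerationError
from .community import (
    ENDMEMBER_SPECIES,
    GridObservation,
    PlotCommunity,
    diversity_table,
)
from .spectral_io import SpectralLibrary, Spectrum

FULL_GRID = np.arange(350, 2501)


@dataclass(frozen=True)
class SpeciesSpectralParams:
    """Parameters of one species' parametric reflectance template.

    The template is a logistic red-edge step from ``vis_base`` up to
    ``nir_plateau``, plus a Gaussian green peak at 550 nm, a linear SWIR
    trend beyond 1300 nm, and two multiplicative water-absorption dips at
    1450 and 1940 nm whose depth scales with ``moisture``.
    """

    functional_type: str  # vascular | moss | litter
    vis_base: float
    green_peak_amp: float
    red_edge_inflection_nm: float
    red_edge_width_nm: float
    nir_plateau: float
    swir_slope: float  # rf change per 1000 nm beyond 1300 nm
    moisture: float  # in [0, 1]

    def __post_init__(self) -> None:
        if self.functional_type not in ("vascular", "moss", "litter"):
            raise ConfigError(f"unknown functional_type {self.functional_type!r}")
        if not 0.0 <= self.moisture <= 1.0:
            raise ConfigError("moisture must be in [0, 1]")

    def template(self, wavelengths: np.ndarray = FULL_GRID) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        green = self.green_peak_amp * np.exp(-0.5 * ((lam - 550.0) / 30.0) ** 2)
        edge = 1.0 / (
            1.0 + np.exp(-(lam - self.red_edge_inflection_nm) / self.red_edge_width_nm)
        )
        base = self.vis_base + green + (self.nir_plateau - self.vis_base) * edge
        base = base + np.where(
            lam > 1300.0, self.swir_slope * (lam - 1300.0) / 1000.0, 0.0
        )
        dips = self.moisture * (
            0.45 * np.exp(-0.5 * ((lam - 1450.0) / 45.0) ** 2)
            + 0.60 * np.exp(-0.5 * ((lam - 1940.0) / 55.0) ** 2)
        )
        rf = base * (1.0 - dips)
        if np.any(rf <= 0.0) or np.any(rf >= 1.0):
            raise GenerationError(
                "parameters produce reflectance outside (0, 1)"
            )
        return rf


def _vascular(vis, amp, infl, width, nir, moist) -> SpeciesSpectralParams:
    return SpeciesSpectralParams("vascular", vis, amp, infl, width, nir, -0.06, moist)


def _moss(vis, amp, infl, width, nir, moist) -> SpeciesSpectralParams:
    return SpeciesSpectralParams("moss", vis, amp, infl, width, nir, -0.05, moist)


#: Synthetic spectral parameters per endmember species.  Shapes follow the
#: field contrasts (herbaceous vascular > moss in green peak and red-edge
#: slope; the shrub Calluna litter-like; litter bright and dry) but every
#: number is invented.
DEFAULT_SPECIES_PARAMS: dict[str, SpeciesSpectralParams] = {
    # minerotrophic vasculars
    "Comarum palustre": _vascular(0.045, 0.100, 715, 18, 0.46, 0.45),
    "Filipendula ulmaria": _vascular(0.050, 0.120, 710, 16, 0.52, 0.40),
    "Menyanthes trifoliata": _vascular(0.040, 0.110, 720, 20, 0.48, 0.50),
    # ombrotrophic vasculars
    "Rubus chamaemorus": _vascular(0.048, 0.090, 712, 22, 0.44, 0.42),
    "Calluna vulgaris": _vascular(0.060, 0.060, 700, 30, 0.40, 0.30),
    # Sphagnum mosses: flatter, wetter
    "Sphagnum angustifolium": _moss(0.060, 0.042, 705, 45, 0.37, 0.80),
    "Sphagnum fallax": _moss(0.055, 0.038, 710, 50, 0.35, 0.85),
    "Sphagnum cuspidatum": _moss(0.050, 0.030, 715, 55, 0.32, 0.90),
    "Sphagnum fuscum": _moss(0.070, 0.035, 708, 48, 0.38, 0.75),
    "Sphagnum rubellum": _moss(0.075, 0.045, 706, 46, 0.39, 0.78),
    # dead Carex litter: monotone VIS-NIR rise, high and dry SWIR
    "Litter": SpeciesSpectralParams(
        "litter", 0.10, 0.0, 705, 140, 0.46, -0.02, 0.12
    ),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level knobs for the synthetic generator.

    Defaults emulate the field campaign's scale: ~60 1-m2 plots per
    trophic level, six candidate species per level, point-intercept grids
    of 100 cells, small additive sensor noise (rf units) and a few percent
    of multiplicative per-plot-per-species brightness variability.
    """

    seed: int = 0
    n_plots: int = 60
    species: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in ENDMEMBER_SPECIES.items()}
    )
    dirichlet_alpha: float = 0.6
    noise_sd: float = 0.002
    brightness_cv: float = 0.05
    shade_max: float = 0.0
    grid_points: int = 100
    min_cover_pct: float = 0.5  # draws below this are zeroed (species absent)

    def __post_init__(self) -> None:
        if self.dirichlet_alpha <= 0:
            raise ConfigError("dirichlet_alpha must be > 0")
        if self.noise_sd < 0 or self.brightness_cv < 0 or not 0 <= self.shade_max < 1:
            raise ConfigError("variability parameters out of range")


def gen_endmember_library(
    params: dict[str, SpeciesSpectralParams] | None = None,
    seed: int = 0,
    jitter_amp: float = 0.01,
) -> SpectralLibrary:
    """Endmember spectra on the full 350-2500 nm grid.

    Each species gets its parametric template plus a seeded, spectrally
    smooth perturbation (a handful of broad Gaussian bumps) so replicate
    libraries differ realistically.  Deterministic given the seed.
    """
    params = params or DEFAULT_SPECIES_PARAMS
    rng = np.random.default_rng(seed)
    lam = FULL_GRID.astype(float)
    spectra = []
    meta_rows = []
    level_of: dict[str, str] = {}
    for level, splist in ENDMEMBER_SPECIES.items():
        for sp in splist:
            level_of[sp] = "shared" if sp in level_of else level
    for sp, prm in params.items():
        rf = prm.template()
        centers = rng.uniform(400, 2400, size=8)
        amps = rng.normal(0.0, jitter_amp, size=8)
        for c, a in zip(centers, amps):
            rf = rf + a * np.exp(-0.5 * ((lam - c) / 180.0) ** 2)
        if np.any(rf <= 0.0) or np.any(rf >= 1.0):
            raise GenerationError(f"{sp}: jittered reflectance left (0, 1)")
        spectra.append(Spectrum(FULL_GRID, rf, quantity="CCRF", sample_id=sp))
        meta_rows.append(
            {
                "sample_id": sp,
                "role": "endmember",
                "species": sp,
                "trophic_level": level_of.get(sp, "shared"),
                "quantity": "CCRF",
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return SpectralLibrary.from_spectra(spectra, metadata=meta)


def gen_communities(
    cfg: SimulationConfig,
    trophic_level: str,
    rng: np.random.Generator | None = None,
) -> list[PlotCommunity]:
    """Per-plot covers drawn from a symmetric Dirichlet, with draws below
    ``min_cover_pct`` zeroed and the remainder renormalized to 100."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    species = list(cfg.species[trophic_level])
    prefix = trophic_level[:3]
    out = []
    for i in range(cfg.n_plots):
        raw = rng.dirichlet(np.full(len(species), cfg.dirichlet_alpha)) * 100.0
        draw = np.where(raw < cfg.min_cover_pct, 0.0, raw)
        if draw.sum() == 0.0:  # every draw tiny: keep the dominant species
            draw[int(np.argmax(raw))] = 1.0
        draw = draw / draw.sum() * 100.0
        cover = {sp: float(f) for sp, f in zip(species, draw)}
        out.append(PlotCommunity(f"{prefix}-{i:03d}", trophic_level, cover))
    return out


def gen_plot_spectrum(
    c: PlotCommunity,
    lib: SpectralLibrary,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """One mixed plot spectrum: linear mixture of the plot's species
    endmembers with brightness jitter, optional shade, and additive noise.
    Negative values (possible at high noise) are clamped at zero with a
    warning counter on the function (``gen_plot_spectrum.clamped``)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lam = lib.wavelengths_nm
    y = np.zeros(lam.size)
    for sp, f in c.cover.items():
        if f <= 0:
            continue
        if sp not in lib.data.columns:
            raise ConfigError(f"endmember {sp!r} missing from library")
        b = rng.lognormal(mean=0.0, sigma=cfg.brightness_cv) if cfg.brightness_cv > 0 else 1.0
        y += (f / 100.0) * b * lib.data[sp].to_numpy(dtype=float)
    if cfg.shade_max > 0:
        y *= 1.0 - rng.uniform(0.0, cfg.shade_max)
    if cfg.noise_sd > 0:
        y += rng.normal(0.0, cfg.noise_sd, size=lam.size)
    n_neg = int(np.sum(y < 0))
    if n_neg:
        gen_plot_spectrum.clamped += n_neg
        y = np.clip(y, 0.0, None)
    return Spectrum(lam, y, quantity="HCRF", sample_id=c.plot_id)


gen_plot_spectrum.clamped = 0  # running count of clamped negative samples


def gen_grid_observation(
    c: PlotCommunity,
    cfg: SimulationConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> GridObservation:
    """Point-intercept labels drawn iid multinomial with p = f_s/100."""
    cfg = cfg or SimulationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    species = list(c.cover.keys())
    p = np.array([c.cover[s] for s in species], dtype=float)
    p = p / p.sum()
    labels = [species[i] for i in rng.choice(len(species), size=cfg.grid_points, p=p)]
    return GridObservation(c.plot_id, labels)


@dataclass
class SyntheticStudy:
    """A complete two-trophic-level synthetic campaign."""

    config: SimulationConfig
    endmembers: SpectralLibrary  # full-grid endmember spectra
    plots: SpectralLibrary  # full-grid mixed plot spectra (both levels)
    communities: list[PlotCommunity]
    grid_observations: list[GridObservation]
    diversity: pd.DataFrame

    def communities_of(self, trophic_level: str) -> list[PlotCommunity]:
        return [c for c in self.communities if c.trophic_level == trophic_level]

    def plots_of(self, trophic_level: str) -> SpectralLibrary:
        meta = self.plots.metadata
        ids = [
            sid for sid in self.plots.sample_ids
            if meta.loc[sid, "trophic_level"] == trophic_level
        ]
        return self.plots.subset(ids)


def gen_study(cfg: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate the full synthetic study for both trophic levels.

    Everything derives from ``cfg.seed``: endmembers, covers, plot
    spectra and grid observations, so the study is reproducible
    bit-for-bit.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    endmembers = gen_endmember_library(seed=cfg.seed)
    communities: list[PlotCommunity] = []
    spectra: list[Spectrum] = []
    observations: list[GridObservation] = []
    meta_rows = []
    for level in sorted(cfg.species):
        comms = gen_communities(cfg, level, rng)
        communities.extend(comms)
        for c in comms:
            spectra.append(gen_plot_spectrum(c, endmembers, cfg, rng))
            observations.append(gen_grid_observation(c, cfg, rng))
            meta_rows.append(
                {
                    "sample_id": c.plot_id,
                    "role": "plot",
                    "plot_id": c.plot_id,
                    "trophic_level": level,
                    "quantity": "HCRF",
                }
            )
    plots = SpectralLibrary.from_spectra(
        spectra, metadata=pd.DataFrame(meta_rows).set_index("sample_id")
    )
    return SyntheticStudy(
        config=cfg,
        endmembers=endmembers,
        plots=plots,
        communities=communities,
        grid_observations=observations,
        diversity=diversity_table(communities),
    )
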