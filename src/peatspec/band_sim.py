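"""Simulation of multispectral sensor bands from hyperspectral spectra.

A hyperspectral spectrum is resampled to sensor bands by convolving it
with each band's spectral response function (SRF):

    band value = sum_l srf(l) * rf(l) / sum_l srf(l)

with the sums running over the wavelengths actually present in the
spectrum, i.e. the SRF is renormalized over the unmasked support.  This
convention preserves constant spectra even when a band partially overlaps
a masked region; a band whose support is entirely masked cannot be
simulated and raises an error naming it (the fate of the cirrus band B10,
which sits inside a water-absorption region).

The default band list is the Sentinel-2 MSI set used for vegetation work
at 10-20 m resolution: B2-B8a, B11 and B12 (B1 and B9 are 60 m bands, B10
is unsimulable on masked data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BandError, ConfigError, GridError
from .spectral_io import SpectralLibrary, Spectrum

#: Sentinel-2 MSI band centres (nm) for the bands simulated here.
SENTINEL2_BAND_CENTERS: dict[str, int] = {
    "B2": 490,
    "B3": 560,
    "B4": 665,
    "B5": 705,
    "B6": 740,
    "B7": 783,
    "B8": 842,
    "B8a": 865,
    "B11": 1610,
    "B12": 2190,
}

#: Approximate full widths at half maximum (nm) used by the synthetic
#: Gaussian SRF set.  These mimic the published MSI bandwidths but are not
#: the measured response curves; the real ESA S2-SRF export is a drop-in
#: replacement via ``load_srf``.
_SYNTHETIC_FWHM: dict[str, int] = {
    "B2": 65, "B3": 35, "B4": 30, "B5": 15, "B6": 15,
    "B7": 20, "B8": 115, "B8a": 20, "B11": 90, "B12": 180,
}


@dataclass(frozen=True)
class Band:
    name: str
    center_nm: int
    wavelengths_nm: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm)
        wt = np.asarray(self.weights, dtype=float)
        if np.any(wt < 0):
            raise ConfigError(f"band {self.name}: negative SRF weights")
        support = wt > 0
        if not support.any():
            raise ConfigError(f"band {self.name}: SRF has no positive weight")
        object.__setattr__(self, "wavelengths_nm", w[support].astype(int))
        object.__setattr__(self, "weights", wt[support])


@dataclass(frozen=True)
class BandSet:
    """An ordered collection of sensor bands with their SRFs."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ConfigError("band names must be unique")

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    @property
    def centers_nm(self) -> np.ndarray:
        return np.array([b.center_nm for b in self.bands])


def load_srf(path, band_names: list[str] | None = None) -> BandSet:
    """Load an SRF table (``wavelength_nm`` column + one column per band).

    This is the layout of the ESA S2-SRF spreadsheet export once saved as
    CSV.  Only the configured bands are kept; by default the 60-m bands
    B1/B9 and the unsimulable cirrus band B10 are dropped by simply not
    requesting them.
    """
    band_names = band_names or list(SENTINEL2_BAND_CENTERS)
    table = pd.read_csv(path)
    if "wavelength_nm" not in table.columns:
        raise GridError(f"{path}: missing 'wavelength_nm' column")
    missing = [b for b in band_names if b not in table.columns]
    if missing:
        raise ConfigError(f"{path}: requested bands absent from SRF table: {missing}")
    wl = table["wavelength_nm"].to_numpy()
    bands = []
    for name in band_names:
        weights = table[name].to_numpy(dtype=float)
        center = SENTINEL2_BAND_CENTERS.get(name)
        if center is None:
            support = weights > 0
            center = int(round(np.average(wl[support], weights=weights[support])))
        bands.append(Band(name, center, wl, weights))
    return BandSet(tuple(bands))


def gaussian_bandset(
    band_names: list[str] | None = None, truncate_sd: float = 4.0
) -> BandSet:
    """Synthetic Gaussian-SRF stand-in for the Sentinel-2 MSI responses.

    Band centres match the MSI bands; response shapes are Gaussians with
    FWHMs close to the published bandwidths.  Intended for tests and
    synthetic studies where the exact measured SRF curves are immaterial.
    """
    band_names = band_names or list(SENTINEL2_BAND_CENTERS)
    bands = []
    for name in band_names:
        if name not in SENTINEL2_BAND_CENTERS:
            raise ConfigError(f"no synthetic SRF defined for band {name!r}")
        center = SENTINEL2_BAND_CENTERS[name]
        sd = _SYNTHETIC_FWHM[name] / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        half = int(np.ceil(truncate_sd * sd))
        wl = np.arange(center - half, center + half + 1)
        weights = np.exp(-0.5 * ((wl - center) / sd) ** 2)
        bands.append(Band(name, center, wl, weights))
    return BandSet(tuple(bands))


def resample_to_bands(s: Spectrum, bs: BandSet) -> Spectrum:
    """Convolve a spectrum with each band's SRF (renormalized over the
    wavelengths present in the spectrum).

    Returns a ``SIMULATED`` spectrum whose grid is the band centres, in
    band-list order.
    """
    values = np.empty(len(bs.bands))
    for i, band in enumerate(bs.bands):
        _, idx_s, idx_b = np.intersect1d(
            s.wavelengths_nm, band.wavelengths_nm, return_indices=True
        )
        if idx_s.size == 0:
            raise BandError(
                f"band {band.name} cannot be simulated: its SRF support has "
                "no overlap with the spectrum's (masked) grid"
            )
        w = band.weights[idx_b]
        values[i] = np.dot(w, s.rf[idx_s]) / w.sum()
    return Spectrum(
        bs.centers_nm, values, quantity="SIMULATED", sample_id=s.sample_id
    )


def resample_library(lib: SpectralLibrary, bs: BandSet) -> SpectralLibrary:
    """Band-resample every spectrum in a library; metadata is carried over
    with ``quantity`` set to SIMULATED."""
    out = SpectralLibrary.from_spectra(
        (resample_to_bands(s, bs) for s in lib.spectra()), metadata=lib.metadata
    )
    out.metadata.loc[out.sample_ids, "quantity"] = "SIMULATED"
    return out
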