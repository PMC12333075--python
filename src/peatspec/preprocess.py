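"""Harmonization of field and laboratory reflectance spectra.

The harmonization chain is: segmented Savitzky-Golay smoothing (window
sizes tuned per spectral region, second-order polynomial), then removal of
the noisy UV edge and the atmospheric water-vapour absorption regions, and
— for leaf-level measurements — per-species averaging of adaxial-side
spectra.  Smoothing always precedes masking, so points inside a masked
band still influence the smoothed values near its edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import ConfigError, EmptySpectrumError
from .spectral_io import SpectralLibrary, Spectrum


@dataclass(frozen=True)
class Segment:
    """One smoothing segment: a closed wavelength interval with its window."""

    lo_nm: int
    hi_nm: int
    window_nm: int
    polyorder: int = 2

    def __post_init__(self) -> None:
        if self.lo_nm > self.hi_nm:
            raise ConfigError(f"segment bounds reversed: {self.lo_nm}-{self.hi_nm}")
        if self.window_nm % 2 == 0 or self.window_nm <= self.polyorder:
            raise ConfigError(
                f"window_nm must be odd and > polyorder, got {self.window_nm}"
            )


def _default_segments() -> list[Segment]:
    return [
        Segment(350, 1000, 15),
        Segment(1001, 2000, 39),
        Segment(2001, 2500, 75),
    ]


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky-Golay smoothing plan.

    Default windows (on the 1-nm grid, so nm and samples coincide):
    15 nm below 1000 nm, 39 nm in 1001-2000 nm, 75 nm in 2001-2500 nm,
    all with a second-order polynomial.  Wider SWIR windows compensate for
    the lower signal-to-noise of the InGaAs detectors there.
    """

    segments: tuple[Segment, ...] = field(default_factory=lambda: tuple(_default_segments()))

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.lo_nm)
        for a, b in zip(segs, segs[1:]):
            if b.lo_nm <= a.hi_nm:
                raise ConfigError(f"segments overlap: {a} and {b}")
        object.__setattr__(self, "segments", tuple(segs))


def _default_removed() -> list[tuple[int, int]]:
    return [(350, 399), (1330, 1549), (1761, 2024), (2311, 2500)]


@dataclass(frozen=True)
class MaskConfig:
    """Wavelength regions removed before analysis.

    Defaults drop the noisy 350-399 nm edge and the atmospheric water
    absorption regions 1330-1549, 1761-2024 and 2311-2500 nm, leaving the
    three analysis windows 400-1329, 1550-1760 and 2025-2310 nm.
    """

    removed_ranges_nm: tuple[tuple[int, int], ...] = field(
        default_factory=lambda: tuple(_default_removed())
    )

    def __post_init__(self) -> None:
        ranges = sorted(tuple(r) for r in self.removed_ranges_nm)
        for (lo, hi) in ranges:
            if lo > hi:
                raise ConfigError(f"mask interval reversed: {lo}-{hi}")
        for (_, hi), (lo2, _) in zip(ranges, ranges[1:]):
            if lo2 <= hi:
                raise ConfigError("mask intervals must be disjoint")
        object.__setattr__(self, "removed_ranges_nm", tuple(ranges))

    def keep_mask(self, wavelengths: np.ndarray) -> np.ndarray:
        keep = np.ones(wavelengths.shape, dtype=bool)
        for lo, hi in self.removed_ranges_nm:
            keep &= ~((wavelengths >= lo) & (wavelengths <= hi))
        return keep


def savitzky_golay_segmented(s: Spectrum, cfg: SmoothingConfig | None = None) -> Spectrum:
    """Smooth a spectrum segment by segment.

    Within each configured segment, each maximal run of contiguous 1-nm
    samples is filtered independently with ``scipy.signal.savgol_filter``
    (``mode="interp"``: edge values come from a polynomial fit to the last
    window, so polynomials up to the configured order are reproduced
    exactly, edges included).  Wavelengths outside every segment pass
    through unchanged.
    """
    cfg = cfg or SmoothingConfig()
    w = s.wavelengths_nm
    out = s.rf.copy()
    for seg in cfg.segments:
        sel = np.flatnonzero((w >= seg.lo_nm) & (w <= seg.hi_nm))
        if sel.size == 0:
            continue
        # split into contiguous 1-nm runs so gaps (e.g. already-masked
        # regions) are never filtered across
        breaks = np.flatnonzero(np.diff(w[sel]) != 1) + 1
        for run in np.split(sel, breaks):
            if run.size < seg.window_nm:
                raise ConfigError(
                    f"window {seg.window_nm} exceeds run length {run.size} "
                    f"in segment {seg.lo_nm}-{seg.hi_nm}"
                )
            out[run] = savgol_filter(
                s.rf[run], seg.window_nm, seg.polyorder, mode="interp"
            )
    return Spectrum(w, out, quantity=s.quantity, sample_id=s.sample_id)


def apply_mask(s: Spectrum, cfg: MaskConfig | None = None) -> Spectrum:
    """Drop wavelengths inside the removed ranges; retained rf values are
    passed through bit-identically."""
    cfg = cfg or MaskConfig()
    keep = cfg.keep_mask(s.wavelengths_nm)
    if not keep.any():
        raise EmptySpectrumError(f"mask removes every wavelength of {s.sample_id!r}")
    return Spectrum(
        s.wavelengths_nm[keep], s.rf[keep], quantity=s.quantity, sample_id=s.sample_id
    )


def average_species_spectra(
    lib: SpectralLibrary, group_key: str = "species"
) -> SpectralLibrary:
    """Average replicate spectra per species (arithmetic mean per wavelength).

    Returns one endmember spectrum per species, labelled by the species
    name.  Used to collapse adaxial leaf replicates to a single species
    reference.
    """
    groups = lib.metadata.loc[lib.sample_ids, group_key]
    if groups.isna().all():
        raise ConfigError(f"no {group_key!r} values in metadata to group on")
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for species, members in groups.groupby(groups):
        ids = list(members.index)
        cols[str(species)] = lib.data[ids].to_numpy(dtype=float).mean(axis=1)
        first = lib.metadata.loc[ids[0]]
        meta_rows.append(
            {
                "sample_id": str(species),
                "role": "endmember",
                "species": species,
                "trophic_level": first.get("trophic_level"),
                "quantity": first.get("quantity"),
            }
        )
    data = pd.DataFrame(cols, index=pd.Index(lib.wavelengths_nm, name="wavelength_nm"))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return SpectralLibrary(data, meta)


def harmonize(
    lib: SpectralLibrary,
    smooth_cfg: SmoothingConfig | None = None,
    mask_cfg: MaskConfig | None = None,
    average_by_species: bool = False,
) -> SpectralLibrary:
    """Full harmonization: smooth first, then mask, then (optionally)
    average leaf-level replicates per species.

    The smooth-then-mask order matters: structure inside a masked band
    still leaks into smoothed values within half a window of the band
    edge, which is the behaviour of smoothing the complete instrument
    record before discarding the noisy regions.
    """
    out = SpectralLibrary.from_spectra(
        (
            apply_mask(savitzky_golay_segmented(s, smooth_cfg), mask_cfg)
            for s in lib.spectra()
        ),
        metadata=lib.metadata,
    )
    if average_by_species:
        out = average_species_spectra(out)
    return out
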