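"""Containers and CSV I/O for reflectance spectral libraries.

A spectral library is a wide table: one ``wavelength_nm`` column plus one
column of reflectance factors (RF) per sample, paired with a sidecar
metadata table keyed by ``sample_id``.  All wavelength grids are integer
nanometres (the 1-nm grid that ASD field spectrometers interpolate to);
fractional grids are rejected unless interpolation is explicitly requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import GridError, MetadataError

#: Measurement geometries a spectrum may carry.  HCRF/DHRF/CCRF are the
#: hemispherical-conical, directional-hemispherical and conical-conical
#: reflectance factors; SIMULATED marks sensor-band resampled output.
QUANTITIES = ("HCRF", "DHRF", "CCRF", "SIMULATED")

METADATA_COLUMNS = ("role", "species", "plot_id", "trophic_level", "quantity")


def _validate_grid(wavelengths: np.ndarray) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size < 1:
        raise GridError("wavelength grid must be a non-empty 1-D sequence")
    if not np.all(np.diff(w) > 0):
        raise GridError("wavelengths must be strictly increasing")
    if not np.allclose(w, np.round(w)):
        raise GridError(
            "wavelength grid must be integer nm; pass interpolate=True to "
            "resample a fractional grid"
        )
    return np.round(w).astype(int)


@dataclass
class Spectrum:
    """A single reflectance-factor spectrum on an integer-nm grid.

    Parameters
    ----------
    wavelengths_nm : sequence of int
        Strictly increasing wavelengths in nanometres.
    rf : sequence of float
        Reflectance factor per wavelength (unitless; nominally 0–1, values
        slightly above 1 can occur for bright targets).
    quantity : str
        One of ``HCRF``, ``DHRF``, ``CCRF``, ``SIMULATED``.
    sample_id : str
        Opaque sample label.
    """

    wavelengths_nm: np.ndarray
    rf: np.ndarray
    quantity: str = "HCRF"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.wavelengths_nm = _validate_grid(self.wavelengths_nm)
        self.rf = np.asarray(self.rf, dtype=float)
        if self.rf.ndim != 1 or self.rf.size != self.wavelengths_nm.size:
            raise GridError("rf and wavelengths must have equal length >= 1")
        if np.any(~np.isfinite(self.rf)):
            raise GridError("rf contains missing or non-finite values")
        if self.quantity not in QUANTITIES:
            raise MetadataError(f"unknown quantity {self.quantity!r}")
        if np.any(self.rf < 0) or np.any(self.rf > 1.5):
            # measured RF can legitimately exceed 1; clamping would hide
            # instrument problems, so we only warn
            warnings.warn(
                f"spectrum {self.sample_id!r}: rf outside [0, 1.5]",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)


@dataclass
class SpectralLibrary:
    """A set of spectra sharing one wavelength grid, plus sample metadata.

    ``data`` is indexed by wavelength (nm) with one column per sample;
    ``metadata`` is indexed by ``sample_id`` with columns
    ``role`` (endmember|plot), ``species``, ``plot_id``, ``trophic_level``
    and ``quantity``.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1:
            raise MetadataError("library must contain at least one sample")
        grid = _validate_grid(self.data.index.to_numpy())
        self.data = self.data.copy()
        self.data.index = pd.Index(grid, name="wavelength_nm")
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(self.data.columns, name="sample_id"))
        self.metadata = self.metadata.copy()
        if self.metadata.index.name != "sample_id" and "sample_id" in self.metadata.columns:
            self.metadata = self.metadata.set_index("sample_id")
        self.metadata.index.name = "sample_id"
        if self.metadata.index.has_duplicates:
            dups = self.metadata.index[self.metadata.index.duplicated()].tolist()
            raise MetadataError(f"duplicated sample_id in metadata: {dups}")
        if pd.Index(self.data.columns).has_duplicates:
            raise MetadataError("duplicated sample column in spectra table")
        missing = [c for c in self.data.columns if c not in self.metadata.index]
        if missing:
            raise MetadataError(f"samples absent from metadata: {missing}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                self.metadata[col] = pd.NA
        if np.any(~np.isfinite(self.data.to_numpy(dtype=float))):
            raise GridError("library contains missing or non-finite rf values")

    # -- accessors ---------------------------------------------------------

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return self.data.shape[1]

    def get(self, sample_id: str) -> Spectrum:
        if sample_id not in self.data.columns:
            raise MetadataError(f"unknown sample {sample_id!r}")
        quantity = self.metadata.loc[sample_id, "quantity"]
        if pd.isna(quantity):
            quantity = "HCRF"
        return Spectrum(
            self.wavelengths_nm,
            self.data[sample_id].to_numpy(dtype=float),
            quantity=str(quantity),
            sample_id=sample_id,
        )

    def spectra(self) -> Iterator[Spectrum]:
        for sid in self.data.columns:
            yield self.get(sid)

    def subset(self, sample_ids: Sequence[str]) -> "SpectralLibrary":
        ids = list(sample_ids)
        return SpectralLibrary(self.data[ids], self.metadata.loc[ids])

    @classmethod
    def from_spectra(
        cls, spectra: Iterable[Spectrum], metadata: pd.DataFrame | None = None
    ) -> "SpectralLibrary":
        spectra = list(spectra)
        if not spectra:
            raise MetadataError("cannot build a library from zero spectra")
        grid = spectra[0].wavelengths_nm
        cols = {}
        quantities = {}
        for s in spectra:
            if not np.array_equal(s.wavelengths_nm, grid):
                raise GridError(f"spectrum {s.sample_id!r} is not on the shared grid")
            if s.sample_id in cols:
                raise MetadataError(f"duplicated sample_id {s.sample_id!r}")
            cols[s.sample_id] = s.rf
            quantities[s.sample_id] = s.quantity
        data = pd.DataFrame(cols, index=pd.Index(grid, name="wavelength_nm"))
        if metadata is None:
            metadata = pd.DataFrame(index=pd.Index(data.columns, name="sample_id"))
        lib = cls(data, metadata)
        for sid, q in quantities.items():
            if pd.isna(lib.metadata.loc[sid, "quantity"]):
                lib.metadata.loc[sid, "quantity"] = q
        return lib


# -- operations -------------------------------------------------------------


def read_spectral_library(path, metadata_path) -> SpectralLibrary:
    """Read a wide spectra CSV plus its sidecar metadata CSV.

    The first column of ``path`` must be ``wavelength_nm``; each remaining
    column is one sample.  ``metadata_path`` must contain a ``sample_id``
    column covering every sample column.
    """
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise MetadataError(f"{path}: expected a wavelength column plus >=1 sample column")
    if table.columns[0] != "wavelength_nm":
        raise GridError(f"{path}: first column must be 'wavelength_nm', got {table.columns[0]!r}")
    data = table.set_index("wavelength_nm")
    meta = pd.read_csv(metadata_path, dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise MetadataError(f"{metadata_path}: missing 'sample_id' column")
    meta = meta.set_index("sample_id")
    data.columns = data.columns.astype(str)
    return SpectralLibrary(data, meta)


def write_spectral_library(lib: SpectralLibrary, path, metadata_path) -> None:
    """Write a library to the wide-CSV + metadata-CSV dialect.

    Round-trip guarantee: ``read_spectral_library`` on the written files
    reproduces wavelengths exactly and rf to <= 1e-9 absolute.
    """
    if len(lib) == 0:
        raise MetadataError("refusing to write an empty library")
    lib.data.reset_index().to_csv(path, index=False, float_format="%.12g")
    lib.metadata.reset_index().to_csv(metadata_path, index=False)


def align_to_common_grid(
    libs: Sequence[SpectralLibrary], interpolate: bool = False
) -> SpectralLibrary:
    """Merge libraries onto the intersection of their wavelength grids.

    By default spectra are restricted (rows dropped) to the common grid;
    with ``interpolate=True`` each library is linearly interpolated onto
    the intersection *range* at 1-nm steps first.
    """
    libs = list(libs)
    if not libs:
        raise MetadataError("no libraries to align")
    grids = [lib.wavelengths_nm for lib in libs]
    if interpolate:
        lo = max(g.min() for g in grids)
        hi = min(g.max() for g in grids)
        if lo > hi:
            raise GridError("wavelength ranges do not overlap")
        common = np.arange(lo, hi + 1)
        frames = []
        for lib in libs:
            interp = {
                c: np.interp(common, lib.wavelengths_nm, lib.data[c].to_numpy(dtype=float))
                for c in lib.data.columns
            }
            frames.append(pd.DataFrame(interp, index=pd.Index(common, name="wavelength_nm")))
    else:
        common = grids[0]
        for g in grids[1:]:
            common = np.intersect1d(common, g)
        if common.size == 0:
            raise GridError("wavelength grids have empty intersection")
        frames = [lib.data.loc[common] for lib in libs]
    data = pd.concat(frames, axis=1)
    if pd.Index(data.columns).has_duplicates:
        raise MetadataError("sample_id collision between libraries")
    meta = pd.concat([lib.metadata for lib in libs], axis=0)
    return SpectralLibrary(data, meta)
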