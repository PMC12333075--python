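"""Goodness-of-fit metrics and per-wavelength regression profiles.

Two distinct R-squared conventions are in play and must not be mixed:

* ``fit_metrics`` evaluates predictions against observations with
  R2 = 1 - SSres/SStot.  This can be negative (a model worse than the
  mean), which is exactly what happens for several species in spectral
  unmixing.
* ``wavelength_r2_profile`` reports the R2 of a *fitted* simple linear
  regression of reflectance on cover at each wavelength, which equals the
  squared Pearson correlation and lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, PeatspecError
from .community import PlotCommunity
from .spectral_io import SpectralLibrary


@dataclass(frozen=True)
class FitMetrics:
    """Prediction accuracy: R2 (may be negative), RMSE and bias.

    ``bias = mean(predicted - observed)``: a positive bias means the model
    over-predicts.
    """

    r2: float
    rmse: float
    bias: float
    n: int


def fit_metrics(observed, predicted, allow_constant: bool = False) -> FitMetrics:
    """Standard accuracy metrics on paired observed/predicted vectors.

    R2 = 1 - sum (o-p)^2 / sum (o-mean o)^2; rmse = sqrt(mean (o-p)^2);
    bias = mean(p-o).  A constant observed vector makes R2 undefined: this
    raises unless ``allow_constant`` is set, in which case R2 is NaN and
    rmse/bias are still returned.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1 or o.size == 0:
        raise ConfigError("observed and predicted must be equal-length 1-D vectors")
    resid = o - p
    rmse = float(np.sqrt(np.mean(resid**2)))
    bias = float(np.mean(p - o))
    sstot = float(np.sum((o - o.mean()) ** 2))
    if sstot == 0.0:
        if not allow_constant:
            raise PeatspecError(
                "observed values have zero variance: R2 is undefined "
                "(pass allow_constant=True to get NaN)"
            )
        r2 = float("nan")
    else:
        r2 = float(1.0 - np.sum(resid**2) / sstot)
    return FitMetrics(r2=r2, rmse=rmse, bias=bias, n=o.size)


@dataclass
class WavelengthR2Profile:
    """Per-wavelength explanatory power of one species' fractional cover."""

    species: str
    table: pd.DataFrame  # columns: wavelength_nm, r2
    best_r2: float
    best_wavelength_nm: int


def wavelength_r2_profile(
    communities: list[PlotCommunity],
    plots: SpectralLibrary,
    species: str,
    occupied_only: bool = False,
) -> WavelengthR2Profile:
    """R2 profile of the simple linear regression rf(lambda) ~ cover.

    At every retained wavelength an ordinary least-squares line of the
    plot reflectance on the species' fractional cover is fitted across
    plots; its R2 is the squared Pearson correlation.  By default all
    plots of the trophic level enter (plots without the species contribute
    cover 0); ``occupied_only`` restricts to plots where the species
    occurs.
    """
    by_plot = {c.plot_id: c for c in communities}
    plot_ids = [pid for pid in plots.sample_ids if pid in by_plot]
    if len(plot_ids) < 3:
        raise ConfigError("need at least 3 plots with both spectra and covers")
    cover = np.array(
        [by_plot[pid].cover.get(species, 0.0) for pid in plot_ids], dtype=float
    )
    if occupied_only:
        sel = cover > 0
        plot_ids = [pid for pid, s in zip(plot_ids, sel) if s]
        cover = cover[sel]
        if cover.size < 3:
            raise ConfigError(f"fewer than 3 plots contain {species!r}")
    if np.var(cover) == 0:
        raise PeatspecError(
            f"cover of {species!r} has zero variance across plots"
        )
    rf = plots.data[plot_ids].to_numpy(dtype=float)  # (n_wl, n_plots)
    x = cover - cover.mean()
    y = rf - rf.mean(axis=1, keepdims=True)
    sxy = y @ x
    sxx = float(x @ x)
    syy = np.sum(y * y, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, (sxy**2) / (sxx * syy), 0.0)
    table = pd.DataFrame({"wavelength_nm": plots.wavelengths_nm, "r2": r2})
    best = int(np.argmax(r2))
    return WavelengthR2Profile(
        species=species,
        table=table,
        best_r2=float(r2[best]),
        best_wavelength_nm=int(plots.wavelengths_nm[best]),
    )
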