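"""Linear spectral unmixing of plot spectra against species endmembers.

The mixing model is linear: an observed plot spectrum is approximated as
a non-negative combination of the endmember spectra of its trophic level,

    a_raw = argmin_{a >= 0} || E a - y ||_2   (Lawson-Hanson NNLS),

with no intercept and no sum-to-one constraint inside the solver.  The
raw coefficients are normalized post hoc (a_norm = a_raw / sum a_raw) and
interpreted as fractional abundances; (plot, species) pairs whose
*observed* cover is zero are dropped from the evaluation set, since
predicted-vs-observed accuracy per species is judged over the plots where
the species actually occurs.

A fully constrained variant (sum-to-one enforced inside the solver, FCLS)
is available for comparison but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .errors import ConfigError, GridError
from .community import PlotCommunity
from .evaluation import FitMetrics, fit_metrics
from .spectral_io import SpectralLibrary, Spectrum


@dataclass
class EndmemberSet:
    """Wavelength-aligned endmember matrix for one trophic level.

    ``E`` has one column per species, rows on the shared wavelength grid
    (1427 rows for harmonized hyperspectral data, 10 for simulated
    multispectral bands).
    """

    trophic_level: str
    species: list[str]
    wavelengths_nm: np.ndarray
    E: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm)
        if self.E.ndim != 2 or self.E.shape[1] != len(self.species):
            raise ConfigError("E must be (n_wavelengths, n_species)")
        if self.E.shape[1] < 1:
            raise ConfigError("need at least one endmember")
        if self.E.shape[0] != self.wavelengths_nm.size:
            raise GridError("E rows must match the wavelength grid")
        if np.any(np.all(self.E == 0, axis=0)):
            raise ConfigError("endmember matrix contains an all-zero column")

    @classmethod
    def from_library(
        cls,
        lib: SpectralLibrary,
        species: list[str],
        trophic_level: str = "",
    ) -> "EndmemberSet":
        """Build the matrix from a harmonized endmember library whose
        sample ids (or ``species`` metadata) name the species."""
        ids = []
        for sp in species:
            if sp in lib.data.columns:
                ids.append(sp)
            else:
                match = lib.metadata.index[lib.metadata["species"] == sp].tolist()
                if not match:
                    raise ConfigError(f"endmember {sp!r} absent from library")
                ids.append(match[0])
        return cls(
            trophic_level=trophic_level,
            species=list(species),
            wavelengths_nm=lib.wavelengths_nm,
            E=lib.data[ids].to_numpy(dtype=float),
        )


@dataclass
class UnmixResult:
    """Per-(plot, species) abundance estimates paired with observed covers.

    ``table`` columns: plot_id, species, a_raw, a_norm, predicted_pct,
    observed_pct, dropped (True where the observed cover is zero and the
    pair is excluded from evaluation).  ``residuals`` maps plot_id to the
    NNLS residual norm; ``excluded_plots`` lists plots whose raw
    coefficients were all zero.
    """

    trophic_level: str
    table: pd.DataFrame
    residuals: dict[str, float] = field(default_factory=dict)
    excluded_plots: list[str] = field(default_factory=list)

    def evaluation_pairs(self, species: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(observed, predicted) percent covers after zero-removal."""
        t = self.table[~self.table["dropped"]]
        if species is not None:
            t = t[t["species"] == species]
        return (
            t["observed_pct"].to_numpy(dtype=float),
            t["predicted_pct"].to_numpy(dtype=float),
        )

    def per_species_metrics(self, min_pairs: int = 2) -> pd.DataFrame:
        """R2/RMSE/bias per species over its evaluation pairs (percent)."""
        rows = []
        for sp in sorted(self.table["species"].unique()):
            obs, pred = self.evaluation_pairs(sp)
            if obs.size < min_pairs or np.var(obs) == 0:
                continue
            m = fit_metrics(obs, pred)
            rows.append(
                {"species": sp, "r2": m.r2, "rmse": m.rmse, "bias": m.bias, "n": m.n}
            )
        return pd.DataFrame(rows)

    def overall_metrics(self) -> FitMetrics:
        obs, pred = self.evaluation_pairs()
        return fit_metrics(obs, pred)


def select_endmembers(
    communities: list[PlotCommunity],
    min_plots: int = 5,
    min_cover_pct: float = 5.0,
    cover_statistic: str = "max",
) -> list[str]:
    """Choose endmember species by abundance across a trophic level.

    A species is *excluded* only when it is rare on both axes: present in
    fewer than ``min_plots`` plots AND with cover below ``min_cover_pct``
    percent in the plots where it occurs (litter counts as a species).
    ``cover_statistic`` selects whether "cover in these plots" is judged
    by the max (default, inclusion-favouring) or the mean over occupied
    plots.
    """
    if not communities:
        raise ConfigError("no communities to select endmembers from")
    if cover_statistic not in ("max", "mean"):
        raise ConfigError(f"unknown cover_statistic {cover_statistic!r}")
    stats: dict[str, list[float]] = {}
    for c in communities:
        for sp, f in c.cover.items():
            if f > 0:
                stats.setdefault(sp, []).append(f)
    selected = []
    for sp in sorted(stats):
        covers = stats[sp]
        stat = max(covers) if cover_statistic == "max" else float(np.mean(covers))
        rare = (len(covers) < min_plots) and (stat < min_cover_pct)
        if not rare:
            selected.append(sp)
    return selected


def nnls_solve(E: EndmemberSet, y: Spectrum) -> np.ndarray:
    """Non-negative least squares abundance of one plot spectrum.

    Solves ``argmin_{a>=0} ||E a - y||`` with the Lawson-Hanson active-set
    algorithm.  No intercept; no sum-to-one constraint.
    """
    if len(y) == 0:
        raise GridError("zero-length spectrum")
    if not np.array_equal(np.asarray(E.wavelengths_nm), y.wavelengths_nm):
        raise GridError(
            f"grid mismatch: endmembers have {E.wavelengths_nm.size} "
            f"wavelengths, spectrum {y.sample_id!r} has {y.wavelengths_nm.size}"
        )
    a, _ = scipy.optimize.nnls(E.E, y.rf)
    return a


def fcls_solve(E: EndmemberSet, y: Spectrum, delta: float = 1e4) -> np.ndarray:
    """Fully constrained variant: abundances >= 0 and summing to one,
    enforced by the standard augmented-row trick with weight ``delta``."""
    if not np.array_equal(np.asarray(E.wavelengths_nm), y.wavelengths_nm):
        raise GridError("grid mismatch between endmembers and spectrum")
    scale = max(np.abs(E.E).max(), 1.0)
    A = np.vstack([E.E / scale, delta * np.ones(E.E.shape[1])])
    b = np.concatenate([y.rf / scale, [delta]])
    a, _ = scipy.optimize.nnls(A, b)
    return a


def normalize_and_filter(
    raw: dict[str, np.ndarray],
    communities: list[PlotCommunity],
    species: list[str],
    trophic_level: str = "",
    residuals: dict[str, float] | None = None,
    drop: str = "observed_zero",
) -> UnmixResult:
    """Normalize raw coefficients and apply the zero-removal rule.

    ``a_norm = a_raw / sum(a_raw)`` per plot; plots with all-zero raw
    coefficients are flagged and excluded.  Then pairs with zero
    *observed* cover (default) or zero *predicted* cover
    (``drop="predicted_zero"``) are marked dropped: they stay in the table
    for inspection but are excluded from evaluation metrics.
    """
    if drop not in ("observed_zero", "predicted_zero"):
        raise ConfigError(f"unknown drop rule {drop!r}")
    by_plot = {c.plot_id: c for c in communities}
    rows = []
    excluded = []
    for plot_id, a_raw in raw.items():
        if plot_id not in by_plot:
            raise ConfigError(f"no observed community for plot {plot_id!r}")
        a_raw = np.asarray(a_raw, dtype=float)
        if a_raw.size != len(species):
            raise ConfigError(f"plot {plot_id!r}: coefficient length mismatch")
        total = a_raw.sum()
        if total <= 0:
            excluded.append(plot_id)
            continue
        a_norm = a_raw / total
        obs = by_plot[plot_id]
        for sp, ar, an in zip(species, a_raw, a_norm):
            f_obs = float(obs.cover.get(sp, 0.0))
            pred_pct = 100.0 * an
            dropped = (f_obs == 0.0) if drop == "observed_zero" else (pred_pct == 0.0)
            rows.append(
                {
                    "plot_id": plot_id,
                    "species": sp,
                    "a_raw": ar,
                    "a_norm": an,
                    "predicted_pct": pred_pct,
                    "observed_pct": f_obs,
                    "dropped": dropped,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "plot_id", "species", "a_raw", "a_norm",
            "predicted_pct", "observed_pct", "dropped",
        ],
    )
    return UnmixResult(
        trophic_level=trophic_level,
        table=table,
        residuals=residuals or {},
        excluded_plots=excluded,
    )


def unmix_trophic_level(
    plots: SpectralLibrary,
    E: EndmemberSet,
    communities: list[PlotCommunity],
    drop: str = "observed_zero",
    constrained: bool = False,
) -> UnmixResult:
    """Unmix every plot of one trophic level against its endmember set.

    Plot spectra and endmembers must already be harmonized on the same
    grid — either hyperspectral or band-simulated; the contract is
    identical for both.
    """
    solver = fcls_solve if constrained else nnls_solve
    raw: dict[str, np.ndarray] = {}
    residuals: dict[str, float] = {}
    for s in plots.spectra():
        a = solver(E, s)
        raw[s.sample_id] = a
        residuals[s.sample_id] = float(np.linalg.norm(E.E @ a - s.rf))
    return normalize_and_filter(
        raw,
        communities,
        species=E.species,
        trophic_level=E.trophic_level,
        residuals=residuals,
        drop=drop,
    )
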