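"""Point-intercept cover estimation and alpha-diversity indices.

Fractional cover is estimated from a square sampling frame overlaid with a
regular grid (default 1 m x 1 m at 10 cm spacing, i.e. 100 cells); the
species at each cell centre is recorded and per-species cover is the
percentage of cells occupied.  Exactly one species is recorded per cell,
so covers partition the plot and sum to 100.

Alpha-diversity follows the community-ecology conventions: Shannon-Wiener
H = -sum p ln p (natural log by default) and Simpson D = 1 - sum p^2,
computed from the relative covers p_s = f_s / sum f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, PeatspecError

#: The endmember species of the two trophic-level unmixing models: the
#: five most abundant plants of each peatland type plus litter, which is
#: common to both.  Minerotrophic (fen) plots are vascular-dominated,
#: ombrotrophic (bog) plots are Sphagnum-dominated.
MINEROTROPHIC_ENDMEMBER_SPECIES: tuple[str, ...] = (
    "Comarum palustre",
    "Filipendula ulmaria",
    "Litter",
    "Menyanthes trifoliata",
    "Sphagnum angustifolium",
    "Sphagnum fallax",
)
OMBROTROPHIC_ENDMEMBER_SPECIES: tuple[str, ...] = (
    "Calluna vulgaris",
    "Litter",
    "Rubus chamaemorus",
    "Sphagnum cuspidatum",
    "Sphagnum fuscum",
    "Sphagnum rubellum",
)
ENDMEMBER_SPECIES: dict[str, tuple[str, ...]] = {
    "minerotrophic": MINEROTROPHIC_ENDMEMBER_SPECIES,
    "ombrotrophic": OMBROTROPHIC_ENDMEMBER_SPECIES,
}


@dataclass
class PlotCommunity:
    """Species -> percent cover for one vegetation plot.

    Covers are percentages in [0, 100] and must sum to 100 (one species
    per grid point implies the covers partition the plot).
    """

    plot_id: str
    trophic_level: str
    cover: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, f in self.cover.items():
            if f < 0:
                raise ConfigError(f"plot {self.plot_id}: negative cover for {sp}")
        total = sum(self.cover.values())
        if abs(total - 100.0) > 1e-9:
            raise ConfigError(
                f"plot {self.plot_id}: covers sum to {total}, expected 100"
            )

    @property
    def species(self) -> list[str]:
        return [s for s, f in self.cover.items() if f > 0]

    @property
    def richness(self) -> int:
        return len(self.species)

    def proportions(self) -> np.ndarray:
        f = np.array([v for v in self.cover.values() if v > 0], dtype=float)
        return f / f.sum()


@dataclass
class GridObservation:
    """The raw point-intercept record: one species label per grid cell."""

    plot_id: str
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ConfigError(f"plot {self.plot_id}: no grid labels")


@dataclass
class DiversityRecord:
    plot_id: str
    shannon: float
    simpson: float


def make_grid(frame_m: float = 1.0, spacing_m: float = 0.1) -> list[tuple[float, float]]:
    """Cell-centre coordinates of a square point-intercept grid.

    A ``frame_m`` x ``frame_m`` frame divided at ``spacing_m`` gives
    ``(frame_m/spacing_m)**2`` cells with centres at ``(i+0.5)*spacing_m``;
    the defaults (1 m, 10 cm) give the standard 100-cell grid.
    """
    n = frame_m / spacing_m
    if abs(n - round(n)) > 1e-9:
        raise ConfigError(
            f"frame {frame_m} m is not divisible by spacing {spacing_m} m"
        )
    n = int(round(n))
    return [
        ((i + 0.5) * spacing_m, (j + 0.5) * spacing_m)
        for j in range(n)
        for i in range(n)
    ]


def estimate_cover(g: GridObservation, trophic_level: str) -> PlotCommunity:
    """Percent cover per species from the grid labels:
    f_s = 100 * count(s) / n_cells."""
    n = len(g.labels)
    counts: dict[str, int] = {}
    for lab in g.labels:
        counts[lab] = counts.get(lab, 0) + 1
    cover = {s: 100.0 * c / n for s, c in counts.items()}
    return PlotCommunity(g.plot_id, trophic_level, cover)


def _proportions(c: PlotCommunity) -> np.ndarray:
    total = sum(c.cover.values())
    if total <= 0:
        raise PeatspecError(f"plot {c.plot_id}: all covers are zero")
    return c.proportions()


def shannon_index(c: PlotCommunity, base: float | None = None) -> float:
    """Shannon-Wiener index H = -sum p ln p (nats unless ``base`` given)."""
    p = _proportions(c)
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def simpson_index(c: PlotCommunity) -> float:
    """Simpson index in the complement form D = 1 - sum p^2, in [0, 1)."""
    p = _proportions(c)
    return float(1.0 - (p * p).sum())


def diversity_record(c: PlotCommunity, base: float | None = None) -> DiversityRecord:
    return DiversityRecord(c.plot_id, shannon_index(c, base=base), simpson_index(c))


def diversity_table(
    communities: list[PlotCommunity], base: float | None = None
) -> pd.DataFrame:
    """Per-plot diversity indices as a tidy table."""
    return pd.DataFrame(
        {
            "plot_id": [c.plot_id for c in communities],
            "trophic_level": [c.trophic_level for c in communities],
            "richness": [c.richness for c in communities],
            "shannon": [shannon_index(c, base=base) for c in communities],
            "simpson": [simpson_index(c) for c in communities],
        }
    )


# -- CSV plumbing -----------------------------------------------------------


def read_communities(path) -> list[PlotCommunity]:
    """Read a long-format cover CSV
    (plot_id, species, cover_percent, trophic_level)."""
    table = pd.read_csv(path, dtype={"plot_id": str})
    required = {"plot_id", "species", "cover_percent", "trophic_level"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (plot_id, level), grp in table.groupby(["plot_id", "trophic_level"], sort=False):
        cover = dict(zip(grp["species"], grp["cover_percent"].astype(float)))
        out.append(PlotCommunity(str(plot_id), str(level), cover))
    return out


def write_communities(communities: list[PlotCommunity], path) -> None:
    rows = [
        {
            "plot_id": c.plot_id,
            "species": sp,
            "cover_percent": f,
            "trophic_level": c.trophic_level,
        }
        for c in communities
        for sp, f in c.cover.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_grid_observations(path) -> list[GridObservation]:
    """Read a grid-observation CSV (plot_id, cell_index, species)."""
    table = pd.read_csv(path, dtype={"plot_id": str})
    out = []
    for plot_id, grp in table.groupby("plot_id", sort=False):
        grp = grp.sort_values("cell_index")
        out.append(GridObservation(str(plot_id), grp["species"].tolist()))
    return out


def write_grid_observations(observations: list[GridObservation], path) -> None:
    rows = [
        {"plot_id": g.plot_id, "cell_index": i, "species": lab}
        for g in observations
        for i, lab in enumerate(g.labels)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
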