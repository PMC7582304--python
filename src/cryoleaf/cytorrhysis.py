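"""Freezing-cytorrhysis morphometry from 2-D cell outlines.

When extracellular ice withdraws water from walled cells, the cells
cave in reversibly (freezing cytorrhysis).  The extent is quantified
from traced cell outlines at the middle focal plane: the cell area (CA)
of each cell at a freezing temperature is related to its own unfrozen
(+20 °C) baseline, giving a CA share.  Palisade cells are approximately
cylindrical and shrink in diameter but hardly in length, so principal-
axis extents separate the two; for volume interpretation a cylinder
model converts diameter and length shares into a volume reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon

from cryoleaf.errors import DataError, GeometryError, ParameterError

TISSUES = ("palisade", "spongy")
STATES = ("baseline", "frozen", "thawed")

#: densities used for the water→ice expansion figure, kg m⁻³
WATER_DENSITY = 999.84  # liquid water at 0 °C
ICE_DENSITY = 916.7  # ice Ih at 0 °C


@dataclass(frozen=True)
class CellOutline:
    """One traced cell outline (polygon vertices in µm)."""

    cell_id: str
    tissue: str
    temperature: float
    state: str
    vertices: tuple

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise DataError(f"unknown tissue {self.tissue!r}")
        if self.state not in STATES:
            raise DataError(f"unknown state {self.state!r}")
        object.__setattr__(self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices))

    def polygon(self) -> Polygon:
        if len(self.vertices) < 3:
            raise GeometryError(f"cell {self.cell_id!r}: outline needs >= 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area == 0:
            raise GeometryError(f"cell {self.cell_id!r}: outline is not a simple polygon")
        return poly


@dataclass(frozen=True)
class CAShare:
    """Cell area at a freezing temperature relative to the +20 °C baseline."""

    cell_id: str
    tissue: str
    temperature: float
    share: float

    def __post_init__(self) -> None:
        if self.share <= 0:
            raise DataError("CA share must be positive")


def polygon_area(outline: CellOutline) -> float:
    """Absolute enclosed area in µm², independent of vertex orientation."""
    return float(outline.polygon().area)


def ca_share(frozen: CellOutline, baseline: CellOutline) -> CAShare:
    """CA share = area(frozen) / area(baseline) for the same cell."""
    if frozen.cell_id != baseline.cell_id:
        raise DataError(f"outline pair mismatch: {frozen.cell_id!r} vs {baseline.cell_id!r}")
    if baseline.state != "baseline":
        raise DataError("baseline outline must have state 'baseline'")
    return CAShare(
        cell_id=frozen.cell_id,
        tissue=frozen.tissue,
        temperature=frozen.temperature,
        share=polygon_area(frozen) / polygon_area(baseline),
    )


def tissue_summary(shares: Sequence[CAShare], temp_cutoff_c: float = -3.0) -> pd.DataFrame:
    """Mean ± SD of CA shares per tissue at temperatures below the cutoff.

    Only shares measured strictly below ``temp_cutoff_c`` enter; tissues
    with fewer than two qualifying shares are omitted.
    """
    rows = [s for s in shares if s.temperature < temp_cutoff_c]
    out = []
    for tissue in TISSUES:
        vals = np.array([s.share for s in rows if s.tissue == tissue])
        if len(vals) < 2:
            continue
        out.append(
            {
                "tissue": tissue,
                "n": len(vals),
                "mean_share": float(vals.mean()),
                "sd_share": float(vals.std(ddof=1)),
            }
        )
    return pd.DataFrame(out, columns=["tissue", "n", "mean_share", "sd_share"])


def compare_tissues(shares: Sequence[CAShare]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of palisade vs spongy CA shares.

    Uses the exact null distribution for combined n ≤ 30 without ties,
    an exact permutation distribution for small tied samples, and the
    normal approximation with tie correction otherwise.  Returns
    (Mann–Whitney U statistic, two-sided p).
    """
    x = np.array([s.share for s in shares if s.tissue == "palisade"])
    y = np.array([s.share for s in shares if s.tissue == "spongy"])
    if len(x) == 0 or len(y) == 0:
        raise DataError("both tissues must be represented")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    n = len(pooled)
    if not has_ties and n <= 30:
        method = "exact"
    elif has_ties and n <= 12:
        method = stats.PermutationMethod(n_resamples=200_000)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cylinder_volume_reduction(d_share: float, l_share: float = 1.0) -> float:
    """Percent volume reduction of a cylinder whose diameter and length
    shrink to ``d_share`` and ``l_share`` of their initial values.

    V share = d_share² · l_share, so the reduction is
    100 · (1 − d_share² · l_share).  A moss leaf cell whose diameter
    drops to 43% of its initial value (length unchanged) loses
    100 · (1 − 0.43²) ≈ 82% of its volume.
    """
    if not (0 < d_share <= 1) or not (0 < l_share <= 1):
        raise ParameterError("shares must lie in (0, 1]")
    return 100.0 * (1.0 - d_share**2 * l_share)


def water_ice_expansion(rho_water: float = WATER_DENSITY, rho_ice: float = ICE_DENSITY) -> float:
    """Percent volume increase on freezing, from mass conservation:
    100 · (ρ_water / ρ_ice − 1) ≈ 9% for standard densities at 0 °C."""
    if rho_water <= 0 or rho_ice <= 0:
        raise ParameterError("densities must be positive")
    return 100.0 * (rho_water / rho_ice - 1.0)


def _principal_extents(vertices) -> tuple[float, float]:
    """(major, minor) extents of a vertex set along its principal axes."""
    pts = np.asarray(vertices, dtype=float)
    pts = pts - pts.mean(axis=0)
    # principal directions of the vertex scatter
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    proj = pts @ vt.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    return float(np.max(extents)), float(np.min(extents))


def dimension_bias(frozen: CellOutline, baseline: CellOutline) -> tuple[float, float]:
    """(diameter_share, length_share) of a palisade cell.

    Length is the extent along the major principal axis of the outline
    vertices, diameter the extent along the minor axis; shares are
    frozen relative to baseline.  Diameter-biased shrinkage gives a
    diameter share well below 1 with a length share near 1.
    """
    if frozen.tissue != "palisade" or baseline.tissue != "palisade":
        raise DataError("dimension bias is defined for palisade (cylindrical) cells")
    if frozen.cell_id != baseline.cell_id:
        raise DataError("outline pair mismatch")
    len_f, dia_f = _principal_extents(frozen.vertices)
    len_b, dia_b = _principal_extents(baseline.vertices)
    return dia_f / dia_b, len_f / len_b


def read_outlines(path) -> list[CellOutline]:
    """Read an outline CSV (cell_id, tissue, state, temperature_c,
    vertex_index, x_um, y_um) into :class:`CellOutline` objects."""
    df = pd.read_csv(path, dtype={"cell_id": str})
    required = {"cell_id", "tissue", "state", "temperature_c", "vertex_index", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"outline CSV missing columns {sorted(missing)}")
    outlines = []
    for (cell_id, state, temp), grp in df.groupby(["cell_id", "state", "temperature_c"], sort=True):
        grp = grp.sort_values("vertex_index")
        outlines.append(
            CellOutline(
                cell_id=cell_id,
                tissue=grp["tissue"].iloc[0],
                temperature=float(temp),
                state=state,
                vertices=list(zip(grp["x_um"], grp["y_um"])),
            )
        )
    return outlines


def write_outlines(outlines: Sequence[CellOutline], path) -> None:
    rows = []
    for o in outlines:
        for i, (x, y) in enumerate(o.vertices):
            rows.append(
                {
                    "cell_id": o.cell_id,
                    "tissue": o.tissue,
                    "state": o.state,
                    "temperature_c": o.temperature,
                    "vertex_index": i,
                    "x_um": x,
                    "y_um": y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
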