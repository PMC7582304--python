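"""Boltzmann viability curves and resampled LT50 estimation.

Frost damage assays expose sets of leaves to a series of subzero target
temperatures and read out viability as the maximum quantum yield of
photosystem II, Fv/Fm.  Viability follows a sigmoid of temperature,
modelled by the Boltzmann function

    Fv/Fm(T) = (vmin − vmax) / (1 + exp((T − LT50) / dx)) + vmax

whose inflection point LT50 is the temperature at which half the
response is lost — the median lethal temperature.  The LT50 estimator
repeatedly subsamples 4 yield values per treatment temperature, refits
the curve, and reports the mean ± SD of the per-replicate LT50 values
(250 replicates), which propagates within-temperature spread into an
uncertainty on LT50.

Gas-exchange normalization for the freeze after-effect experiment is
included: assimilation and dark respiration are divided by the
diffusive conductance to water vapour (GH2O) to remove stomatal
aperture effects, then referenced to each leaf's pre-treatment value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from cryoleaf.errors import DataError, ParameterError

REQUIRED_ASSAY_COLUMNS = ("leaf_id", "treatment_temp_c", "fvfm")


@dataclass(frozen=True)
class BoltzmannParams:
    """Parameters of the Boltzmann viability curve.

    vmin, vmax
        Lower and upper asymptotes in Fv/Fm units (vmax > vmin).
    lt50
        Temperature of the inflection point, °C.
    dx
        Slope factor, °C (> 0; smaller = steeper transition).
    """

    vmin: float
    vmax: float
    lt50: float
    dx: float

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ParameterError("slope factor dx must be positive")
        if not self.vmax > self.vmin:
            raise ParameterError("vmax must exceed vmin")


@dataclass
class BoltzmannFit:
    """Result of one curve fit; ``converged`` is False for degenerate data."""

    params: BoltzmannParams | None
    converged: bool
    message: str = ""
    rss: float = np.nan


@dataclass
class LT50Estimate:
    """Resampled LT50: mean ± SD over converged replicate fits."""

    mean: float
    sd: float
    n_reps: int
    n_converged: int
    per_rep_lt50: list[float] = field(default_factory=list)


def boltzmann(T, params: BoltzmannParams):
    """Evaluate the Boltzmann viability curve at temperature(s) ``T`` (°C).

    Monotonically increasing in T and bounded by [vmin, vmax]; at
    T = LT50 the value is the midpoint (vmin + vmax) / 2.
    """
    T = np.asarray(T, dtype=float)
    val = (params.vmin - params.vmax) / (1.0 + np.exp((T - params.lt50) / params.dx)) + params.vmax
    return float(val) if val.ndim == 0 else val


def _validate_assay(data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_ASSAY_COLUMNS if c not in data.columns]
    if missing:
        raise DataError(f"assay table missing columns {missing}")
    if data["treatment_temp_c"].nunique() < 2:
        raise DataError("assay needs at least two distinct treatment temperatures")
    return data


def fit_boltzmann(data: pd.DataFrame) -> BoltzmannFit:
    """Least-squares Boltzmann fit to an assay table.

    Initialization follows the data: vmax from the warmest temperature's
    mean yield, vmin from the coldest, LT50 from the temperature whose
    mean yield is nearest the midpoint, dx from half the temperature
    step.  Degenerate data (no transition) and optimizer failures are
    reported as ``converged=False`` rather than raised, so that
    resampling replicates can drop them.
    """
    data = _validate_assay(data)
    T = data["treatment_temp_c"].to_numpy(dtype=float)
    y = data["fvfm"].to_numpy(dtype=float)
    if len(T) < 4:
        return BoltzmannFit(None, False, "fewer than 4 points")

    means = data.groupby("treatment_temp_c")["fvfm"].mean()
    temps = means.index.to_numpy(dtype=float)
    vmax0 = float(means.loc[temps.max()])
    vmin0 = float(means.loc[temps.min()])
    if not vmax0 > vmin0 + 1e-9:
        return BoltzmannFit(None, False, "no transition in data")
    mid = 0.5 * (vmin0 + vmax0)
    lt50_0 = float(temps[np.argmin(np.abs(means.to_numpy() - mid))])
    steps = np.diff(np.sort(temps))
    dx0 = max(float(np.median(steps)) / 2.0, 1e-3)

    def model(t, vmin, vmax, lt50, dx):
        return (vmin - vmax) / (1.0 + np.exp((t - lt50) / dx)) + vmax

    try:
        popt, _ = curve_fit(
            model,
            T,
            y,
            p0=[vmin0, vmax0, lt50_0, dx0],
            bounds=([-np.inf, -np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        return BoltzmannFit(None, False, f"optimizer failure: {exc}")

    vmin, vmax, lt50, dx = (float(v) for v in popt)
    if not vmax > vmin:
        return BoltzmannFit(None, False, "degenerate fit: vmax <= vmin")
    params = BoltzmannParams(vmin=vmin, vmax=vmax, lt50=lt50, dx=dx)
    rss = float(np.sum((model(T, *popt) - y) ** 2))
    return BoltzmannFit(params, True, "converged", rss)


def resampled_lt50(
    data: pd.DataFrame,
    k_per_temp: int = 4,
    n_reps: int = 250,
    seed: int = 0,
    with_replacement: bool = False,
) -> LT50Estimate:
    """LT50 by repeated subsampling: draw ``k_per_temp`` yields per
    temperature, fit, repeat ``n_reps`` times, aggregate converged fits.

    Rows are sorted by (temperature, leaf_id) before drawing, so the
    estimate is invariant to input row order for a fixed seed.
    """
    data = _validate_assay(data)
    counts = data.groupby("treatment_temp_c")["fvfm"].count()
    short = counts[counts < k_per_temp]
    if len(short):
        raise DataError(
            f"temperatures with fewer than {k_per_temp} values: {list(short.index)}"
        )
    canon = data.sort_values(["treatment_temp_c", "leaf_id"], kind="mergesort").reset_index(drop=True)
    groups = [grp for _, grp in canon.groupby("treatment_temp_c", sort=True)]

    rng = np.random.default_rng(seed)
    per_rep: list[float] = []
    n_converged = 0
    for _ in range(n_reps):
        parts = []
        for grp in groups:
            idx = rng.choice(len(grp), size=k_per_temp, replace=with_replacement)
            parts.append(grp.iloc[idx])
        fit = fit_boltzmann(pd.concat(parts, ignore_index=True))
        if fit.converged:
            n_converged += 1
            per_rep.append(fit.params.lt50)
    if n_converged == 0:
        return LT50Estimate(np.nan, np.nan, n_reps, 0, [])
    arr = np.asarray(per_rep)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return LT50Estimate(float(arr.mean()), sd, n_reps, n_converged, per_rep)


def normalize_gas_exchange(records: pd.DataFrame) -> pd.DataFrame:
    """Conductance-normalized, baseline-relative gas exchange.

    For each leaf, A/GH2O and Rd/GH2O at every phase are divided by the
    leaf's pre-treatment ('before') value, so the before phase is 1 by
    construction and after-phases express the retained fraction.

    Expects columns leaf_id, phase ('before', '1h_after', '1d_after'),
    treatment, A, Rd, gh2o; gh2o must be positive.
    """
    required = {"leaf_id", "phase", "A", "Rd", "gh2o"}
    missing = required - set(records.columns)
    if missing:
        raise DataError(f"gas-exchange table missing columns {sorted(missing)}")
    if (records["gh2o"] <= 0).any():
        raise DataError("gh2o must be positive for normalization")

    df = records.copy()
    df["a_per_g"] = df["A"] / df["gh2o"]
    df["rd_per_g"] = df["Rd"] / df["gh2o"]

    base = df[df["phase"] == "before"].set_index("leaf_id")
    rows = []
    for leaf_id, grp in df.groupby("leaf_id"):
        if leaf_id not in base.index:
            raise DataError(f"leaf {leaf_id!r} has no 'before' baseline record")
        b = base.loc[leaf_id]
        for _, row in grp.iterrows():
            rows.append(
                {
                    "leaf_id": leaf_id,
                    "phase": row["phase"],
                    "treatment": row.get("treatment"),
                    "a_rel": row["a_per_g"] / b["a_per_g"],
                    "rd_rel": row["rd_per_g"] / b["rd_per_g"],
                }
            )
    return pd.DataFrame(rows)
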