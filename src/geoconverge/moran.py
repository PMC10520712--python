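"""Global and local Moran's I spatial autocorrelation statistics.

Global Moran's I for a cross-section x over weight matrix W is

    I = sum_ij w_ij (x_i - xbar)(x_j - xbar) / (S^2 * sum_ij w_ij),
    S^2 = (1/n) sum_i (x_i - xbar)^2.

Its expectation under no spatial autocorrelation is -1/(n-1); inference
uses the moments of I under random permutation of x (the randomization
assumption) and a one-sided upper-tail normal p-value, matching the
positive-clustering hypothesis.  The local statistic
I_i = ((x_i - xbar)/S^2) * sum_j w_ij (x_j - xbar) attributes the global
association to single regions and classifies each into a Moran-scatter
quadrant (HH/LH/LL/HL) by the signs of its own deviation and its
neighbours' weighted deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .weights import SpatialWeights


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p: float
    n: int
    year: object = None


@dataclass
class LocalMoranResult:
    """Per-region local Moran statistics and quadrant labels.

    ``scale`` records the proportionality constant between sum_i I_i and
    the global I: sum_i I_i = I * sum_ij w_ij.
    """

    table: pd.DataFrame  # region, I_i, z_own, lag, quadrant
    scale: float


def _validate(x: np.ndarray, w: SpatialWeights) -> None:
    if len(x) != w.n:
        raise ValueError("x length does not match weight matrix")
    if w.n < 3:
        raise ValueError("need at least 3 regions")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: x is constant")
    if w.matrix.sum() == 0:
        raise ValueError("all-zero weight matrix")


def global_moran(x, w: SpatialWeights, year=None) -> MoranResult:
    """Global Moran's I with randomization-assumption z/p inference."""
    x = np.asarray(x, dtype=float)
    _validate(x, w)
    m = w.matrix
    n = w.n
    d = x - x.mean()
    s2 = (d**2).mean()
    w0 = m.sum()
    stat = float(d @ m @ d / (s2 * w0))
    expected = -1.0 / (n - 1)

    # permutation moments (randomization assumption)
    s1 = 0.5 * ((m + m.T) ** 2).sum()
    s2w = ((m.sum(axis=1) + m.sum(axis=0)) ** 2).sum()
    b2 = n * (d**4).sum() / (d**2).sum() ** 2
    if n > 3:
        num = n * ((n**2 - 3 * n + 3) * s1 - n * s2w + 3 * w0**2) - b2 * (
            (n**2 - n) * s1 - 2 * n * s2w + 6 * w0**2
        )
        den = (n - 1) * (n - 2) * (n - 3) * w0**2
        variance = num / den - expected**2
    else:
        warnings.warn("randomization variance undefined for n = 3", stacklevel=2)
        variance = np.nan
    if variance > 0:
        z = (stat - expected) / np.sqrt(variance)
        p = float(stats.norm.sf(z))
    else:
        z, p = np.nan, np.nan
    return MoranResult(I=stat, expected=expected, variance=float(variance), z=float(z), p=p, n=n, year=year)


def local_moran(x, w: SpatialWeights) -> LocalMoranResult:
    """Local Moran's I_i with HH/LH/LL/HL quadrant classification.

    Quadrants use the signs of the own deviation and the weighted
    neighbour deviation (the spatial lag of deviations); a deviation or
    lag of exactly 0 is classed as 'low'.
    """
    x = np.asarray(x, dtype=float)
    _validate(x, w)
    d = x - x.mean()
    s2 = (d**2).mean()
    lag = w.matrix @ d
    ii = d / s2 * lag
    own_high = d > 0
    lag_high = lag > 0
    quadrant = np.where(
        own_high & lag_high, "HH", np.where(~own_high & lag_high, "LH", np.where(~own_high & ~lag_high, "LL", "HL"))
    )
    table = pd.DataFrame(
        {
            "region": list(w.region_order),
            "I_i": ii,
            "z_own": d / np.sqrt(s2),
            "lag": lag,
            "quadrant": quadrant,
        }
    )
    return LocalMoranResult(table=table, scale=float(w.matrix.sum()))


def moran_by_year(panel: pd.DataFrame, variable: str, w: SpatialWeights) -> pd.DataFrame:
    """One global Moran's I row per year (year, I, z, p), in year order."""
    if variable not in panel.columns:
        raise KeyError(f"variable {variable!r} absent from panel")
    rows = []
    for year in sorted(panel["year"].unique()):
        sub = panel.loc[panel["year"] == year].set_index("region")[variable]
        try:
            x = sub.loc[list(w.region_order)].to_numpy(dtype=float)
        except KeyError as exc:
            raise ValueError(f"year {year}: panel does not cover all regions") from exc
        try:
            res = global_moran(x, w, year=year)
        except ValueError as exc:
            raise ValueError(f"year {year}: {exc}") from exc
        rows.append({"year": year, "I": res.I, "z": res.z, "p": res.p})
    return pd.DataFrame(rows)
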