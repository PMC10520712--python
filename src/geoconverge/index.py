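"""Composite index construction: polarity-aware min-max standardization and
entropy weighting.

The public-health index aggregates life expectancy (positive polarity) with
perinatal and maternal mortality (negative polarity).  Each indicator is
first mapped to [0, 1] by a linear min-max transform computed within each
year (default) or over the pooled panel; the entropy-weight method then
assigns each indicator a weight proportional to its information divergence
1 - e_j, where e_j is the normalized Shannon entropy of the indicator's
cross-observation proportions.  The composite is the weighted sum, which
stays in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ID_COLS = ("region", "year")


@dataclass(frozen=True)
class IndicatorSpec:
    """Name, polarity ('positive' or 'negative') and units of one indicator."""

    name: str
    polarity: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be 'positive' or 'negative', got {self.polarity!r}")


@dataclass
class EntropyWeights:
    """Per-indicator weights with the entropies and divergences behind them."""

    weights: pd.Series
    entropies: pd.Series
    divergences: pd.Series

    def __post_init__(self) -> None:
        if (self.weights < -1e-12).any():
            raise ValueError("weights must be nonnegative")
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def _check_no_missing(panel: pd.DataFrame, cols: list[str]) -> None:
    sub = panel[list(ID_COLS) + cols]
    if sub[cols].isna().any().any():
        mask = sub[cols].isna()
        r, c = np.argwhere(mask.to_numpy())[0]
        row = sub.iloc[r]
        raise ValueError(
            f"missing value in indicator {cols[c]!r} at region={row['region']!r}, "
            f"year={row['year']!r}"
        )


def standardize(
    panel: pd.DataFrame,
    specs: list[IndicatorSpec],
    scope: str = "per_year",
) -> pd.DataFrame:
    """Min-max standardize indicator columns to [0, 1], respecting polarity.

    Positive indicators map their minimum to 0 and maximum to 1
    (p = (y - min) / (max - min)); negative indicators are reversed
    (p = (max - y) / (max - min)).  With ``scope='per_year'`` the extrema
    are taken across regions within each year; ``'pooled'`` uses the whole
    panel.  A degenerate group (max == min) maps to the midpoint 0.5 with
    a warning.

    Returns a tidy frame with the same ``region``/``year`` keys and the
    standardized indicator columns.
    """
    if scope not in ("per_year", "pooled"):
        raise ValueError("scope must be 'per_year' or 'pooled'")
    cols = [s.name for s in specs]
    missing_cols = [c for c in cols if c not in panel.columns]
    if missing_cols:
        raise KeyError(f"indicators absent from panel: {missing_cols}")
    _check_no_missing(panel, cols)

    out = panel[list(ID_COLS)].copy()
    group_key = panel["year"] if scope == "per_year" else pd.Series(0, index=panel.index)
    for spec in specs:
        y = panel[spec.name].astype(float)
        gmin = y.groupby(group_key).transform("min")
        gmax = y.groupby(group_key).transform("max")
        span = gmax - gmin
        degenerate = span == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            if spec.polarity == "positive":
                p = (y - gmin) / span
            else:
                p = (gmax - y) / span
        if degenerate.any():
            warnings.warn(
                f"indicator {spec.name!r}: {int(degenerate.sum())} observation(s) in "
                "degenerate (constant) groups set to 0.5",
                stacklevel=2,
            )
            p = p.where(~degenerate, 0.5)
        out[spec.name] = p
    return out


def entropy_weights(
    std: pd.DataFrame,
    columns: list[str] | None = None,
    shift: float = 0.0,
) -> EntropyWeights:
    """Entropy-method weights over pooled standardized observations.

    For indicator j with standardized values p_ij over all N observations:
    proportions q_ij = p_ij / sum_i p_ij, entropy
    e_j = -(1/ln N) * sum_i q_ij ln q_ij (with 0*ln 0 := 0), divergence
    d_j = 1 - e_j, and weight w_j = d_j / sum_j d_j.  An indicator constant
    across observations carries no information and gets weight 0.  ``shift``
    optionally adds a constant to every value before forming proportions
    (the common p + eps variant); the default applies no shift.
    """
    if columns is None:
        columns = [c for c in std.columns if c not in ID_COLS]
    if not columns:
        raise ValueError("no indicator columns")
    vals = std[columns].to_numpy(dtype=float) + shift
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if (vals < 0).any():
        raise ValueError("standardized values (after shift) must be nonnegative")
    n_obs = vals.shape[0]
    k = 1.0 / np.log(n_obs)

    entropies = np.empty(len(columns))
    for j in range(len(columns)):
        col = vals[:, j]
        s = col.sum()
        if s == 0 or np.ptp(col) == 0:
            # constant column: no discriminating information
            entropies[j] = 1.0
            continue
        q = col / s
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(q > 0, q * np.log(q), 0.0)
        entropies[j] = -k * terms.sum()
    divergences = 1.0 - entropies
    divergences = np.clip(divergences, 0.0, None)  # guard tiny negative round-off
    total = divergences.sum()
    if total <= 0:
        raise ValueError("no discriminating information: all indicators constant")
    weights = divergences / total
    idx = pd.Index(columns, name="indicator")
    return EntropyWeights(
        weights=pd.Series(weights, index=idx, name="weight"),
        entropies=pd.Series(entropies, index=idx, name="entropy"),
        divergences=pd.Series(divergences, index=idx, name="divergence"),
    )


def composite_index(
    std: pd.DataFrame,
    w: EntropyWeights,
    name: str = "health",
) -> pd.DataFrame:
    """Weighted sum of standardized indicators, one value per region-year."""
    cols = list(w.weights.index)
    missing = [c for c in cols if c not in std.columns]
    if missing:
        raise ValueError(f"weight/indicator mismatch, absent columns: {missing}")
    out = std[list(ID_COLS)].copy()
    out[name] = std[cols].to_numpy(dtype=float) @ w.weights.to_numpy()
    return out
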