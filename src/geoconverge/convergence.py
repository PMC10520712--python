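"""Healthcare-industry convergence scoring by coupling coordination degree.

Each industry's development level U is an entropy-weighted composite of
three pooled-standardized indicators: employment and fixed-asset
investment (inputs) and output (GDP or persons served).  For the focal
healthcare industry H0 and each partner industry Hk, the coupling degree

    C = 2 * sqrt(U1 * U2) / (U1 + U2)        (C = 0 when U1 + U2 = 0)

measures how balanced the two subsystems are (C = 1 iff U1 = U2 > 0, by
AM-GM), the coordination level T = alpha*U1 + (1-alpha)*U2 measures their
joint size, and the coupling coordination degree D = sqrt(C * T) in [0, 1]
is the pairwise convergence score.  The overall healthcare-industry
convergence degree (HICD) per region-year synthesizes the pairwise D
columns, by entropy weighting (default) or a plain mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .index import ID_COLS, EntropyWeights, IndicatorSpec, composite_index, entropy_weights, standardize

INDUSTRY_INDICATORS = ("employment", "investment", "output")


@dataclass
class ConvergenceResult:
    """Pairwise coupling-coordination degrees and the synthesized HICD."""

    pairwise_D: pd.DataFrame  # region, year, D_<partner> columns
    overall: pd.DataFrame  # region, year, hicd
    synthesis_weights: pd.Series


def development_level(
    industry_panel: pd.DataFrame,
    industry: str,
    indicators: tuple[str, ...] = INDUSTRY_INDICATORS,
) -> pd.DataFrame:
    """Entropy-weighted development level U in [0, 1] for one industry.

    ``industry_panel`` is tidy with columns region, year, industry and the
    indicator columns.  All three indicators are positive-polarity and
    standardized over the industry's pooled region-year observations.
    """
    sub = industry_panel.loc[industry_panel["industry"] == industry]
    if sub.empty:
        raise KeyError(f"industry {industry!r} absent from panel")
    if (sub[list(indicators)].to_numpy(dtype=float) < 0).any():
        raise ValueError("industry indicators must be nonnegative")
    specs = [IndicatorSpec(name=c, polarity="positive") for c in indicators]
    std = standardize(sub, specs, scope="pooled")
    w = entropy_weights(std, columns=list(indicators))
    out = composite_index(std, w, name="U")
    return out.reset_index(drop=True)


def coupling_coordination(u1, u2, alpha: float = 0.5):
    """Coupling degree C, coordination level T and degree D = sqrt(C*T).

    ``u1`` and ``u2`` are development levels in [0, 1] (scalars or arrays);
    ``alpha`` weights the first subsystem's contribution to T.
    Returns (C, T, D) with the same shape as the inputs.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if (u1 < -1e-12).any() or (u1 > 1 + 1e-12).any() or (u2 < -1e-12).any() or (u2 > 1 + 1e-12).any():
        raise ValueError("development levels must lie in [0, 1]")
    s = u1 + u2
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(s > 0, 2.0 * np.sqrt(np.clip(u1 * u2, 0, None)) / np.where(s > 0, s, 1.0), 0.0)
    # C <= 1 by AM-GM; clip the tiny overshoot subnormal products can cause
    c = np.clip(c, 0.0, 1.0)
    t = alpha * u1 + (1 - alpha) * u2
    d = np.sqrt(np.clip(c * t, 0, None))
    return c, t, d


def pairwise_convergence(
    industry_panel: pd.DataFrame,
    focal: str = "H0",
    partners: list[str] | None = None,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Coupling-coordination degree between the focal industry and each partner.

    Development levels are computed per industry separately (each industry's
    three indicators get their own pooled standardization and entropy
    weights).  Returns a tidy frame region, year, D_<partner>...
    """
    if partners is None:
        partners = sorted(
            set(industry_panel["industry"].unique()) - {focal},
            key=lambda s: (len(s), s),
        )
    if not partners:
        raise ValueError("no partner industries")
    u_focal = development_level(industry_panel, focal).set_index(list(ID_COLS))["U"]
    out = None
    for p in partners:
        u_p = development_level(industry_panel, p).set_index(list(ID_COLS))["U"]
        joined = pd.concat([u_focal.rename("u1"), u_p.rename("u2")], axis=1)
        if joined.isna().any().any():
            raise ValueError(f"industries {focal!r} and {p!r} cover different region-years")
        _, _, d = coupling_coordination(joined["u1"].to_numpy(), joined["u2"].to_numpy(), alpha)
        col = pd.Series(d, index=joined.index, name=f"D_{p}")
        out = col.to_frame() if out is None else out.join(col)
    return out.reset_index()


def synthesize_hicd(
    pairwise_d: pd.DataFrame,
    method: str = "entropy",
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthesize pairwise D columns into one overall HICD per region-year.

    ``method='entropy'`` treats the pairwise-D columns as positive
    indicators and entropy-weights them; ``'mean'`` averages them equally.
    Returns (frame with region, year, hicd; synthesis weights).
    """
    d_cols = [c for c in pairwise_d.columns if c not in ID_COLS]
    if not d_cols:
        raise ValueError("empty pairwise block")
    if method == "mean":
        weights = pd.Series(1.0 / len(d_cols), index=pd.Index(d_cols, name="indicator"))
    elif method == "entropy":
        try:
            weights = entropy_weights(pairwise_d, columns=d_cols).weights
        except ValueError:
            # all columns constant: fall back to equal weights (any convex
            # combination returns the common value)
            weights = pd.Series(1.0 / len(d_cols), index=pd.Index(d_cols, name="indicator"))
    else:
        raise ValueError("method must be 'entropy' or 'mean'")
    out = pairwise_d[list(ID_COLS)].copy()
    out["hicd"] = pairwise_d[d_cols].to_numpy(dtype=float) @ weights.to_numpy()
    return out, weights


def convergence_analysis(
    industry_panel: pd.DataFrame,
    focal: str = "H0",
    partners: list[str] | None = None,
    alpha: float = 0.5,
    method: str = "entropy",
) -> ConvergenceResult:
    """Full pairwise-then-synthesis convergence scoring."""
    pw = pairwise_convergence(industry_panel, focal=focal, partners=partners, alpha=alpha)
    overall, w = synthesize_hicd(pw, method=method)
    return ConvergenceResult(pairwise_D=pw, overall=overall, synthesis_weights=w)
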