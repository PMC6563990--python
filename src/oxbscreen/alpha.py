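"""Sensitivity of the screening calls to the intensity offset alpha.

delta_beta(alpha) is a ratio of quantities linear in alpha, so its zero
condition

    M_BS * (U_oxBS + alpha) = M_oxBS * (U_BS + alpha)

is linear in alpha and the measure can change sign at most once on
alpha in (0, inf).  Solving gives the closed-form critical offset

    alpha* = (M_oxBS * T_BS - M_BS * T_oxBS) / (M_BS - M_oxBS),   T = M + U,

valid when M_BS != M_oxBS and alpha* > 0.  A probe with a finite alpha* is
flagged as hydroxymethylated for offsets on one side of alpha* and not on the
other -- the screening outcome depends on an essentially arbitrary constant.

As alpha grows, delta_beta(alpha) ~ (M_BS - M_oxBS) / alpha -> 0,
delta_m(alpha) -> delta_m_inf = log2(M_BS / M_oxBS), and the positive call
set {delta_beta(alpha) > 0} converges to {M_BS > M_oxBS} once alpha exceeds
every finite critical offset in the panel.  ``limit_diagnostics`` quantifies
all three statements on a grid of alphas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measures import delta_beta, delta_m, delta_m_inf
from .panel import IntensityPanel

__all__ = [
    "critical_alpha",
    "critical_alpha_panel",
    "sign_change_fraction",
    "default_alpha_grid",
    "limit_diagnostics",
    "AlphaScanResult",
]


def critical_alpha(M_bs, U_bs, M_oxbs, U_oxbs):
    """Offset alpha* at which delta_beta(alpha) crosses zero, or NaN if none.

    Returns ``(alpha_star, degenerate)``: ``alpha_star`` is NaN where no sign
    change exists on alpha in (0, inf); ``degenerate`` is True where
    delta_beta is identically zero for every alpha (M_BS == M_oxBS and equal
    totals, which includes all-zero intensities).  Scalar inputs yield scalar
    outputs.
    """
    scalar = np.isscalar(M_bs) and np.isscalar(U_bs) and np.isscalar(M_oxbs) and np.isscalar(U_oxbs)
    M_bs = np.asarray(M_bs, dtype=float)
    U_bs = np.asarray(U_bs, dtype=float)
    M_oxbs = np.asarray(M_oxbs, dtype=float)
    U_oxbs = np.asarray(U_oxbs, dtype=float)
    t_bs = M_bs + U_bs
    t_oxbs = M_oxbs + U_oxbs
    diff = M_bs - M_oxbs
    with np.errstate(divide="ignore", invalid="ignore"):
        astar = (M_oxbs * t_bs - M_bs * t_oxbs) / diff
    degenerate = (diff == 0) & (t_bs == t_oxbs)
    valid = (diff != 0) & np.isfinite(astar) & (astar > 0)
    astar = np.where(valid, astar, np.nan)
    if scalar:
        return float(astar), bool(degenerate)
    return astar, degenerate


def critical_alpha_panel(panel: IntensityPanel) -> tuple[np.ndarray, np.ndarray]:
    """Per-entry critical alpha and degeneracy flags; masked entries are NaN."""
    astar, degenerate = critical_alpha(panel.M_bs, panel.U_bs, panel.M_oxbs, panel.U_oxbs)
    astar = np.where(panel.mask, astar, np.nan)
    degenerate = degenerate & panel.mask
    return astar, degenerate


def sign_change_fraction(panel: IntensityPanel, alpha_max: float) -> pd.Series:
    """Per-sample fraction of unmasked probes whose alpha* lies in (0, alpha_max].

    This operationalises "delta_beta(alpha) may change its sign" for offsets
    up to ``alpha_max``: the critical offset must exist and be reachable
    within the scanned range.  ``alpha_max = inf`` counts every probe with
    any finite crossing.
    """
    if not alpha_max > 0:
        raise ValueError("alpha_max must be > 0")
    astar, _ = critical_alpha_panel(panel)
    changing = np.isfinite(astar) & (astar <= alpha_max)
    n_valid = panel.mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_valid > 0, changing.sum(axis=0) / n_valid, np.nan)
    return pd.Series(frac, index=panel.sample_ids, name="sign_change_fraction")


def default_alpha_grid(alpha_max: float = 2000.0, n_extra: int = 8) -> np.ndarray:
    """Grid {0, 100, 500, 2000} extended log-uniformly up to ``alpha_max``."""
    base = [0.0, 100.0, 500.0, 2000.0]
    grid = [a for a in base if a <= alpha_max]
    if alpha_max > base[-1] and n_extra > 0:
        extra = np.geomspace(base[-1], alpha_max, n_extra + 1)[1:]
        grid.extend(extra.tolist())
    elif alpha_max not in grid:
        grid.append(float(alpha_max))
    return np.unique(np.asarray(grid, dtype=float))


@dataclass
class AlphaScanResult:
    """Diagnostics of delta_beta(alpha)/delta_m(alpha) across an alpha grid.

    Attributes
    ----------
    alpha_grid : increasing offsets scanned.
    per_sample_sign_change_fraction : fraction of unmasked probes per sample
        with a critical offset in (0, max(alpha_grid)].
    critical_alpha : probe x sample matrix of critical offsets (NaN = none).
    limit_discordance : per-alpha count of unmasked entries where
        {delta_beta(alpha) > 0} disagrees with {M_BS > M_oxBS}.
    diagnostics : per-alpha summary frame with the maximum |delta_beta|,
        the worst relative error of the tail law alpha*delta_beta(alpha)
        against M_BS - M_oxBS, and the maximum |delta_m(alpha) - delta_m_inf|.
    """

    alpha_grid: np.ndarray
    per_sample_sign_change_fraction: pd.Series
    critical_alpha: np.ndarray
    limit_discordance: pd.Series
    diagnostics: pd.DataFrame = field(repr=False)
    per_sample_discordance: pd.DataFrame = field(repr=False)

    @property
    def max_finite_critical_alpha(self) -> float:
        finite = self.critical_alpha[np.isfinite(self.critical_alpha)]
        return float(finite.max()) if finite.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per sample per alpha (CLI output shape)."""
        rows = []
        for a in self.alpha_grid:
            for sample in self.per_sample_discordance.columns:
                rows.append(
                    {
                        "alpha": a,
                        "sample": sample,
                        "discordant_with_limit_set": int(self.per_sample_discordance.loc[a, sample]),
                        "sign_change_fraction_upto_alpha_max": float(
                            self.per_sample_sign_change_fraction[sample]
                        ),
                    }
                )
        return pd.DataFrame(rows)


def limit_diagnostics(panel: IntensityPanel, alpha_grid=None) -> AlphaScanResult:
    """Quantify the large-alpha behaviour of the offset-dependent measures."""
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.ndim != 1 or np.any(np.diff(alpha_grid) <= 0) or np.any(alpha_grid < 0):
        raise ValueError("alpha_grid must be increasing and non-negative")

    dminf = delta_m_inf(panel)
    limit_set = panel.M_bs > panel.M_oxbs
    intensity_diff = panel.M_bs - panel.M_oxbs

    discordance = {}
    per_sample_disc = {}
    diag_rows = []
    for a in alpha_grid:
        db = delta_beta(panel, a)
        positive = db.mask & (db.values > 0)
        disagree = db.mask & (positive != limit_set)
        discordance[a] = int(disagree.sum())
        per_sample_disc[a] = disagree.sum(axis=0)

        max_abs = float(np.nanmax(np.abs(np.where(db.mask, db.values, np.nan)))) if db.mask.any() else np.nan
        if a > 0:
            nonzero = db.mask & (intensity_diff != 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(a * db.values - intensity_diff) / np.abs(intensity_diff)
            tail_err = float(np.nanmax(np.where(nonzero, rel, np.nan))) if nonzero.any() else np.nan
        else:
            tail_err = np.nan
        dm = delta_m(panel, a)
        both = dm.mask & dminf.mask
        gap = float(np.nanmax(np.abs(np.where(both, dm.values - dminf.values, np.nan)))) if both.any() else np.nan
        diag_rows.append(
            {
                "alpha": a,
                "max_abs_delta_beta": max_abs,
                "max_rel_tail_error": tail_err,
                "max_abs_delta_m_gap": gap,
            }
        )

    astar, _ = critical_alpha_panel(panel)
    frac = sign_change_fraction(panel, float(alpha_grid.max()) if alpha_grid.max() > 0 else np.inf)
    return AlphaScanResult(
        alpha_grid=alpha_grid,
        per_sample_sign_change_fraction=frac,
        critical_alpha=astar,
        limit_discordance=pd.Series(discordance, name="limit_discordance"),
        diagnostics=pd.DataFrame(diag_rows).set_index("alpha"),
        per_sample_discordance=pd.DataFrame(per_sample_disc, index=panel.sample_ids).T,
    )
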