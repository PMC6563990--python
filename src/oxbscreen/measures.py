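"""The three 5hmC screening measures and their building blocks.

Paired BS/oxBS array intensities isolate 5-hydroxymethylcytosine because the
BS arm reads 5mC + 5hmC as methylated while the oxBS arm reads only 5mC.  The
measures implemented here turn that contrast into a per-probe, per-sample
screening quantity whose positive values flag a CpG as hydroxymethylated:

* ``delta_beta`` -- difference of methylation proportions
  beta(alpha) = M / (M + U + alpha), i.e.
  ``beta_BS(alpha) - beta_oxBS(alpha)``; the conventional choice is
  alpha = 100.
* ``delta_m`` -- difference of log-ratio (M-value) measures
  m(alpha) = log2(M / (U + alpha)).  The offset is applied to the
  unmethylated intensity only: this is the unique convention under which
  delta_m(alpha) converges to ``delta_m_inf`` as alpha grows and under which
  its sign agrees with delta_beta(alpha) at every alpha (both signs reduce to
  the sign of ``M_BS * (U_oxBS + alpha) - M_oxBS * (U_BS + alpha)``).
* ``delta_m_inf`` -- log2(M_BS / M_oxBS), the alpha-free limit of delta_m;
  positive exactly when M_BS > M_oxBS.
* ``delta_h`` -- 1 - (M_oxBS + U_oxBS) / (M_BS + U_BS), the proportion of
  5hmC in the global methylation signal, under the assumption that a
  substantial 5hmC level depresses the total oxBS intensity.  Negative
  values are retained but flagged as measurement noise.
* ``naive_5hmc`` -- max(0, delta_beta(0)), the constrained naive 5hmC level
  estimate; its strict-positivity pattern is the screening surrogate for the
  beta-distribution maximum-likelihood procedures (oxBS-MLE / OxyBS), which
  flag exactly the probes with delta_beta(0) > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import IntensityPanel, MeasureMatrix

__all__ = [
    "AlphaSpec",
    "beta",
    "m_value",
    "delta_beta",
    "delta_m",
    "delta_m_inf",
    "delta_h",
    "naive_5hmc",
]


@dataclass(frozen=True)
class AlphaSpec:
    """Intensity offset added to the denominator of the proportion measures.

    ``alpha = 100`` is the conventional 450k-array choice; ``alpha = 0`` is
    admitted (it is needed for the oxBS-MLE/OxyBS screening surrogate), with
    degenerate 0/0 entries masked.
    """

    alpha: float = 100.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError("alpha must be finite and >= 0")


def _alpha_value(alpha: AlphaSpec | float) -> float:
    if isinstance(alpha, AlphaSpec):
        return float(alpha.alpha)
    spec = AlphaSpec(float(alpha))  # reuse validation
    return spec.alpha


def beta(M, U, alpha: AlphaSpec | float = 100.0) -> np.ndarray:
    """Methylation proportion M / (M + U + alpha); NaN where the denominator is 0."""
    a = _alpha_value(alpha)
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    denom = M + U + a
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, M / denom, np.nan)
    return out


def m_value(M, U, alpha: AlphaSpec | float = 100.0) -> np.ndarray:
    """Log-ratio measure log2(M / (U + alpha)); NaN where M <= 0 or U + alpha <= 0."""
    a = _alpha_value(alpha)
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    ok = (M > 0) & (U + a > 0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = np.where(ok, np.log2(np.where(ok, M, 1.0) / np.where(ok, U + a, 1.0)), np.nan)
    return out


def delta_beta(panel: IntensityPanel, alpha: AlphaSpec | float = 100.0) -> MeasureMatrix:
    """beta_BS(alpha) - beta_oxBS(alpha) per probe and sample; values in [-1, 1]."""
    a = _alpha_value(alpha)
    vb = beta(panel.M_bs, panel.U_bs, a)
    vo = beta(panel.M_oxbs, panel.U_oxbs, a)
    values = vb - vo
    mask = panel.mask & np.isfinite(values)
    return MeasureMatrix(
        measure_name="delta_beta",
        values=np.where(mask, values, np.nan),
        mask=mask,
        probe_ids=panel.probe_ids,
        sample_ids=panel.sample_ids,
        alpha=a,
    )


def delta_m(panel: IntensityPanel, alpha: AlphaSpec | float = 100.0) -> MeasureMatrix:
    """m_BS(alpha) - m_oxBS(alpha); masked where a methylated intensity is <= 0."""
    a = _alpha_value(alpha)
    vb = m_value(panel.M_bs, panel.U_bs, a)
    vo = m_value(panel.M_oxbs, panel.U_oxbs, a)
    values = vb - vo
    mask = panel.mask & np.isfinite(values)
    return MeasureMatrix(
        measure_name="delta_m",
        values=np.where(mask, values, np.nan),
        mask=mask,
        probe_ids=panel.probe_ids,
        sample_ids=panel.sample_ids,
        alpha=a,
    )


def delta_m_inf(panel: IntensityPanel) -> MeasureMatrix:
    """log2(M_BS / M_oxBS); defined only where both methylated intensities are > 0."""
    ok = (panel.M_bs > 0) & (panel.M_oxbs > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(ok, np.log2(np.where(ok, panel.M_bs, 1.0) / np.where(ok, panel.M_oxbs, 1.0)), np.nan)
    mask = panel.mask & ok
    return MeasureMatrix(
        measure_name="delta_m_inf",
        values=np.where(mask, values, np.nan),
        mask=mask,
        probe_ids=panel.probe_ids,
        sample_ids=panel.sample_ids,
    )


def delta_h(panel: IntensityPanel) -> MeasureMatrix:
    """1 - (M_oxBS + U_oxBS) / (M_BS + U_BS), the global 5hmC proportion.

    Probes with zero BS total intensity are masked (they exhibit measurement
    error by definition).  Negative values -- oxBS total exceeding the BS
    total -- are retained so prevalence denominators stay comparable, but are
    flagged as noise in ``noise_flag``.
    """
    t_bs, t_oxbs = panel.totals()
    ok = t_bs > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(ok, 1.0 - t_oxbs / np.where(ok, t_bs, 1.0), np.nan)
    mask = panel.mask & ok
    noise = mask & (values < 0)
    return MeasureMatrix(
        measure_name="delta_h",
        values=np.where(mask, values, np.nan),
        mask=mask,
        probe_ids=panel.probe_ids,
        sample_ids=panel.sample_ids,
        noise_flag=noise,
    )


def naive_5hmc(panel: IntensityPanel) -> MeasureMatrix:
    """Constrained naive 5hmC estimate max(0, delta_beta(0)).

    Strictly positive exactly where delta_beta(0) > 0, so thresholding at 0
    flags the same probes as the beta-distribution maximum-likelihood
    procedures (oxBS-MLE / OxyBS) do in a screening step.
    """
    db0 = delta_beta(panel, 0.0)
    values = np.clip(db0.values, 0.0, None)
    return MeasureMatrix(
        measure_name="naive_5hmc",
        values=np.where(db0.mask, values, np.nan),
        mask=db0.mask,
        probe_ids=panel.probe_ids,
        sample_ids=panel.sample_ids,
    )
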