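"""Synthetic paired BS/oxBS intensity panels with known ground truth.

The generator emulates the signal model behind the paired-treatment
chemistry.  Each probe carries true per-probe proportions p5mC and p5hmC
(p5mC + p5hmC <= 1).  The BS arm reads both modifications as methylated; the
oxBS arm reads only 5mC, and a substantial 5hmC level may depress the total
oxBS intensity (controlled by ``attenuation_gamma``):

    M_BS   = D * (p5mC + p5hmC)       * e1 + background
    U_BS   = D * (1 - p5mC - p5hmC)   * e2 + background
    M_oxBS = D * (1 - g*p5hmC) * p5mC       * e3 + background
    U_oxBS = D * (1 - g*p5hmC) * (1 - p5mC) * e4 + background

with D a per-probe-per-sample log-normal intensity scale, e_k independent
multiplicative log-normal noise of unit mean and coefficient of variation
``noise_cv``, and g = ``attenuation_gamma``.  With no background and no
noise, delta_h recovers g * p5hmC exactly and p5hmC = 0 forces
M_BS = M_oxBS (so delta_m_inf = 0).

A paired healthy/cancer design is produced by depleting p5hmC
multiplicatively in the cancer arm (``cancer_depletion``), emulating the
reduction of 5hmC observed in tumours.

``figure_demo_points`` constructs the counterexample configurations in which
the sign of delta_beta(100) contradicts the intuitive intensity comparisons:
points with both BS intensities *below* their oxBS counterparts yet
delta_beta(100) > 0, the mirror case with delta_beta(100) < 0, and points
with delta_beta(100) exactly zero despite unequal intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import IntensityPanel

logger = logging.getLogger("oxbscreen")

__all__ = [
    "BetaDist",
    "FixedValue",
    "SimulationConfig",
    "SimulationError",
    "simulate_panels",
    "figure_demo_points",
]


class SimulationError(RuntimeError):
    """The generator could not satisfy its constraints."""


@dataclass(frozen=True)
class BetaDist:
    """Beta(a, b) distribution for a per-probe proportion."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta parameters must be positive")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.beta(self.a, self.b, size=size)


@dataclass(frozen=True)
class FixedValue:
    """Degenerate distribution: every probe gets the same proportion."""

    value: float

    def __post_init__(self) -> None:
        if not 0 <= self.value <= 1:
            raise ValueError("fixed proportion must lie in [0, 1]")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.value)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of the paired BS/oxBS generator.

    Defaults describe a 450k-like paired colorectal study: 38 matched
    samples; mostly-low 5hmC proportions (mean ~5%) on top of a broad 5mC
    distribution; a log-normal intensity scale with median ~3000
    fluorescence units; an additive background of 100; moderate oxBS
    attenuation; a 50% depletion of 5hmC in the cancer arm; and 10%
    multiplicative measurement noise.
    """

    n_probes: int = 10_000
    n_samples: int = 38
    seed: int = 0
    p5mc_dist: BetaDist | FixedValue = BetaDist(0.8, 0.8)
    p5hmc_dist: BetaDist | FixedValue = BetaDist(1.5, 30.0)
    depth_log_mean: float = 8.0   # ln scale: median intensity ~ e^8 ~ 2980
    depth_log_sigma: float = 0.5
    background: float = 100.0
    attenuation_gamma: float = 0.3
    cancer_depletion: float = 0.5
    noise_cv: float = 0.10
    max_truncation_rounds: int = 1000

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.n_samples < 1:
            raise ValueError("n_probes and n_samples must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.attenuation_gamma <= 1:
            raise ValueError("attenuation_gamma must lie in [0, 1]")
        if not 0 <= self.cancer_depletion <= 1:
            raise ValueError("cancer_depletion must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.depth_log_sigma < 0:
            raise ValueError("depth_log_sigma must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["p5mc_dist"] = {"kind": type(self.p5mc_dist).__name__, **asdict(self.p5mc_dist)}
        d["p5hmc_dist"] = {"kind": type(self.p5hmc_dist).__name__, **asdict(self.p5hmc_dist)}
        return d


def _dist_from_dict(d) -> BetaDist | FixedValue:
    if isinstance(d, (BetaDist, FixedValue)):
        return d
    d = dict(d)
    kind = d.pop("kind", "BetaDist")
    return {"BetaDist": BetaDist, "FixedValue": FixedValue}[kind](**d)


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain (e.g. YAML-loaded) mapping."""
    d = dict(d)
    if "p5mc_dist" in d:
        d["p5mc_dist"] = _dist_from_dict(d["p5mc_dist"])
    if "p5hmc_dist" in d:
        d["p5hmc_dist"] = _dist_from_dict(d["p5hmc_dist"])
    return SimulationConfig(**d)


def _sample_proportions(config: SimulationConfig, rng: np.random.Generator):
    """Per-probe (p5mC, p5hmC) with p5mC + p5hmC <= 1 enforced by resampling.

    Resampling (rather than renormalising) keeps both marginals
    interpretable; persistent infeasibility aborts with an error.
    """
    n = config.n_probes
    p5mc = config.p5mc_dist.sample(rng, n)
    p5hmc = config.p5hmc_dist.sample(rng, n)
    for _ in range(config.max_truncation_rounds):
        bad = p5mc + p5hmc > 1
        if not bad.any():
            return p5mc, p5hmc
        k = int(bad.sum())
        p5mc[bad] = config.p5mc_dist.sample(rng, k)
        p5hmc[bad] = config.p5hmc_dist.sample(rng, k)
    raise SimulationError(
        "could not satisfy p5mC + p5hmC <= 1 after "
        f"{config.max_truncation_rounds} resampling rounds; "
        "the proportion distributions are jointly infeasible"
    )


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=shape)


def _arm(config: SimulationConfig, rng: np.random.Generator,
         p5mc: np.ndarray, p5hmc: np.ndarray, tissue: str,
         probe_ids: list[str], sample_ids: list[str]) -> IntensityPanel:
    shape = (config.n_probes, config.n_samples)
    depth = rng.lognormal(config.depth_log_mean, config.depth_log_sigma, size=shape)
    g = config.attenuation_gamma
    pm = p5mc[:, None]
    ph = p5hmc[:, None]
    atten = 1.0 - g * ph
    bg = config.background
    M_bs = depth * (pm + ph) * _noise(rng, config.noise_cv, shape) + bg
    U_bs = depth * (1.0 - pm - ph) * _noise(rng, config.noise_cv, shape) + bg
    M_oxbs = depth * atten * pm * _noise(rng, config.noise_cv, shape) + bg
    U_oxbs = depth * atten * (1.0 - pm) * _noise(rng, config.noise_cv, shape) + bg
    return IntensityPanel(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        tissue=tissue,
        M_bs=M_bs, U_bs=U_bs, M_oxbs=M_oxbs, U_oxbs=U_oxbs,
    )


def simulate_panels(config: SimulationConfig):
    """Generate matched healthy and cancer panels plus a ground-truth table.

    Returns ``(healthy, cancer, truth)`` where ``truth`` is a per-probe
    DataFrame with columns ``p5mc``, ``p5hmc_healthy``, ``p5hmc_cancer``.
    Identical configs (including the seed) yield bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    p5mc, p5hmc = _sample_proportions(config, rng)
    p5hmc_cancer = config.cancer_depletion * p5hmc

    n_pad = len(str(config.n_probes))
    probe_ids = [f"cg{i:0{max(6, n_pad)}d}" for i in range(config.n_probes)]
    sample_ids = [f"sample_{j + 1:02d}" for j in range(config.n_samples)]

    healthy = _arm(config, rng, p5mc, p5hmc, "healthy", probe_ids, sample_ids)
    cancer = _arm(config, rng, p5mc, p5hmc_cancer, "cancer", probe_ids, sample_ids)
    truth = pd.DataFrame(
        {"p5mc": p5mc, "p5hmc_healthy": p5hmc, "p5hmc_cancer": p5hmc_cancer},
        index=pd.Index(probe_ids, name="probe"),
    )
    logger.info("simulated %d probes x %d samples per arm (seed=%d)",
                config.n_probes, config.n_samples, config.seed)
    return healthy, cancer, truth


# ---------------------------------------------------------------------------
# Counterexample demonstrations
# ---------------------------------------------------------------------------

_DEMO_KINDS = ("fig1", "fig2", "fig3")
_MAX_TRIES = 100


def _sign_at_100(m_bs, u_bs, m_oxbs, u_oxbs) -> float:
    # sign(delta_beta(alpha)) == sign(M_bs*(U_ox+alpha) - M_ox*(U_bs+alpha))
    return m_bs * (u_oxbs + 100.0) - m_oxbs * (u_bs + 100.0)


def figure_demo_points(kind: str, n_points: int = 10, seed: int = 0) -> IntensityPanel:
    """Construct intensity points whose delta_beta(100) sign defies intuition.

    * ``fig1``: both BS intensities strictly below their oxBS counterparts
      (intuitively no 5hmC) yet delta_beta(100) > 0 -- the points would be
      flagged as hydroxymethylated.
    * ``fig2``: both BS intensities strictly above (intuitively substantial
      5hmC) yet delta_beta(100) < 0 -- the points would be discarded.
    * ``fig3``: both BS intensities strictly below, with delta_beta(100)
      exactly zero.  The oxBS point is the BS point doubled, with the
      unmethylated intensity shifted so the two proportions coincide; the
      power-of-two scaling keeps the cancellation exact in floating point.

    Every generated point is verified against its defining inequalities
    before return.
    """
    if kind not in _DEMO_KINDS:
        raise ValueError(f"kind must be one of {_DEMO_KINDS}")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_points):
        for _try in range(_MAX_TRIES):
            if kind == "fig1":
                m_bs = rng.uniform(50, 500)
                r = 1.0 + rng.uniform(0.02, 0.15)
                m_oxbs = m_bs * r
                u_bs = rng.uniform(50, 1000)
                u_oxbs = r * (u_bs + 100.0) - 100.0 + rng.uniform(10, 200)
                ok = (m_bs < m_oxbs and u_bs < u_oxbs
                      and _sign_at_100(m_bs, u_bs, m_oxbs, u_oxbs) > 0)
            elif kind == "fig2":
                m_oxbs = rng.uniform(50, 500)
                r = 1.0 + rng.uniform(0.02, 0.15)
                m_bs = m_oxbs * r
                u_oxbs = rng.uniform(50, 1000)
                u_bs = r * (u_oxbs + 100.0) - 100.0 + rng.uniform(10, 200)
                ok = (m_bs > m_oxbs and u_bs > u_oxbs
                      and _sign_at_100(m_bs, u_bs, m_oxbs, u_oxbs) < 0)
            else:  # fig3: exact zero via power-of-two scaling
                m_bs = float(rng.integers(50, 500))
                u_bs = float(rng.integers(50, 1000))
                m_oxbs = 2.0 * m_bs
                u_oxbs = 2.0 * (u_bs + 100.0) - 100.0
                ok = m_bs < m_oxbs and u_bs < u_oxbs
            if ok:
                rows.append((m_bs, u_bs, m_oxbs, u_oxbs))
                break
        else:
            raise SimulationError(f"failed to construct a {kind} point "
                                  f"after {_MAX_TRIES} attempts")
    arr = np.asarray(rows)
    return IntensityPanel(
        probe_ids=[f"s{i + 1}" for i in range(n_points)],
        sample_ids=["demo"],
        tissue="unspecified",
        M_bs=arr[:, [0]], U_bs=arr[:, [1]], M_oxbs=arr[:, [2]], U_oxbs=arr[:, [3]],
    )
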