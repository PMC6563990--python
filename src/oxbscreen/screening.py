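"""Screening calls and prevalence-of-positive-results summaries.

A probe/sample entry is *called* hydroxymethylated when its measure value is
strictly greater than a threshold (0 by default; 0.3 has been used in the
literature for delta_beta).  Prevalence summaries aggregate the calls either
per sample across probes (what fraction of the array looks hydroxymethylated
in this sample) or per probe across samples (the *hydroxymethylation level*
of a CpG: in how many of the samples it is called).  Probes positive in at
least 75% of samples are deemed *substantially hydroxymethylated*.

``compare_tissues`` tests for the expected 5hmC depletion in tumours by
comparing prevalence vectors between matched healthy and cancer arms
(Wilcoxon signed-rank when paired, Mann-Whitney otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel import CallMatrix, MeasureMatrix, PanelError

logger = logging.getLogger("oxbscreen")

AXES = ("per_sample", "per_probe")

__all__ = [
    "PrevalenceSummary",
    "TissueComparison",
    "call_positive",
    "prevalence",
    "joint_prevalence",
    "substantial_cpgs",
    "compare_tissues",
    "adjust_pvalues",
]


@dataclass
class PrevalenceSummary:
    """Proportion of positive calls per sample or per probe.

    ``proportions`` is indexed by sample ID (axis ``per_sample``) or probe ID
    (axis ``per_probe``); ``denominators`` gives the number of unmasked calls
    behind each proportion.  Units with no unmasked calls are omitted.
    """

    axis: str
    measure_name: str
    proportions: pd.Series
    denominators: pd.Series

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise PanelError(f"unknown axis {self.axis!r}; expected one of {AXES}")
        p = self.proportions.to_numpy(dtype=float)
        if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
            raise PanelError("proportions must lie in [0, 1]")
        if (self.denominators <= 0).any():
            raise PanelError("every reported proportion needs a positive denominator")


@dataclass
class TissueComparison:
    """Two-sample location comparison of prevalence vectors.

    ``direction`` is ``"a>b"`` or ``"b>a"`` by the sign of the median
    difference, or None when there is none.  ``p_value`` is None when fewer
    than 3 informative pairs/observations are available.
    """

    test: str
    statistic: float | None
    p_value: float | None
    median_difference: float
    direction: str | None
    n_units: int
    n_informative: int
    warning: str | None = None


def call_positive(measure: MeasureMatrix, threshold: float = 0.0) -> CallMatrix:
    """Binary screening calls: value strictly greater than ``threshold``."""
    if not np.isfinite(threshold):
        raise PanelError("threshold must be finite")
    with np.errstate(invalid="ignore"):
        calls = measure.mask & (measure.values > threshold)
    logger.info(
        "call_positive: measure=%s alpha=%s threshold=%g positives=%d/%d unmasked",
        measure.measure_name, measure.alpha, threshold,
        int(calls.sum()), int(measure.mask.sum()),
    )
    return CallMatrix(
        measure_name=measure.measure_name,
        calls=calls,
        mask=measure.mask,
        probe_ids=measure.probe_ids,
        sample_ids=measure.sample_ids,
        threshold=float(threshold),
    )


def _axis_ids(calls: CallMatrix, axis: str):
    if axis == "per_sample":
        return 0, calls.sample_ids  # reduce over probes
    if axis == "per_probe":
        return 1, calls.probe_ids  # reduce over samples
    raise PanelError(f"unknown axis {axis!r}; expected one of {AXES}")


def prevalence(calls: CallMatrix, axis: str = "per_sample") -> PrevalenceSummary:
    """Fraction of unmasked entries called positive, per sample or per probe."""
    reduce_axis, ids = _axis_ids(calls, axis)
    pos = (calls.calls & calls.mask).sum(axis=reduce_axis)
    n = calls.mask.sum(axis=reduce_axis)
    keep = n > 0
    if not keep.all():
        dropped = [ids[i] for i in np.flatnonzero(~keep)]
        logger.warning("prevalence: omitted %d unit(s) with no unmasked calls: %s",
                       len(dropped), dropped[:5])
    idx = [ids[i] for i in np.flatnonzero(keep)]
    return PrevalenceSummary(
        axis=axis,
        measure_name=calls.measure_name,
        proportions=pd.Series(pos[keep] / n[keep], index=idx, name="prevalence"),
        denominators=pd.Series(n[keep], index=idx, name="n"),
    )


def _check_aligned(calls1: CallMatrix, calls2: CallMatrix) -> None:
    if calls1.probe_ids != calls2.probe_ids or calls1.sample_ids != calls2.sample_ids:
        raise PanelError("call matrices are not aligned on probe/sample IDs")


def joint_prevalence(calls1: CallMatrix, calls2: CallMatrix, axis: str = "per_sample") -> PrevalenceSummary:
    """Fraction of jointly-unmasked entries where *both* measures call positive.

    Using jointly-unmasked denominators keeps the joint prevalence comparable
    with (and bounded by) the marginal prevalences on the same entries.
    """
    _check_aligned(calls1, calls2)
    reduce_axis, ids = _axis_ids(calls1, axis)
    joint_mask = calls1.mask & calls2.mask
    both = (calls1.calls & calls2.calls & joint_mask).sum(axis=reduce_axis)
    n = joint_mask.sum(axis=reduce_axis)
    keep = n > 0
    if not keep.all():
        logger.warning("joint_prevalence: omitted %d unit(s) with no jointly-unmasked calls",
                       int((~keep).sum()))
    idx = [ids[i] for i in np.flatnonzero(keep)]
    return PrevalenceSummary(
        axis=axis,
        measure_name=f"{calls1.measure_name}&{calls2.measure_name}",
        proportions=pd.Series(both[keep] / n[keep], index=idx, name="joint_prevalence"),
        denominators=pd.Series(n[keep], index=idx, name="n"),
    )


def substantial_cpgs(calls: CallMatrix, min_fraction: float = 0.75) -> list[str]:
    """Probes positive in at least ``min_fraction`` of their unmasked samples.

    The boundary is inclusive ("at least 75%"), so a probe positive in
    exactly 3 of 4 samples passes the default.
    """
    if not 0 < min_fraction <= 1:
        raise PanelError("min_fraction must lie in (0, 1]")
    summary = prevalence(calls, axis="per_probe")
    selected = summary.proportions[summary.proportions >= min_fraction]
    return list(selected.index)


def compare_tissues(
    summary_a: PrevalenceSummary,
    summary_b: PrevalenceSummary,
    paired: bool = True,
) -> TissueComparison:
    """Compare two prevalence vectors (e.g. healthy vs cancer arms).

    Paired comparisons match units by ID and use the two-sided Wilcoxon
    signed-rank test; unpaired ones use the two-sided Mann-Whitney U.  With
    fewer than 3 informative pairs (non-zero differences) the p-value is
    reported as absent.
    """
    a, b = summary_a.proportions, summary_b.proportions
    if paired:
        common = a.index.intersection(b.index)
        if len(common) < len(a) or len(common) < len(b):
            logger.warning("compare_tissues: restricting to %d matched units", len(common))
        a, b = a.loc[common], b.loc[common]
        if len(a) == 0:
            raise PanelError("no matched units to compare")
        diff = a.to_numpy() - b.to_numpy()
        median_diff = float(np.median(diff))
        informative = int(np.count_nonzero(diff))
        direction = "a>b" if median_diff > 0 else ("b>a" if median_diff < 0 else None)
        if informative < 3:
            return TissueComparison(
                test="wilcoxon_signed_rank", statistic=None, p_value=None,
                median_difference=median_diff, direction=direction,
                n_units=len(a), n_informative=informative,
                warning=f"only {informative} informative pair(s); p-value not computed",
            )
        stat, p = stats.wilcoxon(a.to_numpy(), b.to_numpy(), alternative="two-sided",
                                 zero_method="wilcox")
        return TissueComparison(
            test="wilcoxon_signed_rank", statistic=float(stat), p_value=float(p),
            median_difference=median_diff, direction=direction,
            n_units=len(a), n_informative=informative,
        )
    # unpaired
    av, bv = a.to_numpy(), b.to_numpy()
    if min(len(av), len(bv)) == 0:
        raise PanelError("empty prevalence vector")
    median_diff = float(np.median(av) - np.median(bv))
    direction = "a>b" if median_diff > 0 else ("b>a" if median_diff < 0 else None)
    if min(len(av), len(bv)) < 3:
        return TissueComparison(
            test="mann_whitney", statistic=None, p_value=None,
            median_difference=median_diff, direction=direction,
            n_units=len(av) + len(bv), n_informative=min(len(av), len(bv)),
            warning="fewer than 3 observations per group; p-value not computed",
        )
    stat, p = stats.mannwhitneyu(av, bv, alternative="two-sided")
    return TissueComparison(
        test="mann_whitney", statistic=float(stat), p_value=float(p),
        median_difference=median_diff, direction=direction,
        n_units=len(av) + len(bv), n_informative=min(len(av), len(bv)),
    )


def adjust_pvalues(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg (default) adjustment across a family of comparisons."""
    pvalues = np.asarray(list(pvalues), dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method=method)[1]
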