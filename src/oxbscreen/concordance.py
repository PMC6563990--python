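"""Pairwise resemblance of screening measures without a gold standard.

No biochemical criterion defines which CpGs are "truly" hydroxymethylated, so
two 5hmC measures can only be compared with each other.  Two complementary
views are implemented over the binary screening calls of a measure pair
(x1, x2), per unit (per CpG across samples, or per sample across CpGs):

* similarity -- the simple matching coefficient
  S = (#concordant-positive + #concordant-nonpositive) / n in [0, 1], and
  the Hamann coefficient SH = (#matches - #mismatches) / n in [-1, 1],
  with the exact identity SH = 2S - 1.  S can be misleadingly large when no
  jointly-positive calls exist at all (all agreement coming from shared
  negatives); such units are flagged so SH can be consulted.
* relative accuracy -- co-positivity SE_r(x1|x2) = P(x1>0 | x2>0),
  co-negativity SP_r(x1|x2) = P(x1<=0 | x2<=0), and the relative false
  discovery rate FDR_r(x1|x2) = 1 - P(x1>0, x2>0)/P(x1>0), which equals
  1 - SE_r(x2|x1) identically.

Expectations over units are provided either as the empirical mean or under
an independence null that fixes the marginal positive counts of both
measures and places calls at random (hypergeometric overlap), under which
E[S] = (a*b + (n-a)*(n-b)) / n^2 per unit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .panel import (
    CONCORDANCE_AXES,
    CallMatrix,
    ConcordanceTable,
    PanelError,
)

logger = logging.getLogger("oxbscreen")

__all__ = [
    "simple_matching",
    "hamann",
    "expected_similarity",
    "relative_accuracy",
    "concordance_suite",
]


def _check_aligned(calls1: CallMatrix, calls2: CallMatrix) -> None:
    if calls1.probe_ids != calls2.probe_ids or calls1.sample_ids != calls2.sample_ids:
        raise PanelError("call matrices are not aligned on probe/sample IDs")


def _unit_counts(calls1: CallMatrix, calls2: CallMatrix, axis: str):
    """Per-unit 2x2 contingency counts over jointly-unmasked entries.

    Returns (ids, n, both_pos, both_neg, pos1, pos2) as 1-D arrays, where a
    unit is a probe (axis ``per_probe_across_samples``, reducing over
    samples) or a sample (axis ``per_sample_across_probes``, reducing over
    probes).
    """
    _check_aligned(calls1, calls2)
    if axis == "per_probe_across_samples":
        reduce_axis, ids = 1, calls1.probe_ids
    elif axis == "per_sample_across_probes":
        reduce_axis, ids = 0, calls1.sample_ids
    else:
        raise PanelError(f"unknown axis {axis!r}; expected one of {CONCORDANCE_AXES}")
    joint = calls1.mask & calls2.mask
    c1 = calls1.calls & joint
    c2 = calls2.calls & joint
    n = joint.sum(axis=reduce_axis)
    both_pos = (c1 & c2).sum(axis=reduce_axis)
    both_neg = (~calls1.calls & ~calls2.calls & joint).sum(axis=reduce_axis)
    pos1 = c1.sum(axis=reduce_axis)
    pos2 = c2.sum(axis=reduce_axis)
    return ids, n, both_pos, both_neg, pos1, pos2


def _drop_empty(ids, n, *arrays):
    keep = n > 0
    if not keep.all():
        logger.warning("concordance: omitted %d unit(s) with no jointly-unmasked entries",
                       int((~keep).sum()))
    kept_ids = [ids[i] for i in np.flatnonzero(keep)]
    return kept_ids, n[keep], tuple(a[keep] for a in arrays)


def simple_matching(
    calls1: CallMatrix,
    calls2: CallMatrix,
    axis: str = "per_probe_across_samples",
    tissue: str = "unspecified",
) -> ConcordanceTable:
    """Simple matching coefficient S per unit, with its empirical-mean expectation.

    ``degenerate`` flags units where S > 0 although no jointly-positive calls
    exist -- agreement is carried entirely by shared negatives and S may be
    misleading for screening purposes.
    """
    ids, n, (both_pos, both_neg) = _drop_empty(*_unit_counts(calls1, calls2, axis)[:4])
    values = (both_pos + both_neg) / n
    degenerate = (both_pos == 0) & (values > 0)
    if degenerate.any():
        logger.warning("simple_matching: %d unit(s) have S > 0 with no joint positives; "
                       "consult the Hamann coefficient", int(degenerate.sum()))
    return ConcordanceTable(
        pair=(calls1.measure_name, calls2.measure_name),
        tissue=tissue,
        axis=axis,
        statistic="S",
        values=pd.Series(values, index=ids),
        expectation=float(np.mean(values)),
        expectation_method="empirical_mean",
        degenerate=pd.Series(degenerate, index=ids),
    )


def hamann(
    calls1: CallMatrix,
    calls2: CallMatrix,
    axis: str = "per_probe_across_samples",
    tissue: str = "unspecified",
) -> ConcordanceTable:
    """Hamann coefficient SH = (matches - mismatches) / n = 2S - 1 per unit."""
    ids, n, (both_pos, both_neg) = _drop_empty(*_unit_counts(calls1, calls2, axis)[:4])
    matches = both_pos + both_neg
    values = (2.0 * matches - n) / n
    return ConcordanceTable(
        pair=(calls1.measure_name, calls2.measure_name),
        tissue=tissue,
        axis=axis,
        statistic="SH",
        values=pd.Series(values, index=ids),
        expectation=float(np.mean(values)),
        expectation_method="empirical_mean",
    )


def expected_similarity(
    calls1: CallMatrix,
    calls2: CallMatrix,
    statistic: str = "S",
    method: str = "empirical_mean",
    axis: str = "per_probe_across_samples",
) -> float:
    """Expectation of S or SH over units.

    ``empirical_mean`` averages the observed unit-wise coefficients.
    ``independence_null`` fixes the marginal positive counts a, b of the two
    measures in each unit and assumes the calls are placed independently at
    random, giving E[S] = (a*b + (n-a)*(n-b)) / n^2 per unit, averaged over
    units.  Under either method E[SH] = 2*E[S] - 1 exactly.
    """
    if statistic not in ("S", "SH"):
        raise PanelError(f"expected_similarity supports S and SH, not {statistic!r}")
    if method == "empirical_mean":
        table = simple_matching(calls1, calls2, axis=axis)
        e_s = float(np.mean(table.values.to_numpy()))
    elif method == "independence_null":
        ids, n, (both_pos, both_neg, pos1, pos2) = _drop_empty(*_unit_counts(calls1, calls2, axis))
        e_s_units = (pos1 * pos2 + (n - pos1) * (n - pos2)) / (n * n)
        e_s = float(np.mean(e_s_units))
    else:
        raise PanelError(f"unknown expectation method {method!r}")
    return e_s if statistic == "S" else 2.0 * e_s - 1.0


def relative_accuracy(
    calls1: CallMatrix,
    calls2: CallMatrix,
    axis: str = "per_probe_across_samples",
    tissue: str = "unspecified",
) -> list[ConcordanceTable]:
    """SE_r, SP_r and FDR_r in both conditioning orders, unit-wise.

    The pair of each returned table is ordered: ``pair=(x1, x2)`` carries
    ``stat(x1 | x2)``.  Units whose conditioning event is empty (no positive
    calls of the conditioning measure for SE_r/FDR_r, no non-positive calls
    for SP_r) get NaN values and are excluded from the expectation.
    FDR_r(x1|x2) is computed through the identity 1 - SE_r(x2|x1), which
    coincides with the direct ratio 1 - P(x1>0, x2>0)/P(x1>0).
    """
    ids, n, (both_pos, both_neg, pos1, pos2) = _drop_empty(*_unit_counts(calls1, calls2, axis))
    name1, name2 = calls1.measure_name, calls2.measure_name

    def _ratio(num, den, what):
        empty = den == 0
        if empty.any():
            logger.warning("relative_accuracy: %s undefined for %d unit(s) "
                           "(empty conditioning set)", what, int(empty.sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(empty, np.nan, num / np.where(empty, 1, den))

    se_12 = _ratio(both_pos, pos2, f"SE_r({name1}|{name2})")
    se_21 = _ratio(both_pos, pos1, f"SE_r({name2}|{name1})")
    sp_12 = _ratio(both_neg, n - pos2, f"SP_r({name1}|{name2})")
    sp_21 = _ratio(both_neg, n - pos1, f"SP_r({name2}|{name1})")
    fdr_12 = 1.0 - se_21  # identity: FDR_r(x1|x2) = 1 - SE_r(x2|x1)
    fdr_21 = 1.0 - se_12

    def _table(stat, pair, values):
        vals = pd.Series(values, index=ids)
        return ConcordanceTable(
            pair=pair,
            tissue=tissue,
            axis=axis,
            statistic=stat,
            values=vals,
            expectation=float(np.nanmean(values)) if np.isfinite(values).any() else None,
            expectation_method="empirical_mean",
        )

    return [
        _table("SE_r", (name1, name2), se_12),
        _table("SE_r", (name2, name1), se_21),
        _table("SP_r", (name1, name2), sp_12),
        _table("SP_r", (name2, name1), sp_21),
        _table("FDR_r", (name1, name2), fdr_12),
        _table("FDR_r", (name2, name1), fdr_21),
    ]


def concordance_suite(
    calls: dict[str, CallMatrix],
    axis: str = "per_probe_across_samples",
    tissue: str = "unspecified",
    include_accuracy: bool = True,
) -> list[ConcordanceTable]:
    """S/SH (and optionally the relative-accuracy trio) for every measure pair."""
    names = list(calls)
    tables: list[ConcordanceTable] = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            tables.append(simple_matching(calls[a], calls[b], axis=axis, tissue=tissue))
            tables.append(hamann(calls[a], calls[b], axis=axis, tissue=tissue))
            if include_accuracy:
                tables.extend(relative_accuracy(calls[a], calls[b], axis=axis, tissue=tissue))
    return tables
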