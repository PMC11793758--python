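"""Exact Wilcoxon signed-rank test and the paired wet-vs-dry comparison.

The exact two-sided p-value is computed on the realized (possibly tied)
rank multiset: the null distribution of W over all 2^n equally likely
sign assignments is built by convolution over doubled ranks, which is
arithmetically identical to full enumeration.  Exact for n <= 20; the
normal approximation with tie and continuity correction is used above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .deviation import DeformationSummary
from .errors import ArchmorphError, ValidationError

__all__ = [
    "WilcoxonResult",
    "PairedOutcomes",
    "NoNonzeroDifferences",
    "wilcoxon_signed_rank",
    "compare_conditions",
]

EXACT_LIMIT = 20


class NoNonzeroDifferences(ArchmorphError):
    """All paired differences are zero: the test statistic is undefined."""


@dataclass(frozen=True)
class WilcoxonResult:
    n_used: int
    statistic: float  # W = sum of positive-difference ranks
    p_value: float
    method: str  # "exact" | "normal-approx"
    has_ties: bool


@dataclass
class PairedOutcomes:
    """Per-specimen outcome summaries for the two storage conditions."""

    specimen_ids: list
    wet: list
    dry: list

    def __post_init__(self) -> None:
        if not (len(self.specimen_ids) == len(self.wet) == len(self.dry)):
            raise ValidationError("specimen ids and both condition lists must align")
        if len(self.specimen_ids) < 1:
            raise ValidationError("need at least one specimen")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, w, d in zip(self.specimen_ids, self.wet, self.dry):
            for cond, summary in (("W", w), ("D", d)):
                row = {"specimen": sid, "condition": cond}
                row.update(summary.as_row())
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PairedOutcomes":
        """Rebuild from the long-format outcomes table written by the pipeline."""
        required = {"specimen", "condition", *DeformationSummary.OUTCOME_NAMES}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"outcomes table missing columns: {sorted(missing)}")
        wet, dry, ids = [], [], []
        for sid, group in frame.groupby("specimen", sort=True):
            by_cond = {}
            for cond in ("W", "D"):
                sel = group[group["condition"] == cond]
                if len(sel) != 1:
                    raise ValidationError(
                        f"specimen {sid!r}: expected exactly one {cond} row"
                    )
                r = sel.iloc[0]
                by_cond[cond] = DeformationSummary(
                    max_plus=float(r["max_plus"]),
                    max_minus=float(r["max_minus"]),
                    area_plus=float(r["area_plus"]),
                    area_minus=float(r["area_minus"]),
                    volume_plus=float(r["volume_plus"]),
                    volume_minus=float(r["volume_minus"]),
                    cutoff=float(r.get("cutoff", 0.0) or 0.0),
                )
            ids.append(sid)
            wet.append(by_cond["W"])
            dry.append(by_cond["D"])
        return cls(ids, wet, dry)


def _exact_two_sided_p(ranks: np.ndarray, w: float) -> float:
    """P over all 2^n sign assignments of the realized rank multiset.

    Doubling the (average) ranks makes them integers, so the null
    distribution of 2W is an exact integer convolution.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = counts.sum()  # == 2^n
    w2 = int(np.rint(2.0 * w))
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray,
    zero_method: str = "wilcox",
) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test on differences x - y.

    ``zero_method='wilcox'`` drops zero differences before ranking (the
    classical convention); ``'pratt'`` ranks them but excludes their
    ranks from the statistic.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d samples")
    if len(x) < 1:
        raise ValidationError("need at least one pair")
    if zero_method not in ("wilcox", "pratt"):
        raise ValidationError(f"unknown zero_method {zero_method!r}")

    d = x - y
    nonzero = d != 0.0
    if not nonzero.any():
        raise NoNonzeroDifferences("no nonzero differences")

    if zero_method == "wilcox":
        d_used = d[nonzero]
        ranks = rankdata(np.abs(d_used), method="average")
    else:  # pratt: rank with zeros included, then drop the zero ranks
        all_ranks = rankdata(np.abs(d), method="average")
        d_used = d[nonzero]
        ranks = all_ranks[nonzero]

    n_used = int(nonzero.sum())
    w = float(ranks[d_used > 0.0].sum())
    abs_sorted = np.sort(np.abs(d_used))
    has_ties = bool(np.any(np.diff(abs_sorted) == 0.0))

    if n_used <= EXACT_LIMIT:
        p = _exact_two_sided_p(ranks, w)
        method = "exact"
    else:
        mu = ranks.sum() / 2.0
        sigma = np.sqrt((ranks**2).sum() / 4.0)
        delta = w - mu
        # continuity correction toward the mean
        z = (delta - 0.5 * np.sign(delta)) / sigma if delta != 0.0 else 0.0
        p = min(1.0, 2.0 * norm.sf(abs(z)))
        method = "normal-approx"

    return WilcoxonResult(
        n_used=n_used, statistic=w, p_value=p, method=method, has_ties=has_ties
    )


def compare_conditions(
    paired: PairedOutcomes, zero_method: str = "wilcox"
) -> pd.DataFrame:
    """Six D-vs-W Wilcoxon tests plus per-group medians and quartiles.

    No multiple-testing adjustment is applied.  A test whose differences
    are all zero is recorded in the table, not raised.  (A single-specimen
    table is allowed so the pipeline can still emit an annotated table.)
    """
    if len(paired.specimen_ids) < 1:
        raise ValidationError("need at least one specimen")
    rows = []
    for outcome in DeformationSummary.OUTCOME_NAMES:
        w_vals = np.array([getattr(s, outcome) for s in paired.wet])
        d_vals = np.array([getattr(s, outcome) for s in paired.dry])
        row = {
            "outcome": outcome,
            "n": len(w_vals),
            "W_median": float(np.median(w_vals)),
            "W_q1": float(np.percentile(w_vals, 25)),
            "W_q3": float(np.percentile(w_vals, 75)),
            "D_median": float(np.median(d_vals)),
            "D_q1": float(np.percentile(d_vals, 25)),
            "D_q3": float(np.percentile(d_vals, 75)),
        }
        try:
            res = wilcoxon_signed_rank(d_vals, w_vals, zero_method=zero_method)
            row.update(
                statistic=res.statistic,
                p_value=res.p_value,
                method=res.method,
                note="",
            )
        except NoNonzeroDifferences:
            row.update(
                statistic=np.nan,
                p_value=np.nan,
                method="",
                note="no nonzero differences",
            )
        rows.append(row)
    return pd.DataFrame(rows)
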