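"""Validation statistics: distributions, enrichment tests, ROC, rank
correlation with censoring, and half-life fitting from decay time courses.

These are the analyses used to relate ARE scores to mRNA stability: binned
score distributions, 2x2 enrichment of high-scoring sequences against a
randomized null (chi-square, Fisher's exact, phi coefficient), ROC
discrimination of labile versus stable transcripts, tie-aware Spearman
correlation in which censored half-lives (">240 min") rank as mutual ties at
the top, and log-linear least-squares fitting of transcription-shutoff decay
curves with censoring of slow decays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyResult",
    "RocResult",
    "DecayTimeCourse",
    "HalfLife",
    "score_distribution",
    "contingency_2x2",
    "enrichment_at_threshold",
    "roc_auc",
    "spearman",
    "fit_half_life",
    "group_summary",
]


# ---------------------------------------------------------------------------
# enrichment contingency tests


@dataclass(frozen=True)
class ContingencyResult:
    """A 2x2 table [[a, b], [c, d]] with its association statistics.

    ``chi2_p`` is the Pearson chi-square p-value without continuity
    correction; it is None when a zero margin makes the test undefined.
    ``fisher_p`` is the two-sided Fisher exact p-value. ``phi`` is
    (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)), zero by convention when a
    margin is zero.
    """

    a: int
    b: int
    c: int
    d: int
    chi2_p: float | None
    fisher_p: float
    phi: float

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def contingency_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Chi-square (no Yates correction), two-sided Fisher, and phi for a 2x2 table."""
    table = np.array([[a, b], [c, d]])
    margins = [a + b, c + d, a + c, b + d]
    if min(margins) == 0:
        chi2_p = None
        phi = 0.0
    else:
        chi2_p = float(sps.chi2_contingency(table, correction=False)[1])
        phi = (a * d - b * c) / math.sqrt(math.prod(margins))
    fisher_p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return ContingencyResult(a, b, c, d, chi2_p, fisher_p, phi)


def enrichment_at_threshold(
    real_scores: Sequence[float],
    control_scores: Sequence[float],
    thresh: float,
) -> ContingencyResult:
    """Enrichment of scores >= ``thresh`` in the real set versus a control set.

    Builds the table [[#real >= t, #real < t], [#control >= t, #control < t]];
    a positive phi means high scores are over-represented in the real set.
    """
    real = np.asarray(real_scores, dtype=float)
    ctrl = np.asarray(control_scores, dtype=float)
    if real.size == 0 or ctrl.size == 0:
        raise ValueError("both score sets must be non-empty")
    a = int((real >= thresh).sum())
    c = int((ctrl >= thresh).sum())
    return contingency_2x2(a, real.size - a, c, ctrl.size - c)


# ---------------------------------------------------------------------------
# distributions


def score_distribution(
    scores: Sequence[float], bin_edges: Sequence[float]
) -> pd.DataFrame:
    """Bin scores into half-open [lo, hi) bins; returns frequency + cumulative.

    The edges must cover every score; the final edge may be ``inf`` to make
    the last bin open-ended. Frequencies sum to 1.
    """
    scores = np.asarray(scores, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores to bin")
    if scores.min() < edges[0] or scores.max() >= edges[-1]:
        raise ValueError(
            f"scores outside [{edges[0]}, {edges[-1]}): "
            f"range is [{scores.min()}, {scores.max()}]"
        )
    # np.histogram closes its last bin; a sentinel edge keeps all bins half-open
    counts, _ = np.histogram(scores, bins=np.append(edges, np.inf))
    counts = counts[:-1]
    freq = counts / scores.size
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
            "frequency": freq,
            "cumulative": np.cumsum(freq),
        }
    )


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    """ROC curve from a full threshold sweep, plus its trapezoid AUC.

    The AUC equals the probability that a random positive outscores a random
    negative, ties counted one half (the Mann-Whitney statistic scaled by
    the number of pairs).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> RocResult:
    """ROC analysis: predict positive when score >= threshold, sweep all values.

    Thresholds are every unique observed score (descending) plus a sentinel
    above the maximum, so the curve runs from (0, 0) to (1, 1).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    uniq = np.unique(np.concatenate([pos, neg]))[::-1]
    thresholds = np.concatenate([[np.inf], uniq])
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


# ---------------------------------------------------------------------------
# rank correlation with censoring


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    x_censored: Sequence[bool] | None = None,
    y_censored: Sequence[bool] | None = None,
) -> float:
    """Spearman rank correlation with optional right-censored entries.

    Censored values (for instance half-lives recorded as ">240 min") are
    treated as mutually tied above every uncensored value; average ranks are
    used throughout, and the result is the Pearson correlation of the rank
    vectors. Returns NaN when either rank vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")

    def with_censoring(v: np.ndarray, cens: Sequence[bool] | None) -> np.ndarray:
        if cens is None:
            return v
        v = v.copy()
        v[np.asarray(cens, dtype=bool)] = np.inf
        return v

    rx = sps.rankdata(with_censoring(x, x_censored))
    ry = sps.rankdata(with_censoring(y, y_censored))
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(sps.pearsonr(rx, ry)[0])


# ---------------------------------------------------------------------------
# half-life fitting


@dataclass(frozen=True)
class HalfLife:
    """A fitted half-life in minutes, possibly censored (">limit")."""

    value: float | None
    censored: bool
    limit: float = 240.0

    def __str__(self) -> str:
        return f">{self.limit:g}" if self.censored else f"{self.value:g}"

    def as_rankable(self) -> float:
        """Numeric stand-in for ranking; censored values sort above all others."""
        return math.inf if self.censored else float(self.value)


@dataclass
class DecayTimeCourse:
    """One transcript's decay measurements after transcription shutoff.

    ``times`` in minutes (strictly increasing, starting at 0) and
    ``abundance`` relative to the value at time 0 (all positive).
    """

    times: np.ndarray
    abundance: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.times.size != self.abundance.size:
            raise ValueError("times and abundance must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.abundance <= 0):
            raise ValueError("abundance must be positive")


def fit_half_life(tc: DecayTimeCourse, censor_limit: float = 240.0) -> HalfLife:
    """Half-life by least squares on log abundance, censored at ``censor_limit``.

    Fits ln(abundance) = a + b*t; the half-life is ln(2)/|b|. A
    non-negative slope or a half-life beyond the censor limit — a decay too
    slow to quantify within the chase window — is reported as censored.
    Needs at least 3 time points including t = 0.
    """
    if tc.times.size < 3 or tc.times[0] != 0:
        raise ValueError("need >= 3 time points including t = 0")
    slope = np.polyfit(tc.times, np.log(tc.abundance), 1)[0]
    if slope >= 0:
        return HalfLife(None, censored=True, limit=censor_limit)
    t_half = math.log(2) / abs(slope)
    if t_half > censor_limit:
        return HalfLife(None, censored=True, limit=censor_limit)
    return HalfLife(t_half, censored=False, limit=censor_limit)


# ---------------------------------------------------------------------------
# grouped summaries


def group_summary(values: Sequence[float], group_labels: Sequence) -> pd.DataFrame:
    """Per-group mean +/- SE, with a two-sided t-test of each group vs the pooled mean.

    Groups of size 1 report their mean but no SE or p-value. Group order
    follows first appearance in ``group_labels``.
    """
    values = np.asarray(values, dtype=float)
    labels = list(group_labels)
    if values.size != len(labels) or values.size == 0:
        raise ValueError("values and group_labels must be equal-length and non-empty")
    pooled_mean = values.mean()
    order = list(dict.fromkeys(labels))
    rows = []
    for g in order:
        v = values[np.asarray([lab == g for lab in labels])]
        row = {"group": g, "n": v.size, "mean": v.mean(), "se": np.nan, "t_p": np.nan}
        if v.size > 1:
            row["se"] = v.std(ddof=1) / math.sqrt(v.size)
            if v.std(ddof=1) > 0:
                row["t_p"] = float(sps.ttest_1samp(v, pooled_mean)[1])
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["pooled_mean"] = float(pooled_mean)
    return out
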