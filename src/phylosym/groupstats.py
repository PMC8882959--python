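"""Group-difference and correlation statistics on communities.

ANOSIM and MRPP are seeded permutation tests on a distance matrix; the
Spearman correlation, Bartlett-gated two-sample t-test and one-way ANOVA
delegate to scipy.stats. Normality is not formally gated — the variance
gate uses Bartlett's test only; a Shapiro–Wilk advisory P is reported but
never changes the decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform

from .errors import InvalidArgumentError, UndefinedStatisticError

DEFAULT_PERMUTATIONS = 9999


@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int


@dataclass
class MrppResult:
    delta: float  # observed weighted mean within-group distance
    a: float  # chance-corrected within-group agreement
    p_value: float
    n_permutations: int


@dataclass
class TTestResult:
    bartlett_p: float
    chosen_test: str  # "student" | "welch"
    t: float
    p_value: float
    shapiro_p: tuple[float, float] | None = None  # advisory only


def _group_codes(dm, groups):
    if isinstance(groups, (pd.Series, dict)):
        groups = [groups[i] for i in dm.ids]
    groups = np.asarray(groups)
    if len(groups) != len(dm.ids):
        raise InvalidArgumentError("one group label per sample required")
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(labels[i]) for i in np.flatnonzero(sizes < 2)]
        raise InvalidArgumentError(f"singleton groups not allowed: {small}")
    return codes


def _within_mask_condensed(codes):
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    return codes[iu[0]] == codes[iu[1]]


def anosim(dm, groups, n_perm=DEFAULT_PERMUTATIONS, seed=None) -> AnosimResult:
    """Analysis of Similarities.

    R = (mean between-group rank - mean within-group rank) / (M/2), on the
    ranks (mean ranks for ties) of all M = n(n-1)/2 pairwise distances;
    P is one-sided from ``n_perm`` label permutations with the +1
    correction. R is 1 when every between-group distance exceeds every
    within-group one, and is invariant to monotone transforms of the
    distances.
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    codes = _group_codes(dm, groups)
    ranks = stats.rankdata(squareform(dm.data, checks=False))
    m = len(ranks)
    denom = m / 2.0

    def r_stat(c):
        within = _within_mask_condensed(c)
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = r_stat(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += r_stat(rng.permutation(codes)) >= r_obs
    p = (1 + hits) / (n_perm + 1)
    return AnosimResult(float(r_obs), float(p), n_perm)


def mrpp(dm, groups, n_perm=DEFAULT_PERMUTATIONS, seed=None) -> MrppResult:
    """Multi-Response Permutation Procedure.

    delta = sum_i (n_i/N) * (mean within-group-i distance); the
    chance-corrected statistic A = 1 - delta_obs / mean(delta_perm); small
    delta (A > 0) means groups are tighter than a random labeling. P is the
    fraction of permuted deltas <= delta_obs, with the +1 correction.
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    codes = _group_codes(dm, groups)
    dvec = squareform(dm.data, checks=False)
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    weights = np.bincount(codes) / n

    def delta(c):
        within = c[iu[0]] == c[iu[1]]
        out = 0.0
        for g, w in enumerate(weights):
            mask = within & (c[iu[0]] == g)
            out += w * dvec[mask].mean()
        return out

    d_obs = delta(codes)
    rng = np.random.default_rng(seed)
    perm_deltas = np.array([delta(rng.permutation(codes)) for _ in range(n_perm)])
    expected = perm_deltas.mean()
    if expected == 0:
        warnings.warn("all distances zero; MRPP A set to 0", stacklevel=2)
        a = 0.0
    else:
        a = 1.0 - d_obs / expected
    p = (1 + int((perm_deltas <= d_obs).sum())) / (n_perm + 1)
    return MrppResult(float(d_obs), float(a), float(p), n_perm)


def spearman_corr(x, y, exact_max_n=9):
    """Tie-corrected Spearman rank correlation with two-sided P.

    For n <= ``exact_max_n`` the P-value is exact, from full enumeration of
    the n! pairings; larger samples use the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidArgumentError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("constant input; correlation undefined")
    rho, p_approx = stats.spearmanr(x, y)
    n = len(x)
    if n <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx = (rx - rx.mean()) / rx.std()
        ry = (ry - ry.mean()) / ry.std()
        perms = np.array(list(permutations(range(n))))
        rhos = (ry[perms] * rx).mean(axis=1)
        p = float((np.abs(rhos) >= abs(rho) - 1e-12).mean())
        return float(rho), p
    return float(rho), float(p_approx)


def variance_gated_ttest(x, y, gate_alpha=0.05) -> TTestResult:
    """Two-sample comparison with a Bartlett variance gate.

    Bartlett's test decides between the pooled-variance Student t-test
    (Bartlett P >= ``gate_alpha``) and Welch's unequal-variance t-test;
    both P-values are two-sided. Shapiro–Wilk P-values for each sample are
    attached as an advisory and never alter the gate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InvalidArgumentError("each sample needs >= 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            warnings.warn("both samples constant and equal; t set to 0", stacklevel=2)
            return TTestResult(1.0, "student", 0.0, 1.0)
        raise UndefinedStatisticError("both samples constant with unequal means")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bart_p = float(stats.bartlett(x, y).pvalue)
        shapiro = (
            float(stats.shapiro(x).pvalue) if len(x) >= 3 else np.nan,
            float(stats.shapiro(y).pvalue) if len(y) >= 3 else np.nan,
        )
    welch = bart_p < gate_alpha
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return TTestResult(
        bart_p, "welch" if welch else "student",
        float(res.statistic), float(res.pvalue), shapiro,
    )


def oneway_anova(values, groups):
    """Classical one-way ANOVA F statistic and P across >= 2 groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    samples = [values[groups == lab] for lab in labels]
    if sum(len(s) for s in samples) <= len(labels):
        raise InvalidArgumentError("need more observations than groups")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        raise UndefinedStatisticError("zero total variance; F undefined")
    within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if within == 0:
        raise UndefinedStatisticError("zero residual variance; F undefined")
    res = stats.f_oneway(*samples)
    return float(res.statistic), float(res.pvalue)
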