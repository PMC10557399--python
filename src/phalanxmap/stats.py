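"""Statistical comparison chain for thickness maps and shaft properties.

The chain mirrors common practice in comparative skeletal morphometrics:

1. each of the 4850 thickness measurements is a variable in a PCA
   (covariance form: the variables share units);
2. group differences in thickness distribution are tested by permutational
   MANOVA (pseudo-F on Euclidean distances) on the first three PC scores,
   omnibus first, then pairwise with Bonferroni correction;
3. scalar traits are gated by Shapiro-Wilk normality and compared with
   Kruskal-Wallis + post hoc Dunn tests when non-normal;
4. palmar vs dorsal mean thickness is compared by paired t-tests with the
   palmar-minus-dorsal sign convention (dorsal-dominant bones give a
   negative t);
5. curvature is regressed against mean scaled thickness with digits pooled
   within a taxon.

All permutation procedures are seeded and reproduce bit-identical
p-values for the same seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA as _SKPCA

__all__ = [
    "PCAResult",
    "PermanovaResult",
    "RankTestResult",
    "PairedTResult",
    "RegressionResult",
    "pca_thickness",
    "permanova",
    "permanova_pairwise",
    "normality_gate",
    "kruskal_dunn",
    "paired_palmar_dorsal",
    "regress_ia_thickness",
]


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    scores: np.ndarray  # specimens x components
    loadings: np.ndarray  # components x variables
    variance_fraction: np.ndarray


def pca_thickness(X, n_components: int | None = None) -> PCAResult:
    """Covariance PCA of the specimen-by-variable thickness matrix.

    Variables are column-centered but not scaled to unit variance — all
    4850 thickness variables share the same units, and unit-variance
    scaling would inflate low-signal rays.  Component signs follow a
    deterministic convention: the loading of largest magnitude on each
    component is made positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 specimens")
    pca = _SKPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_fraction=pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    pairwise: pd.DataFrame | None = None


def _group_codes(groups):
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    return labels, codes


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Pseudo-F from a squared Euclidean distance matrix and group codes."""
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        m = codes == g
        ng = int(m.sum())
        ss_within += d2[np.ix_(m, m)].sum() / (2.0 * ng)
    ss_between = ss_total - ss_within
    if ss_total <= 0:  # all observations identical
        return 0.0, 0.0
    if ss_within == 0:
        return float("inf"), 1.0
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(
    X, groups, n_perm: int = 9999, seed: int = 0, method: str = "permutation"
) -> PermanovaResult:
    """One-way permutational MANOVA on Euclidean distances.

    ``X`` is the observations-by-features matrix (typically the first three
    PC scores).  The pseudo-F statistic is computed from the pairwise
    squared-distance matrix; its null distribution comes from random label
    permutations (``method='permutation'``, seeded) or from complete
    enumeration of all distinct label assignments (``method='exact'``,
    feasible only for small samples).  p respects the permutation lower
    bound 1/(n_perm + 1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels, codes = _group_codes(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs at least two members")
    diff = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    f_obs, r2 = _pseudo_f(d2, codes, g)
    if method == "exact":
        perms = _distinct_assignments(codes)
        stats = np.array([_pseudo_f(d2, p, g)[0] for p in perms])
        # the observed assignment is one of the enumerated ones
        p = float(np.mean(stats >= f_obs - 1e-12))
        n_used = len(perms)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            if _pseudo_f(d2, perm, g)[0] >= f_obs - 1e-12:
                count += 1
        p = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm
    else:
        raise ValueError("method must be 'permutation' or 'exact'")
    return PermanovaResult(
        pseudo_F=float(f_obs), R2=float(r2), p_value=float(p), n_permutations=n_used
    )


def _distinct_assignments(codes: np.ndarray):
    """All distinct relabelings preserving group sizes (multiset permutations)."""
    n = len(codes)
    counts = np.bincount(codes)
    out = []
    positions = list(range(n))

    def rec(remaining, assignment):
        if not remaining:
            out.append(np.array(assignment))
            return
        # assign the group of the first remaining position
        first, rest = remaining[0], remaining[1:]
        for g in range(len(counts)):
            used = assignment.count(g)
            if used < counts[g]:
                rec(rest, assignment + [g])

    rec(positions, [])
    return out


def permanova_pairwise(
    X, groups, n_perm: int = 9999, seed: int = 0
) -> pd.DataFrame:
    """All pairwise one-way permutational MANOVAs with Bonferroni correction.

    The Bonferroni multiplier is the number of group pairs; adjusted p is
    capped at 1.  Seeds are derived per pair from ``seed`` so the table is
    reproducible yet pairs are independent.
    """
    labels, codes = _group_codes(groups)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    n_comp = len(pairs)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_comp)
    for (a, b), cs in zip(pairs, child_seeds):
        m = (codes == a) | (codes == b)
        res = permanova(
            X[m], codes[m], n_perm=n_perm, seed=int(cs.generate_state(1)[0] % (2**31))
        )
        rows.append(
            {
                "group_a": labels[a],
                "group_b": labels[b],
                "pseudo_F": res.pseudo_F,
                "R2": res.R2,
                "p_raw": res.p_value,
                "p_bonferroni": min(1.0, res.p_value * n_comp),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# normality gate and rank tests

def normality_gate(values, groups, alpha: float = 0.05):
    """Choose the test family from per-group Shapiro-Wilk normality.

    Returns ``(route, table)`` where route is ``"parametric"`` when every
    group passes Shapiro-Wilk at ``alpha`` and ``"nonparametric"``
    otherwise.  Groups smaller than 3 observations, or with zero variance,
    default to the nonparametric route with a warning flag in the table.
    """
    values = np.asarray(values, dtype=float)
    labels, codes = _group_codes(groups)
    rows = []
    route = "parametric"
    for g, lab in enumerate(labels):
        v = values[codes == g]
        if len(v) < 3 or np.ptp(v) == 0:
            rows.append({"group": lab, "W": np.nan, "p": np.nan, "warning": True})
            route = "nonparametric"
            continue
        w, p = sps.shapiro(v)
        rows.append({"group": lab, "W": float(w), "p": float(p), "warning": False})
        if p < alpha:
            route = "nonparametric"
    return route, pd.DataFrame(rows)


@dataclass
class RankTestResult:
    H: float
    p_value: float
    dunn: pd.DataFrame
    shapiro: pd.DataFrame | None = None


def _dunn_test(values, codes, labels) -> pd.DataFrame:
    """Dunn's post hoc z tests on mean ranks with tie correction.

    Raw two-sided p and Bonferroni-adjusted p are both reported, since the
    choice of adjustment is often left unstated in applied work.
    """
    n = len(values)
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    pairs = list(itertools.combinations(range(len(labels)), 2))
    rows = []
    for a, b in pairs:
        ma, mb = codes == a, codes == b
        na, nb = int(ma.sum()), int(mb.sum())
        num = ranks[ma].mean() - ranks[mb].mean()
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = num / se if se > 0 else 0.0  # se = 0 only when every value ties
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": labels[a],
                "group_b": labels[b],
                "z": float(z),
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, p * len(pairs))),
            }
        )
    return pd.DataFrame(rows)


def kruskal_dunn(values, groups) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis test with Dunn post hoc comparisons."""
    values = np.asarray(values, dtype=float)
    labels, codes = _group_codes(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[codes == g] for g in range(len(labels))]
    if np.ptp(values) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    return RankTestResult(
        H=float(h), p_value=float(p), dunn=_dunn_test(values, codes, labels)
    )


# ---------------------------------------------------------------------------
# paired palmar/dorsal comparison

@dataclass
class PairedTResult:
    palmar_mean: float
    dorsal_mean: float
    t_ratio: float
    p_value: float
    n: int


def paired_palmar_dorsal(palmar, dorsal) -> PairedTResult:
    """Paired t-test on per-specimen (palmar - dorsal) mean thickness.

    Sign convention: dorsal-dominant cortices give a negative t ratio.
    """
    palmar = np.asarray(palmar, dtype=float)
    dorsal = np.asarray(dorsal, dtype=float)
    if palmar.shape != dorsal.shape or palmar.ndim != 1:
        raise ValueError("palmar and dorsal must be matching 1D arrays")
    n = len(palmar)
    if n < 2:
        raise ValueError("need at least two paired observations")
    d = palmar - dorsal
    if np.ptp(d) == 0 and d[0] == 0:
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(palmar, dorsal)
    return PairedTResult(
        palmar_mean=float(palmar.mean()),
        dorsal_mean=float(dorsal.mean()),
        t_ratio=float(t),
        p_value=float(p),
        n=n,
    )


# ---------------------------------------------------------------------------
# curvature vs thickness regression

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    R2: float
    p_value: float
    n: int
    pooled_digits: bool = True


def regress_ia_thickness(theta_deg, mean_thickness, pooled_digits: bool = True) -> RegressionResult:
    """OLS of mean scaled thickness on the included angle, digits pooled."""
    x = np.asarray(theta_deg, dtype=float)
    y = np.asarray(mean_thickness, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least three (theta, thickness) points")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        R2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
        pooled_digits=pooled_digits,
    )
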