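"""Statistical chain for the trial table.

The two per-trial movement totals (walking distance, head movements without
walking) are merged into a single 'movement component' by a correlation-matrix
PCA (varimax rotation, which is the identity for a single retained component),
preceded by Bartlett's test of sphericity on the 2x2 correlation matrix.
Component scores are made positive (shift by the most negative score, then
square root) before export to mixed-model software. Post hoc comparisons use
exact Wilcoxon signed-rank tests (within species, paired across phases) and
exact Wilcoxon rank-sum / Mann-Whitney tests (between species), with Holm's
sequential Bonferroni correction; repeatability across the two phases is
quantified by a one-way random-effects intraclass correlation (single
measure, consistency).

Exact two-sided p-values are defined by reflection of the standardized linear
statistic around its null expectation, P(|T - E[T]| >= |T_obs - E[T]|), with
midranks for ties and zero differences dropped; the null distribution is
computed exactly by dynamic programming over integer doubled ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import ValidationError

__all__ = [
    "PCAResult",
    "TestResult",
    "ICCResult",
    "movement_pca",
    "pca_two_variable",
    "bartlett_sphericity",
    "transform_positive_sqrt",
    "exact_wilcoxon_signed_rank",
    "exact_wilcoxon_rank_sum",
    "icc_oneway",
    "holm_adjust",
    "model_ready_table",
]

MOVEMENT_COLS = ("total_walking_px", "total_head_movement_px")


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the two movement variables."""

    eigenvalues: np.ndarray  # length 2, descending
    loadings: np.ndarray  # length 2: variable-component correlations, PC1
    scores: np.ndarray  # per-trial scores on PC1
    variance_explained: np.ndarray  # proportions, length 2
    correlation: float


@dataclass
class TestResult:
    """Outcome of one test in the chain.

    ``statistic`` is the standardized linear statistic Z for the Wilcoxon
    tests and the chi-square statistic for Bartlett's test.
    """

    test: str  # signed_rank | rank_sum | bartlett
    statistic: float
    p: float
    n: int
    df: int | None = None
    zeros_dropped: int = 0
    note: str = ""


@dataclass
class ICCResult:
    """One-way random-effects, single-measure, consistency ICC."""

    icc: float
    F: float
    df1: int
    df2: int
    p: float


def pca_two_variable(x: np.ndarray, y: np.ndarray) -> PCAResult:
    """Correlation-matrix PCA of two variables, retaining component 1.

    Closed form: for sample correlation r the eigenvalues are 1+|r| and
    1-|r|; the standardized loading of each variable on PC1 is
    sqrt((1+|r|)/2), reported with a nonnegative sign convention. Scores are
    the standardized data projected on the unit eigenvector. Varimax rotation
    of a single component is the identity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need two equal-length vectors with n >= 3")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValidationError("zero-variance variable: PCA undefined")
    zx = (x - x.mean()) / sx
    zy = (y - y.mean()) / sy
    r = float((zx * zy).sum() / (x.size - 1))
    corr = np.array([[1.0, r], [r, 1.0]])
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    v1 = eigvec[:, 0]
    # deterministic sign: loadings nonnegative when possible (r >= 0),
    # else first loading nonnegative
    if v1.sum() < 0 or (v1.sum() == 0 and v1[0] < 0):
        v1 = -v1
    loadings = v1 * np.sqrt(max(eigval[0], 0.0))
    scores = np.column_stack([zx, zy]) @ v1
    return PCAResult(
        eigenvalues=eigval,
        loadings=loadings,
        scores=scores,
        variance_explained=eigval / eigval.sum(),
        correlation=r,
    )


def movement_pca(table: pd.DataFrame, cols: tuple[str, str] = MOVEMENT_COLS) -> PCAResult:
    """PCA of the walking / head-movement totals of a trial table."""
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    return pca_two_variable(table[cols[0]].to_numpy(), table[cols[1]].to_numpy())


def bartlett_sphericity(r: float, n: int, p: int = 2) -> TestResult:
    """Bartlett's test of sphericity for a p-variable correlation matrix.

    chi2 = -(n - 1 - (2p+5)/6) * ln det(R), df = p(p-1)/2. For p = 2,
    det(R) = 1 - r^2 and df = 1.
    """
    if abs(r) >= 1.0:
        raise ValidationError("singular correlation matrix (|r| = 1)")
    if n <= p:
        raise ValidationError("need n > p")
    det = 1.0 - r * r
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * np.log(det)
    df = p * (p - 1) // 2
    pval = float(sps.chi2.sf(chi2, df))
    return TestResult(test="bartlett", statistic=float(chi2), p=pval, n=n, df=df)


def transform_positive_sqrt(scores: np.ndarray) -> np.ndarray:
    """Shift by |min| when the minimum is negative, then take square roots.

    Maps the most negative score to 0; inputs that are already all
    nonnegative are square-rooted unshifted.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("empty score vector")
    m = scores.min()
    shifted = scores + abs(m) if m < 0 else scores
    return np.sqrt(shifted)


def _midranks(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def _doubled_int_ranks(ranks: np.ndarray) -> np.ndarray:
    """Midranks doubled to exact integers (midranks are multiples of 1/2)."""
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    if not np.allclose(r2, 2.0 * ranks):
        raise AssertionError("midranks not half-integers")
    return r2


def _signed_rank_distribution(r2: np.ndarray) -> np.ndarray:
    """counts[t] = number of sign assignments with doubled positive-rank sum t."""
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for w in r2:
        counts[w:] = counts[w:] + counts[:-w] if w > 0 else counts[w:] * 2
    return counts


def exact_wilcoxon_signed_rank(x, y) -> TestResult:
    """Exact Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties take midranks. T is the sum of ranks
    of positive differences; Z = (T - E[T]) / sqrt(Var[T]) with the
    tie-corrected variance sum(r_j^2)/4; the exact two-sided p is the
    probability, over all 2^m equally likely sign assignments, of
    |T - E[T]| >= |T_obs - E[T]|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValidationError("paired samples must be nonempty and equal length")
    d = x - y
    nz = d != 0
    zeros = int(np.count_nonzero(~nz))
    d = d[nz]
    m = d.size
    if m == 0:
        warnings.warn("all differences are zero", stacklevel=2)
        return TestResult(
            test="signed_rank", statistic=0.0, p=1.0, n=int(x.size),
            zeros_dropped=zeros, note="all differences zero",
        )
    ranks = _midranks(np.abs(d))
    t_obs = float(ranks[d > 0].sum())
    e_t = float(ranks.sum()) / 2.0
    var_t = float((ranks**2).sum()) / 4.0
    z = (t_obs - e_t) / np.sqrt(var_t) if var_t > 0 else 0.0

    r2 = _doubled_int_ranks(ranks)
    counts = _signed_rank_distribution(r2)
    s2 = int(r2.sum())
    # integer deviation scale: |2*T2 - S2| with T2 the doubled rank sum
    d_obs = abs(int(np.rint(4.0 * t_obs)) - s2)
    t2 = np.arange(s2 + 1)
    p = float(counts[np.abs(2 * t2 - s2) >= d_obs].sum() / counts.sum())
    note = f"{zeros} zero differences dropped" if zeros else ""
    return TestResult(
        test="signed_rank", statistic=float(z), p=min(p, 1.0), n=int(x.size),
        zeros_dropped=zeros, note=note,
    )


def _rank_sum_distribution(r2: np.ndarray, n_a: int) -> np.ndarray:
    """counts[w] = number of size-n_a subsets with doubled rank sum w."""
    total = int(r2.sum())
    table = np.zeros((n_a + 1, total + 1), dtype=float)
    table[0, 0] = 1.0
    for w in r2:
        w = int(w)
        for k in range(n_a - 1, -1, -1):
            table[k + 1, w:] += table[k, : total + 1 - w]
    return table[n_a]


def exact_wilcoxon_rank_sum(a, b) -> TestResult:
    """Exact Wilcoxon rank-sum (Mann-Whitney U) test for two groups.

    W is the midrank sum of group a; Z uses the tie-corrected variance of
    sampling n_a ranks without replacement; the exact two-sided p enumerates
    all C(n, n_a) group assignments via |W - E[W]| reflection.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = _midranks(np.concatenate([a, b]))
    w_obs = float(ranks[:n_a].sum())
    e_w = n_a * (n + 1) / 2.0
    rbar = (n + 1) / 2.0
    pop_ss = float(((ranks - rbar) ** 2).sum())
    var_w = n_a * n_b * pop_ss / (n * (n - 1))
    z = (w_obs - e_w) / np.sqrt(var_w) if var_w > 0 else 0.0

    r2 = _doubled_int_ranks(ranks)
    counts = _rank_sum_distribution(r2, n_a)
    e2 = n_a * (n + 1)  # doubled expectation, exact integer
    d_obs = abs(int(np.rint(2.0 * w_obs)) - e2)
    w2 = np.arange(counts.size)
    p = float(counts[np.abs(w2 - e2) >= d_obs].sum() / counts.sum())
    return TestResult(
        test="rank_sum", statistic=float(z), p=min(p, 1.0), n=n,
        note=f"n_a={n_a}, n_b={n_b}",
    )


def icc_oneway(phase1, phase2) -> ICCResult:
    """One-way random-effects single-measure ICC over two repeated phases.

    ICC(1) = (MSB - MSW) / (MSB + (k-1) MSW) with k = 2 measurements per
    subject; F = MSB/MSW on (n-1, n(k-1)) degrees of freedom.
    """
    y = np.column_stack(
        [np.asarray(phase1, dtype=float), np.asarray(phase2, dtype=float)]
    )
    n, k = y.shape
    if n < 3:
        raise ValidationError("need at least 3 subjects")
    subj_means = y.mean(axis=1)
    grand = y.mean()
    ssb = k * ((subj_means - grand) ** 2).sum()
    ssw = ((y - subj_means[:, None]) ** 2).sum()
    df1 = n - 1
    df2 = n * (k - 1)
    msb = ssb / df1
    msw = ssw / df2
    if msb == 0 and msw == 0:
        raise ValidationError("degenerate data: no variance at all")
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f = msb / msw if msw > 0 else np.inf
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return ICCResult(icc=float(icc), F=float(f), df1=df1, df2=df2, p=p)


def holm_adjust(pvals) -> np.ndarray:
    """Holm's sequential Bonferroni adjustment, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[idx]))
        adj[idx] = running
    return adj


def model_ready_table(
    table: pd.DataFrame, pca: PCAResult | None = None
) -> pd.DataFrame:
    """Trial table augmented with the transformed movement component.

    Adds 'movement_component' (PC1 score) and 'movement_component_sqrt' (the
    positivized square-root transform), ready for external mixed-model
    software with species/phase/condition/testing_time/incubation_group as
    factors and subject_id as the random effect.
    """
    if pca is None:
        pca = movement_pca(table)
    out = table.copy()
    out["movement_component"] = pca.scores
    out["movement_component_sqrt"] = transform_positive_sqrt(pca.scores)
    return out
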