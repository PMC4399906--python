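"""Generalized weighted-sum statistics (GWSS) with permutation p-values.

A GWSS method is a triple (weight scheme, summary measure, threshold mode):

* weight scheme in {MAF, OR, D, DW} (see :mod:`gwss.variant_stats`);
* summary in {rank-sum, t-sum}: sum of case ranks of the aggregated
  per-subject burden scores, or the absolute Welch two-sample t statistic
  of case vs control scores;
* threshold mode: a fixed MAF cutoff theta (variants with adjusted control
  MAF above theta are dropped), or the variable-threshold (VT) supremum of
  the statistic over all candidate cutoffs — by default every distinct
  observed adjusted MAF.

The ten named methods (WSS, ORWSS, WSS-t, ORWSS-t, DSS-t, DWSS-t, VWSS-t,
VORWSS-t, VDSS-t, VDWSS-t) are registered in :data:`METHODS`.

Significance is assessed by permuting disease labels with the case/control
ratio fixed and recomputing the *entire* pipeline — adjusted MAFs, odds
ratios, weights, candidate thresholds and the statistic — under each
permuted labeling.  The empirical p-value uses the add-one estimator
(1 + #{S_perm >= S_obs}) / (B + 1).

The engine is vectorised across permutations: allele counts for all
labelings come from one matrix product, and the VT sweep reuses cumulative
sums over variants sorted by adjusted MAF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .variant_stats import (
    WEIGHT_SCHEMES,
    adjusted_control_maf,
    clean_genotypes,
    estimate_or,
    validate_phenotype,
    weights_from_counts,
)

__all__ = [
    "GenotypeMatrix",
    "GwssMethod",
    "METHODS",
    "TestResult",
    "resolve_method",
    "aggregate",
    "ranksum_summary",
    "tsum_summary",
    "threshold_set",
    "gwss_statistic",
    "permutation_pvalue",
    "permutation_test",
    "GwssTest",
]

_TIE_RTOL = 1e-9  # relative tolerance when comparing permuted to observed S


@dataclass
class GenotypeMatrix:
    """Subjects x variants minor-allele-count matrix with variant metadata."""

    G: np.ndarray
    variant_ids: Optional[Sequence[str]] = None
    subject_ids: Optional[Sequence[str]] = None
    variants: Optional[pd.DataFrame] = None  # chrom/pos/ref/alt provenance
    region_id: Optional[str] = None

    def __post_init__(self):
        self.G = clean_genotypes(self.G)
        if self.variant_ids is None:
            self.variant_ids = [f"v{j + 1}" for j in range(self.G.shape[1])]
        if len(self.variant_ids) != self.G.shape[1]:
            raise ValueError("variant_ids length does not match genotype columns")

    @property
    def n_subjects(self) -> int:
        return self.G.shape[0]

    @property
    def n_variants(self) -> int:
        return self.G.shape[1]


@dataclass(frozen=True)
class GwssMethod:
    """A (weight scheme, summary measure, threshold mode) triple.

    ``theta=None`` in fixed mode means "no MAF filter" (every variant kept).
    """

    name: str
    weight: str
    summary: str  # "rank-sum" | "t-sum"
    variable_threshold: bool = False
    theta: Optional[float] = None

    def __post_init__(self):
        if self.weight not in WEIGHT_SCHEMES:
            raise ValueError(f"unknown weight scheme {self.weight!r}")
        if self.summary not in ("rank-sum", "t-sum"):
            raise ValueError(f"unknown summary {self.summary!r}")
        if self.variable_threshold and self.theta is not None:
            raise ValueError("variable-threshold mode does not take a fixed theta")
        if self.theta is not None and not 0.0 < self.theta:
            raise ValueError("theta must be positive")


#: Registry of the ten named GWSS methods.  "V" = variable threshold,
#: "-t" = t-sum summary; bare WSS/ORWSS use rank-sum with a fixed cutoff.
METHODS: dict[str, GwssMethod] = {
    m.name: m
    for m in [
        GwssMethod("WSS", "MAF", "rank-sum"),
        GwssMethod("ORWSS", "OR", "rank-sum"),
        GwssMethod("WSS-t", "MAF", "t-sum"),
        GwssMethod("ORWSS-t", "OR", "t-sum"),
        GwssMethod("DSS-t", "D", "t-sum"),
        GwssMethod("DWSS-t", "DW", "t-sum"),
        GwssMethod("VWSS-t", "MAF", "t-sum", variable_threshold=True),
        GwssMethod("VORWSS-t", "OR", "t-sum", variable_threshold=True),
        GwssMethod("VDSS-t", "D", "t-sum", variable_threshold=True),
        GwssMethod("VDWSS-t", "DW", "t-sum", variable_threshold=True),
    ]
}


def resolve_method(method, theta: Optional[float] = None) -> GwssMethod:
    """Look up a method by Table-style name, or pass a GwssMethod through.

    ``theta`` attaches a fixed MAF cutoff to a fixed-threshold method.
    """
    if isinstance(method, GwssMethod):
        m = method
    else:
        try:
            m = METHODS[str(method)]
        except KeyError:
            raise ValueError(
                f"unknown method {method!r}; known methods: {sorted(METHODS)}"
            ) from None
    if theta is not None:
        if m.variable_threshold:
            raise ValueError(f"{m.name} uses a variable threshold; theta not allowed")
        m = replace(m, theta=float(theta))
    return m


@dataclass
class TestResult:
    """Outcome of one permutation test of one method on one region."""

    method: GwssMethod
    statistic: float
    p_value: float
    n_permutations: int
    selected_threshold: float
    per_threshold_thetas: Optional[np.ndarray] = None
    per_threshold_stats: Optional[np.ndarray] = None
    null_statistics: Optional[np.ndarray] = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Elementary operations (spec'd surface; the engine below re-derives them in
# stacked form for speed, and tests pin the two routes together).
# ---------------------------------------------------------------------------

def aggregate(G, w, q, theta=None):
    """Per-subject aggregated burden score G_i(theta) = sum_j w_j I(q_j<=theta) G_ij.

    ``theta=None`` applies no MAF filter.
    """
    G = np.asarray(G, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if G.ndim != 2 or w.shape != (G.shape[1],) or q.shape != (G.shape[1],):
        raise ValueError("genotypes, weights and MAFs must share variant order")
    if theta is not None:
        w = np.where(q <= theta, w, 0.0)
    return G @ w


def ranksum_summary(scores, y):
    """Sum of case subjects' ranks of the pooled scores (midranks for ties)."""
    scores = np.asarray(scores, dtype=np.float64)
    y = validate_phenotype(y)
    r = rankdata(scores, method="average")
    return float(r[y == 1].sum())


def tsum_summary(scores, y):
    """Absolute Welch two-sample t statistic of case vs control scores.

    Degenerate case (both group variances zero): 0 when the means agree,
    +inf otherwise (only possible on pathological tiny inputs; logged).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = validate_phenotype(y)
    s1, s0 = scores[y == 1], scores[y == 0]
    if s1.size < 2 or s0.size < 2:
        raise ValueError("t-sum needs at least 2 cases and 2 controls")
    num = abs(s1.mean() - s0.mean())
    den = np.sqrt(s1.var(ddof=1) / s1.size + s0.var(ddof=1) / s0.size)
    if den > 0.0:
        return float(num / den)
    if num <= 1e-9 * (1.0 + abs(s1.mean()) + abs(s0.mean())):
        return 0.0
    warnings.warn("degenerate t-sum: zero variance in both groups with unequal means")
    return float("inf")


def threshold_set(q, policy="observed", grid=None, theta=None):
    """Candidate MAF thresholds Theta for the variable-threshold sweep.

    ``observed`` (default): the sorted distinct adjusted control MAFs — the
    finest partition the data can distinguish.  ``grid``: a user-supplied
    increasing grid.  ``fixed``: the single value ``theta``.
    """
    q = np.asarray(q, dtype=np.float64)
    if q.size == 0:
        raise ValueError("empty frequency vector")
    if policy == "observed":
        return np.unique(q)
    if policy == "grid":
        if grid is None or len(grid) == 0:
            raise ValueError("grid policy requires a nonempty grid")
        return np.unique(np.asarray(grid, dtype=np.float64))
    if policy == "fixed":
        if theta is None:
            raise ValueError("fixed policy requires theta")
        return np.asarray([float(theta)])
    raise ValueError(f"unknown threshold policy {policy!r}")


# ---------------------------------------------------------------------------
# Vectorised engine
# ---------------------------------------------------------------------------

def _tsum_stack(scores, P, n1, n0):
    """Welch |t| for stacked scores (rows, T, n) against labelings P (rows, n)."""
    mean_all = scores.mean(axis=-1, keepdims=True)
    sc = scores - mean_all  # centering improves the moment computation
    s1 = np.einsum("btn,bn->bt", sc, P)
    ss1 = np.einsum("btn,bn->bt", sc * sc, P)
    st = sc.sum(axis=-1)
    sst = (sc * sc).sum(axis=-1)
    s0 = st - s1
    ss0 = sst - ss1
    m1, m0 = s1 / n1, s0 / n0
    v1 = np.maximum(ss1 - s1 * s1 / n1, 0.0) / (n1 - 1)
    v0 = np.maximum(ss0 - s0 * s0 / n0, 0.0) / (n0 - 1)
    num = np.abs(m1 - m0)
    den = np.sqrt(v1 / n1 + v0 / n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / den
    degenerate = den == 0.0
    if degenerate.any():
        tol = 1e-9 * (1.0 + np.abs(m1) + np.abs(m0))
        t = np.where(degenerate, np.where(num <= tol, 0.0, np.inf), t)
    return t


def _ranksum_stack(scores, P):
    """Case rank-sum for stacked scores (rows, T, n), midranks for ties."""
    r = rankdata(scores, method="average", axis=-1)
    return np.einsum("btn,bn->bt", r, P)


def _method_stats(G, P, q, or_hat, n1, n0, method):
    """Statistic S and selected theta for every labeling row in the chunk.

    Returns (S, theta_sel, per_threshold) where per_threshold is
    (thetas, stats) for the first row (or None in fixed mode).
    """
    rows, k = q.shape
    w = weights_from_counts(method.weight, q, or_hat, n0)

    if not method.variable_threshold:
        if method.theta is not None:
            w = np.where(q <= method.theta, w, 0.0)
        scores = (w @ G.T)[:, None, :]  # (rows, 1, n)
        if method.summary == "t-sum":
            stats = _tsum_stack(scores, P, n1, n0)
        else:
            stats = _ranksum_stack(scores, P)
        theta_sel = np.full(rows, np.inf if method.theta is None else method.theta)
        return stats[:, 0], theta_sel, None

    # VT sweep: sort variants by adjusted MAF per labeling, take cumulative
    # weighted scores; a cumulative position is a valid threshold only at the
    # end of a run of tied q values.
    order = np.argsort(q, axis=1, kind="stable")
    qs = np.take_along_axis(q, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    contrib = ws[:, :, None] * G.T[order]  # (rows, k, n)
    scores = np.cumsum(contrib, axis=1)
    if method.summary == "t-sum":
        stats = _tsum_stack(scores, P, n1, n0)
    else:
        stats = _ranksum_stack(scores, P)
    valid = np.empty_like(qs, dtype=bool)
    valid[:, -1] = True
    valid[:, :-1] = qs[:, 1:] > qs[:, :-1]
    masked = np.where(valid, stats, -np.inf)
    idx = np.argmax(masked, axis=1)  # first max = smallest theta on ties
    rows_i = np.arange(rows)
    S = masked[rows_i, idx]
    theta_sel = qs[rows_i, idx]
    per_threshold = (qs[0][valid[0]], stats[0][valid[0]])
    return S, theta_sel, per_threshold


def _engine(G, y, methods, permutations, chunk_size=64):
    """Run the full pipeline for the observed labeling plus each permutation.

    ``permutations``: (B, n) matrix of 0/1 label rows, each with the observed
    case count.  Returns per-method dicts of stacked results.
    """
    G = np.asarray(G, dtype=np.float64)
    y = validate_phenotype(y)
    n, k = G.shape
    if y.size != n:
        raise ValueError("phenotype length does not match genotype rows")
    n1 = int(y.sum())
    n0 = n - n1
    labels = np.vstack([y[None, :], permutations]) if permutations is not None else y[None, :]
    if labels.shape[1] != n:
        raise ValueError("permutation rows must match subject count")
    rows = labels.shape[0]
    colsum = G.sum(axis=0)

    out = {m.name: {"S": np.empty(rows), "theta": np.empty(rows), "per_threshold": None}
           for m in methods}
    for start in range(0, rows, chunk_size):
        P = labels[start:start + chunk_size].astype(np.float64)
        A = P @ G  # minor alleles in cases, per labeling row
        M = colsum[None, :] - A
        q = adjusted_control_maf(control_alleles=M, n_controls=n0)
        or_hat = estimate_or(case_alleles=A, control_alleles=M,
                             n_cases=n1, n_controls=n0)
        for m in methods:
            S, th, per = _method_stats(G, P, q, or_hat, n1, n0, m)
            out[m.name]["S"][start:start + P.shape[0]] = S
            out[m.name]["theta"][start:start + P.shape[0]] = th
            if start == 0:
                out[m.name]["per_threshold"] = per
    return out


def _sample_permutations(y, B, rng):
    """B uniform label permutations (case count preserved), with replacement."""
    y = np.asarray(y, dtype=np.int8)
    return rng.permuted(np.tile(y, (B, 1)), axis=1)


def _pvalue(S_obs, S_perm):
    ge = (S_perm > S_obs) | np.isclose(S_perm, S_obs, rtol=_TIE_RTOL, atol=1e-12)
    if np.isinf(S_obs):
        ge = S_perm >= S_obs  # inf >= inf counts as a tie
    return (1.0 + int(ge.sum())) / (S_perm.size + 1.0)


def _as_array(genotypes):
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.G
    return clean_genotypes(genotypes)


def gwss_statistic(genotypes, y, method="VDWSS-t", theta=None):
    """Observed GWSS statistic S, selected threshold, and the VT profile.

    Returns ``(S, selected_theta, (thetas, stats_per_theta))``; the profile
    is ``None`` for fixed-threshold methods.  ``selected_theta`` is +inf for
    an unfiltered fixed method, and the smallest maximising cutoff in VT
    mode.
    """
    m = resolve_method(method, theta)
    G = _as_array(genotypes)
    out = _engine(G, y, [m], permutations=None)[m.name]
    return float(out["S"][0]), float(out["theta"][0]), out["per_threshold"]


def permutation_test(genotypes, y, methods=("VDWSS-t",), n_permutations=1000,
                     seed=None, rng=None, theta=None, permutations=None,
                     keep_null=False):
    """Permutation test of several GWSS methods on one region.

    All methods share the same permuted labelings (common random numbers),
    and the per-labeling allele counts are computed once, so testing the
    whole Table-1 family costs little more than a single method.

    Parameters
    ----------
    methods : iterable of method names or GwssMethod
    n_permutations : B; ignored when an explicit ``permutations`` matrix
        (B x n rows of 0/1 labels with the observed case count) is given.
    theta : optional fixed MAF cutoff applied to every fixed-mode method.
    keep_null : store the B permuted statistics on each result.

    Returns dict: method name -> :class:`TestResult`.
    """
    # theta only attaches to fixed-threshold methods
    ms = []
    for m in methods:
        m = resolve_method(m)
        if theta is not None and not m.variable_threshold:
            m = replace(m, theta=float(theta))
        ms.append(m)
    G = _as_array(genotypes)
    y = validate_phenotype(y)
    if permutations is None:
        if n_permutations < 1:
            raise ValueError("need at least one permutation")
        if rng is None:
            rng = np.random.default_rng(seed)
        permutations = _sample_permutations(y, int(n_permutations), rng)
    else:
        permutations = np.asarray(permutations, dtype=np.int8)
        if permutations.ndim != 2 or not np.all(permutations.sum(axis=1) == y.sum()):
            raise ValueError("explicit permutations must be rows of labels "
                             "with the observed case count")
    out = _engine(G, y, ms, permutations)
    results = {}
    for m in ms:
        S = out[m.name]["S"]
        per = out[m.name]["per_threshold"]
        results[m.name] = TestResult(
            method=m,
            statistic=float(S[0]),
            p_value=_pvalue(S[0], S[1:]),
            n_permutations=permutations.shape[0],
            selected_threshold=float(out[m.name]["theta"][0]),
            per_threshold_thetas=None if per is None else per[0],
            per_threshold_stats=None if per is None else per[1],
            null_statistics=S[1:].copy() if keep_null else None,
        )
    return results


def permutation_pvalue(genotypes, y, method="VDWSS-t", n_permutations=1000,
                       seed=None, rng=None, theta=None, permutations=None,
                       keep_null=False) -> TestResult:
    """Permutation test of a single GWSS method; see :func:`permutation_test`."""
    m = resolve_method(method, theta)
    return permutation_test(genotypes, y, [m], n_permutations=n_permutations,
                            seed=seed, rng=rng, permutations=permutations,
                            keep_null=keep_null)[m.name]


class GwssTest(BaseEstimator):
    """Scikit-learn-style front end to the GWSS permutation test.

    Parameters
    ----------
    method : str or GwssMethod, default "VDWSS-t"
        One of the ten registered method names, or a custom triple.
    n_permutations : int, default 1000
        Number of label permutations B for the empirical p-value.
    theta : float or None
        Fixed MAF cutoff for fixed-threshold methods (None = no filter).
    random_state : int, Generator or None
        Seed for the permutation stream; fixing it makes the result
        bit-reproducible.

    Attributes (after :meth:`fit`)
    ------------------------------
    statistic_ : float observed summary statistic S.
    p_value_ : float empirical permutation p-value in (0, 1].
    selected_threshold_ : float cutoff achieving the supremum (VT mode).
    per_threshold_stats_ : DataFrame of S_theta over the candidate cutoffs
        (VT mode only).
    result_ : the underlying :class:`TestResult`.
    """

    def __init__(self, method="VDWSS-t", n_permutations=1000, theta=None,
                 random_state=None):
        self.method = method
        self.n_permutations = n_permutations
        self.theta = theta
        self.random_state = random_state

    def fit(self, X, y):
        """Run the permutation test of X (subjects x variants counts) vs y."""
        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        res = permutation_pvalue(X, y, method=self.method,
                                 n_permutations=self.n_permutations,
                                 rng=rng, theta=self.theta)
        self.n_features_in_ = _as_array(X).shape[1]
        self.result_ = res
        self.statistic_ = res.statistic
        self.p_value_ = res.p_value
        self.selected_threshold_ = res.selected_threshold
        if res.per_threshold_thetas is not None:
            self.per_threshold_stats_ = pd.DataFrame(
                {"theta": res.per_threshold_thetas, "statistic": res.per_threshold_stats}
            )
        else:
            self.per_threshold_stats_ = None
        return self
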