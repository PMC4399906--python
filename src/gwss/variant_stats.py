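"""Per-variant summary statistics and weight schemes for weighted-sum tests.

All quantities here are functions of a minor-allele-count genotype matrix
``G`` (subjects x variants, entries in {0, 1, 2}) and a binary phenotype
vector ``y`` (1 = case, 0 = control).  They are recomputed from scratch for
every permutation of ``y`` by the permutation engine, so everything is
vectorised to accept a *stack* of phenotype labelings: the ``case_alleles``
/ ``control_alleles`` arguments of the low-level helpers may be 2-D with one
row per labeling.
"""

from __future__ import annotations

import warnings

import numpy as np

WEIGHT_SCHEMES = ("MAF", "OR", "D", "DW")

__all__ = [
    "WEIGHT_SCHEMES",
    "validate_phenotype",
    "clean_genotypes",
    "minor_allele_counts",
    "adjusted_control_maf",
    "estimate_or",
    "compute_weights",
    "weights_from_counts",
]


def validate_phenotype(y) -> np.ndarray:
    """Validate a 0/1 disease-status vector; return it as an int8 array.

    Requires at least one case and one control.
    """
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError("phenotype must be a 1-D vector")
    vals = np.unique(y)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError("phenotype labels must be 0 (control) or 1 (case)")
    y = y.astype(np.int8)
    if y.sum() < 1 or (y.size - y.sum()) < 1:
        raise ValueError("need at least one case and one control")
    return y


def clean_genotypes(G, missing_warn_frac: float = 0.2) -> np.ndarray:
    """Validate a minor-allele-count matrix and impute missing entries to 0.

    Missing entries may be encoded as NaN or any negative value.  Imputing
    to 0 copies is conservative toward the null (it removes carrier signal
    rather than inventing it).  A per-variant missingness rate above
    ``missing_warn_frac`` triggers a warning.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (subjects x variants)")
    miss = ~np.isfinite(G) | (G < 0)
    if miss.any():
        rate = miss.mean(axis=0)
        bad = np.flatnonzero(rate > missing_warn_frac)
        if bad.size:
            warnings.warn(
                f"{bad.size} variant(s) exceed {missing_warn_frac:.0%} "
                f"missing genotypes (max {rate.max():.1%}); "
                "missing entries imputed to 0 copies"
            )
        G = np.where(miss, 0.0, G)
    if not np.all(np.isin(G, [0, 1, 2])):
        raise ValueError("genotype entries must be 0, 1 or 2 (or missing)")
    return G.astype(np.int8)


def minor_allele_counts(G, y):
    """Minor-allele counts per variant in cases and controls.

    Returns ``(case_alleles, control_alleles)``, each of length k.
    """
    G = np.asarray(G, dtype=np.float64)
    y = validate_phenotype(y)
    a = y.astype(np.float64) @ G
    m = G.sum(axis=0) - a
    return a, m


def adjusted_control_maf(G=None, y=None, *, control_alleles=None, n_controls=None):
    """Pseudo-count-adjusted minor-allele frequency in controls.

    q_j = (m_j + 1) / (2 n0 + 2), where m_j is the minor-allele count of
    variant j among the n0 controls.  The +1/+2 adjustment keeps q_j
    strictly inside (0, 1) even for monomorphic variants, so MAF-based
    weights are always finite.

    Either pass ``(G, y)`` or precomputed ``control_alleles`` (any shape,
    e.g. one row per permuted labeling) with ``n_controls``.
    """
    if control_alleles is None:
        _, control_alleles = minor_allele_counts(G, y)
        n_controls = int(np.sum(np.asarray(y) == 0))
    if n_controls < 1:
        raise ValueError("need at least one control to compute adjusted MAF")
    return (np.asarray(control_alleles, dtype=np.float64) + 1.0) / (2.0 * n_controls + 2.0)


def estimate_or(G=None, y=None, *, case_alleles=None, control_alleles=None,
                n_cases=None, n_controls=None):
    """Continuity-corrected per-variant odds ratio from allele-count tables.

    For each variant the 2x2 table of (minor, major) alleles in (cases,
    controls) gets 0.5 added to every cell; the cross-product ratio

        OR_j = (a + .5)(d + .5) / ((b + .5)(c + .5))

    with a = minor alleles in cases, b = major in cases, c = minor in
    controls, d = major in controls, is then always finite and positive.
    """
    if case_alleles is None:
        case_alleles, control_alleles = minor_allele_counts(G, y)
        y = validate_phenotype(y)
        n_cases = int(y.sum())
        n_controls = int(y.size - y.sum())
    a = np.asarray(case_alleles, dtype=np.float64)
    c = np.asarray(control_alleles, dtype=np.float64)
    b = 2.0 * n_cases - a
    d = 2.0 * n_controls - c
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


def weights_from_counts(scheme, q, or_hat, n_controls):
    """The four weight schemes, vectorised over any shape of q / or_hat.

    MAF : w_j = 1 / sqrt(n0 q_j (1 - q_j))          (Madsen-Browning style;
          rarer in controls => larger weight; direction-blind)
    OR  : w_j = log(OR_j)                           (signed strength)
    D   : w_j = I(OR_j > 1) - I(OR_j < 1)           (direction only)
    DW  : w_j = D_j * MAF_j                          (signed MAF weight)
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {scheme!r}; expected one of {WEIGHT_SCHEMES}")
    if scheme in ("MAF", "DW"):
        q = np.asarray(q, dtype=np.float64)
        maf_w = 1.0 / np.sqrt(n_controls * q * (1.0 - q))
        if scheme == "MAF":
            return maf_w
    if scheme in ("OR", "D", "DW"):
        or_hat = np.asarray(or_hat, dtype=np.float64)
        if scheme == "OR":
            return np.log(or_hat)
        d = (or_hat > 1.0).astype(np.float64) - (or_hat < 1.0).astype(np.float64)
        if scheme == "D":
            return d
        return d * maf_w


def compute_weights(scheme, G, y):
    """Per-variant weights of the given scheme from data.

    Convenience wrapper: computes adjusted control MAFs and odds ratios from
    ``(G, y)`` and applies :func:`weights_from_counts`.
    """
    y = validate_phenotype(y)
    a, m = minor_allele_counts(G, y)
    n1 = int(y.sum())
    n0 = int(y.size) - n1
    q = adjusted_control_maf(control_alleles=m, n_controls=n0)
    or_hat = estimate_or(case_alleles=a, control_alleles=m, n_cases=n1, n_controls=n0)
    return weights_from_counts(scheme, q, or_hat, n0)
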