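"""Case-control genotype/phenotype simulator with latent-Gaussian LD.

The generative model, used throughout the power studies:

* Each variant j has a minor-allele frequency MAF_j drawn uniformly from a
  range set by its class — rare variants from U(0.001, 0.01) (signal RVs
  from U(0.001, 0.005) in "different" MAF mode), common variants from
  U(0.01, 0.1).  Variant positions (which columns are signal vs noise) are
  a uniform random permutation, redrawn per dataset.
* Genotypes come from a threshold model on two independent latent Gaussian
  haplotype vectors per subject with AR(1) correlation rho^|u-v| between
  variants: the haplotype carries the minor allele at variant j iff its
  latent value falls below the MAF_j-quantile of N(0,1); the genotype sums
  the two indicators.  rho = 0 gives independent Binomial(2, MAF_j) counts.
* Disease follows a logistic liability model with baseline prevalence 0.05:
  the first four signal variants act additively on the log-odds (per-allele
  odds ratio ``or_rv``; a signal CV, when present, replaces one additive
  slot with ``or_cv``), and the remaining four signal variants form an
  "any-carrier" block multiplying the odds by ``or_carrier`` if any of them
  carries a minor allele.
* Case-control sampling is by rejection: population subjects are drawn
  until the case and control strata (default 500/500) are both full.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .gwss_test import GenotypeMatrix

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "draw_mafs",
    "sample_genotypes",
    "disease_probability",
    "sample_case_control",
]

ROLE_ADDITIVE_RV = "signal_rv_additive"
ROLE_ADDITIVE_CV = "signal_cv_additive"
ROLE_CARRIER_RV = "signal_rv_carrier"
ROLE_NOISE_RV = "noise_rv"
ROLE_NOISE_CV = "noise_cv"


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario of the power study grid.

    Defaults are the base study conditions: 500 cases / 500 controls,
    8 signal rare variants (4 additive with per-allele OR 2, 4 in the
    any-carrier block with joint OR 3), no noise variants, independent
    variants, identical MAF distributions for signal and noise RVs, and
    background prevalence 0.05.
    """

    n_cases: int = 500
    n_controls: int = 500
    n_signal_rv: int = 8
    n_signal_cv: int = 0
    n_noise_rv: int = 0
    n_noise_cv: int = 0
    maf_mode: str = "identical"  # or "different" (signal RVs rarer)
    rho: float = 0.0
    or_rv: float = 2.0
    or_cv: float = 1.5
    or_carrier: float = 3.0
    prevalence: float = 0.05
    maf_signal_rv: Optional[Tuple[float, float]] = None
    maf_noise_rv: Tuple[float, float] = (0.001, 0.01)
    maf_cv: Tuple[float, float] = (0.01, 0.1)

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if self.n_variants < 1:
            raise ValueError("scenario must contain at least one variant")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.maf_mode not in ("identical", "different"):
            raise ValueError("maf_mode must be 'identical' or 'different'")
        if self.n_signal_cv not in (0, 1):
            raise ValueError("at most one signal CV is supported")
        for lo, hi in (self.signal_rv_range, self.maf_noise_rv, self.maf_cv):
            if not (0.0 < lo < hi < 0.5):
                raise ValueError("MAF ranges must satisfy 0 < lo < hi < 0.5")

    @property
    def n_variants(self) -> int:
        return self.n_signal_rv + self.n_signal_cv + self.n_noise_rv + self.n_noise_cv

    @property
    def signal_rv_range(self) -> Tuple[float, float]:
        if self.maf_signal_rv is not None:
            return self.maf_signal_rv
        return (0.001, 0.005) if self.maf_mode == "different" else (0.001, 0.01)

    def protective(self) -> "ScenarioSpec":
        """The protective-effects counterpart of this scenario.

        The additive per-allele odds ratios (rare-variant and CV slots) are
        inverted; the any-carrier block keeps its effect, since the
        liability model fixes that term at odds 3 regardless of the
        direction of the additive effects.
        """
        return replace(self, or_rv=1.0 / self.or_rv, or_cv=1.0 / self.or_cv)

    def null(self) -> "ScenarioSpec":
        """Same genotype structure with every effect switched off."""
        return replace(self, or_rv=1.0, or_cv=1.0, or_carrier=1.0)


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotype: np.ndarray
    truth: pd.DataFrame  # per-variant: role, maf


def draw_mafs(spec: ScenarioSpec, rng: np.random.Generator):
    """Draw per-variant MAFs and roles; column order is randomised.

    The signal block is ordered additive-first internally, then the whole
    set of columns is permuted uniformly, so signal positions are random.
    A signal CV, when present, takes one additive slot.
    """
    roles = []
    n_sig = spec.n_signal_rv + spec.n_signal_cv
    n_carrier = min(4, n_sig) if n_sig > 4 else 0
    n_additive = n_sig - n_carrier
    n_additive_rv = n_additive - spec.n_signal_cv
    if n_additive_rv < 0:
        raise ValueError("signal CV requires at least one additive slot")
    roles += [ROLE_ADDITIVE_CV] * spec.n_signal_cv
    roles += [ROLE_ADDITIVE_RV] * n_additive_rv
    roles += [ROLE_CARRIER_RV] * n_carrier
    roles += [ROLE_NOISE_RV] * spec.n_noise_rv
    roles += [ROLE_NOISE_CV] * spec.n_noise_cv
    roles = np.asarray(roles, dtype=object)

    lo_hi = {
        ROLE_ADDITIVE_RV: spec.signal_rv_range,
        ROLE_CARRIER_RV: spec.signal_rv_range,
        ROLE_ADDITIVE_CV: spec.maf_cv,
        ROLE_NOISE_RV: spec.maf_noise_rv,
        ROLE_NOISE_CV: spec.maf_cv,
    }
    mafs = np.empty(roles.size)
    for j, role in enumerate(roles):
        lo, hi = lo_hi[role]
        mafs[j] = rng.uniform(lo, hi)
    perm = rng.permutation(roles.size)
    return mafs[perm], roles[perm]


def sample_genotypes(mafs, rho: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Genotype matrix from the latent-Gaussian AR(1) threshold model.

    Two independent latent N(0, Sigma) vectors per subject with
    Sigma_uv = rho^|u-v| (generated by the exact scalar AR(1) recursion);
    each contributes a minor allele at variant j when its value is below
    Phi^{-1}(MAF_j).
    """
    mafs = np.asarray(mafs, dtype=np.float64)
    k = mafs.size
    thresh = norm.ppf(mafs)
    G = np.zeros((n, k), dtype=np.int8)
    for _ in range(2):  # two haplotypes
        eps = rng.standard_normal((n, k))
        if rho > 0.0:
            Z = np.empty_like(eps)
            Z[:, 0] = eps[:, 0]
            c = np.sqrt(1.0 - rho * rho)
            for u in range(1, k):
                Z[:, u] = rho * Z[:, u - 1] + c * eps[:, u]
        else:
            Z = eps
        G += (Z <= thresh).astype(np.int8)
    return G


def _log_odds_effects(roles, spec: ScenarioSpec):
    """Per-variant additive log-OR vector and the carrier-block mask."""
    beta = np.zeros(roles.size)
    beta[roles == ROLE_ADDITIVE_RV] = np.log(spec.or_rv)
    beta[roles == ROLE_ADDITIVE_CV] = np.log(spec.or_cv)
    carrier = roles == ROLE_CARRIER_RV
    return beta, carrier


def disease_probability(G, roles, spec: ScenarioSpec) -> np.ndarray:
    """P(D=1 | G) under the logistic liability model, vectorised over rows.

    logit P = logit(prevalence) + sum(additive log-OR * G) +
              log(or_carrier) * I(any carrier-block minor allele).
    """
    G = np.atleast_2d(np.asarray(G, dtype=np.float64))
    roles = np.asarray(roles, dtype=object)
    if G.shape[1] != roles.size:
        raise ValueError("genotypes and truth roles disagree on variant count")
    beta, carrier = _log_odds_effects(roles, spec)
    lo = logit(spec.prevalence) + G @ beta
    if carrier.any():
        lo = lo + np.log(spec.or_carrier) * (G[:, carrier].sum(axis=1) > 0)
    return expit(lo)


def sample_case_control(spec: ScenarioSpec, rng=None, seed=None,
                        max_draws: int = 5_000_000) -> SimulatedDataset:
    """Simulate one case-control dataset by rejection sampling.

    Population subjects are drawn in batches until both strata are full;
    surplus subjects of a filled stratum are discarded.  Raises after
    ``max_draws`` population draws if a stratum is unreachable.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mafs, roles = draw_mafs(spec, rng)
    need = {1: spec.n_cases, 0: spec.n_controls}
    pools = {1: [], 0: []}
    drawn = 0
    # expected draws to fill the rarer stratum, with headroom
    batch = int(min(max(1024, 1.3 * max(spec.n_cases, spec.n_controls) / min(spec.prevalence, 1 - spec.prevalence)), 65536))
    while need[1] > 0 or need[0] > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                f"case-control sampling did not converge after {drawn} draws "
                f"(still need {need[1]} cases, {need[0]} controls); "
                "check the scenario's prevalence and effect sizes"
            )
        batch = int(min(batch, max_draws - drawn))
        Gb = sample_genotypes(mafs, spec.rho, batch, rng)
        p = disease_probability(Gb, roles, spec)
        d = rng.random(batch) < p
        drawn += batch
        for status in (1, 0):
            if need[status] > 0:
                take = Gb[d == bool(status)][: need[status]]
                pools[status].append(take)
                need[status] -= take.shape[0]
        batch = min(batch, 65536)
    G = np.vstack(pools[1] + pools[0])
    y = np.concatenate([np.ones(spec.n_cases, dtype=np.int8),
                        np.zeros(spec.n_controls, dtype=np.int8)])
    truth = pd.DataFrame({
        "variant_id": [f"v{j + 1}" for j in range(spec.n_variants)],
        "role": roles,
        "maf": mafs,
    })
    gm = GenotypeMatrix(G, variant_ids=list(truth["variant_id"]))
    return SimulatedDataset(genotypes=gm, phenotype=y, truth=truth)
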