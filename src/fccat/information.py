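"""Fisher information for forced-choice pairs, posterior information, and SEMs.

For a pair :math:`\\{i,k\\}` the Fisher information matrix in the trait metric
is the rank-one outer product

.. math::

    F_{\\{i,k\\}}(\\eta) = \\frac{[\\phi(z)]^2 \\,
        (\\lambda_i - \\lambda_k)(\\lambda_i - \\lambda_k)^T}
        {p(1-p)(\\psi_i^2 + \\psi_k^2)},

the negative expected Hessian of the Bernoulli log-likelihood.  Test
information sums these over administered pairs; adding the inverse trait
covariance of a multivariate normal prior yields the posterior information
used both for Bayesian A-optimality selection and for directional standard
errors of measurement:  :math:`\\mathrm{SEM}_s = \\sqrt{(I^{-1})_{ss}}`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.special import ndtr

from .bank import ItemBank
from .model import PairBlock, Z_CLAMP, _as_eta, _pair_indices

__all__ = [
    "PriorSpec",
    "PeakLocus",
    "pair_information",
    "accumulate_test_information",
    "posterior_information",
    "directional_sem",
    "information_peak_locus",
    "information_to_frame",
    "default_trait_prior",
    "P_CLAMP",
]

#: Probabilities are clamped to [P_CLAMP, 1 - P_CLAMP] inside information and
#: likelihood denominators so extreme z never produces 0/0.
P_CLAMP = 1e-10

_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


class PriorConfigError(ValueError):
    """The prior covariance is not symmetric positive-definite."""


@dataclass(frozen=True)
class PriorSpec:
    """Multivariate normal prior on the latent trait profile.

    ``cov`` is the trait covariance estimated during calibration; its inverse
    (computed once, via Cholesky) is the prior contribution to the posterior
    information matrix.
    """

    mean: np.ndarray
    cov: np.ndarray
    _chol: np.ndarray = field(init=False, repr=False, compare=False)
    _cov_inv: np.ndarray = field(init=False, repr=False, compare=False)

    def __init__(self, mean, cov):
        mean = np.asarray(mean, dtype=float).copy()
        cov = np.asarray(cov, dtype=float).copy()
        if mean.ndim != 1 or cov.shape != (mean.size, mean.size):
            raise PriorConfigError(f"incompatible shapes: mean {mean.shape}, cov {cov.shape}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise PriorConfigError("prior covariance must be symmetric")
        try:
            chol = linalg.cholesky(cov, lower=True)
        except linalg.LinAlgError:
            raise PriorConfigError("prior covariance must be positive-definite") from None
        cov_inv = linalg.cho_solve((chol, True), np.eye(mean.size))
        cov_inv = 0.5 * (cov_inv + cov_inv.T)
        for name, val in (("mean", mean), ("cov", cov), ("_chol", chol), ("_cov_inv", cov_inv)):
            val.setflags(write=False)
            object.__setattr__(self, name, val)

    @property
    def n_scales(self) -> int:
        return self.mean.size

    @property
    def cov_inv(self) -> np.ndarray:
        return self._cov_inv

    def logpdf(self, eta) -> float:
        eta = np.asarray(eta, dtype=float)
        dev = eta - self.mean
        w = linalg.solve_triangular(self._chol, dev, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(self._chol)))
        return float(-0.5 * (w @ w + logdet + self.n_scales * math.log(2 * math.pi)))

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((size, self.n_scales))
        return self.mean + z @ self._chol.T


#: Default HEXACO-style trait correlation matrix (unit variances, modest
#: correlations; the calibration covariances are not public).
DEFAULT_TRAIT_CORRELATIONS = np.array(
    [
        #  H     E     X     A     C     O
        [1.0, 0.1, 0.1, 0.3, 0.2, 0.1],  # H
        [0.1, 1.0, -0.2, 0.1, 0.1, 0.0],  # E
        [0.1, -0.2, 1.0, 0.2, 0.1, 0.2],  # X
        [0.3, 0.1, 0.2, 1.0, 0.1, 0.0],  # A
        [0.2, 0.1, 0.1, 0.1, 1.0, 0.1],  # C
        [0.1, 0.0, 0.2, 0.0, 0.1, 1.0],  # O
    ]
)


def default_trait_prior(n_scales: int = 6) -> PriorSpec:
    """Zero-mean MVN prior with the default trait correlation pattern."""
    if n_scales == 6:
        cov = DEFAULT_TRAIT_CORRELATIONS
    else:
        cov = np.eye(n_scales)
    return PriorSpec(np.zeros(n_scales), cov)


def _phi2(z: np.ndarray | float) -> np.ndarray | float:
    return np.exp(-z * z) * (_INV_SQRT_2PI**2)


def pair_information(block: PairBlock, eta, bank: ItemBank) -> np.ndarray:
    """Rank-<=1 Fisher information matrix of a pair at trait profile ``eta``."""
    i, k = _pair_indices(block, bank)
    eta = _as_eta(eta, bank.n_scales)
    psisum = bank.psi2[i] + bank.psi2[k]
    v = np.zeros(bank.n_scales)
    v[bank.scale_idx[i]] += bank.loading[i]
    v[bank.scale_idx[k]] -= bank.loading[k]
    z = (bank.mu[i] - bank.mu[k] + v @ eta) / math.sqrt(psisum)
    z = float(np.clip(z, -Z_CLAMP, Z_CLAMP))
    p = float(np.clip(ndtr(z), P_CLAMP, 1.0 - P_CLAMP))
    coef = _phi2(z) / (p * (1.0 - p) * psisum)
    return coef * np.outer(v, v)


def accumulate_test_information(blocks: Sequence[PairBlock], eta, bank: ItemBank) -> np.ndarray:
    """Sum of per-pair Fisher information matrices (all evaluated at ``eta``)."""
    info = np.zeros((bank.n_scales, bank.n_scales))
    for b in blocks:
        info += pair_information(b, eta, bank)
    return info


def posterior_information(test_info: np.ndarray, prior: PriorSpec) -> np.ndarray:
    """Bayesian posterior information: prior precision plus test information.

    Positive-definite even when ``test_info`` is singular (e.g. at the start
    of an adaptive session, before any pairs were administered).
    """
    test_info = np.asarray(test_info, dtype=float)
    if test_info.shape != (prior.n_scales, prior.n_scales):
        raise ValueError("test information has wrong shape for this prior")
    return prior.cov_inv + test_info


def directional_sem(post_info: np.ndarray) -> np.ndarray:
    """Directional SEM per trait: sqrt of the diagonal of the inverse information.

    The matrix inverse (not ``1/sqrt(I_ss)``) is used so that cross-trait
    correlations in the posterior are accounted for.
    """
    post_info = np.asarray(post_info, dtype=float)
    try:
        chol = linalg.cholesky(post_info, lower=True)
    except linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "posterior information is singular or not positive-definite; "
            "directional SEMs are undefined"
        ) from None
    inv = linalg.cho_solve((chol, True), np.eye(post_info.shape[0]))
    return np.sqrt(np.diag(inv))


def information_to_frame(matrix: np.ndarray, scales: Sequence[str]):
    """Label an S x S information matrix with scale names (rows and columns).

    The returned DataFrame writes directly to CSV via ``.to_csv(path)``.
    """
    import pandas as pd

    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(scales), len(scales)):
        raise ValueError("matrix shape does not match the number of scales")
    return pd.DataFrame(matrix, index=list(scales), columns=list(scales))


@dataclass(frozen=True)
class PeakLocus:
    """The hyperplane ``intercept + coefficients . eta = 0`` of maximal pair information.

    A pair is most informative where its choice probability is 1/2, i.e. where
    ``mu_i - mu_k + lambda_i eta_{s_i} - lambda_k eta_{s_k} = 0``.
    """

    intercept: float
    coefficients: np.ndarray

    def evaluate(self, eta) -> float:
        return float(self.intercept + np.asarray(eta, dtype=float) @ self.coefficients)


class UndefinedLocusError(ValueError):
    """Both items share the same loading vector; the pair carries no information."""


def information_peak_locus(block: PairBlock, bank: ItemBank) -> PeakLocus:
    """The eta-locus where the pair's information (its nonzero eigenvalue) peaks."""
    i, k = _pair_indices(block, bank)
    v = np.zeros(bank.n_scales)
    v[bank.scale_idx[i]] += bank.loading[i]
    v[bank.scale_idx[k]] -= bank.loading[k]
    if np.allclose(v, 0.0):
        raise UndefinedLocusError(
            f"pair ({block.first}, {block.second}) has identical loading vectors; "
            "its information is identically zero"
        )
    v.setflags(write=False)
    return PeakLocus(float(bank.mu[i] - bank.mu[k]), v)
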