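"""Dirichlet posterior over per-sample transcript proportions.

Counts for one sample are modelled as multinomial given the total; with a
symmetric Dirichlet prior of mass ``prior_mass`` per gene the posterior over
the proportion vector is Dirichlet(counts + prior_mass).  The default prior
mass of 0.5 is the Jeffreys/reference prior for the multinomial, which
maximises the information taken from the data while keeping every posterior
proportion strictly positive — a count of zero never forces an inferred
proportion of exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream

__all__ = ["DirichletParams", "PosteriorDraws", "posterior_alpha", "sample_posterior"]

DEFAULT_PRIOR_MASS = 0.5


@dataclass
class DirichletParams:
    """Concentration parameters of a Dirichlet posterior."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.ndim != 1 or self.alpha.size < 2:
            raise ValueError("alpha must be a vector of length >= 2")
        if np.any(self.alpha <= 0):
            raise ValueError("all concentration parameters must be positive")

    @property
    def alpha0(self) -> float:
        return float(self.alpha.sum())

    @property
    def mean(self) -> np.ndarray:
        """Posterior mean proportions alpha_i / alpha0."""
        return self.alpha / self.alpha0


@dataclass
class PosteriorDraws:
    """Monte-Carlo proportion draws for one sample.

    ``proportions`` has shape (n_mc, D); every row sums to one and every
    entry is strictly positive.
    """

    sample_id: str
    proportions: np.ndarray

    @property
    def n_mc(self) -> int:
        return self.proportions.shape[0]


def posterior_alpha(counts_for_sample: np.ndarray, prior_mass: float = DEFAULT_PRIOR_MASS) -> DirichletParams:
    """Posterior concentrations for one sample: counts + prior mass per gene."""
    if prior_mass <= 0:
        raise ValueError("prior_mass must be positive")
    c = np.asarray(counts_for_sample, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    return DirichletParams(c + prior_mass)


def _dirichlet_matrix(rng: np.random.Generator, alpha: np.ndarray, n_mc: int) -> np.ndarray:
    """n_mc Dirichlet(alpha) draws via normalised gammas, strictly positive.

    Gamma underflow to exact zero is possible (though astronomically rare for
    shape >= 0.5); affected entries are replaced by the smallest positive
    normal so proportions can never be exactly zero.
    """
    g = rng.standard_gamma(alpha, size=(n_mc, alpha.size))
    tiny = np.finfo(float).tiny
    np.maximum(g, tiny, out=g)
    g /= g.sum(axis=1, keepdims=True)
    np.maximum(g, tiny, out=g)
    return g


def sample_posterior(
    params: DirichletParams,
    n_mc: int,
    stream: np.random.Generator | None = None,
    *,
    seed: int | None = None,
    sample_id: str = "",
) -> PosteriorDraws:
    """Draw ``n_mc`` Monte-Carlo proportion vectors from the posterior.

    Either an explicit Generator or a (seed, sample_id) pair may be given;
    the latter derives a content-keyed substream so that results do not
    depend on the order samples are processed in.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if stream is None:
        if seed is None:
            raise ValueError("either stream or seed must be given")
        stream = substream(seed, "posterior", sample_id)
    p = _dirichlet_matrix(stream, params.alpha, int(n_mc))
    return PosteriorDraws(sample_id=sample_id, proportions=p)


def sample_posterior_sorted(
    counts_for_sample: np.ndarray,
    order: np.ndarray,
    n_mc: int,
    prior_mass: float,
    stream: np.random.Generator,
    return_sorted: bool = False,
) -> np.ndarray:
    """Dirichlet draws generated in a canonical gene order.

    ``order`` is the permutation that sorts gene identifiers.  Gammas are
    drawn in sorted order and mapped back, so permuting input rows permutes
    the output rows without changing any draw — the gene-permutation
    invariance of the pipeline rests on this.  With ``return_sorted`` the
    draws stay in sorted order (the pipeline works there and unsorts only
    its final outputs, keeping even the floating-point summation order
    permutation-independent).
    """
    alpha = posterior_alpha(counts_for_sample, prior_mass).alpha
    sorted_draws = _dirichlet_matrix(stream, alpha[order], int(n_mc))
    if return_sorted:
        return sorted_draws
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    return sorted_draws[:, inv]
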