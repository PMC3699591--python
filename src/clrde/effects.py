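"""Per-gene Monte-Carlo effect statistics and the full pipeline.

The method treats within-condition expression as a random variable rather
than a nuisance.  For each gene it builds four Monte-Carlo distributions
from the per-sample posterior log-ratio draws z:

* the within-condition mixture: at each MC index one replicate of the
  condition is chosen uniformly and its z value taken, pooling replicates
  as an equal-weight mixture;
* delta_A, the between-condition difference: one draw from each
  condition's mixture, subtracted (condition 1 minus condition 2);
* delta_W, the within-condition difference: in each condition two distinct
  replicates are drawn and subtracted; the absolute difference of greatest
  magnitude across the two conditions is kept, a conservative surrogate for
  the pooled within-condition spread;
* delta_R = delta_A / delta_W, the relative effect size, formed per MC
  index (the median of the ratio is not the ratio of the medians, so the
  pairing matters).

zeta is the symmetric quantile of zero of delta_A: with F the fraction of
realizations <= 0, zeta = min(F, 1 - F) in [0, 0.5].  Small zeta means the
between-condition difference distribution rarely crosses zero.  A gene is
called differential when |median delta_R| >= effect_cutoff and
zeta <= zeta_cutoff.  Medians (robust to the heavy tails of low-count
genes) are used for every reported summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .io import CountTable, DesignTwoGroup
from .logratio import clr_transform
from .posterior import sample_posterior_sorted

__all__ = [
    "PipelineConfig",
    "within_mixture",
    "between_difference",
    "within_difference",
    "effect_ratio",
    "zeta",
    "call_differential",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Tunable parameters of the pipeline.

    n_mc : Monte-Carlo realizations per sample (default 128).
    prior_mass : symmetric Dirichlet prior mass per gene (default 0.5,
        the Jeffreys prior).
    log_base : base of the reported log-ratios (default 2; one unit = one
        two-fold change).
    effect_cutoff : minimum |median effect size| to call a gene (1.5 is the
        minimum practical threshold; 2.0 is the conservative preset).
    zeta_cutoff : maximum symmetric quantile of zero (default 0.01).
    quantiles : extra quantiles reported alongside the medians.
    seed : master seed; every random stream derives from it.
    drop_all_zero : drop genes with zero counts in every sample instead of
        flagging them.
    """

    n_mc: int = 128
    prior_mass: float = 0.5
    log_base: float = 2.0
    effect_cutoff: float = 1.5
    zeta_cutoff: float = 0.01
    quantiles: tuple[float, ...] = (0.01, 0.99)
    seed: int = 0
    drop_all_zero: bool = False

    def __post_init__(self) -> None:
        if self.effect_cutoff <= 0 or self.zeta_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")


def _choose_replicates(z_reps: np.ndarray, stream: np.random.Generator) -> np.ndarray:
    """Uniform replicate choice per MC cell.  z_reps: (R, n_mc, ...)."""
    r = z_reps.shape[0]
    idx = stream.integers(0, r, size=z_reps.shape[1:])
    if r == 2:
        return np.where(idx == 0, z_reps[0], z_reps[1])
    return np.take_along_axis(z_reps, idx[None, ...], axis=0)[0]


def within_mixture(z_reps: list[np.ndarray] | np.ndarray, stream: np.random.Generator) -> np.ndarray:
    """Equal-weight mixture across a condition's replicates.

    ``z_reps`` holds one (n_mc, ...) draw array per replicate; at each MC
    cell one replicate is chosen uniformly at random.
    """
    z = np.asarray(z_reps, dtype=float)
    if z.ndim < 2 or z.shape[0] < 2:
        raise ValueError("at least two replicates with equal n_mc are required")
    return _choose_replicates(z, stream)


def between_difference(mix1: np.ndarray, mix2: np.ndarray) -> np.ndarray:
    """Per-realization between-condition difference, condition 1 minus 2."""
    mix1 = np.asarray(mix1)
    mix2 = np.asarray(mix2)
    if mix1.shape != mix2.shape:
        raise ValueError("mixture draws must have equal shape")
    return mix1 - mix2


def _pair_difference(z_reps: np.ndarray, stream: np.random.Generator) -> np.ndarray:
    """|z_a - z_b| for a uniformly chosen unordered pair of distinct replicates."""
    r = z_reps.shape[0]
    if r < 2:
        raise ValueError("a condition needs >= 2 replicates for the within-difference")
    if r == 2:
        # the single unordered pair; no stream consumption needed
        return np.abs(z_reps[0] - z_reps[1])
    pairs = [(i, j) for i in range(r) for j in range(i + 1, r)]
    k = stream.integers(0, len(pairs), size=z_reps.shape[1:])
    a = np.asarray([p[0] for p in pairs])[k]
    b = np.asarray([p[1] for p in pairs])[k]
    za = np.take_along_axis(z_reps, a[None, ...], axis=0)[0]
    zb = np.take_along_axis(z_reps, b[None, ...], axis=0)[0]
    return np.abs(za - zb)


def within_difference(
    z_reps_cond1: list[np.ndarray] | np.ndarray,
    z_reps_cond2: list[np.ndarray] | np.ndarray,
    stream1: np.random.Generator,
    stream2: np.random.Generator,
) -> np.ndarray:
    """Per-realization max-magnitude within-condition difference (delta_W)."""
    m1 = _pair_difference(np.asarray(z_reps_cond1, dtype=float), stream1)
    m2 = _pair_difference(np.asarray(z_reps_cond2, dtype=float), stream2)
    return np.maximum(m1, m2)


def effect_ratio(delta_a: np.ndarray, delta_w: np.ndarray) -> np.ndarray:
    """Relative effect size delta_A / delta_W, paired by MC index."""
    delta_a = np.asarray(delta_a, dtype=float)
    delta_w = np.asarray(delta_w, dtype=float)
    if delta_a.shape != delta_w.shape:
        raise ValueError("delta_A and delta_W must be paired realization-wise")
    with np.errstate(divide="ignore", invalid="ignore"):
        return delta_a / delta_w


def zeta(delta_a: np.ndarray, axis: int = 0) -> np.ndarray | float:
    """Symmetric quantile of zero of the delta_A distribution.

    zeta = min(F, 1 - F) with F the fraction of realizations <= 0; always
    in [0, 0.5].
    """
    delta_a = np.asarray(delta_a)
    if delta_a.size == 0:
        raise ValueError("empty draws")
    f = np.mean(delta_a <= 0, axis=axis)
    return np.minimum(f, 1.0 - f)


def call_differential(
    effect: np.ndarray | float,
    zeta_value: np.ndarray | float,
    effect_cutoff: float = 1.5,
    zeta_cutoff: float = 0.01,
) -> np.ndarray | bool:
    """Decision rule: |effect| >= effect_cutoff and zeta <= zeta_cutoff."""
    if effect_cutoff <= 0 or zeta_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    return (np.abs(effect) >= effect_cutoff) & (np.asarray(zeta_value) <= zeta_cutoff)


def _q(arr: np.ndarray, q: float) -> np.ndarray:
    return np.quantile(arr, q, axis=0, method="linear")


def run_pipeline(counts: CountTable, design: DesignTwoGroup, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Full analysis: posterior draws -> log-ratios -> effect statistics.

    Returns one row per gene with per-sample and per-condition median
    expression, the overall median expression A, the median between-
    condition difference M, median within-condition difference W, median
    effect size E, zeta, and the boolean call.  Deterministic given
    ``config.seed``; invariant to permutations of gene rows and sample
    columns, and exactly antisymmetric (M, E negated; A, W, zeta fixed)
    under swapping the two condition labels.
    """
    cfg = config or PipelineConfig()
    design.validate_against(counts)
    if cfg.drop_all_zero:
        counts = counts.drop_all_zero()
    all_zero = counts.all_zero_genes()

    gene_order = np.argsort(np.asarray(counts.gene_ids))
    inv_order = np.empty_like(gene_order)
    inv_order[gene_order] = np.arange(counts.n_genes)
    n_mc, d = cfg.n_mc, counts.n_genes

    def unsort(v: np.ndarray) -> np.ndarray:
        return v[..., inv_order]

    # everything below works in canonical sorted-gene order (draws, random
    # choices and even floating-point reductions are then independent of the
    # input row order); per-gene outputs are mapped back at the very end
    z_by_sample: dict[str, np.ndarray] = {}
    for s in counts.sample_ids:
        stream = substream(cfg.seed, "posterior", s)
        p = sample_posterior_sorted(
            counts.column(s), gene_order, n_mc, cfg.prior_mass, stream, return_sorted=True
        )
        z_by_sample[s] = clr_transform(p, base=cfg.log_base)

    c1, c2 = design.conditions
    groups = {c: design.samples_of(c) for c in (c1, c2)}

    def group_stream(tag: str, condition: str) -> np.random.Generator:
        # keyed by the member sample ids, not the label, so relabelling the
        # conditions reuses the identical draws
        return substream(cfg.seed, tag, *groups[condition])

    z_reps = {c: np.stack([z_by_sample[s] for s in groups[c]]) for c in (c1, c2)}
    mix = {c: within_mixture(z_reps[c], group_stream("mixture", c)) for c in (c1, c2)}

    delta_a = between_difference(mix[c1], mix[c2])
    delta_w = within_difference(
        z_reps[c1], z_reps[c2], group_stream("within", c1), group_stream("within", c2)
    )

    # float-collision guard: a zero denominator has probability zero for
    # genuine posterior draws; redraw those cells once, then flag whatever
    # remains (constant degenerate input) rather than dividing by zero
    degenerate = np.zeros(d, dtype=bool)
    zero_cells = delta_w == 0.0
    if zero_cells.any():
        redraw = within_difference(
            z_reps[c1], z_reps[c2],
            group_stream("within-redraw", c1), group_stream("within-redraw", c2),
        )
        delta_w = np.where(zero_cells, redraw, delta_w)
        still = delta_w == 0.0
        if still.any():
            degenerate = still.any(axis=0)
            delta_w = np.where(still, np.finfo(float).tiny, delta_w)

    delta_r = effect_ratio(delta_a, delta_w)
    zeta_vals = np.asarray(zeta(delta_a, axis=0), dtype=float)
    if degenerate.any():
        zeta_vals[degenerate] = 0.5

    m_med = np.median(delta_a, axis=0)
    w_med = np.median(delta_w, axis=0)
    e_med = np.median(delta_r, axis=0)
    if degenerate.any():
        e_med[degenerate] = 0.0
    a_med = np.median(np.concatenate([mix[c1], mix[c2]], axis=0), axis=0)

    called = call_differential(e_med, zeta_vals, cfg.effect_cutoff, cfg.zeta_cutoff)

    out: dict[str, np.ndarray | list] = {"gene_id": list(counts.gene_ids)}
    for s in counts.sample_ids:
        out[f"med.{s}"] = unsort(np.median(z_by_sample[s], axis=0))
    out[f"med.cond.{c1}"] = unsort(np.median(mix[c1], axis=0))
    out[f"med.cond.{c2}"] = unsort(np.median(mix[c2], axis=0))
    out["A"] = unsort(a_med)
    out["M"] = unsort(m_med)
    out["W"] = unsort(w_med)
    out["E"] = unsort(e_med)
    out["zeta"] = unsort(zeta_vals)
    for q in cfg.quantiles:
        out[f"M.q{q:g}"] = unsort(_q(delta_a, q))
        out[f"W.q{q:g}"] = unsort(_q(delta_w, q))
        out[f"E.q{q:g}"] = unsort(_q(delta_r, q))
    out["called"] = unsort(np.asarray(called, dtype=bool))
    out["all_zero"] = all_zero
    out["degenerate"] = unsort(degenerate)
    return pd.DataFrame(out)
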