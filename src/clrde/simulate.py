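"""Synthetic count generation and the spike-in true/false-positive harness.

The harness emulates a bacterial transcriptome experiment: a heavy-tailed
backbone of null genes stands in for a real single-organism library, 22
spike-in genes (two sets of 11, base counts 1..1024 in two-fold increments)
are appended with a known fold difference — one set boosted in each
condition — and technical replicates are produced by Dirichlet-multinomial
resampling, which models the sampling variance of repeated sequencing of
one library.  False positives can then only arise from outliers of the
Dirichlet sampling itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .effects import PipelineConfig, run_pipeline
from .io import CountTable, DesignTwoGroup
from .posterior import DEFAULT_PRIOR_MASS

__all__ = [
    "make_backbone",
    "spike_in",
    "technical_replicate",
    "run_harness",
    "SpikeInTruth",
    "HarnessReport",
]

BASE_COUNTS = tuple(2**k for k in range(11))  # 1, 2, 4, ..., 1024
DEFAULT_N_GENES = 5358
DEFAULT_DEPTH = 1_000_000
DEFAULT_FOLDS = (1.1, 1.5, 2.0, 5.0, 10.0)


def make_backbone(
    n_genes: int = DEFAULT_N_GENES,
    depth: int = DEFAULT_DEPTH,
    sigma: float = 2.0,
    zero_fraction: float = 0.01,
    stream: np.random.Generator | None = None,
    *,
    seed: int | None = None,
) -> np.ndarray:
    """Heavy-tailed null count vector for one library.

    Per-gene intensities are log-normal (log-sd ``sigma``), a small fraction
    of genes is forced silent (real bacterial libraries report ~1% of coding
    sequences with zero reads), and counts are a single multinomial draw of
    ``depth`` reads — so the vector sums exactly to the requested depth and
    doubling the depth doubles the totals without changing the composition.
    """
    if n_genes < 100:
        raise ValueError("n_genes must be >= 100")
    if depth < 10 * n_genes:
        raise ValueError("depth must be at least 10 reads per gene on average")
    if stream is None:
        stream = substream(0 if seed is None else seed, "backbone")
    w = stream.lognormal(mean=0.0, sigma=sigma, size=n_genes)
    n_zero = int(round(zero_fraction * n_genes))
    if n_zero:
        w[stream.choice(n_genes, size=n_zero, replace=False)] = 0.0
    return stream.multinomial(depth, w / w.sum()).astype(np.int64)


@dataclass
class SpikeInTruth:
    """A two-condition spike-in dataset with known differential genes."""

    counts: CountTable
    design: DesignTwoGroup
    truth: pd.DataFrame = field(repr=False)  # gene_id, is_spike, fold, base_count
    fold: float
    seed: int | None = None

    @property
    def spike_ids(self) -> list[str]:
        return self.truth.loc[self.truth["is_spike"], "gene_id"].tolist()

    @property
    def null_ids(self) -> list[str]:
        return self.truth.loc[~self.truth["is_spike"], "gene_id"].tolist()


def spike_in(
    backbone: np.ndarray,
    fold: float,
    base_counts: tuple[int, ...] = BASE_COUNTS,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Append two sets of spike genes and build the two condition vectors.

    Set 1 is multiplied by ``fold`` in condition 1, set 2 in condition 2, so
    the design is symmetric with 2 x len(base_counts) true positives.
    Fold-multiplied counts are rounded half-even; at fold 1.1 and base count
    1 the boosted count rounds back to 1, a designed hard case.

    Returns (cond1_vector, cond2_vector, truth_frame).
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    backbone = np.asarray(backbone, dtype=np.int64)
    base = np.asarray(base_counts, dtype=np.int64)
    boosted = np.round(base * float(fold)).astype(np.int64)  # banker's rounding
    cond1 = np.concatenate([backbone, boosted, base])
    cond2 = np.concatenate([backbone, base, boosted])
    n_bb = backbone.size
    gene_ids = (
        [f"g{i:05d}" for i in range(n_bb)]
        + [f"spike1_{b}" for b in base]
        + [f"spike2_{b}" for b in base]
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_spike": [False] * n_bb + [True] * (2 * base.size),
            "fold": [np.nan] * n_bb + [float(fold)] * (2 * base.size),
            "base_count": [np.nan] * n_bb + list(base) + list(base),
        }
    )
    return cond1, cond2, truth


def technical_replicate(
    counts: np.ndarray,
    depth: int | None = None,
    prior: float = DEFAULT_PRIOR_MASS,
    stream: np.random.Generator | None = None,
    *,
    seed: int | None = None,
) -> np.ndarray:
    """Simulated technical replicate of one library.

    A proportion vector is drawn from the Dirichlet posterior of the
    library, p ~ Dirichlet(counts + prior), and scaled to ``depth`` reads
    with largest-remainder rounding so the replicate sums exactly to depth.
    The replicate therefore carries exactly the variance the Dirichlet
    models — which is what repeated lanes of one library show empirically.
    (Adding a further multinomial resampling stage on top of the Dirichlet
    draw would double the technical variance relative to real replicate
    lanes.)  With ``depth`` unset the replicate is sequenced to the
    original total.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("empty count vector")
    if depth is None:
        depth = int(counts.sum())
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if stream is None:
        stream = substream(0 if seed is None else seed, "techrep")
    p = stream.dirichlet(counts + prior)
    scaled = p * depth
    base = np.floor(scaled).astype(np.int64)
    short = depth - int(base.sum())
    if short > 0:
        frac = scaled - base
        top = np.argsort(-frac, kind="stable")[:short]
        base[top] += 1
    return base


def simulate_dataset(
    fold: float,
    n_genes: int = DEFAULT_N_GENES,
    depth: int = DEFAULT_DEPTH,
    base_counts: tuple[int, ...] = BASE_COUNTS,
    prior: float = DEFAULT_PRIOR_MASS,
    seed: int = 0,
    sigma: float = 2.0,
    zero_fraction: float = 0.01,
) -> SpikeInTruth:
    """One complete spike-in dataset: 2 conditions x 2 technical replicates."""
    bb = make_backbone(n_genes, depth, sigma, zero_fraction, substream(seed, "backbone"))
    cond1, cond2, truth = spike_in(bb, fold, base_counts)
    cols, sample_ids, labels = [], [], []
    for ci, vec in ((1, cond1), (2, cond2)):
        for ri in (1, 2):
            sid = f"c{ci}r{ri}"
            cols.append(technical_replicate(vec, None, prior, substream(seed, "techrep", sid)))
            sample_ids.append(sid)
            labels.append(f"cond{ci}")
    table = CountTable(truth["gene_id"].tolist(), sample_ids, np.column_stack(cols))
    design = DesignTwoGroup(dict(zip(sample_ids, labels)))
    return SpikeInTruth(counts=table, design=design, truth=truth, fold=fold, seed=seed)


@dataclass
class HarnessReport:
    """Aggregate true/false-positive rates of the spike-in harness."""

    tpr: pd.DataFrame          # fold, base_count, tpr, n_trials
    fp: pd.DataFrame           # trial, fold, effect_cutoff, fp_calls, fp_rate, n_null
    n_trials: int
    seed: int

    @property
    def mean_fp_per_trial(self) -> pd.Series:
        """Mean false-positive calls per trial, indexed by effect cutoff."""
        return self.fp.groupby("effect_cutoff")["fp_calls"].mean()


def run_harness(
    trials: int = 100,
    folds: tuple[float, ...] = DEFAULT_FOLDS,
    effect_cutoffs: tuple[float, ...] = (1.5, 2.0),
    zeta_cutoff: float = 0.01,
    n_genes: int = DEFAULT_N_GENES,
    depth: int = DEFAULT_DEPTH,
    n_mc: int = 1000,
    prior: float = DEFAULT_PRIOR_MASS,
    seed: int = 0,
) -> HarnessReport:
    """Run ``trials`` spike-in simulations and score calls against truth.

    Each trial uses one fold value (cycling through ``folds``), a fresh
    backbone, and fresh technical replicates.  True-positive rates are
    aggregated per (fold, base count) at the first effect cutoff;
    false-positive counts are recorded per trial for every cutoff (the
    cutoffs are nested, so stricter ones can only remove calls).

    The harness default of 1000 Monte-Carlo realizations is higher than the
    pipeline default: a zeta cutoff of 0.01 needs finer resolution than the
    1/128 granularity of the quick default, otherwise borderline null genes
    slip under the cutoff through estimation noise alone.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    tp_rows, fp_rows = [], []
    for t in range(trials):
        fold = folds[t % len(folds)]
        trial_seed = (seed * 1_000_003 + t) % (2**31)
        ds = simulate_dataset(fold, n_genes, depth, prior=prior, seed=trial_seed)
        cfg = PipelineConfig(
            n_mc=n_mc, prior_mass=prior,
            effect_cutoff=min(effect_cutoffs), zeta_cutoff=zeta_cutoff,
            quantiles=(), seed=trial_seed,
        )
        res = run_pipeline(ds.counts, ds.design, cfg).set_index("gene_id")
        is_spike = ds.truth.set_index("gene_id")["is_spike"]
        for cutoff in effect_cutoffs:
            called = (res["E"].abs() >= cutoff) & (res["zeta"] <= zeta_cutoff)
            fp_calls = int((called & ~is_spike).sum())
            n_null = int((~is_spike).sum())
            fp_rows.append(
                {"trial": t, "fold": fold, "effect_cutoff": cutoff,
                 "fp_calls": fp_calls, "fp_rate": fp_calls / n_null, "n_null": n_null}
            )
        called_min = res["called"]
        spike_truth = ds.truth[ds.truth["is_spike"]]
        for _, row in spike_truth.iterrows():
            tp_rows.append(
                {"trial": t, "fold": fold, "base_count": int(row["base_count"]),
                 "detected": bool(called_min.loc[row["gene_id"]])}
            )
    tp = pd.DataFrame(tp_rows)
    tpr = (
        tp.groupby(["fold", "base_count"])["detected"]
        .agg(tpr="mean", n_trials="size")
        .reset_index()
    )
    return HarnessReport(tpr=tpr, fp=pd.DataFrame(fp_rows), n_trials=trials, seed=seed)
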