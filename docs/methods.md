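# Methods

## The model

A sequencing library reports, for each of D genes, a read count; the
per-sample total is an artefact of the machine run, not a biological
quantity. `clrde` therefore treats the count vector of one sample as a
multinomial draw from an underlying proportion vector q and infers q with a
full Bayesian posterior rather than a point estimate:

    q | counts ~ Dirichlet(counts + gamma),   gamma = 0.5 per gene

The symmetric prior mass gamma = 0.5 is the Jeffreys/reference prior for
the multinomial — the choice that maximises the information taken from the
data when all gene frequencies are of equal interest. Two consequences
matter downstream: no inferred proportion is ever exactly zero (a zero
count means "not observed", not "not present"), and the posterior marginal
for a gene is wide when its count is low and narrow when it is high, so a
count of 1/100 and a count of 100/10,000 carry very different precision at
the same fraction.

Each posterior draw is mapped to centred (sum-zero) log-ratios

    z_i = log2 q_i − (1/D) Σ_j log2 q_j ,

which are invariant to the library's total depth, sum to zero in every
draw, and read as fold-changes relative to the sample's geometric mean (one
unit = one two-fold change). The closed-form moments of z under the
Dirichlet are implemented for verification and diagnostics: with ψ and ψ′
the digamma and trigamma functions, E[ln q_i] = ψ(α_i) − ψ(α₀) and
Cov[ln q_i, ln q_j] = ψ′(α_i)δ_ij − ψ′(α₀); centring annihilates the
rank-one ψ′(α₀) term, leaving cov_z = H diag(ψ′(α)) H with
H = I − (1/D)J. Because ψ′(x) ≈ 1/x, the induced between-gene covariance
decays inversely with both total count and panel size, which is what makes
gene-wise analysis safe at transcriptome scale. These matrix forms were
verified against brute-force Monte-Carlo (1e5–1e6 draws) before anything
was built on them, and the test suite re-verifies them on every run.

## The decision statistics

Within-condition expression is treated as a random variable in its own
right, not a nuisance to be assumed small. For every gene, four Monte-Carlo
distributions are built from the per-sample z draws (n_mc realizations per
sample):

* **within-condition mixture** — at each MC index one replicate of the
  condition is selected uniformly and its z value taken; pooling
  realizations across replicates approximates the condition's expression
  distribution without assuming replicates share a mean;
* **Δ_A** (between) — one draw from each condition's mixture, subtracted
  (condition 1 − condition 2); its median is the reported fold change M;
* **Δ_W** (within) — in each condition two distinct replicates are drawn
  and subtracted; the absolute difference of greatest magnitude across the
  two conditions is kept. The max makes Δ_W a conservative surrogate for
  the pooled within-condition spread; its median is W;
* **Δ_R = Δ_A / Δ_W** — the relative effect size, formed per MC index and
  only then summarised (the median of a ratio is not the ratio of
  medians); its median is E.

ζ is the symmetric quantile of zero of Δ_A: with F the fraction of
realizations ≤ 0, ζ = min(F, 1−F) ∈ [0, 0.5]. A gene is called
differential when |E| ≥ effect_cutoff and ζ ≤ zeta_cutoff. All summaries
are medians (with optional extra quantiles) because low-count genes have
heavy-tailed, skewed posteriors.

## Parameters

| name | default | meaning |
|---|---|---|
| `n_mc` | 128 | MC realizations per sample. 128 is fine for exploration; summaries of ζ near a 0.01 cutoff need ≥1000 (granularity of ζ is 1/n_mc). The harness defaults to 1000 for exactly this reason. |
| `prior_mass` | 0.5 | Dirichlet prior mass per gene (Jeffreys). |
| `log_base` | 2 | reporting base; one unit of z = one two-fold change. |
| `effect_cutoff` | 1.5 | minimum practical \|E\|; 2.0 is the conservative preset (`--conservative`). |
| `zeta_cutoff` | 0.01 | ζ threshold; 0.01 and 0.001 behave very similarly, larger values admit genes with high within-condition variation. |
| `seed` | 0 | master seed; every stream derives from it. |

## Randomness and invariances

All randomness is derived from the master seed through content-keyed
substreams: per-sample streams are keyed by the sample identifier, group
streams by the sorted member sample identifiers, and all per-cell draws are
generated in canonical sorted-gene order (outputs are mapped back at the
end, so even floating-point reduction order is canonical). This buys three
exact guarantees, each asserted bitwise in the tests:

* permuting gene rows or sample columns does not change any reported value;
* re-running with the same seed is byte-identical;
* exchanging the two groups' condition assignment negates M and E
  realization-wise and leaves A, W and ζ untouched.

With two replicates per condition the within-difference pair is forced, so
no stream is consumed for it; with more replicates the mixture picks a
replicate uniformly per MC cell and Δ_W picks an unordered distinct pair
uniformly per MC cell, independently per statistic.

## Numerical choices

* Dirichlet draws via normalised gammas; entries are clamped to the
  smallest positive normal (gamma underflow at shape ≥ 0.5 has probability
  ~1e-150, but the strict-positivity invariant is enforced regardless).
* Quantiles use linear interpolation between order statistics everywhere.
* An exact-zero Δ_W realization (a float collision, probability zero for
  genuine draws) is redrawn once; if zeros persist the input is a constant
  degenerate gene: it is flagged, E set to 0, ζ to 0.5, and the zero
  denominators replaced by the smallest positive normal so W stays
  positive. This path is unreachable from real counts and exists for
  defined behaviour on degenerate synthetic input.
* Genes with zero counts in every sample are retained (the prior makes
  their posterior proper) and flagged `all_zero`; `--drop-zero-genes`
  removes them instead.

## The synthetic world

`make_backbone` emulates a single-organism bacterial RNA-seq library:
log-normal per-gene intensities (log-sd 2.0, giving a max/median ratio well
above 50 as real libraries show), ~1% of genes forced silent (real
bacterial datasets report ≈50–60 zero-read coding sequences out of ~5400),
and one multinomial draw at the requested depth (default 5358 genes at
1e6 reads; real libraries run 10–20× deeper, so this is a desk-scale
surrogate). The log-sd was fixed at 2.0 a priori as a typical transcriptome
dispersion; it is a shape knob, not a tuning target.

`spike_in` appends two sets of 11 genes with base counts 1..1024 in
two-fold increments; one set is multiplied by the trial's fold (1.1–10) in
each condition, symmetric in direction, rounding half-even — so fold 1.1 at
base 1 rounds back to 1 and is a designed undetectable case.

`technical_replicate` draws p ~ Dirichlet(counts + 0.5) and scales it to
depth with largest-remainder rounding. The replicate therefore carries
exactly the variance the Dirichlet posterior models, which is what repeated
sequencing lanes of one library show empirically; stacking a further
multinomial resampling on top of the Dirichlet draw would double the
technical variance relative to real replicate lanes and roughly tenfold the
null false-positive count of the harness.

What the generator does **not** emulate: biological replication
(no between-organism or between-culture dispersion; a negative-binomial
layer is deliberately out of scope), mixed-community structure
(organism-abundance confounding in meta-transcriptomes), and positional
effects (GC/length bias). A green harness therefore establishes calibration
against *technical* noise only: the false-positive bound says nothing about
biologically variable genes, and the true-positive curves assume the spike
fold is the only signal.

## Known limitations

* Exactly two conditions, each with ≥ 2 samples; no covariates, no paired
  designs.
* No p-values and no false-discovery machinery: the method deliberately
  avoids variance-sharing assumptions across genes, and ζ is a
  posterior-consistency measure, not a frequentist error rate.
* ζ has resolution 1/n_mc; calls at ζ cutoffs near that resolution are
  noisy (hence the harness default n_mc = 1000).
* The sampling-variance envelope assumes replicates differ only by
  sequencing noise; library-preparation effects will push genes outside it.
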