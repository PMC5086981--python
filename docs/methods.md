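# Methods

## Model and procedure

`pairdiff` identifies differentially expressed (DE) genes between two
phenotypes by reproducibility of *ranked absolute expression differences*
rather than by a per-gene test statistic.

**Averaged pairs.** Tissue samples are biological replicates with large
between-individual variation, so individual samples cannot act as replicate
experiments. Each dataset is therefore collapsed to one averaged
cancer-normal pair: per-gene arithmetic means of the linear-scale (non-log)
intensities over normal samples (`x̄_N`, `n1` samples) and cancer samples
(`x̄_C`, `n2` samples), with signed difference `D = x̄_C − x̄_N`. The sign of
`D` is the gene's deregulation direction. Averaging on the linear scale is
deliberate: averaging log values would rank genes by geometric-mean fold
behaviour and reintroduce the low-expression bias the method exists to avoid.
Genes with `D = 0` have no direction and are excluded from that pair's
ranking (logged).

**Block expansion.** Within each pair, genes are sorted by descending
`|D|`, ties broken lexicographically by gene id so runs are bit-for-bit
reproducible. For each unordered pair of ranked lists, depths grow from an
initial step (default 300) in equal increments (the final block may be
partial, ending at the shorter list's length). At depth `n`, the two top-`n`
lists share `k` genes of which `s` agree in sign; expansion continues while
the consistency score `s/k` is at or above the threshold (default 95%). An
empty overlap counts as failure (`p = 1`).

**Significance.** Chance direction agreement for one gene in two unrelated
lists is `p_e = 0.5`; the probability of at least `s` agreements among `k`
shared genes is the binomial upper tail `P(X ≥ s)`, evaluated through the
regularized incomplete beta function so that far-tail values (e.g. `1e-150`)
remain accurate. The reproducible depth `n*` of a comparison is the deepest
visited depth where the score passed the threshold **and** `p < alpha`
(default 0.01). The two conditions are checked separately: at the default
step of 300 a passing score implies a vanishing `p`, but on small problems a
fully consistent overlap of `k ≤ 6` genes is still compatible with chance
(`2^-6 > 0.01`), and the explicit check keeps such runs honest.

**Combination.** A comparison's DE genes are the direction-consistent
overlap at `n*`. With more than two pairs, each unordered pair of lists is
compared and the final set is the union (default) or intersection of the
per-comparison sets. Under union a gene can in principle receive conflicting
directions from disjoint comparisons; such genes are dropped and logged.
Union is the default because pooling more datasets should *extend* the
reproducible list, and the direction-conflict rule removes the only
ambiguity this can create.

**Optional refinement.** The block schedule stops at the first failing
depth. An optional refinement (`refine=True` / `--refine`) halves the step
after each failure and resumes from the last passing depth down to
single-gene resolution, locating the exact boundary at which consistency
drops below the threshold. It is off by default; the fixed-step schedule is
the documented procedure, and refinement is exposed for users who want the
boundary rather than the last full block.

**Single dataset.** One dataset is split evenly into `m` sub-datasets by
taking samples of each phenotype in input order and cutting them into `m`
consecutive groups whose sizes differ by at most one, smaller groups first
(25 → 12+13; 25 → 6+6+6+7). Input order stands in for acquisition order; no
randomized or stratified splitting is offered, so the split is deterministic
and reproducible from the file alone.

**Permutation null.** The control experiment permutes the sample-label
vector twice (values untouched, label counts preserved, gene–gene
correlation intact), builds the two averaged pairs, and scores the
consistency of their top-`n` lists; repeated (default 1000×) it yields the
null distribution of consistency scores. For any fixed data a balanced
random relabelling gives a sign-symmetric `D`, and the two permutations are
independent, so the distribution is centred on `p_e = 0.5` regardless of the
data's heteroskedasticity. The production path is vectorised (each pair is
one weighted column sum of the value matrix); a slower reference path
through the full pair-building pipeline exists and the two are cross-checked
statistically in the tests.

**Enrichment.** DE lists are tested against gene-set collections (GMT) with
the hypergeometric upper tail: universe `N` = measured genes of the analysed
dataset (not the union of the collection), `n` DE genes, set size `m`
counted after trimming each set to the universe, `k` the DE∩set overlap.
Raw p values are Benjamini–Hochberg adjusted and flagged at FDR 10% by
default. DE genes absent from the universe raise an error rather than being
dropped, since they indicate an upstream identifier mismatch.

## Scale bookkeeping and probe collapsing

The measurement scale (`log2` or `linear`) is an explicit dataset attribute
and every transform validates it — the most likely silent-corruption bug in
this pipeline is averaging log2 values as if they were intensities.
Probe-to-gene collapsing is defined on the log2 scale (arithmetic mean of a
gene's probes per sample); phenotype averaging is defined on the linear
scale; `to_linear`/`to_log2` refuse double transforms. Unmapped probes are
dropped and counted, never imputed. Duplicate feature rows in an
already-gene-level log2 matrix collapse by the same mean rule with a
warning; on the linear scale they are an error.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `step` | 300 | initial block size for list expansion (genes) |
| `threshold` | 0.95 | minimum consistency score to keep expanding |
| `alpha` | 0.01 | binomial significance level for reproducibility |
| `p_e` | 0.5 | chance probability of direction agreement |
| `combine` | union | per-comparison DE set combination rule |
| curve depths | 1000…5000 | top-`n` grid for consistency curves |
| null `n_top`, `reps` | 1000, 1000 | permutation-null experiment size |
| enrichment FDR | 0.10 | BH significance level |

There is no FDR control on the PD DE list itself: the threshold controls the
per-block false-consistency rate, but its relationship to the list-level FDR
is complex and is not estimated here.

## The synthetic-data generator

`simulate_datasets` emulates the regime the method is designed for, with
known ground truth:

* **Baselines**: per-gene linear intensities are log-normal, `log2 b ~
  Normal(8, 1.5)` — linear median 256, spanning more than three orders of
  magnitude across a 12,000-gene universe, comparable to RMA-summarised
  array intensities. The spread is chosen so that the extreme
  high-intensity tail stays thin enough for a planted high-expression
  signal to dominate between-individual sampling noise; with a much heavier
  tail (e.g. log2 sd 2), a few hundred ultra-bright null genes out-rank the
  weakest planted genes and block expansion stalls before covering the
  planted set — a real failure mode of the method on very heavy-tailed
  data, documented under limitations.
* **Noise**: multiplicative log-normal per individual with mean 1 and CV
  0.3 by default — the simplest model in which absolute variance grows with
  the mean, the behaviour that makes t-style statistics favour
  low-expression genes.
* **Planted signal**: 600 of 12,000 genes by default, signed multiplicative
  shifts with fold sizes log-uniform on [2, 4], applied to cancer samples.
  All planted genes are drawn from the top baseline-expression quartile by
  default (`frac_high_expression = 1.0`), since the generator's purpose is
  the high-expression DE regime; the fraction is configurable.
* **Sharing**: all datasets carry exactly the same planted effects; an
  optional per-dataset log-normal batch factor (`batch_sd`) stress-tests
  reproducibility.

What passing tests on this generator do **not** show: real microarray data
have probe-level artifacts, correlated genes, platform differences and DE
at all expression levels; recovery rates measured here quantify behaviour
under the planted high-expression regime only.

Default study conditions (3 datasets, 25+25 samples, 600 planted DE at
≥2-fold, CV 0.3, step 300 / threshold 0.95 / alpha 0.01) give mean recall
≈ 0.93 and precision ≈ 0.97 for the planted set; the exact figures are
recomputed by the test suite, never asserted as constants.

## Numerical choices

* Binomial and hypergeometric tails via `scipy.stats` survival functions
  (incomplete-beta evaluation), verified against exhaustive summation /
  enumeration oracles at small sizes to 1e-12 relative.
* BH adjustment via `statsmodels`, verified against hand step-up vectors.
  Note the BH map is not idempotent; only flag nesting across FDR levels is
  an invariant.
* Ranking ties break lexicographically by gene id; all stochastic
  operations take a single integer seed (`numpy.random.default_rng`).
* Degenerate cases: `k = 0` overlap is a failed block with `p = 1`;
  `s = 0` gives `p = 1`; a phenotype with zero samples, a non-numeric cell,
  a duplicate sample id, and a probe mapped to two genes are hard errors.

## Problem sizes used in the checks

The permutation-null experiment runs at full published scale (12,000 genes ×
120 samples × 1000 repetitions; seconds, thanks to the vectorised path).
Parameter recovery uses 20 seeds at the full default configuration and 200
seeds for the empty-null check at two datasets. Unit tests use scaled-down
configurations (1,500–4,000 genes) chosen so the planted block structure is
preserved; with only ~100 planted genes a 300-gene first block is
majority-noise and correctly reports nothing, so small-universe tests plant
≥300 genes or shrink the step.

## Known limitations

* No FDR estimate for the DE list (see above); the DE list's size is
  controlled indirectly by the threshold.
* Biased against low-expression DE genes by construction; it complements,
  not replaces, t/SAM-style analysis.
* Very heavy-tailed intensity distributions reduce recall: extreme-intensity
  null genes can crowd the top ranks and stop expansion early.
* The even split follows input order; confounding between acquisition order
  and biology transfers directly into the sub-datasets.
* Union combination can (rarely) assign conflicting directions; such genes
  are dropped rather than adjudicated.
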