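"""Synthetic multi-dataset expression data with known ground truth.

The generator emulates the data regime the reproducibility analysis is built
for: linear-scale intensities spanning several orders of magnitude (log-normal
baselines), multiplicative between-individual biological noise whose absolute
variance grows with the mean, a planted subset of DE genes with signed
multiplicative shifts concentrated among highly expressed genes, and several
independent datasets sharing the same planted signal.  Nothing probe-level or
array-physical is modelled.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import LINEAR, ExpressionDataset, write_matrix
from .enrichment import GeneSetCollection, write_gmt


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Attributes
    ----------
    n_genes, n_datasets : int
        Universe size and number of independent datasets sharing the signal.
    n_normal, n_cancer : int
        Samples per phenotype in every dataset.
    baseline_log2_median, baseline_log2_sd : float
        Per-gene baseline intensities are log-normal: log2 baseline ~
        Normal(median, sd).  The defaults (8, 1.5) give a linear median of
        256 and a span of more than three orders of magnitude across the
        gene universe, RMA-summary-like, while keeping the extreme
        high-intensity tail thin enough that the planted high-expression
        signal dominates the between-individual sampling noise -- the regime
        the reproducibility analysis is designed for.
    cv : float
        Biological coefficient of variation of the multiplicative
        per-individual noise (log-normal with mean 1).
    n_de : int
        Number of planted DE genes.
    min_fold, max_fold : float
        Planted effect sizes are log-uniform on [min_fold, max_fold] and
        applied multiplicatively to cancer samples (divided for
        down-regulated genes); sign is chosen uniformly.
    frac_high_expression : float
        Fraction of planted genes drawn from the top baseline-expression
        quartile (1.0 = fully concentrated among high expressors, the regime
        the method targets); the rest are drawn uniformly from the remainder.
    batch_sd : float
        Optional per-dataset, per-gene multiplicative batch factor
        (log-normal, sd on the natural-log scale); 0 disables it.
    seed : int
        Base seed for the whole scenario.
    """

    n_genes: int = 12000
    n_datasets: int = 3
    n_normal: int = 25
    n_cancer: int = 25
    baseline_log2_median: float = 8.0
    baseline_log2_sd: float = 1.5
    cv: float = 0.3
    n_de: int = 600
    min_fold: float = 2.0
    max_fold: float = 4.0
    frac_high_expression: float = 1.0
    batch_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("cannot plant more DE genes than genes")
        for name in ("n_genes", "n_datasets", "n_normal", "n_cancer"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if not (1.0 <= self.min_fold <= self.max_fold):
            raise ValueError("need 1 <= min_fold <= max_fold")
        if not (0.0 <= self.frac_high_expression <= 1.0):
            raise ValueError("frac_high_expression must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted DE genes (direction and fold) plus all baseline means."""

    table: pd.DataFrame  # index gene_id; columns direction, fold
    baseline: pd.Series  # linear-scale baseline mean per gene

    @property
    def de_genes(self) -> pd.Index:
        return self.table.index


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def simulate_datasets(
    config: SimulationConfig, seed=None
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate independent linear-scale datasets sharing one planted signal.

    Every value is ``baseline[gene] * effect * noise`` with the effect
    applied only to cancer samples of planted genes and noise drawn per
    individual.  ``seed`` overrides ``config.seed`` when given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gene_ids = pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="gene_id")
    baseline = 2.0 ** rng.normal(
        config.baseline_log2_median, config.baseline_log2_sd, config.n_genes
    )

    # plant the signal: a configurable share inside the top expression quartile
    order = np.argsort(-baseline, kind="stable")
    quartile = order[: max(config.n_genes // 4, 1)]
    n_high = min(round(config.frac_high_expression * config.n_de), len(quartile))
    chosen_high = rng.choice(quartile, size=n_high, replace=False)
    rest_pool = np.setdiff1d(np.arange(config.n_genes), chosen_high)
    chosen_rest = rng.choice(rest_pool, size=config.n_de - n_high, replace=False)
    planted = np.sort(np.concatenate([chosen_high, chosen_rest]))

    directions = rng.choice([-1, 1], size=config.n_de)
    folds = 2.0 ** rng.uniform(
        np.log2(config.min_fold), np.log2(config.max_fold), config.n_de
    )
    effect = np.ones(config.n_genes)
    effect[planted] = folds**directions

    n_per = config.n_normal + config.n_cancer
    labels = np.array(["N"] * config.n_normal + ["C"] * config.n_cancer)
    datasets = []
    for d in range(config.n_datasets):
        sample_ids = pd.Index(
            [f"d{d + 1}_{lab}{i + 1:02d}" for i, lab in enumerate(labels)],
            name="sample_id",
        )
        values = baseline[:, None] * _lognormal_noise(
            rng, config.cv, (config.n_genes, n_per)
        )
        values[:, labels == "C"] *= effect[:, None]
        if config.batch_sd > 0:
            values *= rng.lognormal(0.0, config.batch_sd, config.n_genes)[:, None]
        frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
        phen = pd.Series(labels, index=sample_ids)
        datasets.append(ExpressionDataset(frame, LINEAR, phen))

    truth = GroundTruth(
        pd.DataFrame(
            {"direction": directions, "fold": folds}, index=gene_ids[planted]
        ),
        pd.Series(baseline, index=gene_ids),
    )
    return datasets, truth


def write_truth(truth: GroundTruth, path) -> None:
    out = truth.table.copy()
    out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# hand-built worked example
#
# Twelve genes, two datasets of 2 normal + 2 cancer samples each.  Eight
# planted genes carry large differences (|D| = 1000 down to 300, alternating
# direction) that agree between the datasets; four noise genes have small
# differences whose signs flip between the datasets.  With step=2 the block
# expansion passes depths 2..8 (score 1) and fails at depth 10 (8/10 = 0.8),
# and depth 8 is the deepest with binomial p = 2**-8 < 0.01, so the algorithm
# reports exactly the eight planted genes.

_TOY_PLANTED_D = {  # gene -> signed D, identical in both datasets
    "T01": 1000.0, "T02": -900.0, "T03": 800.0, "T04": -700.0,
    "T05": 600.0, "T06": -500.0, "T07": 400.0, "T08": -300.0,
}
_TOY_NOISE_D = {  # gene -> signed D in dataset A; dataset B flips the sign
    "T09": 10.0, "T10": -8.0, "T11": 6.0, "T12": -4.0,
}


def toy_datasets() -> tuple[list[ExpressionDataset], pd.DataFrame]:
    """The 12-gene worked example with hand-checkable D values."""
    genes = list(_TOY_PLANTED_D) + list(_TOY_NOISE_D)
    datasets = []
    for flip in (1.0, -1.0):
        rows = []
        for g in genes:
            d = _TOY_PLANTED_D.get(g)
            if d is None:
                d = _TOY_NOISE_D[g] * flip
            base = 2000.0 if d < 0 else 200.0  # keep intensities positive
            # N samples straddle the mean; C samples are shifted by exactly D
            rows.append([base - 10.0, base + 10.0, base + d - 10.0, base + d + 10.0])
        label = "toyA" if flip > 0 else "toyB"
        sample_ids = pd.Index([f"{label}_N1", f"{label}_N2", f"{label}_C1", f"{label}_C2"])
        frame = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
        phen = pd.Series(["N", "N", "C", "C"], index=sample_ids)
        datasets.append(ExpressionDataset(frame, LINEAR, phen))
    truth = pd.DataFrame(
        {
            "direction": [int(np.sign(d)) for d in _TOY_PLANTED_D.values()],
            "D": list(_TOY_PLANTED_D.values()),
        },
        index=pd.Index(list(_TOY_PLANTED_D), name="gene_id"),
    )
    return datasets, truth


def _fixture_gmt(truth: GroundTruth, rng: np.random.Generator) -> GeneSetCollection:
    planted = list(truth.de_genes)
    background = [g for g in truth.baseline.index if g not in set(planted)]
    up = [g for g in planted if truth.table.at[g, "direction"] > 0]
    down = [g for g in planted if truth.table.at[g, "direction"] < 0]
    pick = lambda pool, n: sorted(rng.choice(pool, size=min(n, len(pool)), replace=False))
    return GeneSetCollection(
        {
            "planted_up": pick(up, 30),
            "planted_down": pick(down, 30),
            "planted_mixed": pick(planted, 40),
            "background_only": pick(background, 40),
            "half_and_half": pick(planted, 20) + pick(background, 20),
        }
    )


def make_fixture_suite(out_dir, seed: int = 2016) -> dict:
    """Write the standard small fixture set used by the test suite.

    Produces, under ``out_dir``:

    * ``planted_d{1..3}.tsv`` (+ phenotype files, + ``planted_truth.tsv``):
      a three-dataset planted-signal scenario (12,000 genes, 600 planted DE);
    * ``null.tsv`` (+ phenotype): one exchangeable 120-sample dataset with no
      phenotype signal, for the permutation-null experiment;
    * ``toy_{A,B}.tsv`` (+ phenotypes, + ``toy_truth.tsv``): the hand-built
      12-gene worked example;
    * ``toy_sets.gmt``: five gene sets over the planted-scenario universe.

    Returns a dict mapping fixture names to file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {}

    planted_cfg = SimulationConfig(seed=seed)
    datasets, truth = simulate_datasets(planted_cfg)
    for i, ds in enumerate(datasets, start=1):
        mat, phen = out / f"planted_d{i}.tsv", out / f"planted_d{i}.phenotype.tsv"
        write_matrix(ds, mat, phen)
        paths[f"planted_d{i}"] = mat
        paths[f"planted_d{i}_phenotype"] = phen
    write_truth(truth, out / "planted_truth.tsv")
    paths["planted_truth"] = out / "planted_truth.tsv"

    null_cfg = SimulationConfig(
        n_datasets=1, n_normal=60, n_cancer=60, n_de=0, seed=seed + 1
    )
    (null_ds,), _ = simulate_datasets(null_cfg)
    write_matrix(null_ds, out / "null.tsv", out / "null.phenotype.tsv")
    paths["null"] = out / "null.tsv"
    paths["null_phenotype"] = out / "null.phenotype.tsv"

    toys, toy_truth = toy_datasets()
    for ds, tag in zip(toys, ("A", "B")):
        mat, phen = out / f"toy_{tag}.tsv", out / f"toy_{tag}.phenotype.tsv"
        write_matrix(ds, mat, phen)
        paths[f"toy_{tag}"] = mat
        paths[f"toy_{tag}_phenotype"] = phen
    toy_truth.to_csv(out / "toy_truth.tsv", sep="\t")
    paths["toy_truth"] = out / "toy_truth.tsv"

    gmt = _fixture_gmt(truth, np.random.default_rng(seed + 2))
    write_gmt(gmt, out / "toy_sets.gmt")
    paths["gmt"] = out / "toy_sets.gmt"
    return paths
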