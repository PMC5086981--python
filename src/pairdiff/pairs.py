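"""Averaged cancer-normal pairs and even splitting of a dataset.

Tissue samples are biological replicates with large between-individual
variation, so a single cancer/normal sample pairing is not reproducible.
Instead each dataset (or sub-dataset) is reduced to one *averaged pair*: the
per-gene arithmetic means of the linear-scale (non-log) intensities over the
normal samples (x̄_N, over n1 samples) and over the cancer samples (x̄_C, over
n2 samples), plus their signed difference D = x̄_C − x̄_N.  D > 0 marks
up-regulation in cancer, D < 0 down-regulation.  Several such pairs, built
from independent datasets or from an even split of one dataset, act as
independent replicate experiments for the reproducibility analysis in
:mod:`pairdiff.core`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LINEAR, ExpressionDataset

NORMAL = "N"
CANCER = "C"


@dataclass
class AveragedPair:
    """Per-gene phenotype means and their signed difference for one dataset.

    ``d = mean_c - mean_n`` is recomputed on construction so the identity is
    exact by definition.
    """

    mean_n: pd.Series
    mean_c: pd.Series
    n1: int
    n2: int
    source_label: str = ""
    d: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("both phenotypes need at least one sample")
        if not self.mean_n.index.equals(self.mean_c.index):
            raise ValueError("mean_n and mean_c must share one gene index")
        if self.mean_n.index.has_duplicates:
            raise ValueError("duplicate gene ids in averaged pair")
        self.d = self.mean_c - self.mean_n

    @property
    def gene_ids(self) -> pd.Index:
        return self.mean_n.index

    @property
    def direction(self) -> pd.Series:
        """Sign of D per gene: +1 up-regulated in cancer, -1 down, 0 tied."""
        return pd.Series(np.sign(self.d.to_numpy()).astype(int), index=self.gene_ids)

    def restrict(self, gene_ids) -> "AveragedPair":
        idx = self.gene_ids.intersection(pd.Index(gene_ids))
        return AveragedPair(
            self.mean_n.loc[idx], self.mean_c.loc[idx], self.n1, self.n2, self.source_label
        )

    def __len__(self) -> int:
        return len(self.mean_n)


def build_pair(
    dataset: ExpressionDataset,
    normal_label: str = NORMAL,
    cancer_label: str = CANCER,
    source_label: str | None = None,
) -> AveragedPair:
    """Average a linear-scale dataset into one cancer-normal pair."""
    if dataset.scale != LINEAR:
        raise ValueError("averaged pairs are built from linear-scale intensities")
    mask_n = (dataset.phenotype == normal_label).to_numpy()
    mask_c = (dataset.phenotype == cancer_label).to_numpy()
    if mask_n.sum() == 0:
        raise ValueError(f"no samples labeled {normal_label!r}")
    if mask_c.sum() == 0:
        raise ValueError(f"no samples labeled {cancer_label!r}")
    mean_n = dataset.values.loc[:, mask_n].mean(axis=1)
    mean_c = dataset.values.loc[:, mask_c].mean(axis=1)
    return AveragedPair(
        mean_n,
        mean_c,
        int(mask_n.sum()),
        int(mask_c.sum()),
        source_label if source_label is not None else "pair",
    )


@dataclass
class SplitPlan:
    """Sample allocation for an even split into ``m`` consecutive sub-datasets."""

    m: int
    groups: dict  # label -> list of m lists of sample ids, in input order

    def sizes(self, label: str) -> list[int]:
        return [len(g) for g in self.groups[label]]


def plan_split(dataset: ExpressionDataset, m: int) -> SplitPlan:
    """Allocate samples to ``m`` consecutive groups per phenotype.

    Within each phenotype the samples are taken in input (column) order and
    cut into ``m`` consecutive blocks whose sizes differ by at most one,
    smaller blocks first: 25 samples -> (12, 13); 25 -> (6, 6, 6, 7).
    """
    if m < 2:
        raise ValueError("a split needs m >= 2")
    labels = dataset.phenotype
    groups: dict = {}
    for label in pd.unique(labels):
        ids = [s for s in dataset.sample_ids if labels[s] == label]
        if len(ids) < m:
            raise ValueError(
                f"phenotype {label!r} has {len(ids)} samples, fewer than m={m}"
            )
        q, r = divmod(len(ids), m)
        sizes = [q] * (m - r) + [q + 1] * r
        cuts = np.cumsum([0] + sizes)
        groups[label] = [ids[cuts[i]:cuts[i + 1]] for i in range(m)]
    return SplitPlan(m, groups)


def split_dataset(dataset: ExpressionDataset, m: int) -> list[ExpressionDataset]:
    """Evenly split one dataset into ``m`` sub-datasets (consecutive blocks)."""
    plan = plan_split(dataset, m)
    position = {s: i for i, s in enumerate(dataset.sample_ids)}
    out = []
    for i in range(m):
        chosen: list[str] = []
        for label in plan.groups:
            chosen.extend(plan.groups[label][i])
        chosen.sort(key=position.__getitem__)
        out.append(dataset.subset_samples(chosen))
    return out


def permute_labels(dataset: ExpressionDataset, seed=None) -> ExpressionDataset:
    """Randomly reassign phenotype labels, preserving the count of each label.

    The label vector is permuted across samples (values untouched), so the
    gene-gene correlation structure of the data is preserved.  ``seed`` may be
    an integer or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shuffled = rng.permutation(dataset.phenotype.to_numpy())
    return dataset.with_phenotype(pd.Series(shuffled, index=dataset.sample_ids))


def write_pair_file(pair: AveragedPair, path) -> None:
    """Write a pair as a 4-column tab file with provenance header comments."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# source={pair.source_label}\n")
        fh.write(f"# n1={pair.n1}\n# n2={pair.n2}\n")
        fh.write("gene_id\tmean_N\tmean_C\tD\n")
        for g in pair.gene_ids:
            fh.write(
                f"{g}\t{pair.mean_n[g]:.10g}\t{pair.mean_c[g]:.10g}\t{pair.d[g]:.10g}\n"
            )


def read_pair_file(path) -> AveragedPair:
    meta = {"source": "pair", "n1": 1, "n2": 1}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, value = line[1:].strip().partition("=")
        meta[key.strip()] = value.strip()
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", index_col=0)
    return AveragedPair(
        df["mean_N"], df["mean_C"], int(meta["n1"]), int(meta["n2"]), str(meta["source"])
    )
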