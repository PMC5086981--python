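"""Hypergeometric pathway enrichment with Benjamini-Hochberg FDR control.

For n DE genes drawn from a universe of N measured genes, the chance of
seeing at least k of them inside a gene set of m universe members is the
upper hypergeometric tail; p values over all sets are adjusted by the BH
step-up procedure and flagged at a stated FDR (10% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways read from a GMT file)."""

    sets: dict  # name -> frozenset of gene ids

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-delimited name, description, members."""
    sets: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = frozenset(g for g in fields[2:] if g)
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description] + sorted(members)) + "\n")


def hypergeometric_p(N: int, n: int, m: int, k: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(N population, m successes, n draws)."""
    for name, v in (("N", N), ("n", n), ("m", m), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if m > N or n > N:
        raise ValueError(f"set size m={m} and draw count n={n} cannot exceed N={N}")
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n={n}, m={m})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(de_genes, collection: GeneSetCollection, universe, fdr: float = 0.10) -> pd.DataFrame:
    """Test every gene set for over-representation of the DE genes.

    The universe is the measured genes of the analysed dataset; gene sets
    are trimmed to it before counting so the hypergeometric sampling frame
    is consistent.  DE genes outside the universe signal an upstream
    identifier mismatch and raise.  Returns one row per set: m, k, raw p,
    BH-adjusted p and a significance flag at the requested FDR.
    """
    universe = frozenset(universe)
    de = frozenset(de_genes)
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    if len(de) == 0:
        raise ValueError("empty DE gene list")
    stray = de - universe
    if stray:
        raise ValueError(
            f"{len(stray)} DE genes are not in the universe (id mismatch?): "
            f"{sorted(stray)[:5]}"
        )

    N, n = len(universe), len(de)
    rows = []
    for name, members in collection.sets.items():
        trimmed = members & universe
        m, k = len(trimmed), len(trimmed & de)
        rows.append((name, m, k, hypergeometric_p(N, n, m, k)))
    table = pd.DataFrame(rows, columns=["set", "m", "k", "p"]).set_index("set")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < fdr
    return table
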