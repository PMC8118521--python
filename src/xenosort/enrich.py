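"""Gene-set enrichment of cross-species DEG lists.

An open replacement for knowledge-base "core analysis": user-supplied GMT
gene sets are tested against a DEG list with a right-tailed Fisher exact
test (hypergeometric tail) on the 2x2 table

    a = |DEGs in set|,  K = |set in universe|,  n = |DEGs|,  N = |universe|

where the universe is the pool of orthologues actually tested (those
surviving the expressed-in-at-least-one-sample filter). P-values are
corrected with the Benjamini-Hochberg step-up procedure at FDR 0.05.

A simplified activation z-score summarizes direction agreement: for set
members carrying a direction annotation (+1 = expected up on the host/TME
side when the pathway is active) and a DEG-level fold change,

    z = sum_g d_g * sign(log2FC_g) / sqrt(m)

Positive z indicates activation on the host/TME side, negative on the graft
tumor side; with no annotated members the z-score is undetermined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

FDR_LEVEL = 0.05


@dataclass
class GeneSet:
    """A named gene set with optional per-member direction annotations."""

    name: str
    members: frozenset[str]
    directions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        extra = set(self.directions) - set(self.members)
        if extra:
            raise ValueError(f"direction annotations outside members: {sorted(extra)[:5]}")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse GMT (name, description, members...), with optional ``|+1``/``|-1``
    direction suffixes on member ids. Empty sets are dropped with a warning."""
    sets: list[GeneSet] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected name, description, members")
            name, _desc, *raw_members = fields
            members: set[str] = set()
            directions: dict[str, int] = {}
            for tok in raw_members:
                if not tok:
                    continue
                if "|" in tok:
                    gene, _, suffix = tok.partition("|")
                    try:
                        d = int(suffix)
                    except ValueError as exc:
                        raise ValueError(f"{path}:{lineno}: bad direction suffix {tok!r}") from exc
                    if d not in (1, -1):
                        raise ValueError(f"{path}:{lineno}: direction must be +1 or -1, got {d}")
                    directions[gene] = d
                else:
                    gene = tok
                members.add(gene)
            if not members:
                warnings.warn(f"{path}:{lineno}: empty gene set {name!r} dropped")
                continue
            sets.append(GeneSet(name, frozenset(members), directions))
    if not sets:
        warnings.warn(f"no gene sets parsed from {path}")
    return sets


def fisher_right_tail(a: int, K: int, n: int, N: int) -> float:
    """Right-tailed Fisher exact p = P(X >= a), X ~ Hypergeom(N, K, n)."""
    if not (0 <= a <= min(K, n)) or K > N or n > N or K < 0 or n < 0 or N < 0:
        raise ValueError(f"inconsistent 2x2 margins: a={a}, K={K}, n={n}, N={N}")
    if a == 0:
        return 1.0
    return float(hypergeom.sf(a - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1, input order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=FDR_LEVEL, method="fdr_bh")
    return q


def activation_zscore(
    gene_set: GeneSet, fold_changes: pd.DataFrame, deg_only: bool = True
) -> float | None:
    """Direction-agreement z over annotated set members; None if undetermined.

    ``fold_changes`` is a DEG table indexed by gene with ``log2fc`` and
    ``is_deg`` columns (host-side gene ids for orthologue pairs). With
    ``deg_only`` (default) only DEG-flagged members enter the score.
    """
    fc = fold_changes
    if deg_only and "is_deg" in fc.columns:
        fc = fc[fc["is_deg"]]
    terms = []
    for gene, d in gene_set.directions.items():
        if gene in fc.index:
            val = fc.at[gene, "log2fc"]
            if val != 0:
                terms.append(d * (1 if val > 0 else -1))
    if not terms:
        return None
    return float(sum(terms) / np.sqrt(len(terms)))


def enrich_sets(
    deg_genes: Iterable[str],
    universe: Iterable[str],
    sets: Sequence[GeneSet],
    fold_changes: pd.DataFrame | None = None,
    fdr: float = FDR_LEVEL,
) -> pd.DataFrame:
    """Fisher/BH enrichment of a DEG list against gene sets.

    One row per set with at least one member in the universe; columns
    ``name, a, K, n, N, ratio, p, q, z, significant`` with ``ratio = a/K``.
    Rows are sorted by p ascending, ties broken by name. BH correction runs
    across all tested sets (one family per DEG list).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    degs = set(deg_genes)
    stray = degs - universe
    if stray:
        raise ValueError(f"DEGs outside universe: {sorted(stray)[:5]}")

    N, n = len(universe), len(degs)
    rows = []
    for gs in sets:
        in_universe = gs.members & universe
        if not in_universe:
            continue
        K = len(in_universe)
        a = len(in_universe & degs)
        p = fisher_right_tail(a, K, n, N)
        z = activation_zscore(gs, fold_changes) if fold_changes is not None else None
        rows.append((gs.name, a, K, n, N, a / K, p, z))
    result = pd.DataFrame(
        rows, columns=["name", "a", "K", "n", "N", "ratio", "p", "z"]
    )
    if result.empty:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result[["name", "a", "K", "n", "N", "ratio", "p", "q", "z", "significant"]]
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["q"] <= fdr
    result = result.sort_values(["p", "name"], kind="mergesort").reset_index(drop=True)
    return result[["name", "a", "K", "n", "N", "ratio", "p", "q", "z", "significant"]]
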