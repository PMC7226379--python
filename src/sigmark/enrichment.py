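"""Gene-set Z-score enrichment and between-experiment comparison.

A set's activity in one perturbation is summarized by a Stouffer combined
Z: the per-gene standardized effects of its members, summed and divided by
the square root of the member count. Two experiments (e.g. a knockdown and
an over-expression of the same regulator) are then compared by the Pearson
correlation of their set-Z vectors, and by the hypergeometric overlap of
their top-N gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GeneSetCollection
from .differential import DifferentialTable

logger = logging.getLogger(__name__)

__all__ = [
    "SetZTable",
    "ZComparison",
    "set_z_scores",
    "compare_z_vectors",
    "top_n_overlap_test",
    "select_significant_sets",
]


@dataclass
class SetZTable:
    """Set-level Z-scores; ``table`` indexed by set_name with columns z_set, m."""

    table: pd.DataFrame
    min_size: int

    @property
    def set_names(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            self.table.to_csv(fh, sep="\t", index_label="set_name")


@dataclass
class ZComparison:
    set_names: list[str]
    z_a: np.ndarray
    z_b: np.ndarray
    r: float
    p: float

    @property
    def n(self) -> int:
        return len(self.set_names)


@dataclass
class OverlapResult:
    overlap: int
    n: int
    universe: int
    p: float
    genes: list[str]


def set_z_scores(
    diff: DifferentialTable,
    sets: GeneSetCollection,
    min_size: int = 5,
) -> SetZTable:
    """Stouffer combined Z per gene set.

    For each set S with m = |S ∩ universe| >= ``min_size``,
    z_set = sum(z_g for g in S ∩ universe) / sqrt(m). Positive z_set means
    the set's genes rise with treatment; negative means depletion. Sets
    below ``min_size`` are dropped with a logged count.
    """
    if len(diff) == 0:
        raise ValueError("empty differential table")
    z = diff.table["z"]
    names, zs, ms = [], [], []
    n_dropped = 0
    for s in sets:
        members = [g for g in s.members if g in z.index]
        m = len(members)
        if m < min_size:
            n_dropped += 1
            continue
        names.append(s.name)
        zs.append(float(z.loc[members].sum()) / np.sqrt(m))
        ms.append(m)
    if n_dropped:
        logger.warning("dropped %d sets below min_size=%d", n_dropped, min_size)
    if not names:
        raise ValueError("no usable sets: every set is below min_size or disjoint "
                         "from the gene universe")
    table = pd.DataFrame({"z_set": zs, "m": ms}, index=pd.Index(names, name="set_name"))
    return SetZTable(table, min_size=min_size)


def compare_z_vectors(a: SetZTable, b: SetZTable) -> ZComparison:
    """Pearson correlation of two experiments' set-Z vectors over common sets."""
    common = [n for n in a.set_names if n in set(b.set_names)]
    if len(common) < 3:
        raise ValueError(f"need >= 3 common sets, got {len(common)}")
    za = a.table.loc[common, "z_set"].to_numpy(dtype=float)
    zb = b.table.loc[common, "z_set"].to_numpy(dtype=float)
    if np.std(za) == 0 or np.std(zb) == 0:
        raise ValueError("zero variance in a set-Z vector")
    r, p = stats.pearsonr(za, zb)
    return ZComparison(set_names=common, z_a=za, z_b=zb, r=float(r), p=float(p))


def top_n_overlap_test(
    diff_a: DifferentialTable,
    diff_b: DifferentialTable,
    n: int,
    direction_a: str = "up",
    direction_b: str = "down",
) -> OverlapResult:
    """Reciprocal top-N overlap of two experiments' ranked gene lists.

    Over the common gene universe, take the ``n`` most increased ("up") or
    decreased ("down") genes by effect from each table, count the overlap k,
    and report the one-sided hypergeometric tail P(X >= k) with
    X ~ Hypergeom(N, n, n) — Fisher's exact test for the 2x2 overlap table.
    """
    for d in (direction_a, direction_b):
        if d not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {d!r}")
    common = diff_a.table.index.intersection(diff_b.table.index)
    N = len(common)
    if n > N:
        raise ValueError(f"n={n} exceeds common universe size {N}")
    if N < 2 * n:
        raise ValueError(f"common universe ({N}) must be >= 2n ({2 * n})")

    def top(diff: DifferentialTable, direction: str) -> set[str]:
        # ties broken deterministically by gene symbol (sort by symbol first,
        # then stable-sort by effect)
        eff = diff.table.loc[common, "effect"].sort_index()
        eff_sorted = eff.sort_values(ascending=(direction == "down"), kind="stable")
        return set(eff_sorted.index[:n])

    top_a = top(diff_a, direction_a)
    top_b = top(diff_b, direction_b)
    k = len(top_a & top_b)
    p = float(stats.hypergeom.sf(k - 1, N, n, n))
    return OverlapResult(overlap=k, n=n, universe=N, p=p, genes=sorted(top_a & top_b))


def select_significant_sets(
    zt: SetZTable, cutoff: float = 3.0
) -> tuple[list[str], list[str]]:
    """Set names beyond the Z cutoff.

    Returns ``(activated, depleted)``: names with z_set > cutoff and with
    z_set < -cutoff respectively, each sorted by |z_set| descending.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    z = zt.table["z_set"]
    activated = z[z > cutoff].abs().sort_values(ascending=False).index.tolist()
    depleted = z[z < -cutoff].abs().sort_values(ascending=False).index.tolist()
    return activated, depleted
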