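"""Per-gene statistics for a two-group perturbation experiment.

One perturbation (e.g. a knockdown vs. control, each in replicate arrays)
yields, per gene, the mean log2 difference (effect), the across-gene
standardized effect z, and a two-sided t-test p-value. The z column is the
quantity thresholded downstream ("|z| > 2" signature filters) and summed into
set-level enrichment Z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["DifferentialTable", "differential_table", "ddct_relative_expression"]


@dataclass
class DifferentialTable:
    """Per-gene effect / z / p for one perturbation.

    ``table`` is indexed by gene_id with columns ``effect`` (mean log2
    difference, treated minus control), ``z`` (effect standardized across
    genes: mean 0, sample SD 1) and ``p`` (two-sided t-test).
    """

    table: pd.DataFrame
    n_treated: int
    n_control: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            self.table.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, n_treated: int = 0, n_control: int = 0) -> "DifferentialTable":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(df, n_treated=n_treated, n_control=n_control)


def differential_table(
    expr: ExpressionMatrix,
    treated: Sequence[str],
    control: Sequence[str],
    *,
    test: str = "student",
    z_mode: str = "effect",
) -> DifferentialTable:
    """Per-gene differential statistics for treated vs. control samples.

    Parameters
    ----------
    expr
        Log2 expression matrix containing every listed sample.
    treated, control
        Disjoint sample-id groups, each with at least two replicates.
    test
        ``"student"`` (default; classic pooled-variance two-sample t) or
        ``"welch"`` (unequal variances, Welch-Satterthwaite df) — a
        sensitivity switch. At triplicate scale the Welch df estimate is
        biased low, making its p-values conservative, so the exact pooled
        test is the default.
    z_mode
        ``"effect"`` (default): z is the effect standardized across genes,
        so mean(z) = 0 and sample SD(z) = 1 exactly. ``"intensity"``: each
        sample column is z-scored across genes first and the effect is the
        mean difference of those standardized intensities (no second
        standardization); an alternative reading kept for sensitivity
        analysis.
    """
    treated = list(treated)
    control = list(control)
    if set(treated) & set(control):
        raise ValueError("treated and control groups overlap")
    for name, grp in (("treated", treated), ("control", control)):
        if len(grp) < 2:
            raise ValueError(f"{name} group needs >= 2 replicates, got {len(grp)}")
        missing = [s for s in grp if s not in expr.values.columns]
        if missing:
            raise ValueError(f"{name} samples not in matrix: {missing}")
    if z_mode not in ("effect", "intensity"):
        raise ValueError(f"unknown z_mode {z_mode!r}")
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")

    vals = expr.values
    if z_mode == "intensity":
        vals = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)

    a = vals[treated].to_numpy(dtype=float)
    b = vals[control].to_numpy(dtype=float)
    effect = a.mean(axis=1) - b.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=(test == "student"))
    p = np.asarray(res.pvalue, dtype=float)

    # both groups constant -> t undefined; degenerate limit
    degenerate = np.isnan(p)
    if degenerate.any():
        logger.warning(
            "%d genes with zero within-group variance in both groups; "
            "p set to degenerate limit", int(degenerate.sum()),
        )
        p = np.where(degenerate, np.where(np.isclose(effect, 0.0), 1.0, 0.0), p)

    if z_mode == "effect":
        sd = effect.std(ddof=1)
        if sd == 0:
            raise ValueError("all genes have identical effect; z undefined")
        z = (effect - effect.mean()) / sd
    else:
        z = effect

    df = pd.DataFrame({"effect": effect, "z": z, "p": p}, index=expr.values.index)
    df.index.name = "gene_id"
    return DifferentialTable(df, n_treated=len(treated), n_control=len(control))


def ddct_relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,calibrator - Ct_ref,calibrator), where the reference
    gene is a normalization control (e.g. cyclophilin A) and the calibrator
    is the untreated/control condition. Returns the fold change 2^-ddCt.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))
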