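"""Per-gene upregulation calling: treatment vs control t-tests on log2 ratios.

Each treated array carries log2(sample/reference) ratios against the common
reference; a gene's differential expression for a treatment is the mean of
its treated ratios minus the mean of its control ratios, tested with a
two-sample two-sided Student's t-test (equal-variance by default, Welch
optionally).  Significance cutoffs are applied to raw p-values — the
original analysis style used fixed cutoffs (strict 0.001, relaxed 0.01)
with no multiple-testing correction, and this module follows that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExprMatrix

logger = logging.getLogger(__name__)

DE_COLUMNS = ["condition", "mean_log2fc", "fold_change", "p_value",
              "n_treat", "n_ctrl"]


@dataclass(frozen=True)
class Cutoffs:
    """Significance and ranking parameters for upregulation calling."""

    strict_alpha: float = 0.001
    relaxed_alpha: float = 0.01
    top_k: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.strict_alpha < self.relaxed_alpha < 1:
            raise ValueError("need 0 < strict_alpha < relaxed_alpha < 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def test_gene(treat_values, ctrl_values, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test of one gene's log2 ratios.

    Returns ``(mean_log2fc, p_value)`` where mean_log2fc is
    mean(treat) - mean(ctrl).  NaNs are dropped; each group needs at least
    two remaining values.  When both groups are constant, p is 1 for equal
    means and ~0 otherwise.
    """
    treat = np.asarray(treat_values, float)
    ctrl = np.asarray(ctrl_values, float)
    treat = treat[np.isfinite(treat)]
    ctrl = ctrl[np.isfinite(ctrl)]
    if len(treat) < 2 or len(ctrl) < 2:
        raise ValueError("need at least 2 values per group")
    diff = float(treat.mean() - ctrl.mean())
    if treat.std(ddof=1) == 0.0 and ctrl.std(ddof=1) == 0.0:
        return diff, 1.0 if diff == 0.0 else np.nextafter(0, 1)
    res = stats.ttest_ind(treat, ctrl, equal_var=equal_var)
    return diff, float(res.pvalue)


def de_test(matrix: ExprMatrix, design: pd.DataFrame, condition: str,
            control: str = "control", equal_var: bool = True,
            one_sample: bool = False, min_per_group: int = 2) -> pd.DataFrame:
    """Differential-expression table for one treatment vs the controls.

    Vectorized over genes; genes with fewer than ``min_per_group``
    non-missing replicates in either group are dropped (and counted in the
    log).  ``one_sample=True`` instead tests the treated ratios against
    zero, for designs where each array is already control-normalized.

    Returns a DataFrame indexed by gene_id with columns
    condition, mean_log2fc, fold_change, p_value, n_treat, n_ctrl.
    """
    treat_ids = design.loc[design["condition"] == condition, "array_id"]
    ctrl_ids = design.loc[design["condition"] == control, "array_id"]
    if len(treat_ids) == 0:
        raise ValueError(f"no arrays for condition {condition!r}")
    treat = matrix.values[list(treat_ids)].to_numpy(float)
    n_treat = np.isfinite(treat).sum(axis=1)

    if one_sample:
        keep = n_treat >= min_per_group
        t_kept = treat[keep]
        res = stats.ttest_1samp(t_kept, 0.0, axis=1, nan_policy="omit")
        mean_fc = np.nanmean(t_kept, axis=1)
        pvals = np.asarray(res.pvalue, float)
        degenerate = ~np.isfinite(pvals)
        if degenerate.any():
            pvals[degenerate & (mean_fc == 0.0)] = 1.0
            pvals[degenerate & (mean_fc != 0.0)] = np.nextafter(0, 1)
        n_ctrl_kept = np.zeros(keep.sum(), dtype=int)
        n_treat_kept = n_treat[keep]
    else:
        if len(ctrl_ids) == 0:
            raise ValueError(f"no arrays for control condition {control!r}")
        ctrl = matrix.values[list(ctrl_ids)].to_numpy(float)
        n_ctrl = np.isfinite(ctrl).sum(axis=1)
        keep = (n_treat >= min_per_group) & (n_ctrl >= min_per_group)
        t_kept, c_kept = treat[keep], ctrl[keep]
        res = stats.ttest_ind(t_kept, c_kept, axis=1, equal_var=equal_var,
                              nan_policy="omit")
        mean_fc = np.nanmean(t_kept, axis=1) - np.nanmean(c_kept, axis=1)
        pvals = np.asarray(res.pvalue, float)
        # constant-in-both-groups genes: NaN p from a zero denominator
        degenerate = ~np.isfinite(pvals)
        if degenerate.any():
            pvals[degenerate & (mean_fc == 0.0)] = 1.0
            pvals[degenerate & (mean_fc != 0.0)] = np.nextafter(0, 1)
        n_ctrl_kept = n_ctrl[keep]
        n_treat_kept = n_treat[keep]

    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.info("%s: %d genes skipped (<%d replicates in a group)",
                    condition, n_skipped, min_per_group)
    return pd.DataFrame(
        {
            "condition": condition,
            "mean_log2fc": mean_fc,
            "fold_change": np.exp2(mean_fc),
            "p_value": pvals,
            "n_treat": n_treat_kept,
            "n_ctrl": n_ctrl_kept,
        },
        index=matrix.gene_ids[keep],
    )


def upregulated_set(results: pd.DataFrame, alpha: float) -> set[str]:
    """Genes significantly *up*: p strictly below alpha and positive shift."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    mask = (results["p_value"] < alpha) & (results["mean_log2fc"] > 0)
    return set(results.index[mask])


def rank_upregulated(results: pd.DataFrame) -> pd.DataFrame:
    """Upregulated-tested genes ranked by ascending p-value.

    Ties broken by descending fold change, then by gene id, so the top-k
    selection is fully deterministic.
    """
    up = results[results["mean_log2fc"] > 0].copy()
    up = up.reset_index(names="gene_id")
    up = up.sort_values(["p_value", "fold_change", "gene_id"],
                        ascending=[True, False, True], kind="mergesort")
    return up.set_index("gene_id")


def top_k_mean_fc(results: pd.DataFrame, k: int = 50) -> float:
    """Mean linear fold change of the k most significantly upregulated genes."""
    ranked = rank_upregulated(results)
    if len(ranked) < k:
        logger.warning("only %d upregulated-tested genes for top-%d mean",
                       len(ranked), k)
    top = ranked.head(k)
    return float(top["fold_change"].mean())


def write_de_table(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
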