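"""Synergy-ratio scoring of supra-additively upregulated genes.

For each gene the three linear fold changes over the unstimulated control
(ligand A alone, ligand B alone, and the combination) give the synergy
ratio

    ratio = FC_combo / (FC_A + FC_B)

A gene is *synergistically regulated* when the combination exceeds
1.5-fold the sum of the single-ligand inductions, i.e. ratio >= 1.5; the
boundary is inclusive.  Reported ratios are rounded half-up to one
decimal.

The module ships a 62-gene reference panel of published fold changes from
a TLR7 costimulation study of a human pDC line (columns: 9.2s RNA alone,
CL264 alone, their combination, and the reported synergy ratio), used to
validate the scoring arithmetic end to end.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_EVEN, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 1.5
DEFAULT_TOLERANCE = 0.1

#: Comparisons with the decimal threshold tolerate this much float error,
#: so fold changes read from decimal text (e.g. 4.2 / (1.1 + 1.7)) hit the
#: 1.5 boundary exactly as printed.
_EPS = 1e-9

_PANEL_RESOURCE = "costim_62gene_panel.tsv"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero, e.g. 1.95 -> 2.0.

    The value is first quantized to 9 decimal places (ties to even) so
    that binary float representations of decimal inputs — 4.2/2.8 is
    stored as 1.4999999999999996 — round like their exact decimal
    counterparts.
    """
    q = Decimal(x).quantize(Decimal("1e-9"), rounding=ROUND_HALF_EVEN)
    return float(q.quantize(Decimal(f"1e-{decimals}"), rounding=ROUND_HALF_UP))


def synergy_ratio(fc_a, fc_b, fc_combo):
    """Combination fold change over the sum of the single-ligand fold
    changes.  Scale-invariant; accepts scalars or aligned arrays."""
    fc_a = np.asarray(fc_a, float)
    fc_b = np.asarray(fc_b, float)
    fc_combo = np.asarray(fc_combo, float)
    if (fc_a <= 0).any() or (fc_b <= 0).any() or (fc_combo <= 0).any():
        raise ValueError("fold changes must be strictly positive")
    out = fc_combo / (fc_a + fc_b)
    return float(out) if out.ndim == 0 else out


def classify_synergy(records: pd.DataFrame,
                     threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Score and classify a table of per-gene fold-change triples.

    ``records`` needs columns fc_a, fc_b, fc_combo (linear fold changes
    over control).  Adds ``ratio`` (unrounded), ``ratio_rounded``
    (half-up, 1 decimal) and ``is_synergistic`` (ratio >= threshold,
    inclusive boundary).
    """
    out = records.copy()
    ratio = synergy_ratio(out["fc_a"], out["fc_b"], out["fc_combo"])
    out["ratio"] = ratio
    out["ratio_rounded"] = [round_half_up(r) for r in np.atleast_1d(ratio)]
    out["is_synergistic"] = out["ratio"] >= threshold - _EPS
    return out


def synergy_table(results_a: pd.DataFrame, results_b: pd.DataFrame,
                  results_combo: pd.DataFrame,
                  eligible: set[str] | None = None,
                  threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Build and classify fold-change triples from three DE tables.

    ``eligible`` restricts scoring to a gene set (conventionally the
    strict-cutoff combination-upregulated genes, from which published
    synergy lists are drawn); None scores every gene tested in all three
    conditions.
    """
    genes = results_a.index.intersection(results_b.index).intersection(
        results_combo.index)
    if eligible is not None:
        genes = genes.intersection(pd.Index(sorted(eligible)))
    records = pd.DataFrame(
        {
            "fc_a": results_a.loc[genes, "fold_change"],
            "fc_b": results_b.loc[genes, "fold_change"],
            "fc_combo": results_combo.loc[genes, "fold_change"],
        },
        index=genes,
    )
    return classify_synergy(records, threshold=threshold)


# ---------------------------------------------------------------------------
# published 62-gene reference panel


def load_reference_panel() -> pd.DataFrame:
    """The packaged 62-gene published fold-change panel.

    Indexed by gene symbol, with columns fc_a (9.2s RNA), fc_b (CL264),
    fc_combo (combination) and reported_ratio (the published rounded
    synergy ratio).
    """
    with resources.files("costim_synergy").joinpath(
            "data", _PANEL_RESOURCE).open() as fh:
        panel = pd.read_csv(fh, sep="\t")
    panel = panel.rename(columns={"fc_rna_92s": "fc_a", "fc_cl264": "fc_b"})
    return panel.set_index("gene_symbol")


def validate_against_table(records: pd.DataFrame, printed_ratios: pd.Series,
                           tolerance: float = DEFAULT_TOLERANCE) -> pd.DataFrame:
    """Compare recomputed rounded ratios with published ones, per gene.

    ``records`` must carry fc_a/fc_b/fc_combo indexed like
    ``printed_ratios``.  Returns a per-gene report with the recomputed
    rounded ratio, the printed ratio, their absolute difference and a
    pass flag (difference <= tolerance).  Raises if any printed gene is
    missing from the records.
    """
    missing = printed_ratios.index.difference(records.index)
    if len(missing):
        raise KeyError(f"records missing genes: {sorted(missing)}")
    scored = classify_synergy(records.loc[printed_ratios.index])
    diff = (scored["ratio_rounded"] - printed_ratios).abs()
    report = pd.DataFrame(
        {
            "recomputed_ratio": scored["ratio_rounded"],
            "printed_ratio": printed_ratios,
            "abs_diff": diff,
            "passed": diff <= tolerance + _EPS,
        },
        index=printed_ratios.index,
    )
    return report


def validate_reference_panel(tolerance: float = DEFAULT_TOLERANCE) -> pd.DataFrame:
    """Re-score the packaged panel from its fold-change columns and compare
    with the published ratios."""
    panel = load_reference_panel()
    return validate_against_table(panel[["fc_a", "fc_b", "fc_combo"]],
                                  panel["reported_ratio"], tolerance=tolerance)


def write_synergy_table(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
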