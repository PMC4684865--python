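"""Venn and relaxed-cutoff "recruitment" accounting of upregulated gene sets.

Counts how much of the costimulation-upregulated set is attributable to
the single ligands: genes already significant under a monostimulation at
the strict cutoff (the Venn overlap), plus genes unique to costimulation
that become significant under a monostimulation when the cutoff is relaxed
tenfold (the recruited genes).  Because significance sets are nested in
the cutoff, recruitment can never double-count a strict-cutoff gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import pandas as pd

from .diffexpr import upregulated_set, Cutoffs

logger = logging.getLogger(__name__)


@dataclass
class VennReport:
    """Set sizes of the strict-cutoff Venn plus recruitment accounting.

    ``frac_mono_in_combo_union`` and ``frac_mono_in_combo_sum`` are the
    two readings of "share of monostimulation genes also in the combo
    set": overlap over \\|A ∪ B\\| and over \\|A\\| + \\|B\\| (a gene upregulated
    by both ligands counts twice in the latter).  Both are reported since
    either denominator is defensible.
    """

    n_a: int
    n_b: int
    n_combo: int
    n_mono_union: int
    n_overlap: int
    n_unique_combo: int
    frac_mono_in_combo_union: float | None = None
    frac_mono_in_combo_sum: float | None = None
    n_recruited: int | None = None
    n_mono_attributable: int | None = None
    fraction_attributable: float | None = None

    def __post_init__(self) -> None:
        if self.n_overlap + self.n_unique_combo != self.n_combo:
            raise ValueError("overlap + unique-combo must equal combo size")
        if self.n_recruited is not None and self.n_recruited > self.n_unique_combo:
            raise ValueError("recruited genes cannot exceed unique-combo genes")

    def to_dict(self) -> dict:
        return asdict(self)


def venn(set_a: set, set_b: set, set_combo: set) -> VennReport:
    """Strict-cutoff Venn accounting of the three upregulated sets."""
    set_a, set_b, set_combo = set(set_a), set(set_b), set(set_combo)
    mono_union = set_a | set_b
    overlap = set_combo & mono_union
    unique_combo = set_combo - mono_union
    n_mono_sum = len(set_a) + len(set_b)
    return VennReport(
        n_a=len(set_a),
        n_b=len(set_b),
        n_combo=len(set_combo),
        n_mono_union=len(mono_union),
        n_overlap=len(overlap),
        n_unique_combo=len(unique_combo),
        frac_mono_in_combo_union=(
            len(mono_union & set_combo) / len(mono_union) if mono_union else None),
        frac_mono_in_combo_sum=(
            (len(set_a & set_combo) + len(set_b & set_combo)) / n_mono_sum
            if n_mono_sum else None),
    )


def recruit(unique_combo: set, results_a: pd.DataFrame, results_b: pd.DataFrame,
            relaxed_alpha: float = 0.01) -> set:
    """Genes unique to costimulation that a relaxed cutoff ascribes to a
    monostimulation (significantly up in A *or* B at ``relaxed_alpha``)."""
    relaxed = (upregulated_set(results_a, relaxed_alpha)
               | upregulated_set(results_b, relaxed_alpha))
    unique_combo = set(unique_combo)
    untested = unique_combo - set(results_a.index) - set(results_b.index)
    if untested:
        logger.warning("%d unique-combo genes missing from mono results; "
                       "counted as not recruited", len(untested))
    return unique_combo & relaxed


def attributable(n_overlap: int, n_recruited: int, n_combo: int) -> tuple[int, float]:
    """Total combo genes attributable to a single ligand and their fraction.

    Sum of the strict-cutoff overlap and the relaxed-cutoff recruits, as a
    count and as a fraction of the combo set size.
    """
    if n_combo <= 0:
        raise ValueError("n_combo must be positive")
    n_attr = n_overlap + n_recruited
    return n_attr, n_attr / n_combo


def percent(fraction: float) -> int:
    """Whole-percent rounding used in the textual summaries."""
    return int(round(100 * fraction))


def recruitment_report(results_a: pd.DataFrame, results_b: pd.DataFrame,
                       results_combo: pd.DataFrame,
                       cutoffs: Cutoffs = Cutoffs()) -> VennReport:
    """Full strict-Venn + recruitment report from three DE tables."""
    strict_a = upregulated_set(results_a, cutoffs.strict_alpha)
    strict_b = upregulated_set(results_b, cutoffs.strict_alpha)
    strict_combo = upregulated_set(results_combo, cutoffs.strict_alpha)
    report = venn(strict_a, strict_b, strict_combo)
    unique_combo = strict_combo - (strict_a | strict_b)
    recruited = recruit(unique_combo, results_a, results_b,
                        relaxed_alpha=cutoffs.relaxed_alpha)
    # nested cutoffs: a recruited gene can never already sit in a strict set
    assert not recruited & (strict_a | strict_b), "double-counted recruit"
    report.n_recruited = len(recruited)
    report.n_mono_attributable, report.fraction_attributable = attributable(
        report.n_overlap, report.n_recruited, report.n_combo
    ) if report.n_combo else (report.n_overlap + len(recruited), 0.0)
    return report


def membership_table(results_a: pd.DataFrame, results_b: pd.DataFrame,
                     results_combo: pd.DataFrame,
                     cutoffs: Cutoffs = Cutoffs()) -> pd.DataFrame:
    """Gene x {A_strict, B_strict, combo_strict, A_relaxed, B_relaxed}
    boolean membership table over all tested genes."""
    genes = sorted(set(results_a.index) | set(results_b.index)
                   | set(results_combo.index))
    cols = {
        "A_strict": upregulated_set(results_a, cutoffs.strict_alpha),
        "B_strict": upregulated_set(results_b, cutoffs.strict_alpha),
        "combo_strict": upregulated_set(results_combo, cutoffs.strict_alpha),
        "A_relaxed": upregulated_set(results_a, cutoffs.relaxed_alpha),
        "B_relaxed": upregulated_set(results_b, cutoffs.relaxed_alpha),
    }
    table = pd.DataFrame(
        {name: [g in s for g in genes] for name, s in cols.items()},
        index=pd.Index(genes, name="gene_id"),
    )
    return table
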