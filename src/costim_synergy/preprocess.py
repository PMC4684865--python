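"""Preprocessing of two-channel microarray spot tables.

Turns raw per-array spot intensity tables (reference channel = Cy3-labelled
common reference, sample channel = Cy5-labelled treated/control sample) into
a filtered, normalized matrix of log2(sample/reference) ratios.

The pipeline order is fixed and recorded in the matrix provenance:

    background correction -> flag / low-intensity filtering -> log2 ratios
    -> lowess intensity-dependent normalization -> presence filtering

Only the two filtering steps remove spots; normalization never adds or
removes genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

SPOT_COLUMNS = ["gene_id", "ch_reference", "ch_sample", "flag"]

#: Intensity below which a spot is considered "low" when BOTH channels are
#: under it; such spots are discarded during filtering.
DEFAULT_LOW_THRESHOLD = 100.0

#: Default lowess span (fraction of spots in each local regression window).
DEFAULT_SPAN = 0.3

#: Minimum number of spots required to fit the intensity-dependent trend.
DEFAULT_MIN_SPOTS = 50


@dataclass
class SpotTable:
    """Raw or partially processed spot intensities for one array.

    Parameters
    ----------
    array_id
        Identifier of the hybridization.
    data
        One row per spotted gene with columns ``gene_id`` (unique within the
        array), ``ch_reference`` and ``ch_sample`` (non-negative intensities)
        and ``flag`` (boolean; True marks a scanner/quality flag).
    """

    array_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"spot table missing columns: {missing}")
        if self.data["gene_id"].duplicated().any():
            raise ValueError(f"duplicate gene_id in array {self.array_id!r}")
        vals = self.data[["ch_reference", "ch_sample"]].to_numpy(float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("intensities must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.data)

    def replace(self, data: pd.DataFrame) -> "SpotTable":
        return SpotTable(self.array_id, data.reset_index(drop=True))


@dataclass
class ExprMatrix:
    """Genes x arrays matrix of normalized log2(sample/reference) ratios.

    ``values`` is indexed by gene id with one column per array; missing
    entries (filtered spots) are NaN.  ``provenance`` lists the processing
    steps applied, in order.
    """

    values: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def array_ids(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# file I/O


def read_spot_table(path: str | Path, array_id: str | None = None,
                    swap_channels: bool = False) -> SpotTable:
    """Read a tab-delimited spot table (gene_id, ch_reference, ch_sample, flag).

    ``swap_channels=True`` exchanges the reference and sample columns, for
    experiments where the dye assignment is reversed (sample on Cy3).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    df["flag"] = df["flag"].astype(bool)
    if swap_channels:
        df = df.rename(columns={"ch_reference": "ch_sample",
                                "ch_sample": "ch_reference"})
    return SpotTable(array_id or path.stem, df[SPOT_COLUMNS])


def write_spot_table(spots: SpotTable, path: str | Path) -> None:
    out = spots.data[SPOT_COLUMNS].copy()
    out["flag"] = out["flag"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the design table (array_id, condition, replicate)."""
    design = pd.read_csv(path, sep="\t", dtype={"array_id": str, "condition": str})
    for col in ("array_id", "condition", "replicate"):
        if col not in design.columns:
            raise ValueError(f"design table missing column {col!r}")
    return design


def write_expr_matrix(matrix: ExprMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id",
                         float_format="%.6g")


def read_expr_matrix(path: str | Path) -> ExprMatrix:
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExprMatrix(values, provenance=["loaded"])


# ---------------------------------------------------------------------------
# background correction


def estimate_background(spots: SpotTable, quantile: float = 0.05) -> tuple[float, float]:
    """Per-array global background estimate for each channel.

    Returns the median intensity of the lowest ``quantile`` fraction of
    spots, per channel — a robust stand-in when no per-spot background
    measurements accompany the scan.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    out = []
    for col in ("ch_reference", "ch_sample"):
        v = np.sort(spots.data[col].to_numpy(float))
        k = max(1, int(np.ceil(quantile * len(v))))
        out.append(float(np.median(v[:k])))
    return out[0], out[1]


def background_correct(spots: SpotTable,
                       bg_reference: float | None = None,
                       bg_sample: float | None = None,
                       floor: float = 1.0,
                       quantile: float = 0.05) -> SpotTable:
    """Subtract a per-channel background, flooring the result.

    When a background is not given it is estimated with
    :func:`estimate_background`.  The floor (default 1) keeps every
    intensity strictly positive so that downstream log ratios are defined.
    """
    if bg_reference is None or bg_sample is None:
        est_r, est_s = estimate_background(spots, quantile=quantile)
        bg_reference = est_r if bg_reference is None else bg_reference
        bg_sample = est_s if bg_sample is None else bg_sample
    if bg_reference < 0 or bg_sample < 0:
        raise ValueError("background estimates must be >= 0")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    data = spots.data.copy()
    data["ch_reference"] = np.maximum(data["ch_reference"] - bg_reference, floor)
    data["ch_sample"] = np.maximum(data["ch_sample"] - bg_sample, floor)
    return spots.replace(data)


# ---------------------------------------------------------------------------
# spot filtering


def filter_spots(spots: SpotTable,
                 low_threshold: float = DEFAULT_LOW_THRESHOLD) -> SpotTable:
    """Drop flagged spots and spots dim in both channels.

    A spot is removed when it carries a flag, or when *both* channels are
    below ``low_threshold``; a spot bright in either channel survives.
    """
    data = spots.data
    both_low = ((data["ch_reference"] < low_threshold)
                & (data["ch_sample"] < low_threshold))
    keep = ~data["flag"].astype(bool) & ~both_low
    return spots.replace(data.loc[keep])


# ---------------------------------------------------------------------------
# log ratios


def log_ratios(spots: SpotTable) -> pd.DataFrame:
    """Per-gene M (log2 ratio) and A (mean log2 intensity) for one array.

    M = log2(sample / reference), A = 0.5 * log2(sample * reference).
    Requires strictly positive channels (guaranteed after flooring).
    """
    data = spots.data
    r = data["ch_reference"].to_numpy(float)
    s = data["ch_sample"].to_numpy(float)
    if (r <= 0).any() or (s <= 0).any():
        raise ValueError("channels must be strictly positive for log ratios")
    return pd.DataFrame(
        {"M": np.log2(s / r), "A": 0.5 * np.log2(s * r)},
        index=pd.Index(data["gene_id"], name="gene_id"),
    )


# ---------------------------------------------------------------------------
# intensity-dependent (lowess) normalization


def normalize_array(ma: pd.DataFrame, span: float = DEFAULT_SPAN,
                    min_spots: int = DEFAULT_MIN_SPOTS) -> pd.Series:
    """Subtract a lowess fit of M on A from one array's log ratios.

    Removes the smooth intensity-dependent dye bias (Cy5 vs Cy3 labelling
    efficiency).  ``span`` is the lowess window as a fraction of spots.
    """
    if len(ma) < min_spots:
        raise ValueError(
            f"only {len(ma)} spots; need at least {min_spots} to fit the "
            "intensity-dependent trend")
    a = ma["A"].to_numpy(float)
    m = ma["M"].to_numpy(float)
    # delta collapses near-identical A values into one local fit; pure speed.
    delta = 0.005 * (a.max() - a.min())
    fitted = lowess(m, a, frac=span, it=3, delta=delta, return_sorted=False)
    return pd.Series(m - fitted, index=ma.index, name="M")


def normalize_intensity(per_array: dict[str, pd.DataFrame],
                        span: float = DEFAULT_SPAN,
                        min_spots: int = DEFAULT_MIN_SPOTS) -> ExprMatrix:
    """Normalize each array and assemble the genes x arrays ratio matrix."""
    cols = {aid: normalize_array(ma, span=span, min_spots=min_spots)
            for aid, ma in per_array.items()}
    values = pd.DataFrame(cols)
    values.index.name = "gene_id"
    return ExprMatrix(values, provenance=[f"lowess_normalize(span={span})"])


# ---------------------------------------------------------------------------
# presence filtering


def presence_filter(matrix: ExprMatrix, min_fraction: float = 0.5) -> ExprMatrix:
    """Keep genes measured on strictly more than ``min_fraction`` of arrays."""
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    n_arrays = matrix.values.shape[1]
    present = matrix.values.notna().sum(axis=1)
    keep = present > min_fraction * n_arrays
    return ExprMatrix(
        matrix.values.loc[keep],
        provenance=matrix.provenance + [f"presence_filter(>{min_fraction:g})"],
    )


# ---------------------------------------------------------------------------
# full pipeline


def preprocess_arrays(spot_tables: list[SpotTable],
                      background: str | tuple[float, float] | None = "auto",
                      floor: float = 1.0,
                      low_threshold: float = DEFAULT_LOW_THRESHOLD,
                      span: float = DEFAULT_SPAN,
                      min_fraction: float = 0.5,
                      min_spots: int = DEFAULT_MIN_SPOTS,
                      bg_quantile: float = 0.05) -> ExprMatrix:
    """Run the full preprocessing chain over a set of arrays.

    ``background`` is ``"auto"`` (per-array estimate), a fixed
    ``(bg_reference, bg_sample)`` pair applied to all arrays, or ``None``
    to skip background correction.
    """
    provenance: list[str] = []
    per_array: dict[str, pd.DataFrame] = {}
    for spots in spot_tables:
        if background == "auto":
            corrected = background_correct(spots, floor=floor, quantile=bg_quantile)
        elif background is None:
            corrected = spots
        else:
            bg_r, bg_s = background
            corrected = background_correct(spots, bg_r, bg_s, floor=floor)
        filtered = filter_spots(corrected, low_threshold=low_threshold)
        logger.debug("array %s: %d of %d spots retained after filtering",
                     spots.array_id, len(filtered), len(spots))
        per_array[spots.array_id] = log_ratios(filtered)
    if background is not None:
        provenance.append(f"background_correct({background!r}, floor={floor:g})")
    provenance.append(f"filter_spots(low<{low_threshold:g})")
    provenance.append("log2_ratio")
    matrix = normalize_intensity(per_array, span=span, min_spots=min_spots)
    matrix.provenance = provenance + matrix.provenance
    return presence_filter(matrix, min_fraction=min_fraction)
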