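"""Quantitative metabarcoding calibration via internal-standard DNA.

Each sequencing sample carries spiked standard DNAs of known copy number.
The reads-vs-copies relationship is fitted per sample as a through-origin
linear regression, reads = slope * copies, and the slope converts read
counts of every other taxon into estimated copies/µl.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import AbundanceTable

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "fit_all_curves",
    "reads_to_copies",
    "curves_report",
]


@dataclass
class StandardCurve:
    """Per-sample through-origin regression of standard reads on copies."""

    sample_id: str
    slope: float
    r_squared: float
    n_standards: int
    flagged: bool = False


def fit_standard_curve(
    standard_reads,
    standard_copies,
    sample_id: str = "",
) -> StandardCurve:
    """Fit reads = slope * copies with the intercept fixed at zero.

    slope = sum(reads * copies) / sum(copies^2); r^2 is the uncentered
    coefficient of determination of the through-origin fit.  Curves with
    all-zero reads (or nonpositive slope) are flagged and unusable.
    """
    reads = np.asarray(standard_reads, dtype=float)
    copies = np.asarray(standard_copies, dtype=float)
    if reads.shape != copies.shape:
        raise ValueError("standard reads and copies must have equal length")
    if reads.size < 2:
        raise ValueError("need >= 2 standards to fit a curve")
    if (copies <= 0).any():
        raise ValueError("standard copies must be strictly positive")
    if (reads == 0).all():
        return StandardCurve(sample_id, np.nan, np.nan, reads.size, True)
    slope = float((reads * copies).sum() / (copies**2).sum())
    resid = reads - slope * copies
    ss_tot = float((reads**2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else np.nan
    flagged = slope <= 0
    return StandardCurve(sample_id, slope, r2, reads.size, flagged)


def fit_all_curves(
    standard_read_table: pd.DataFrame,
    standard_copies,
) -> dict:
    """Fit one curve per sample column of a standards x samples table.

    ``standard_copies`` may be a mapping standard_id -> copies/µl or a
    vector aligned with the table's rows.
    """
    if isinstance(standard_copies, dict):
        copies = np.array(
            [standard_copies[s] for s in standard_read_table.index]
        )
    else:
        copies = np.asarray(standard_copies, dtype=float)
    return {
        sid: fit_standard_curve(
            standard_read_table[sid].values, copies, sample_id=sid
        )
        for sid in standard_read_table.columns
    }


def curves_report(curves: dict) -> pd.DataFrame:
    """Tabulate fitted curves (sample_id, slope, r2, n, flagged)."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "slope": c.slope,
                "r_squared": c.r_squared,
                "n_standards": c.n_standards,
                "flagged": c.flagged,
            }
            for c in curves.values()
        ]
    )


def reads_to_copies(
    read_table: pd.DataFrame,
    curves: dict,
    metadata: pd.DataFrame | None = None,
    aggregate_filters: str = "mean",
) -> pd.DataFrame | AbundanceTable:
    """Convert a taxa x samples read table to estimated copies/µl.

    copies = reads / slope per sample; samples with flagged curves yield
    missing values.  With a metadata table (sample_id, plot, date,
    filter_type) the per-sample estimates are assembled into an
    :class:`AbundanceTable`, combining filter types per (plot, date) by
    ``aggregate_filters`` ("mean" by default, since in the simulated
    design both filter types observe the same community; "sum" suits
    designs where filters capture disjoint taxa).  Without metadata the
    converted taxa x samples DataFrame is returned.
    """
    missing = [s for s in read_table.columns if s not in curves]
    if missing:
        raise ValueError(f"missing standard curves for samples: {missing}")
    out = pd.DataFrame(
        index=read_table.index, columns=read_table.columns, dtype=float
    )
    for sid in read_table.columns:
        c = curves[sid]
        if c.flagged or not np.isfinite(c.slope):
            out[sid] = np.nan
        else:
            out[sid] = read_table[sid].values / c.slope
    if metadata is None:
        return out

    meta = metadata.set_index("sample_id")
    plots = sorted(meta["plot"].unique())
    dates = pd.DatetimeIndex(sorted(meta["date"].unique()))
    values = np.full((len(read_table.index), len(dates), len(plots)), np.nan)
    for p, plot in enumerate(plots):
        for t, date in enumerate(dates):
            sids = meta.index[(meta["plot"] == plot) & (meta["date"] == date)]
            cols = out[sids].values
            if np.isnan(cols).all():
                continue
            if aggregate_filters == "sum":
                values[:, t, p] = np.nansum(cols, axis=1)
            else:
                values[:, t, p] = np.nanmean(cols, axis=1)
    return AbundanceTable(values, list(read_table.index), dates, plots)
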