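"""Time-series assembly and preparation.

Holds the central :class:`AbundanceTable` container (taxa x time x plot DNA
copy numbers), the taxon filter used to select series with enough temporal
information for state-space methods, z-score standardization, and the
EDM-independent community summaries (daily diversity, total DNA, per-taxon
coefficient of variation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "FilterCriteria",
    "filter_taxa",
    "standardize",
    "community_summaries",
]


@dataclass
class AbundanceTable:
    """Taxa x time x plot array of DNA copy numbers (copies/µl).

    Missing observations are NaN.  ``values[i, t, p]`` is the abundance of
    taxon ``taxon_ids[i]`` on day ``dates[t]`` in plot ``plot_ids[p]``.
    Dates must be consecutive days; abundances must be nonnegative where
    present.
    """

    values: np.ndarray
    taxon_ids: list = field(default_factory=list)
    dates: pd.DatetimeIndex | None = None
    plot_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:  # single plot convenience
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError("values must be a taxa x time x plot array")
        n_taxa, n_time, n_plots = self.values.shape
        if not self.taxon_ids:
            self.taxon_ids = [f"taxon_{i:04d}" for i in range(n_taxa)]
        if not self.plot_ids:
            self.plot_ids = [f"plot_{p + 1}" for p in range(n_plots)]
        if self.dates is None:
            self.dates = pd.date_range("2017-05-23", periods=n_time, freq="D")
        self.dates = pd.DatetimeIndex(self.dates)
        if len(self.taxon_ids) != n_taxa or len(self.plot_ids) != n_plots:
            raise ValueError("axis labels do not match values shape")
        if len(self.dates) != n_time:
            raise ValueError("dates do not match values shape")
        if n_time > 1:
            steps = np.diff(self.dates.values).astype("timedelta64[D]")
            if not (steps == np.timedelta64(1, "D")).all():
                raise ValueError("dates must be strictly increasing, daily")
        present = ~np.isnan(self.values)
        if (self.values[present] < 0).any():
            raise ValueError("abundances must be nonnegative where present")

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def n_plots(self) -> int:
        return self.values.shape[2]

    def series(self, taxon, plot) -> np.ndarray:
        """Return one taxon's time series in one plot (1-D array)."""
        i = self.taxon_ids.index(taxon) if not isinstance(taxon, int) else taxon
        p = self.plot_ids.index(plot) if not isinstance(plot, int) else plot
        return self.values[i, :, p]

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per (taxon, date, plot) with abundance."""
        idx = pd.MultiIndex.from_product(
            [self.taxon_ids, self.dates, self.plot_ids],
            names=["taxon", "date", "plot"],
        )
        return (
            pd.DataFrame({"abundance": self.values.ravel()}, index=idx)
            .reset_index()
        )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "AbundanceTable":
        wide = df.pivot_table(
            index="taxon", columns=["date", "plot"], values="abundance",
            dropna=False,
        )
        taxa = list(wide.index)
        dates = sorted(df["date"].unique())
        plots = sorted(df["plot"].unique())
        values = np.full((len(taxa), len(dates), len(plots)), np.nan)
        for ti, t in enumerate(dates):
            for pi, p in enumerate(plots):
                if (t, p) in wide.columns:
                    values[:, ti, pi] = wide[(t, p)].values
        return cls(values, taxa, pd.DatetimeIndex(dates), plots)

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AbundanceTable":
        df = pd.read_csv(path, parse_dates=["date"])
        return cls.from_long_frame(df)


@dataclass
class FilterCriteria:
    """Thresholds for keeping a taxon's series in the EDM analysis.

    A taxon passes in a plot when it is present (positive) in at least
    ``min_prevalence`` of the time points, its mean abundance over the
    series is at least ``min_mean_abundance`` copies/µl, and the series
    takes at least ``min_distinct_values`` distinct present values (a
    proxy for usable temporal information).
    """

    min_prevalence: float = 0.1
    min_mean_abundance: float = 1.0
    min_distinct_values: int = 10

    def __post_init__(self):
        if min(self.min_prevalence, self.min_mean_abundance,
               self.min_distinct_values) < 0:
            raise ValueError("filter thresholds must be nonnegative")


class EmptyFilterResult(ValueError):
    """Raised when no taxon survives filtering."""


def _criteria_per_plot(series: np.ndarray, criteria: FilterCriteria):
    present = ~np.isnan(series)
    n = present.sum()
    if n == 0:
        return False, False, False
    vals = series[present]
    prevalence = float((vals > 0).sum()) / n
    mean_abund = float(vals.mean())
    distinct = len(np.unique(vals))
    return (
        prevalence >= criteria.min_prevalence,
        mean_abund >= criteria.min_mean_abundance,
        distinct >= criteria.min_distinct_values,
    )


def filter_taxa(
    table: AbundanceTable,
    criteria: FilterCriteria | None = None,
    return_report: bool = False,
):
    """Keep taxa meeting all three criteria in at least one plot.

    Returns the filtered :class:`AbundanceTable`; with
    ``return_report=True`` also a per-taxon DataFrame of pass/fail
    reasons.  Raises :class:`EmptyFilterResult` when nothing survives.
    """
    criteria = criteria or FilterCriteria()
    keep = np.zeros(table.n_taxa, dtype=bool)
    rows = []
    for i, taxon in enumerate(table.taxon_ids):
        best = (False, False, False)
        for p in range(table.n_plots):
            flags = _criteria_per_plot(table.values[i, :, p], criteria)
            if all(flags):
                best = flags
                break
            if sum(flags) > sum(best):
                best = flags
        keep[i] = all(best)
        rows.append(
            {
                "taxon": taxon,
                "pass_prevalence": best[0],
                "pass_mean_abundance": best[1],
                "pass_distinct_values": best[2],
                "kept": keep[i],
            }
        )
    if not keep.any():
        raise EmptyFilterResult("no taxon passed the filter criteria")
    out = AbundanceTable(
        table.values[keep],
        [t for t, k in zip(table.taxon_ids, keep) if k],
        table.dates,
        list(table.plot_ids),
    )
    if return_report:
        return out, pd.DataFrame(rows)
    return out


def standardize(series: np.ndarray) -> np.ndarray:
    """Z-score a series to zero mean, unit variance (population sd).

    Missing values (NaN) are ignored in the moments and stay missing.
    Raises ``ValueError`` for a constant (zero-variance) series.
    """
    x = np.asarray(series, dtype=float)
    present = ~np.isnan(x)
    if len(np.unique(x[present])) < 2:
        raise ValueError("zero variance: series has < 2 distinct values")
    mu = x[present].mean()
    sd = x[present].std()  # population (n) denominator
    out = np.full_like(x, np.nan)
    out[present] = (x[present] - mu) / sd
    return out


def community_summaries(
    table: AbundanceTable,
    min_prevalence: float = 0.1,
    exclude_zeros_in_cv: bool = True,
):
    """Per-plot, per-day diversity and total DNA; per-taxon CV.

    Returns ``(daily, cv)`` DataFrames.  ``daily`` has one row per
    (plot, date) with ``S`` (count of taxa with positive abundance that
    day) and ``total_dna`` (summed copies/µl).  ``cv`` has one row per
    (taxon, plot) with the coefficient of variation sd/mean (population
    sd) over the taxon's present — and by default positive — time points;
    the community mean CV averages taxa present in at least
    ``min_prevalence`` of days.
    """
    daily_rows = []
    cv_rows = []
    for p, plot in enumerate(table.plot_ids):
        vals = table.values[:, :, p]
        present = ~np.isnan(vals)
        positive = present & (vals > 0)
        s_t = positive.sum(axis=0)
        total = np.where(present, vals, 0.0).sum(axis=0)
        for t, date in enumerate(table.dates):
            daily_rows.append(
                {"plot": plot, "date": date, "S": int(s_t[t]),
                 "total_dna": float(total[t])}
            )
        for i, taxon in enumerate(table.taxon_ids):
            sel = positive[i] if exclude_zeros_in_cv else present[i]
            x = vals[i][sel]
            prevalence = positive[i].sum() / max(present[i].sum(), 1)
            if x.size == 0 or x.mean() == 0:
                cv = np.nan
            else:
                cv = float(x.std() / x.mean())
            cv_rows.append(
                {"taxon": taxon, "plot": plot, "cv": cv,
                 "prevalence": float(prevalence),
                 "in_community_mean": prevalence >= min_prevalence}
            )
    return pd.DataFrame(daily_rows), pd.DataFrame(cv_rows)
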