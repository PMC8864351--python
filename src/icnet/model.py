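"""Model/Results interface to the full network-reconstruction pipeline.

:class:`InteractionNetworkModel` bundles the analysis chain — taxon
filtering, standardization, all-pairs convergent cross-mapping, the
multivariate regularized S-map, and the per-day network properties — in
the fit/results style of statistical modelling packages:

    model = InteractionNetworkModel(table, temperature=temp)
    res = model.fit(seed=1)
    print(res.summary())
    res.snapshots          # per-(plot, day) S, N_link, IC, IS_link, C, stability
    res.tensor             # time-varying interaction strengths IS_{i->j}(t)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edm import EmbeddingSpec
from .network import (
    HypothesisParams,
    detect_links,
    driver_analysis,
    estimate_converged_is,
    links_frame,
    shuffle_control,
    smax_predict,
    snapshots_frame,
)
from .prep import AbundanceTable, FilterCriteria, community_summaries, filter_taxa
from .smap import SmapConfig, build_interaction_tensor

__all__ = ["InteractionNetworkModel", "InteractionNetworkResults"]


class InteractionNetworkModel:
    """Time-varying interaction network model for a community time series.

    Parameters
    ----------
    table
        Taxa x time x plot abundance table (estimated DNA copies/µl).
    temperature
        Daily air-temperature series aligned with the table's dates; used
        as the exogenous covariate of every S-map (together with a linear
        time trend) so the estimated coefficients are net interactions.
    filter_criteria
        Optional taxon filter applied before the analysis; None keeps
        every taxon.
    embedding, smap_config
        EDM and S-map hyperparameters.
    alpha, n_surrogates, E
        CCM screen settings (E=None selects the embedding dimension per
        effect series by simplex projection).
    """

    def __init__(
        self,
        table: AbundanceTable,
        temperature=None,
        filter_criteria: FilterCriteria | None = None,
        embedding: EmbeddingSpec | None = None,
        smap_config: SmapConfig | None = None,
        alpha: float = 0.05,
        n_surrogates: int = 100,
        E: int | None = None,
        ccm_kwargs: dict | None = None,
    ):
        self.table = table
        self.temperature = (
            None if temperature is None else np.asarray(temperature, float)
        )
        self.filter_criteria = filter_criteria
        self.embedding = embedding or EmbeddingSpec()
        self.smap_config = smap_config or SmapConfig()
        self.alpha = alpha
        self.n_surrogates = n_surrogates
        self.E = E
        self.ccm_kwargs = ccm_kwargs or {}

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, temperature=None, **kwargs
    ) -> "InteractionNetworkModel":
        """Build from a long table with taxon/date/plot/abundance columns."""
        return cls(AbundanceTable.from_long_frame(df), temperature, **kwargs)

    def fit(self, seed: int = 0) -> "InteractionNetworkResults":
        """Run the full pipeline and return the results object."""
        table = self.table
        filter_report = None
        if self.filter_criteria is not None:
            table, filter_report = filter_taxa(
                table, self.filter_criteria, return_report=True
            )
        links = set()
        results = []
        for p, plot in enumerate(table.plot_ids):
            pl, pr = detect_links(
                table,
                plot=p,
                spec=self.embedding,
                seed=seed + 104729 * p,
                alpha=self.alpha,
                n_surrogates=self.n_surrogates,
                E=self.E,
                **self.ccm_kwargs,
            )
            links |= pl
            results.extend(pr)
        tensor = build_interaction_tensor(
            links, table, temperature=self.temperature, config=self.smap_config
        )
        snapshots = snapshots_frame(tensor, table)
        daily, cv = community_summaries(table)
        return InteractionNetworkResults(
            model=self,
            table=table,
            links=links,
            ccm_results=results,
            tensor=tensor,
            snapshots=snapshots,
            daily_summaries=daily,
            taxon_cv=cv,
            filter_report=filter_report,
            seed=seed,
        )


@dataclass
class InteractionNetworkResults:
    """Fitted time-varying interaction network and its derived properties."""

    model: InteractionNetworkModel
    table: AbundanceTable
    links: set
    ccm_results: list
    tensor: object
    snapshots: pd.DataFrame
    daily_summaries: pd.DataFrame
    taxon_cv: pd.DataFrame
    filter_report: pd.DataFrame | None = None
    seed: int = 0
    hypothesis: HypothesisParams = field(default_factory=HypothesisParams)

    @property
    def links_table(self) -> pd.DataFrame:
        return links_frame(self.ccm_results)

    def converged_is(self, s_quantile: float = 0.75) -> float:
        """Converged mean interaction strength of this system (mean
        IS_link over the high-diversity snapshots)."""
        return estimate_converged_is(self.snapshots, s_quantile)

    def predict_smax(self, ic=None, c=None, is_converged=None) -> float:
        """Maximum-diversity prediction S_max = IC/(2*IS_conv*C), using
        snapshot means unless overridden."""
        df = self.snapshots[self.snapshots["N_link"] > 0]
        ic = float(df["IC"].mean()) if ic is None else ic
        c = float(df["C"].mean()) if c is None else c
        params = (
            HypothesisParams(is_converged)
            if is_converged is not None
            else self.hypothesis
        )
        return smax_predict(ic, c, params)

    def shuffle_control(self, n_shuffles: int = 5, seed: int | None = None,
                        **kwargs) -> dict:
        """Rerun the causal screen on time-shuffled series (negative
        control: only false positives should remain)."""
        return shuffle_control(
            self.table,
            n_shuffles=n_shuffles,
            seed=self.seed if seed is None else seed,
            alpha=self.model.alpha,
            n_surrogates=self.model.n_surrogates,
            E=self.model.E,
            **kwargs,
        )

    def driver_analysis(self, seed: int | None = None, **kwargs):
        """Causal influence of temperature and total DNA on IC, C and S."""
        if self.model.temperature is None:
            raise ValueError("model has no temperature series")
        total = {
            plot: grp.sort_values("date")["total_dna"].values
            for plot, grp in self.daily_summaries.groupby("plot")
        }
        return driver_analysis(
            self.snapshots,
            self.model.temperature,
            total_dna=total or None,
            seed=self.seed if seed is None else seed,
            **kwargs,
        )

    def summary(self) -> str:
        """Plain-text overview in the style of statistical model results."""
        df = self.snapshots
        with_links = df[df["N_link"] > 0]
        lines = [
            "Interaction network reconstruction",
            "=" * 50,
            f"Taxa analysed:          {self.table.n_taxa}",
            f"Plots x days:           {self.table.n_plots} x {self.table.n_time}",
            f"Directed pairs tested:  {len(self.ccm_results)}",
            f"Significant links:      {len(self.links)}"
            f" (alpha = {self.model.alpha})",
            f"Snapshots (plot x day): {len(df)}",
        ]
        if len(with_links):
            ident = with_links["IC"] / (
                2 * with_links["IS_link"] * with_links["C"]
            )
            lines += [
                f"Mean S:                 {df['S'].mean():.2f}",
                f"Mean IC:                {with_links['IC'].mean():.4f}",
                f"Mean IS_link:           {with_links['IS_link'].mean():.4f}",
                f"Mean connectance C:     {with_links['C'].mean():.4f}",
                f"Mean stability |λ_max|: {df['stability'].mean():.4f}"
                f" (unstable days: {int(df['unstable'].sum())}/{len(df)})",
                f"Identity S=IC/(2·IS·C): max rel err "
                f"{float(((ident - with_links['S']).abs() / with_links['S']).max()):.2e}",
            ]
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Write snapshots, links, tensor and a reproducibility manifest."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.snapshots.to_csv(d / "snapshots.csv", index=False)
        self.links_table.to_csv(d / "links.csv", index=False)
        self.tensor.save(d / "tensor.csv", d / "tensor_models.json")
        self.tensor.static_edge_list().to_csv(d / "edges.csv", index=False)
        self.daily_summaries.to_csv(d / "daily_summaries.csv", index=False)
        self.taxon_cv.to_csv(d / "taxon_cv.csv", index=False)
        manifest = {
            "seed": self.seed,
            "alpha": self.model.alpha,
            "n_surrogates": self.model.n_surrogates,
            "E": self.model.E,
            "embedding": vars(self.model.embedding),
            "smap": {
                "theta": self.model.smap_config.theta,
                "ridge_lambda": self.model.smap_config.ridge_lambda,
                "include_temperature_trend":
                    self.model.smap_config.include_temperature_trend,
            },
        }
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    def plot_network(self, plot=0, ax=None, min_strength: float = 0.0):
        """Static (time-averaged) network drawing via networkx."""
        import matplotlib.pyplot as plt
        import networkx as nx

        plot_id = (
            self.table.plot_ids[plot]
            if isinstance(plot, (int, np.integer))
            else plot
        )
        edges = self.tensor.static_edge_list()
        edges = edges[(edges["plot"] == plot_id)
                      & (edges["abs_IS"] > min_strength)]
        G = nx.DiGraph()
        G.add_nodes_from(self.table.taxon_ids)
        for _, row in edges.iterrows():
            G.add_edge(row["cause"], row["effect"], weight=row["abs_IS"])
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        pos = nx.circular_layout(G)
        weights = [5 * G[u][v]["weight"] for u, v in G.edges]
        nx.draw_networkx(
            G, pos, ax=ax, node_size=300, font_size=6, width=weights,
            arrows=True,
        )
        ax.set_title(f"Time-averaged interaction network ({plot_id})")
        ax.axis("off")
        return ax

    def plot_properties(self, axes=None):
        """Network properties against diversity (scatter panels)."""
        import matplotlib.pyplot as plt

        df = self.snapshots[self.snapshots["N_link"] > 0]
        if axes is None:
            _, axes = plt.subplots(1, 4, figsize=(16, 3.5))
        for ax, col, label in zip(
            axes,
            ["IS_link", "IC", "C", "stability"],
            ["mean IS per link", "interaction capacity",
             "connectance", "dynamic stability"],
        ):
            ax.scatter(df["S"], df[col], s=8, alpha=0.6)
            ax.set_xlabel("diversity S")
            ax.set_ylabel(label)
        return axes
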