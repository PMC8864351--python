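"""Network properties and the interaction-capacity computations.

From the time-varying interaction tensor this module derives, per plot and
day: species diversity S, link count N_link, mean realized interaction
capacity IC = 2 * sum_{i != j} |IS_{i->j}| / S, mean interaction strength
per link IS_link, connectance C = N_link / S^2, and dynamic stability (the
modulus of the dominant eigenvalue of the day's interaction matrix; > 1
means small perturbations amplify in discrete time).  These satisfy the
identity S = IC / (2 * IS_link * C) whenever N_link > 0, which links
diversity to interaction capacity and connectance; with a converged mean
interaction strength the identity becomes a prediction of the maximum
community diversity S_max = IC / (2 * is_converged * C).

Also here: the shuffle-surrogate control (rerunning the causal screen on
independently time-permuted series should leave only false positives) and
the driver analysis quantifying how temperature and total DNA causally
influence IC, C and S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edm import EmbeddingSpec, ccm
from .prep import AbundanceTable, standardize
from .smap import SmapConfig, build_interaction_tensor, fit_multivariate_smap

__all__ = [
    "NetworkSnapshot",
    "HypothesisParams",
    "snapshot",
    "snapshots_frame",
    "dynamic_stability",
    "smax_predict",
    "estimate_converged_is",
    "detect_links",
    "shuffle_control",
    "driver_analysis",
]


@dataclass
class NetworkSnapshot:
    """Per-(plot, date) properties of the interaction network."""

    plot_id: str
    date: object
    S: int
    N_link: int
    IC: float
    IS_link: float
    C: float
    stability: float
    unstable: bool
    no_links: bool = False


@dataclass
class HypothesisParams:
    """System constants of the diversity prediction.

    ``is_converged`` is the converged mean interaction strength per link
    the system approaches at high diversity (a system-specific constant;
    re-estimate it for each analysed system via
    :func:`estimate_converged_is`).
    """

    is_converged: float = 0.03

    def __post_init__(self):
        if self.is_converged <= 0:
            raise ValueError("is_converged must be > 0")


def dynamic_stability(interaction_matrix, subset=None) -> float:
    """Modulus of the dominant eigenvalue of an interaction matrix.

    ``subset`` optionally restricts rows/columns to a taxon index set.
    Values above 1 mean perturbations amplify step to step (discrete-time
    instability).
    """
    M = np.asarray(interaction_matrix, dtype=float)
    if subset is not None:
        idx = np.asarray(list(subset))
        M = M[np.ix_(idx, idx)]
    if M.size == 0:
        raise ValueError("empty interaction matrix")
    if not np.isfinite(M).all():
        raise ValueError("interaction matrix has non-finite entries")
    return float(np.max(np.abs(np.linalg.eigvals(M))))


def snapshot(
    tensor,
    table: AbundanceTable,
    plot,
    t,
    include_self_in_stability: bool = True,
    presence: str = "positive",
) -> NetworkSnapshot:
    """Network properties for one plot and day.

    S counts taxa present (positive abundance) that day; links are
    off-diagonal fitted entries with |IS| > 0 among present taxa.  The
    stability matrix keeps the diagonal self-regulation terms (they are
    part of the community Jacobian); unfitted entries count as 0.
    """
    p = (
        table.plot_ids.index(plot)
        if not isinstance(plot, (int, np.integer))
        else plot
    )
    plot_id = table.plot_ids[p]
    if not isinstance(t, (int, np.integer)):
        t = list(table.dates).index(pd.Timestamp(t))
    date = table.dates[t]
    abund = table.values[:, t, p]
    if presence == "positive":
        present = np.where(~np.isnan(abund) & (abund > 0))[0]
    else:
        present = np.arange(table.n_taxa)
    S = present.size
    if S == 0:
        raise ValueError(f"empty community at {plot_id} {date}")

    M = tensor.matrix_at(p, t)[np.ix_(present, present)]
    off = ~np.eye(S, dtype=bool)
    fitted = np.isfinite(M)
    link_mask = off & fitted & (np.abs(np.nan_to_num(M)) > 0)
    N_link = int(link_mask.sum())
    total_abs = float(np.abs(M[link_mask]).sum()) if N_link else 0.0
    if N_link:
        IC = 2.0 * total_abs / S
        IS_link = total_abs / N_link
        C = N_link / S**2
        no_links = False
    else:
        IC, IS_link, C = 0.0, 0.0, 0.0
        no_links = True
    Mstab = np.nan_to_num(M, nan=0.0)
    if not include_self_in_stability:
        np.fill_diagonal(Mstab, 0.0)
    stability = (
        float(np.max(np.abs(np.linalg.eigvals(Mstab)))) if S else np.nan
    )
    return NetworkSnapshot(
        plot_id=plot_id,
        date=date,
        S=S,
        N_link=N_link,
        IC=IC,
        IS_link=IS_link,
        C=C,
        stability=stability,
        unstable=bool(stability > 1),
        no_links=no_links,
    )


def snapshots_frame(tensor, table: AbundanceTable) -> pd.DataFrame:
    """Snapshot every (plot, day) with at least one fitted model."""
    rows = []
    for p, plot in enumerate(table.plot_ids):
        for t in range(table.n_time):
            if not tensor.valid[p, t].any():
                continue
            try:
                s = snapshot(tensor, table, p, t)
            except ValueError:
                continue
            rows.append(vars(s))
    return pd.DataFrame(rows)


def smax_predict(ic: float, c: float, params: HypothesisParams | None = None):
    """Predicted maximum community diversity S_max = IC/(2*IS_conv*C)."""
    params = params or HypothesisParams()
    if c <= 0:
        raise ValueError("connectance must be > 0 to predict S_max")
    if ic < 0:
        raise ValueError("interaction capacity must be >= 0")
    return ic / (2.0 * params.is_converged * c)


def estimate_converged_is(
    snapshots: pd.DataFrame, s_quantile: float = 0.75
) -> float:
    """Converged mean interaction strength: mean IS_link over the
    high-diversity snapshots (S above the given quantile)."""
    df = snapshots[snapshots["N_link"] > 0]
    if df.empty:
        raise ValueError("no snapshots with links")
    thresh = df["S"].quantile(s_quantile)
    top = df[df["S"] >= thresh]
    return float(top["IS_link"].mean())


def detect_links(
    table: AbundanceTable,
    plot=0,
    spec: EmbeddingSpec | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    n_surrogates: int = 100,
    E: int | None = None,
    standardized: bool = False,
    **ccm_kwargs,
):
    """All-pairs CCM screen within one plot.

    Returns ``(links, results)``: the set of significant (cause, effect)
    taxon-id pairs and the full list of :class:`CausalLink` results.
    Taxa whose series cannot be standardized (constant) are skipped.
    """
    spec = spec or EmbeddingSpec()
    p = (
        table.plot_ids.index(plot)
        if not isinstance(plot, (int, np.integer))
        else plot
    )
    series = {}
    for i, taxon in enumerate(table.taxon_ids):
        raw = table.values[i, :, p]
        try:
            series[taxon] = raw if standardized else standardize(raw)
        except ValueError:
            continue
    taxa = list(series)
    results = []
    links = set()
    for k, cause in enumerate(taxa):
        for m, effect in enumerate(taxa):
            if cause == effect:
                continue
            try:
                link = ccm(
                    series[cause],
                    series[effect],
                    spec=spec,
                    seed=seed + 7919 * k + m,
                    alpha=alpha,
                    n_surrogates=n_surrogates,
                    cause_id=cause,
                    effect_id=effect,
                    E=E,
                    **ccm_kwargs,
                )
            except ValueError:
                continue
            results.append(link)
            if link.significant:
                links.add((cause, effect))
    return links, results


def links_frame(results) -> pd.DataFrame:
    """Tabulate CCM results (one row per directed pair)."""
    return pd.DataFrame(
        [
            {
                "cause": r.cause_id,
                "effect": r.effect_id,
                "E": r.E_used,
                "rho_min": r.rho_min,
                "rho_max": r.rho_max,
                "convergence": r.convergence,
                "p_value": r.p_value,
                "optimal_tp": r.optimal_tp,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def _shuffle_table(table: AbundanceTable, rng) -> AbundanceTable:
    """Independently permute each taxon's series within each plot."""
    values = table.values.copy()
    for p in range(table.n_plots):
        for i in range(table.n_taxa):
            values[i, :, p] = rng.permutation(values[i, :, p])
    return AbundanceTable(
        values, list(table.taxon_ids), table.dates, list(table.plot_ids)
    )


def shuffle_control(
    table: AbundanceTable,
    n_shuffles: int = 5,
    seed: int = 0,
    plot=0,
    alpha: float = 0.05,
    smap_config: SmapConfig | None = None,
    temperature=None,
    run_smap: bool = False,
    **ccm_kwargs,
) -> dict:
    """Rerun the causal screen on time-shuffled series.

    Shuffling each taxon's series independently destroys the dynamics, so
    the significant-link count should fall to the false-positive budget
    (about alpha x pairs tested).  Returns a report dict with real and
    shuffled link counts/fractions and, when ``run_smap`` is set, the
    property-diversity correlations of both pipelines.
    """
    rng = np.random.default_rng(seed)
    real_links, real_results = detect_links(
        table, plot=plot, seed=seed, alpha=alpha, **ccm_kwargs
    )
    n_pairs = len(real_results)
    shuffled_counts, shuffled_pairs = [], 0
    for s in range(n_shuffles):
        shuffled = _shuffle_table(table, rng)
        sl, sres = detect_links(
            shuffled, plot=plot, seed=seed + 1000 + s, alpha=alpha,
            **ccm_kwargs,
        )
        shuffled_counts.append(len(sl))
        shuffled_pairs += len(sres)
    report = {
        "n_pairs_tested": n_pairs,
        "real_links": len(real_links),
        "real_fraction": len(real_links) / n_pairs if n_pairs else np.nan,
        "shuffled_links": shuffled_counts,
        "shuffled_links_total": int(np.sum(shuffled_counts)),
        "shuffled_pairs_total": shuffled_pairs,
        "shuffled_fraction": (
            float(np.sum(shuffled_counts)) / shuffled_pairs
            if shuffled_pairs
            else np.nan
        ),
        "alpha": alpha,
    }
    if run_smap:
        cfg = smap_config or SmapConfig()
        for label, links in (("real", real_links),):
            tensor = build_interaction_tensor(
                links, table, temperature=temperature, config=cfg
            )
            snaps = snapshots_frame(tensor, table)
            report[f"{label}_ic_vs_s_spearman"] = (
                float(snaps["IC"].corr(snaps["S"], method="spearman"))
                if len(snaps) > 2
                else np.nan
            )
    return report


def driver_analysis(
    snapshots: pd.DataFrame,
    temperature,
    total_dna=None,
    properties=("IC", "C", "S"),
    spec: EmbeddingSpec | None = None,
    smap_config: SmapConfig | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    min_length: int = 60,
    **ccm_kwargs,
) -> pd.DataFrame:
    """Causal influence of drivers (temperature, total DNA) on network
    properties, per plot: CCM screens driver -> property, then an S-map
    quantifies the time-varying effect coefficient of each causal driver.

    Returns a long DataFrame (plot, property, driver, date_index,
    coefficient, ccm_p, significant).
    """
    spec = spec or EmbeddingSpec()
    smap_config = smap_config or SmapConfig()
    rows = []
    for plot, df in snapshots.groupby("plot_id"):
        df = df.sort_values("date")
        n = len(df)
        if n < min_length:
            raise ValueError(
                f"snapshot series for {plot} has length {n}; "
                f"need >= {min_length}"
            )
        temp = np.asarray(temperature, dtype=float)[:n]
        drivers = {"temperature": temp}
        if total_dna is not None:
            dna = (
                total_dna[plot] if isinstance(total_dna, dict) else total_dna
            )
            drivers["total_dna"] = np.asarray(dna, dtype=float)[:n]
        for prop in properties:
            y_raw = df[prop].values.astype(float)
            try:
                y = standardize(y_raw)
            except ValueError:
                continue
            causal = {}
            for name, d_raw in drivers.items():
                d = standardize(d_raw)  # raises on constant drivers
                link = ccm(
                    d, y, spec=spec, seed=seed, alpha=alpha,
                    cause_id=name, effect_id=prop, **ccm_kwargs,
                )
                causal[name] = link
            sig_names = [n_ for n_, l in causal.items() if l.significant]
            if sig_names:
                X = np.column_stack(
                    [y] + [standardize(drivers[n_]) for n_ in sig_names]
                )
                fit = fit_multivariate_smap(
                    y, X, config=smap_config,
                    cause_names=[prop] + sig_names,
                )
                for k, name in enumerate(sig_names, start=1):
                    for r, t in enumerate(fit.target_times):
                        rows.append(
                            {
                                "plot": plot,
                                "property": prop,
                                "driver": name,
                                "date_index": int(t),
                                "coefficient": fit.coefficients[r, k],
                                "ccm_p": causal[name].p_value,
                                "significant": True,
                            }
                        )
            for name, link in causal.items():
                if not link.significant:
                    rows.append(
                        {
                            "plot": plot,
                            "property": prop,
                            "driver": name,
                            "date_index": -1,
                            "coefficient": np.nan,
                            "ccm_p": link.p_value,
                            "significant": False,
                        }
                    )
    return pd.DataFrame(rows)
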