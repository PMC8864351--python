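"""Synthetic community dynamics with known interaction structure.

Generates multispecies time series from a discrete-time Ricker map with a
temperature forcing term,

    x_i(t+1) = x_i(t) * exp( r_i + b_i*T_t - sum_j A_ij * x_j(t) + eps_it ),

together with the exact Jacobian of the map along the realized trajectory
(the ground truth that S-map coefficients estimate), and an observation
model emulating quantitative amplicon sequencing with internal-standard
spike-ins: per-sample amplification efficiency, negative-binomial total
depth, and multinomial allocation of reads across taxa and standards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .prep import AbundanceTable

__all__ = [
    "SimulationConfig",
    "ObservationConfig",
    "SyntheticTruth",
    "UnstableParameterization",
    "simulate_community",
    "observe_reads",
    "seasonal_temperature",
    "coupled_logistic_pair",
    "coupled_logistic_network",
]

_EXTINCTION = 1e-12
_DIVERGENCE = 1e12


class UnstableParameterization(RuntimeError):
    """Trajectory diverged (|x| > 1e12); names the first offending step."""


def seasonal_temperature(
    n_steps: int,
    mean: float = 23.0,
    amplitude: float = 5.0,
    trend_per_day: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """A daily air-temperature series (°C): seasonal sine + linear trend.

    Defaults emulate a temperate rice-growing season peaking mid-series.
    """
    t = np.arange(n_steps)
    rng = np.random.default_rng(seed)
    series = (
        mean
        + amplitude * np.sin(np.pi * t / max(n_steps - 1, 1))
        + trend_per_day * t
    )
    if noise_sd > 0:
        series = series + rng.normal(0.0, noise_sd, n_steps)
    return series


@dataclass
class ObservationConfig:
    """Sequencing observation model parameters.

    ``standards`` lists (standard_id, copies_per_µl) spike-ins spanning a
    copy-number gradient (at least 3 distinct levels).  Expected reads of
    every template are ``efficiency_slope`` reads per copy, with the slope
    drawn once per sample with lognormal coefficient of variation
    ``efficiency_cv_across_samples``.  Total depth per sample is negative
    binomial with the given mean and dispersion (Poisson in the limit
    dispersion -> 0); reads are multinomial given depth.  ``sampling`` may
    be "expected" for the deep-sequencing, noise-free limit in which the
    expected (fractional) reads are returned directly.
    """

    read_depth_mean: int = 50_000
    read_depth_dispersion: float = 0.1
    standards: list = field(
        default_factory=lambda: [
            ("std_1", 10.0), ("std_2", 50.0), ("std_3", 250.0),
            ("std_4", 1250.0), ("std_5", 6250.0),
        ]
    )
    efficiency_slope: float = 2.0
    efficiency_cv_across_samples: float = 0.3
    n_filter_types: int = 2
    sampling: str = "multinomial"

    def __post_init__(self):
        copies = [c for _, c in self.standards]
        if len(set(copies)) < 3:
            raise ValueError("standards must span >= 3 distinct copy levels")
        if min(copies) <= 0:
            raise ValueError("standard copies must be positive")
        if self.sampling not in ("multinomial", "expected"):
            raise ValueError("sampling must be 'multinomial' or 'expected'")


def _default_interaction_matrix(n_species: int, rng: np.ndarray) -> np.ndarray:
    """Sparse signed interactions with self-regulation on the diagonal."""
    A = np.zeros((n_species, n_species))
    np.fill_diagonal(A, 1.0)
    n_links = max(1, int(0.15 * n_species * (n_species - 1)))
    off = [(i, j) for i in range(n_species) for j in range(n_species) if i != j]
    idx = rng.choice(len(off), size=n_links, replace=False)
    for k in idx:
        i, j = off[k]
        A[i, j] = rng.choice([-1.0, 1.0]) * rng.uniform(0.1, 0.5)
    return A


@dataclass
class SimulationConfig:
    """Parameters of the Ricker community simulator.

    ``interaction_matrix`` A holds per-capita effects (A[i, j] is the
    effect of species j's abundance on species i's growth, entering the
    exponent with a minus sign, so positive entries are suppressive);
    its diagonal must be zero or positive (self-regulation, which enters
    negatively).  ``temperature_sensitivity`` b_i scales the temperature
    term in the exponent (per °C).
    """

    n_species: int = 5
    n_steps: int = 122
    n_plots: int = 1
    interaction_matrix: np.ndarray | None = None
    growth_rates: np.ndarray | None = None
    temperature_series: np.ndarray | None = None
    temperature_sensitivity: np.ndarray | None = None
    process_noise_sd: float = 0.05
    initial_abundance: np.ndarray | None = None
    observation: ObservationConfig = field(default_factory=ObservationConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_steps < 50:
            raise ValueError("n_steps must be >= 50")
        if self.process_noise_sd < 0:
            raise ValueError("process_noise_sd must be >= 0")
        rng = np.random.default_rng(self.seed)
        if self.interaction_matrix is None:
            self.interaction_matrix = _default_interaction_matrix(
                self.n_species, rng
            )
        self.interaction_matrix = np.asarray(
            self.interaction_matrix, dtype=float
        )
        if self.interaction_matrix.shape != (self.n_species, self.n_species):
            raise ValueError("interaction_matrix must be n_species square")
        if (np.diag(self.interaction_matrix) < 0).any():
            raise ValueError(
                "diagonal of A must be >= 0 (self-regulation enters with a "
                "minus sign in the exponent)"
            )
        if self.growth_rates is None:
            self.growth_rates = np.full(self.n_species, 1.2)
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        if self.temperature_series is None:
            self.temperature_series = seasonal_temperature(self.n_steps)
        self.temperature_series = np.asarray(
            self.temperature_series, dtype=float
        )
        if self.temperature_sensitivity is None:
            self.temperature_sensitivity = np.zeros(self.n_species)
        self.temperature_sensitivity = np.asarray(
            self.temperature_sensitivity, dtype=float
        )
        if self.initial_abundance is None:
            self.initial_abundance = rng.uniform(0.5, 1.5, self.n_species)
        self.initial_abundance = np.asarray(
            self.initial_abundance, dtype=float
        )

    def to_yaml(self, path) -> None:
        payload = {
            "n_species": self.n_species,
            "n_steps": self.n_steps,
            "n_plots": self.n_plots,
            "interaction_matrix": self.interaction_matrix.tolist(),
            "growth_rates": self.growth_rates.tolist(),
            "temperature_series": self.temperature_series.tolist(),
            "temperature_sensitivity": self.temperature_sensitivity.tolist(),
            "process_noise_sd": self.process_noise_sd,
            "initial_abundance": self.initial_abundance.tolist(),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        for key in (
            "interaction_matrix", "growth_rates", "temperature_series",
            "temperature_sensitivity", "initial_abundance",
        ):
            if payload.get(key) is not None:
                payload[key] = np.asarray(payload[key])
        return cls(**payload)


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulation.

    ``jacobians[p][t]`` is the exact n x n Jacobian
    J(t)_ij = d x_i(t+1) / d x_j(t) of the realized map (noise included as
    a known constant at each step) in plot p.  ``links`` is the nonzero
    off-diagonal support of A as (cause, effect) index pairs, i.e. (j, i)
    for A[i, j] != 0.
    """

    abundances: AbundanceTable
    jacobians: np.ndarray  # (n_plots, n_steps - 1, n, n)
    temperature_series: np.ndarray
    links: set
    config: SimulationConfig

    def save(self, directory) -> None:
        """Write abundances, truth matrices and config as CSV/JSON/YAML."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.abundances.to_csv(d / "abundances.csv")
        pd.DataFrame(
            self.config.interaction_matrix,
            index=self.abundances.taxon_ids,
            columns=self.abundances.taxon_ids,
        ).to_csv(d / "interaction_matrix.csv")
        with open(d / "truth.json", "w") as fh:
            json.dump(
                {
                    "links": sorted([list(l) for l in self.links]),
                    "temperature_series": self.temperature_series.tolist(),
                    "jacobians": self.jacobians.tolist(),
                },
                fh,
            )
        self.config.to_yaml(d / "config.yaml")


def _ricker_jacobian(x, growth, A, b_temp_term, eps):
    """Jacobian of x -> x * exp(growth + b*T - A @ x + eps) at state x."""
    expo = np.exp(growth + b_temp_term - A @ x + eps)
    n = len(x)
    return expo[:, None] * (np.eye(n) - x[:, None] * A)


def simulate_community(config: SimulationConfig) -> SyntheticTruth:
    """Run the Ricker community forward and attach exact Jacobians.

    Species falling below 1e-12 are clamped to zero and stay extinct.
    Raises :class:`UnstableParameterization` on divergence (|x| > 1e12).
    """
    n, T, P = config.n_species, config.n_steps, config.n_plots
    A = config.interaction_matrix
    r = config.growth_rates
    b = config.temperature_sensitivity
    temp = config.temperature_series
    rng = np.random.default_rng(config.seed)

    values = np.zeros((n, T, P))
    jacobians = np.zeros((P, T - 1, n, n))
    for p in range(P):
        x = config.initial_abundance * rng.uniform(0.9, 1.1, n) if P > 1 \
            else config.initial_abundance.copy()
        values[:, 0, p] = x
        for t in range(T - 1):
            eps = (
                rng.normal(0.0, config.process_noise_sd, n)
                if config.process_noise_sd > 0
                else np.zeros(n)
            )
            b_term = b * temp[t]
            jacobians[p, t] = _ricker_jacobian(x, r, A, b_term, eps)
            x = x * np.exp(r + b_term - A @ x + eps)
            extinct = x < _EXTINCTION
            x[extinct] = 0.0
            jacobians[p, t][extinct, :] = 0.0
            if (np.abs(x) > _DIVERGENCE).any() or not np.isfinite(x).all():
                raise UnstableParameterization(
                    f"unstable parameterization: |x| exceeded {_DIVERGENCE:g} "
                    f"at step {t + 1} (plot {p + 1})"
                )
            values[:, t + 1, p] = x

    table = AbundanceTable(values)
    links = {
        (j, i)
        for i in range(n)
        for j in range(n)
        if i != j and A[i, j] != 0.0
    }
    return SyntheticTruth(
        abundances=table,
        jacobians=jacobians,
        temperature_series=temp,
        links=links,
        config=config,
    )


def observe_reads(
    truth: SyntheticTruth,
    obs: ObservationConfig | None = None,
    seed: int = 0,
):
    """Simulate sequencing of every (plot, date, filter-type) sample.

    Returns ``(read_table, standard_read_table, metadata_table)``:
    taxa x samples and standards x samples DataFrames of read counts plus
    a long metadata table (sample_id, plot, date, filter_type, depth,
    uncalibratable flag).  Expected reads of each template are
    proportional to copies/µl with a sample-specific efficiency slope;
    realized reads are multinomial given a negative-binomial total depth.
    """
    obs = obs or truth.config.observation
    table = truth.abundances
    rng = np.random.default_rng(seed)
    std_ids = [s for s, _ in obs.standards]
    std_copies = np.array([c for _, c in obs.standards])

    sample_ids, meta_rows = [], []
    read_cols, std_cols = [], []
    for p, plot in enumerate(table.plot_ids):
        for t, date in enumerate(table.dates):
            for f in range(obs.n_filter_types):
                filt = f"F{f + 1}"
                sid = f"{plot}_{date.strftime('%Y%m%d')}_{filt}"
                sample_ids.append(sid)
                copies = np.nan_to_num(table.values[:, t, p], nan=0.0)
                slope = obs.efficiency_slope
                if obs.efficiency_cv_across_samples > 0:
                    cv = obs.efficiency_cv_across_samples
                    sigma = np.sqrt(np.log1p(cv**2))
                    slope = slope * rng.lognormal(-sigma**2 / 2, sigma)
                expected = np.concatenate([copies, std_copies]) * slope
                total_expected = expected.sum()
                uncalibratable = bool(
                    copies.sum() == 0 and std_copies.sum() == 0
                )
                if total_expected == 0:
                    reads = np.zeros_like(expected)
                    depth = 0
                elif obs.sampling == "expected":
                    # deep-sequencing limit: expected fractional reads
                    reads = expected
                    depth = float(total_expected)
                else:
                    if obs.read_depth_dispersion > 0:
                        k = 1.0 / obs.read_depth_dispersion
                        lam = rng.gamma(k, obs.read_depth_mean / k)
                        depth = int(rng.poisson(lam))
                    else:
                        depth = int(rng.poisson(obs.read_depth_mean))
                    reads = rng.multinomial(depth, expected / total_expected)
                read_cols.append(reads[: table.n_taxa])
                std_cols.append(reads[table.n_taxa:])
                meta_rows.append(
                    {
                        "sample_id": sid, "plot": plot, "date": date,
                        "filter_type": filt, "depth": depth,
                        "uncalibratable": uncalibratable,
                    }
                )
    read_table = pd.DataFrame(
        np.column_stack(read_cols), index=table.taxon_ids, columns=sample_ids
    )
    standard_read_table = pd.DataFrame(
        np.column_stack(std_cols), index=std_ids, columns=sample_ids
    )
    metadata_table = pd.DataFrame(meta_rows)
    return read_table, standard_read_table, metadata_table


def coupled_logistic_pair(
    n_steps: int = 400,
    coupling_xy: float = 0.3,
    coupling_yx: float = 0.0,
    r_x: float = 3.8,
    r_y: float = 3.5,
    seed: int = 0,
    burn_in: int = 100,
):
    """Unidirectionally (or bidirectionally) coupled logistic maps.

    x(t+1) = x (r_x - r_x x - c_yx y);  y(t+1) = y (r_y - r_y y - c_xy x).
    The classic benchmark for cross-mapping causality: with c_xy > 0 and
    c_yx = 0, X drives Y and only the X -> Y direction is causal.
    Returns (x, y) after burn-in.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.2, 0.8)
    y = rng.uniform(0.2, 0.8)
    xs = np.empty(n_steps + burn_in)
    ys = np.empty(n_steps + burn_in)
    for t in range(n_steps + burn_in):
        xs[t], ys[t] = x, y
        x_new = x * (r_x - r_x * x - coupling_yx * y)
        y_new = y * (r_y - r_y * y - coupling_xy * x)
        # keep trajectories in the unit interval (coupling can push them out)
        x = min(max(x_new, 1e-6), 1.0 - 1e-6)
        y = min(max(y_new, 1e-6), 1.0 - 1e-6)
    return xs[burn_in:], ys[burn_in:]


def coupled_logistic_network(
    coupling: np.ndarray,
    n_steps: int = 400,
    growth_rates=None,
    seed: int = 0,
    burn_in: int = 100,
) -> AbundanceTable:
    """Network of coupled logistic maps with known directed structure.

    ``coupling[i, j]`` is the strength with which species j suppresses
    species i's growth: x_i(t+1) = x_i (r_i - r_i x_i - sum_j c_ij x_j).
    Distinct growth rates r_i in the chaotic band (3.6-3.9 by default)
    keep the maps desynchronized, so the nonzero off-diagonal support of
    ``coupling`` is the ground-truth link set (j -> i).  Returns a
    single-plot :class:`AbundanceTable`.
    """
    C = np.asarray(coupling, dtype=float)
    n = C.shape[0]
    rng = np.random.default_rng(seed)
    if growth_rates is None:
        growth_rates = np.linspace(3.6, 3.9, n)
    r = np.asarray(growth_rates, dtype=float)
    x = rng.uniform(0.2, 0.8, n)
    out = np.empty((n, n_steps))
    off = C.copy()
    np.fill_diagonal(off, 0.0)
    for t in range(n_steps + burn_in):
        if t >= burn_in:
            out[:, t - burn_in] = x
        x = x * (r - r * x - off @ x)
        x = np.clip(x, 1e-6, 1.0 - 1e-6)
    return AbundanceTable(out[:, :, None])
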