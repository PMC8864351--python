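"""Empirical dynamic modelling core.

State-space reconstruction by delay embedding, simplex projection
(nearest-neighbour forecasting, used to select the embedding dimension),
and convergent cross-mapping (CCM) with surrogate-based significance.

CCM tests whether variable X causally forces variable Y: if it does, the
delay embedding of Y contains information about X, so cross-mapping from
Y's reconstructed state space recovers X with a skill that increases
("converges") as the library of reconstructed states grows.  Significance
combines that convergence requirement, an exceedance test against
amplitude-adjusted phase-randomized (or time-shifted) surrogate causes,
and a cross-map lag criterion that separates a true cause from the echo a
strongly driven variable carries of its driver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmbeddingSpec",
    "CausalLink",
    "embed",
    "simplex_skill",
    "select_E",
    "ccm",
    "aaft_surrogates",
    "ebisuzaki_surrogates",
    "time_shift_surrogates",
]


@dataclass
class EmbeddingSpec:
    """Delay-embedding parameters: dimension E, lag tau (days) and the
    Theiler window (temporal exclusion radius for neighbour searches)."""

    E: int = 2
    tau: int = 1
    theiler_w: int = 0

    def __post_init__(self):
        if self.E < 1 or self.tau < 1 or self.theiler_w < 0:
            raise ValueError("require E >= 1, tau >= 1, theiler_w >= 0")


@dataclass
class CausalLink:
    """Result of one directed CCM test (cause -> effect)."""

    cause_id: str
    effect_id: str
    skill_profile: dict  # library size -> mean cross-map skill rho
    rho_min: float
    rho_max: float
    convergence: float
    p_value: float
    significant: bool
    E_used: int
    optimal_tp: int = 0
    tp_profile: dict = field(default_factory=dict)


def embed(series, spec: EmbeddingSpec):
    """Delay-coordinate matrix of a series.

    Rows are (x_t, x_{t-tau}, ..., x_{t-(E-1)tau}) for
    t = (E-1)*tau .. n-1, as a masked array: rows containing missing
    values are masked, never silently dropped.  Also exposes the time
    index of each row via the ``.times`` attribute of the returned tuple.

    Returns ``(M, times)`` where ``M`` is a masked (n_rows, E) array.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    min_len = (spec.E - 1) * spec.tau + 2
    if n < min_len:
        raise ValueError(
            f"series too short for embedding: need length >= {min_len}, "
            f"got {n}"
        )
    start = (spec.E - 1) * spec.tau
    times = np.arange(start, n)
    cols = [x[times - k * spec.tau] for k in range(spec.E)]
    M = np.column_stack(cols)
    mask = np.isnan(M).any(axis=1)
    M = np.ma.masked_array(M, mask=np.repeat(mask[:, None], spec.E, axis=1))
    return M, times


def _simplex_predictions(M, times, targets, spec, lib_rows=None):
    """One-step-ahead simplex predictions at every usable row.

    ``targets[i]`` is the value to predict for row i (x at time
    times[i] + 1); rows with masked coordinates or missing targets are
    excluded.  Leave-one-out: each prediction excludes its own row and
    rows within the Theiler window.
    """
    valid = ~M.mask.any(axis=1) & ~np.isnan(targets)
    rows = np.where(valid)[0]
    X = np.asarray(M[rows])
    t = times[rows]
    y = targets[rows]
    n = rows.size
    k = spec.E + 1
    if n < k + 1:
        raise ValueError(
            f"insufficient rows for simplex projection: have {n}, "
            f"need > {k}"
        )
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    excl = np.abs(t[:, None] - t[None, :]) <= spec.theiler_w
    d[excl] = np.inf
    nbr = np.argpartition(d, k - 1, axis=1)[:, :k]
    nd = np.take_along_axis(d, nbr, axis=1)
    order = np.argsort(nd, axis=1, kind='stable')
    nbr = np.take_along_axis(nbr, order, axis=1)
    nd = np.take_along_axis(nd, order, axis=1)
    d1 = nd[:, [0]]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-nd / d1)
    # all-zero nearest distances: fall back to uniform weights
    zero_d1 = (d1[:, 0] == 0)
    if zero_d1.any():
        w[zero_d1] = 1.0
    w = w / w.sum(axis=1, keepdims=True)
    preds = (w * y[nbr]).sum(axis=1)
    return preds, y


def _pearson(a, b):
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def simplex_skill(series, E: int, spec: EmbeddingSpec | None = None) -> float:
    """Leave-one-out, one-step-ahead simplex forecast skill (Pearson rho).

    Each point is predicted from its E+1 nearest embedded neighbours
    (Theiler-window excluded) with exponential weights exp(-d/d_1).
    """
    spec = spec or EmbeddingSpec()
    spec = EmbeddingSpec(E=E, tau=spec.tau, theiler_w=spec.theiler_w)
    x = np.asarray(series, dtype=float)
    M, times = embed(x, spec)
    targets = np.full(times.size, np.nan)
    ahead = times + 1
    ok = ahead < x.size
    targets[ok] = x[ahead[ok]]
    preds, obs = _simplex_predictions(M, times, targets, spec)
    return _pearson(preds, obs)


def select_E(
    series,
    E_max: int = 10,
    spec: EmbeddingSpec | None = None,
    tol: float = 1e-3,
) -> int:
    """Embedding dimension maximizing simplex forecast skill over 1..E_max.

    Near-ties break toward the smaller E: the smallest E whose skill comes
    within ``tol`` of the maximum is returned, so numerically flat skill
    profiles (e.g. already-unfolded periodic signals) do not inflate E.
    """
    spec = spec or EmbeddingSpec()
    x = np.asarray(series, dtype=float)
    present = x[~np.isnan(x)]
    if len(np.unique(present)) < 2:
        raise ValueError("cannot select E for a constant series")
    skills = {}
    for E in range(1, E_max + 1):
        try:
            rho = simplex_skill(x, E, spec)
        except ValueError:
            break
        if np.isfinite(rho):
            skills[E] = rho
    if not skills:
        raise ValueError("no embedding dimension produced a finite skill")
    best = max(skills.values())
    return min(E for E, rho in skills.items() if rho >= best - tol)


def ebisuzaki_surrogates(series, n_surrogates: int, rng) -> np.ndarray:
    """Phase-randomized surrogates preserving the power spectrum."""
    x = np.asarray(series, dtype=float)
    n = x.size
    mu = x.mean()
    f = np.fft.rfft(x - mu)
    n_freq = f.size
    out = np.empty((n, n_surrogates))
    for s in range(n_surrogates):
        phases = rng.uniform(0, 2 * np.pi, n_freq)
        phases[0] = 0.0
        if n % 2 == 0:
            phases[-1] = 0.0
        g = np.abs(f) * np.exp(1j * phases)
        out[:, s] = np.fft.irfft(g, n) + mu
    return out


def aaft_surrogates(series, n_surrogates: int, rng) -> np.ndarray:
    """Amplitude-adjusted phase-randomized surrogates.

    Phase randomization alone replaces the marginal distribution with a
    Gaussian, which makes the null anti-conservative for skewed series;
    the amplitude adjustment rank-remaps each surrogate onto the observed
    values, preserving the exact marginal and approximately the power
    spectrum.
    """
    x = np.asarray(series, dtype=float)
    base = ebisuzaki_surrogates(x, n_surrogates, rng)
    sorted_x = np.sort(x)
    out = np.empty_like(base)
    for s in range(n_surrogates):
        ranks = np.argsort(np.argsort(base[:, s]))
        out[:, s] = sorted_x[ranks]
    return out


def time_shift_surrogates(series, n_surrogates: int, rng) -> np.ndarray:
    """Circular time-shift surrogates (shift >= 1, uniform)."""
    x = np.asarray(series, dtype=float)
    n = x.size
    shifts = rng.integers(1, n, size=n_surrogates)
    return np.column_stack([np.roll(x, s) for s in shifts])


def _cross_map_structures(M, times, spec, lib_rows, pred_rows, k):
    """Neighbour indices (into the full time axis) and weights for
    cross-mapping from library ``lib_rows`` onto prediction rows."""
    X = np.asarray(M)
    d = np.sqrt(
        ((X[pred_rows][:, None, :] - X[lib_rows][None, :, :]) ** 2).sum(-1)
    )
    t_pred = times[pred_rows]
    t_lib = times[lib_rows]
    excl = np.abs(t_pred[:, None] - t_lib[None, :]) <= spec.theiler_w
    d[excl] = np.inf
    nbr = np.argpartition(d, k - 1, axis=1)[:, :k]
    nd = np.take_along_axis(d, nbr, axis=1)
    order = np.argsort(nd, axis=1, kind='stable')
    nbr = np.take_along_axis(nbr, order, axis=1)
    nd = np.take_along_axis(nd, order, axis=1)
    d1 = nd[:, [0]]
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        w = np.exp(-nd / d1)
    zero_d1 = d1[:, 0] == 0
    if zero_d1.any():
        rows = np.where(zero_d1)[0]
        w[rows] = (nd[rows] == 0).astype(float)
    bad = ~np.isfinite(w)
    if bad.any():
        w[bad] = 0.0
    w = w / w.sum(axis=1, keepdims=True)
    nbr_times = t_lib[nbr]
    return nbr_times, w


def _lag_skill_profile(M, times, x, spec, k, tps):
    """Cross-map skill as a function of the prediction lag tp.

    For a true cause the effect's manifold best estimates the cause at a
    non-positive lag (the cause precedes its signature in the effect);
    a skill peak at positive tp marks the spurious back-direction that
    strong unidirectional forcing induces.
    """
    out = {}
    for tp in tps:
        tt = times + tp
        inb = (tt >= 0) & (tt < x.size)
        ok = (~M.mask.any(axis=1)) & inb
        ok[inb] &= ~np.isnan(x[tt[inb]])
        rows = np.where(ok)[0]
        if rows.size < k + 2:
            out[tp] = np.nan
            continue
        nbr_times, w = _cross_map_structures(M, times, spec, rows, rows, k)
        pred = (w * x[nbr_times + tp]).sum(axis=1)
        out[tp] = _pearson(pred, x[times[rows] + tp])
    return out


def _batch_rho(preds, obs):
    """Column-wise Pearson correlation of (n, m) preds against (n, m) obs."""
    pm = preds - preds.mean(axis=0)
    om = obs - obs.mean(axis=0)
    num = (pm * om).sum(axis=0)
    den = np.sqrt((pm**2).sum(axis=0) * (om**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / den
    return rho


def ccm(
    cause,
    effect,
    spec: EmbeddingSpec | None = None,
    library_sizes=None,
    n_surrogates: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    n_draws: int = 20,
    surrogate_method: str = "aaft",
    cause_id: str = "cause",
    effect_id: str = "effect",
    E: int | None = None,
    E_max: int = 8,
    tp_grid=(-3, -2, -1, 0, 1, 2, 3),
    require_nonpositive_lag: bool = True,
    lag_gap_tol: float = 0.05,
) -> CausalLink:
    """Convergent cross-mapping test of cause -> effect.

    The effect series is delay-embedded and used to cross-map the cause;
    skill rising with library size indicates that the cause leaves a
    signature in the effect's dynamics.  The skill profile averages
    ``n_draws`` random library subsamples per size.  Significance
    combines three conditions: (i) surrogate exceedance — p is the
    fraction of ``n_surrogates`` surrogate causes whose cross-map skill
    at the largest library exceeds the observed rho_max, and p < alpha is
    required; (ii) convergence > 0; (iii) by default, the
    cross-map skill over the prediction-lag grid ``tp_grid`` must peak at
    a non-positive lag — a cause precedes its signature in the effect, so
    a peak at positive lag flags the spurious reverse direction that
    strong unidirectional forcing induces.  The lag condition uses the
    tolerance ``lag_gap_tol``: the best skill at tp <= 0 must come within
    that margin of the best skill overall, so near-flat lag profiles
    (tightly coupled or synchronized systems, where the peak location is
    noise) are not rejected, while a genuinely one-sided profile (skill
    concentrated at positive lags) is.
    """
    spec = spec or EmbeddingSpec()
    if n_surrogates < 20:
        warnings.warn("n_surrogates < 20 gives a coarse p-value")
    x = np.asarray(cause, dtype=float)
    y = np.asarray(effect, dtype=float)
    if x.size != y.size:
        raise ValueError("cause and effect must have equal length")
    rng = np.random.default_rng(seed)

    if E is None:
        E = select_E(y, E_max=min(E_max, max(1, x.size // 10)), spec=spec)
    espec = EmbeddingSpec(E=E, tau=spec.tau, theiler_w=spec.theiler_w)
    M, times = embed(y, espec)
    row_ok = ~M.mask.any(axis=1) & ~np.isnan(x[times])
    rows = np.where(row_ok)[0]
    n_valid = rows.size
    k = E + 1
    if n_valid < k + 2:
        raise ValueError("too few valid embedded points for CCM")

    if library_sizes is None:
        lo = max(k + 2, 10)
        library_sizes = np.unique(
            np.round(np.geomspace(lo, n_valid, 5)).astype(int)
        )
    library_sizes = np.asarray(sorted(set(int(L) for L in library_sizes)))
    if library_sizes[0] < k + 1 or library_sizes[-1] > n_valid:
        raise ValueError(
            f"library sizes must lie in [{k + 1}, {n_valid}]"
        )

    if surrogate_method == "aaft":
        surr = aaft_surrogates(x, n_surrogates, rng)
    elif surrogate_method == "ebisuzaki":
        surr = ebisuzaki_surrogates(x, n_surrogates, rng)
    elif surrogate_method == "time_shift":
        surr = time_shift_surrogates(x, n_surrogates, rng)
    else:
        raise ValueError(
            "surrogate_method must be 'aaft', 'ebisuzaki' or 'time_shift'"
        )
    # column 0 = observed cause, remaining columns = surrogates
    C = np.column_stack([x, surr])

    L_min, L_max = int(library_sizes[0]), int(library_sizes[-1])
    profile = {}
    surro_rho = {L_min: [], L_max: []}
    for L in library_sizes:
        L = int(L)
        draws = 1 if L == n_valid else n_draws
        rhos_obs = []
        for _ in range(draws):
            if L == n_valid:
                lib = rows
            else:
                lib = rows[rng.choice(n_valid, size=L, replace=False)]
            nbr_times, w = _cross_map_structures(
                M, times, espec, lib, rows, k
            )
            if L in (L_min, L_max):
                preds = np.einsum("pk,pkm->pm", w, C[nbr_times])
                obs = C[times[rows]]
                rho = _batch_rho(preds, obs)
                rhos_obs.append(rho[0])
                surro_rho[L].append(rho[1:])
            else:
                pred = (w * x[nbr_times]).sum(axis=1)
                rhos_obs.append(_pearson(pred, x[times[rows]]))
        profile[L] = float(np.nanmean(rhos_obs))

    rho_min = profile[L_min]
    rho_max = profile[L_max]
    convergence = rho_max - rho_min
    surr_min = np.nanmean(np.vstack(surro_rho[L_min]), axis=0)
    surr_max = np.nanmean(np.vstack(surro_rho[L_max]), axis=0)
    # single-statistic exceedance: a joint (convergence AND rho_max)
    # condition would be anti-conservative, since beating the observation
    # on both statistics at once is rarer than on either alone
    p_value = float(np.mean(surr_max >= rho_max))

    tp_prof = _lag_skill_profile(M, times, x, espec, k, tp_grid)
    finite = {t: r for t, r in tp_prof.items() if np.isfinite(r)}
    optimal_tp = min(finite, key=lambda t: (-finite[t], t)) if finite else 0

    significant = bool(p_value < alpha and convergence > 0)
    if require_nonpositive_lag and finite:
        best_overall = max(finite.values())
        nonpos = [r for t, r in finite.items() if t <= 0]
        best_nonpos = max(nonpos) if nonpos else -np.inf
        significant = significant and (
            best_nonpos >= best_overall - lag_gap_tol
        )
    return CausalLink(
        cause_id=cause_id,
        effect_id=effect_id,
        skill_profile=profile,
        rho_min=float(rho_min),
        rho_max=float(rho_max),
        convergence=float(convergence),
        p_value=p_value,
        significant=significant,
        E_used=E,
        optimal_tp=int(optimal_tp),
        tp_profile=tp_prof,
    )
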