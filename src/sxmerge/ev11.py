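"""Ev11 measurement-error model: inflation, calibration and refinement.

Photon-counting sigmas from still-image integration systematically
underestimate the scatter actually observed among repeated measurements of
the same reflection (partiality-correction residuals, gain misestimation,
instrument instability...). The Ev11 model inflates each counting sigma
with three terms in quadrature,

    sigma_Ev11 = s_fac * [ sigma_hj^2 + s_B * <I_h> + (s_add * <I_h>)^2 ]^(1/2)

where <I_h> is the plain mean of the corrected measurements of reflection h.
s_fac absorbs multiplicative sigma errors such as a wrong detector gain
(wrong by the square root of the gain ratio), s_add absorbs errors
proportional to the intensity, and s_B is an empirical middle term with no
assigned physical meaning.

Calibration is judged through leave-one-out normalized deviations

    delta_hj = [(n-1)/n]^(1/2) * (I_hj - <I'_hj>) / sigma

which are standard-normal when the sigmas are right. Initial parameters come
from a normal probability plot of the deviations (slope -> s_fac, offset ->
s_add, s_B = s_add^(1/2)); refinement then minimizes, by bound-constrained
L-BFGS, the weighted squared departure from 1 of the per-intensity-bin
r.m.s. of the deviations over 100 equal-width bins of <I_h>:

    f = sum_b m_b^(1/2) * (rmsd_b - 1)^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .data_model import ReflectionGroup, ValidationError

__all__ = [
    "ErrorModelParams",
    "NormalProbabilityPlot",
    "IntensityBinSet",
    "PreparedGroups",
    "RefinementResult",
    "leave_one_out_mean",
    "normalized_deviation",
    "rankits",
    "normal_probability_plot",
    "fit_npp_line",
    "initialize_params",
    "sigma_ev11",
    "prepare_groups",
    "bin_measurements",
    "target_function",
    "target_gradient",
    "refine_error_model",
    "deviations_for_plot",
]

@dataclass(frozen=True)
class ErrorModelParams:
    """The Ev11 triple (s_fac, s_B, s_add).

    s_fac and s_add are non-negative scale terms; s_B is unconstrained (it
    can legitimately refine to or through zero).
    """

    s_fac: float = 1.0
    s_B: float = 0.0
    s_add: float = 0.0

    def __post_init__(self) -> None:
        if self.s_fac < 0:
            raise ValidationError(f"s_fac must be >= 0, got {self.s_fac}")
        if self.s_add < 0:
            raise ValidationError(f"s_add must be >= 0, got {self.s_add}")

    def as_array(self) -> np.ndarray:
        return np.array([self.s_fac, self.s_B, self.s_add], dtype=float)


@dataclass
class NormalProbabilityPlot:
    """Sorted normalized deviations against standard-normal rankits."""

    sorted_deviations: np.ndarray
    rankits: np.ndarray
    slope: float
    offset: float
    fit_range: tuple[float, float]


@dataclass
class IntensityBinSet:
    """Equal-width bins of group mean intensity with per-bin deviation r.m.s."""

    n_bins: int
    edges: np.ndarray            # n_bins + 1 boundaries over [min<I_h>, max<I_h>]
    counts: np.ndarray           # m_b, measurements per bin
    rmsd: np.ndarray             # r.m.s. of normalized deviations per bin
    weights: np.ndarray          # w_b = m_b^(1/2)
    target_value: float          # f = sum_b w_b (rmsd_b - 1)^2


# ---------------------------------------------------------------------------
# per-measurement building blocks

def leave_one_out_mean(group: ReflectionGroup, j: int) -> float:
    """Mean of the group's measurements excluding measurement j (0-based).

    For a single-measurement group the leave-one-out mean is defined as 0.
    """
    n = group.n
    if not 0 <= j < n:
        raise IndexError(f"index {j} out of range for group of size {n}")
    if n == 1:
        return 0.0
    i = np.asarray(group.intensities, dtype=float)
    return float((i.sum() - i[j]) / (n - 1))


def normalized_deviation(group: ReflectionGroup, j: int, sigma: float) -> float:
    """Leave-one-out standardized residual of measurement j.

    delta = [(n-1)/n]^(1/2) * (I_j - <I'_j>) / sigma. The (n-1)/n prefactor
    makes the variance of the leave-one-out difference equal sigma^2 when all
    measurements share the same true sigma. Single-measurement groups return
    exactly 0 and are excluded from normal probability analysis.
    """
    n = group.n
    if n == 1:
        return 0.0
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    loo = leave_one_out_mean(group, j)
    return float(
        np.sqrt((n - 1) / n) * (group.intensities[j] - loo) / sigma
    )


def rankits(m: int) -> np.ndarray:
    """Normal order-statistic medians z_i = Phi^-1[(i - a)/(m + 1 - 2a)].

    a = 3/8 for m <= 10 and 0.5 for m > 10 (the qqnorm convention). The
    result is strictly increasing and antisymmetric: z_i = -z_{m+1-i}.
    """
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    a = 0.375 if m <= 10 else 0.5
    i = np.arange(1, m + 1, dtype=float)
    return stats.norm.ppf((i - a) / (m + 1 - 2 * a))


def fit_npp_line(
    sorted_deviations: np.ndarray,
    z: np.ndarray,
    lo: float = -0.5,
    hi: float = 0.5,
) -> tuple[float, float]:
    """Least-squares line through the central region of the probability plot.

    Only points whose rankit lies in [lo, hi] enter the fit, keeping the tail
    outliers away from the slope/offset estimate.
    """
    z = np.asarray(z, dtype=float)
    d = np.asarray(sorted_deviations, dtype=float)
    mask = (z >= lo) & (z <= hi)
    if mask.sum() < 2:
        raise ValidationError(
            f"only {int(mask.sum())} plot points with rankit in [{lo}, {hi}]; "
            "widen the fit range"
        )
    slope, offset = np.polyfit(z[mask], d[mask], 1)
    return float(slope), float(offset)


def normal_probability_plot(
    deviations: np.ndarray, lo: float = -0.5, hi: float = 0.5
) -> NormalProbabilityPlot:
    """Build the normal probability plot and fit its central line."""
    d = np.sort(np.asarray(deviations, dtype=float), kind="stable")
    z = rankits(len(d))
    slope, offset = fit_npp_line(d, z, lo, hi)
    return NormalProbabilityPlot(
        sorted_deviations=d, rankits=z, slope=slope, offset=offset,
        fit_range=(lo, hi),
    )


def initialize_params(slope: float, offset: float) -> ErrorModelParams:
    """Initial Ev11 parameters from the probability-plot line.

    s_fac is the slope; s_add is the offset (clamped at 0, both being
    non-negative scale terms); s_B starts at s_add^(1/2).
    """
    s_add = max(float(offset), 0.0)
    return ErrorModelParams(s_fac=float(slope), s_B=float(np.sqrt(s_add)), s_add=s_add)


def sigma_ev11(
    sigma: np.ndarray | float,
    mean_i: np.ndarray | float,
    params: ErrorModelParams,
) -> np.ndarray | float:
    """Inflated error estimate s_fac*[sigma^2 + s_B*<I_h> + (s_add*<I_h>)^2]^(1/2).

    If a negative s_B drives the radicand negative, the result is clamped to
    s_fac * sigma with a warning.
    """
    s = np.asarray(sigma, dtype=float)
    mu = np.asarray(mean_i, dtype=float)
    radicand = s**2 + params.s_B * mu + (params.s_add * mu) ** 2
    bad = radicand <= 0
    if np.any(bad):
        warnings.warn(
            f"sigma_ev11: {int(np.count_nonzero(bad))} non-positive radicand(s) "
            "clamped to s_fac * sigma",
            RuntimeWarning,
            stacklevel=2,
        )
        radicand = np.where(bad, s**2, radicand)
    out = params.s_fac * np.sqrt(radicand)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# refinement machinery (vectorized over all measurements)

@dataclass
class PreparedGroups:
    """Flat arrays for fast target/gradient evaluation.

    Only measurements from groups with n >= 2 are retained (single
    measurements have identically-zero deviations and are excluded from
    binning). The leave-one-out numerators and the group means are fixed
    once; refinement only moves the sigma model.
    """

    numer: np.ndarray      # [(n-1)/n]^(1/2) * (I_j - <I'_j>) per measurement
    sigma: np.ndarray      # counting sigma (corrected to full equivalent)
    mean_i: np.ndarray     # <I_h> of the owning group, per measurement
    bin_index: np.ndarray  # intensity bin of the owning group, per measurement
    bins: IntensityBinSet  # skeleton: edges/counts/weights (rmsd filled on eval)
    n_excluded: int        # measurements dropped from n = 1 groups


def bin_measurements(
    groups: Sequence[ReflectionGroup], n_bins: int = 100
) -> IntensityBinSet:
    """Equal-width bins of <I_h> spanning [min <I_h>, max <I_h>].

    Every measurement of a group lands in the single bin containing the
    group's mean intensity (top edge inclusive). Groups with n = 1 are
    excluded. If all means coincide, a single bin holds everything.
    """
    multi = [g for g in groups if g.n >= 2]
    if not multi:
        raise ValidationError("no groups with n >= 2 to bin")
    means = np.array([g.mean for g in multi])
    lo, hi = float(means.min()), float(means.max())
    if lo == hi:
        warnings.warn(
            "all group means identical; falling back to a single bin",
            RuntimeWarning, stacklevel=2,
        )
        n_bins = 1
        edges = np.array([lo, lo])
        idx = np.zeros(len(multi), dtype=np.intp)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        width = (hi - lo) / n_bins
        idx = np.minimum(
            ((means - lo) / width).astype(np.intp), n_bins - 1
        )
    counts = np.bincount(
        np.repeat(idx, [g.n for g in multi]), minlength=n_bins
    ).astype(np.intp)
    return IntensityBinSet(
        n_bins=n_bins, edges=edges, counts=counts,
        rmsd=np.zeros(n_bins), weights=np.sqrt(counts.astype(float)),
        target_value=np.nan,
    )


def prepare_groups(
    groups: Iterable[ReflectionGroup], n_bins: int = 100
) -> PreparedGroups:
    """Precompute the parameter-independent pieces of the refinement target."""
    groups = list(groups)
    multi = [g for g in groups if g.n >= 2]
    bins = bin_measurements(groups, n_bins=n_bins)
    numer, sigma, mean_i, bin_index = [], [], [], []
    lo = bins.edges[0]
    width = (bins.edges[-1] - bins.edges[0]) / bins.n_bins if bins.n_bins > 0 else 1.0
    n_excluded = 0
    for g in groups:
        if g.n < 2:
            n_excluded += g.n
            continue
        i = np.asarray(g.intensities, dtype=float)
        n = len(i)
        loo = (i.sum() - i) / (n - 1)
        numer.append(np.sqrt((n - 1) / n) * (i - loo))
        sigma.append(np.asarray(g.sigmas, dtype=float))
        mean_i.append(np.full(n, g.mean))
        if width > 0:
            b = min(int((g.mean - lo) / width), bins.n_bins - 1)
        else:
            b = 0
        bin_index.append(np.full(n, b, dtype=np.intp))
    return PreparedGroups(
        numer=np.concatenate(numer),
        sigma=np.concatenate(sigma),
        mean_i=np.concatenate(mean_i),
        bin_index=np.concatenate(bin_index),
        bins=bins,
        n_excluded=n_excluded,
    )


def _sigma2_ev11(
    p: PreparedGroups, s_fac: float, s_b: float, s_add: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(sigma_Ev11^2, clamped radicand, clamp mask)."""
    radicand = p.sigma**2 + s_b * p.mean_i + (s_add * p.mean_i) ** 2
    bad = radicand <= 0
    if bad.any():
        radicand = np.where(bad, p.sigma**2, radicand)
    return s_fac**2 * radicand, radicand, bad


def _bin_stats(
    p: PreparedGroups, d2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(rmsd_b, sum of delta^2 per bin)."""
    s_b = np.bincount(p.bin_index, weights=d2, minlength=p.bins.n_bins)
    m_b = p.bins.counts
    rmsd = np.zeros_like(s_b)
    nz = m_b > 0
    rmsd[nz] = np.sqrt(s_b[nz] / m_b[nz])
    return rmsd, s_b


def target_function(
    params: ErrorModelParams, prepared: PreparedGroups
) -> float:
    """f = sum_b m_b^(1/2) * (rmsd_b - 1)^2 over occupied intensity bins."""
    sig2, _, _ = _sigma2_ev11(prepared, params.s_fac, params.s_B, params.s_add)
    d2 = prepared.numer**2 / sig2
    rmsd, _ = _bin_stats(prepared, d2)
    occ = prepared.bins.counts > 0
    f = float(np.sum(prepared.bins.weights[occ] * (rmsd[occ] - 1.0) ** 2))
    prepared.bins.rmsd = rmsd
    prepared.bins.target_value = f
    return f


def target_gradient(
    params: ErrorModelParams, prepared: PreparedGroups
) -> np.ndarray:
    """Analytic gradient (df/ds_fac, df/ds_B, df/ds_add).

    Chain rule through f -> rmsd_b -> sum-of-delta^2 -> sigma_Ev11^2: with
    S_b = sum_k delta_bk^2,  df/dS_b = (rmsd_b - 1) / (rmsd_b * m_b^(1/2)),
    and d(delta^2)/dtheta = -delta^2 * d(sigma_E^2)/dtheta / sigma_E^2.
    Rows clamped by the negative-radicand guard contribute no s_B/s_add
    gradient (their sigma depends on s_fac only).
    """
    s_fac, s_b_, s_add = params.s_fac, params.s_B, params.s_add
    sig2, radicand, clamped = _sigma2_ev11(prepared, s_fac, s_b_, s_add)
    d2 = prepared.numer**2 / sig2
    rmsd, _ = _bin_stats(prepared, d2)
    m_b = prepared.bins.counts
    df_ds = np.zeros_like(rmsd)
    nz = (m_b > 0) & (rmsd > 0)
    df_ds[nz] = (rmsd[nz] - 1.0) / (rmsd[nz] * np.sqrt(m_b[nz].astype(float)))
    per_row = df_ds[prepared.bin_index]

    # d(delta^2)/ds_fac = -2 delta^2 / s_fac  (all rows, clamped or not)
    g_fac = float(np.sum(per_row * (-2.0 * d2 / s_fac))) if s_fac != 0 else 0.0
    live = ~clamped
    mu_term = np.where(live, prepared.mean_i / radicand, 0.0)
    g_b = float(np.sum(per_row * (-d2 * mu_term)))
    g_add = float(np.sum(per_row * (-2.0 * d2 * s_add * prepared.mean_i**2 / radicand * live)))
    return np.array([g_fac, g_b, g_add])


@dataclass
class RefinementResult:
    """Outcome of the quasi-Newton error-model refinement."""

    params: ErrorModelParams
    trace: np.ndarray          # f at the start point and each accepted step
    n_steps: int
    converged: bool
    message: str
    n_clamped: int = 0


#: Coarse restart candidates: multipliers of the starting s_fac and absolute
#: s_add fractions. The binned target is nearly flat along the ridge where
#: s_fac^2*(sigma^2 + s_B*<I>) trades off against the s_add term, so a purely
#: local quasi-Newton run can park far from the best basin; a deterministic
#: coarse scan (cheap next to one line search) guards against that.
_SFAC_GRID = (0.15, 0.3, 0.5, 0.75, 1.0)
_SADD_GRID = (0.0, 0.02, 0.1, 0.3, 0.6, 1.2)
_SADD_PROBES = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0)

_BOUNDS = [(1e-12, None), (0.0, None), (0.0, None)]


def refine_error_model(
    prepared: PreparedGroups | Sequence[ReflectionGroup],
    init: ErrorModelParams,
    max_iter: int = 200,
    gtol: float = 1e-8,
    ftol: float = 1e-10,
) -> RefinementResult:
    """Refine (s_fac, s_B, s_add) by bound-constrained L-BFGS.

    All three parameters are bounded below at zero (s_B pinned at 0.00 is an
    admissible solution, matching how the term behaves in practice). Because
    s_add enters the model squared, the target gradient with respect to it
    vanishes identically at s_add = 0, which makes that plane a spurious
    stationary set; and the target is nearly degenerate along an s_fac/s_B
    ridge. Both traps are escaped deterministically: after a first L-BFGS
    run from ``init``, a coarse (s_fac, s_add) scan is evaluated and, if it
    undercuts the converged target, a second run starts from the best scan
    point; a converged s_add = 0 additionally triggers a probe along s_add.
    The reported trace is that of the winning run (start point plus every
    accepted iterate) and is non-increasing.

    Raises on a non-finite target or gradient, dumping the offending bins.
    """
    if not isinstance(prepared, PreparedGroups):
        prepared = prepare_groups(prepared)

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        p = ErrorModelParams(s_fac=max(x[0], 0.0), s_B=max(x[1], 0.0),
                             s_add=max(x[2], 0.0))
        f = target_function(p, prepared)
        g = target_gradient(p, prepared)
        if not np.isfinite(f) or not np.all(np.isfinite(g)):
            bad = np.flatnonzero(~np.isfinite(prepared.bins.rmsd))
            raise FloatingPointError(
                f"non-finite target/gradient at {p}; offending bins: {bad[:10]}"
            )
        return f, g

    def run(x0: np.ndarray) -> tuple["optimize.OptimizeResult", list[float]]:
        trace = [target_function(
            ErrorModelParams(max(x0[0], 0.0), max(x0[1], 0.0), max(x0[2], 0.0)),
            prepared,
        )]

        def callback(xk: np.ndarray) -> None:
            trace.append(objective(xk)[0])

        res = optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B", bounds=_BOUNDS,
            callback=callback,
            options={"maxiter": max_iter, "gtol": gtol, "ftol": ftol},
        )
        return res, trace

    x0 = init.as_array()
    if x0[0] == 0.0:  # zero s_fac start has no gradient scale
        x0[0] = 1e-6
    best_res, best_trace = run(x0)

    # coarse scan for a better basin than the local run found
    sfac_scale = max(init.s_fac, 1e-3)
    cand_best, cand_f = None, np.inf
    for mf in _SFAC_GRID:
        for sa in _SADD_GRID:
            x = np.array([sfac_scale * mf, 0.0, sa])
            f = target_function(ErrorModelParams(*x), prepared)
            if f < cand_f:
                cand_best, cand_f = x, f
    if cand_best is not None and cand_f < best_res.fun * (1.0 - 1e-3):
        res2, trace2 = run(cand_best)
        if res2.fun < best_res.fun:
            best_res, best_trace = res2, trace2

    # s_add stuck exactly at zero: probe along the vanishing-gradient axis
    if best_res.x[2] < 1e-10:
        probe_f = [
            target_function(
                ErrorModelParams(best_res.x[0], best_res.x[1], a), prepared
            )
            for a in _SADD_PROBES
        ]
        if min(probe_f) < best_res.fun:
            x_probe = np.array([
                best_res.x[0], best_res.x[1],
                _SADD_PROBES[int(np.argmin(probe_f))],
            ])
            res3, trace3 = run(x_probe)
            if res3.fun < best_res.fun:
                best_res, best_trace = res3, trace3

    final = ErrorModelParams(
        s_fac=max(float(best_res.x[0]), 0.0), s_B=max(float(best_res.x[1]), 0.0),
        s_add=max(float(best_res.x[2]), 0.0),
    )
    f_final = target_function(final, prepared)
    trace = list(best_trace)
    if f_final < trace[-1]:
        trace.append(f_final)
    _, _, clamped = _sigma2_ev11(prepared, final.s_fac, final.s_B, final.s_add)
    return RefinementResult(
        params=final, trace=np.asarray(trace), n_steps=int(best_res.nit),
        converged=bool(best_res.success), message=str(best_res.message),
        n_clamped=int(np.count_nonzero(clamped)),
    )


def deviations_for_plot(
    groups: Iterable[ReflectionGroup],
    params: ErrorModelParams | None = None,
) -> np.ndarray:
    """All normalized deviations from groups with n >= 2.

    With ``params`` given, the denominator is sigma_Ev11; otherwise the raw
    counting sigma (the initialization-time convention).
    """
    out = []
    for g in groups:
        if g.n < 2:
            continue
        i = np.asarray(g.intensities, dtype=float)
        n = len(i)
        loo = (i.sum() - i) / (n - 1)
        if params is None:
            denom = np.asarray(g.sigmas, dtype=float)
        else:
            denom = np.asarray(sigma_ev11(g.sigmas, g.mean, params))
        out.append(np.sqrt((n - 1) / n) * (i - loo) / denom)
    if not out:
        return np.empty(0)
    return np.concatenate(out)
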