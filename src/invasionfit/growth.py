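"""Population growth-curve fitting and trajectory classification.

Each survey site contributes a yearly abundance time series.  Three
candidate families are fitted — exponential, quadratic, and logistic —
with additive Gaussian errors on the (effort-normalized) count scale, so
their likelihoods are comparable and the small-sample Akaike criterion
(AICc) can rank them.  The best family labels the trajectory; sites whose
best fit is monotone non-increasing over the observed window are treated
as having missed the colonization dynamics and are discarded.

Carrying capacity K comes from the quadratic vertex (an upper limit where
the fitted derivative is zero) or from the logistic asymptote; the
exponential growth rate r is the OLS slope of log abundance on time, and
is reported only where the exponential family has substantial support
(ΔAICc below the support threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

FAMILIES = ("exponential", "quadratic", "logistic")

#: parameter counts including the residual sigma
K_PARAMS = {"exponential": 3, "quadratic": 4, "logistic": 4}

#: family order used to break exact AICc ties after the fewer-parameters rule
_TIE_ORDER = {"exponential": 0, "logistic": 1, "quadratic": 2}

_SIGMA2_FLOOR = 1e-12


@dataclass
class AbundanceTimeSeries:
    """One site's yearly (effort-normalized) abundance counts."""

    site_id: str
    years: np.ndarray
    counts: np.ndarray
    effort: np.ndarray | None = None

    def __post_init__(self):
        self.years = np.asarray(self.years)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.years.size != self.counts.size:
            raise ValueError("years and counts must have equal length")
        if self.years.size and not np.all(np.diff(self.years) > 0):
            raise ValueError("years must be strictly increasing")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and nonnegative")
        if self.effort is not None:
            self.effort = np.asarray(self.effort, dtype=float)

    @property
    def t(self) -> np.ndarray:
        """Time in years since the first observation (t=0 at first year)."""
        return np.asarray(self.years, dtype=float) - float(self.years[0])

    def __len__(self):
        return self.years.size


@dataclass
class GrowthModelFit:
    family: str
    params: dict
    sigma: float
    loglik: float
    n_obs: int
    k_params: int
    aicc: float
    converged: bool
    t_window: tuple = (0.0, 0.0)
    message: str = ""


@dataclass
class ModelComparison:
    fits: dict  # family -> GrowthModelFit
    delta_aicc: dict
    best_family: str | None
    label: str = "unresolved"


@dataclass
class SitePopulationParameters:
    site_id: str
    label: str
    K: float | None = None
    K_source: str | None = None
    r: float | None = None
    flags: list = field(default_factory=list)


def compute_aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion.

    AICc = -2*loglik + 2k + 2k(k+1)/(n-k-1).  Undefined (returned as +inf)
    when n <= k+1, where the correction term blows up.
    """
    if n <= k + 1:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _gaussian_loglik(sse: float, n: int) -> tuple[float, float]:
    """Profile log-likelihood with sigma at its MLE; returns (loglik, sigma)."""
    sigma2 = max(sse / n, _SIGMA2_FLOOR)
    ll = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    return ll, math.sqrt(sigma2)


def _finish(family, params, sse, n, t, converged, message=""):
    ll, sigma = _gaussian_loglik(sse, n)
    k = K_PARAMS[family]
    aicc = compute_aicc(ll, k, n) if converged else math.inf
    return GrowthModelFit(
        family=family,
        params=params,
        sigma=sigma,
        loglik=ll,
        n_obs=n,
        k_params=k,
        aicc=aicc,
        converged=converged,
        t_window=(float(t[0]), float(t[-1])),
        message=message,
    )


def _fit_exponential(t, y):
    # init from log-linear OLS; free sign of r so declines are representable
    slope, logn0 = np.polyfit(t, np.log(y + 0.5), 1)
    x0 = np.array([max(math.exp(logn0), 1e-6), float(np.clip(slope, -9.9, 9.9))])

    def resid(p):
        return p[0] * np.exp(np.clip(p[1] * t, -700, 700)) - y

    def jac(p):
        e = np.exp(np.clip(p[1] * t, -700, 700))
        return np.column_stack([e, p[0] * t * e])

    try:
        sol = least_squares(
            resid, x0, jac=jac, bounds=([1e-12, -10.0], [np.inf, 10.0]),
            xtol=1e-12, ftol=1e-12,
        )
    except Exception as exc:  # pragma: no cover - scipy failure path
        return _finish("exponential", {}, np.inf, t.size, t, False, str(exc))
    n0, r = sol.x
    params = {"N0": float(n0), "r_exp": float(r)}
    ok = sol.success and np.all(np.isfinite(sol.x))
    return _finish("exponential", params, float(np.sum(sol.fun**2)), t.size, t, ok)


def _fit_quadratic(t, y):
    a, b, c = np.polyfit(t, y, 2)
    pred = np.polyval([a, b, c], t)
    sse = float(np.sum((pred - y) ** 2))
    return _finish("quadratic", {"a": float(a), "b": float(b), "c": float(c)},
                   sse, t.size, t, True)


def logistic_curve(t, K, r, t_mid):
    z = np.clip(-r * (np.asarray(t, dtype=float) - t_mid), -700, 700)
    return K / (1.0 + np.exp(z))


def _fit_logistic(t, y):
    n = t.size
    ymax = float(np.max(y))
    if np.ptp(y) < 1e-12:
        return _finish("logistic", {}, np.inf, n, t, False, "constant counts")
    lo_K, hi_K = max(0.5 * ymax, 1e-6), 100.0 * max(ymax, 1e-6)
    bounds = ([lo_K, -5.0, t[0] - 50.0], [hi_K, 5.0, t[-1] + 50.0])
    # trend sign picks the sign of the initial growth rate
    trend = np.polyfit(t, y, 1)[0]
    r0 = 0.3 if trend >= 0 else -0.3
    span = t[-1] - t[0]
    starts = [
        np.array([kf * max(ymax, 1e-6), r0, t[0] + frac * span])
        for kf in (1.05, 2.0, 5.0)
        for frac in (0.25, 0.5, 0.75)
    ]

    def resid(p):
        return logistic_curve(t, *p) - y

    def jac(p):
        K, r, t_mid = p
        s = logistic_curve(t, 1.0, r, t_mid)
        return np.column_stack([
            s,
            K * s * (1.0 - s) * (t - t_mid),
            -K * s * (1.0 - s) * r,
        ])

    # screen the 3x3 grid of initials by their starting SSE and refine only
    # from the most promising ones; the local optimizer does the rest
    starts = [np.clip(x0, bounds[0], bounds[1]) for x0 in starts]
    starts.sort(key=lambda p: float(np.sum(resid(p) ** 2)))
    sse_stop = 1e-12 * float(np.sum(y**2))  # a start this good cannot improve
    best = None
    for x0 in starts[:3]:
        try:
            sol = least_squares(resid, x0, jac=jac, bounds=bounds,
                                xtol=1e-10, ftol=1e-10, max_nfev=200)
        except Exception:
            continue
        if not sol.success:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)
            if sse <= sse_stop:
                break
    if best is None:
        return _finish("logistic", {}, np.inf, n, t, False, "optimizer failed")
    sse, (K, r, t_mid) = best
    # a solution pinned to a parameter bound is the non-convergence pathway:
    # the logistic is a poor empirical description of the series
    at_bound = (
        K >= 0.999 * hi_K
        or K <= 1.001 * lo_K
        or abs(r) >= 4.999
        or t_mid <= bounds[0][2] + 1e-6
        or t_mid >= bounds[1][2] - 1e-6
    )
    # identifiability: the asymptote is only estimated if the series passes
    # its inflection inside the observed window; a midpoint beyond the data
    # means the window shows pure accelerating growth (or pure decline) and
    # K would be extrapolation, not estimation
    unidentified = (r > 0 and t_mid > t[-1]) or (r < 0 and t_mid < t[0])
    ok = not (at_bound or unidentified)
    msg = "" if ok else ("parameter at bound" if at_bound
                         else "inflection outside observed window")
    params = {"K_asym": float(K), "r_log": float(r), "t_mid": float(t_mid)}
    return _finish("logistic", params, sse, n, t, ok, msg)


def fit_growth_model(ts: AbundanceTimeSeries, family: str) -> GrowthModelFit:
    """Fit one candidate family to a site's series by Gaussian least squares.

    Time is measured from the site's first observation year.  Failure to
    converge is reported on the returned fit (``converged=False``, AICc
    +inf) rather than raised, since non-convergent logistic fits are an
    expected pathway for series the logistic describes poorly.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown growth family {family!r}")
    if len(ts) < 5:
        raise ValueError("need at least 5 observations to fit growth models")
    t, y = ts.t, ts.counts
    if family == "exponential":
        return _fit_exponential(t, y)
    if family == "quadratic":
        return _fit_quadratic(t, y)
    return _fit_logistic(t, y)


def fit_all_families(ts: AbundanceTimeSeries) -> list[GrowthModelFit]:
    return [fit_growth_model(ts, fam) for fam in FAMILIES]


def compare_models(fits) -> ModelComparison:
    """Rank candidate fits by AICc; ΔAICc is measured from the minimum.

    Exact ties go to the family with fewer parameters, then to a fixed
    family order, so output is deterministic.  With no converged fit the
    comparison is labeled unresolved.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    by_family = {f.family: f for f in fits}
    conv = [f for f in fits if f.converged and math.isfinite(f.aicc)]
    if not conv:
        return ModelComparison(fits=by_family, delta_aicc={}, best_family=None,
                               label="unresolved")
    amin = min(f.aicc for f in conv)
    delta = {f.family: f.aicc - amin for f in conv}
    best = min(conv, key=lambda f: (f.aicc, f.k_params, _TIE_ORDER[f.family]))
    comp = ModelComparison(fits=by_family, delta_aicc=delta, best_family=best.family)
    comp.label = classify_trajectory(comp)
    return comp


def _is_monotone_decreasing(fit: GrowthModelFit) -> bool:
    t0, t1 = fit.t_window
    if fit.family == "exponential":
        return fit.params.get("r_exp", 0.0) < 0.0
    if fit.family == "logistic":
        return fit.params.get("r_log", 0.0) < 0.0
    # quadratic: derivative 2at + b is linear, so non-increasing over the
    # window iff it is <= 0 at both endpoints
    a, b = fit.params.get("a", 0.0), fit.params.get("b", 0.0)
    return (2 * a * t0 + b) <= 0.0 and (2 * a * t1 + b) <= 0.0


def classify_trajectory(comp: ModelComparison) -> str:
    """Label a site's trajectory by its best-supported family.

    A best fit that is monotone non-increasing over the observed window
    (negative exponential, in-window-decreasing quadratic, or negative
    logistic) is labeled ``decreasing``: the series began after the local
    population had already peaked, so the colonization dynamics were missed.
    """
    if comp.best_family is None:
        return "unresolved"
    best = comp.fits[comp.best_family]
    if _is_monotone_decreasing(best):
        return "decreasing"
    return comp.best_family


def extract_carrying_capacity(comp: ModelComparison, delta_threshold: float = 2.0):
    """Carrying capacity K from the best-supported saturating fit.

    Quadratic label: K is the vertex maximum c - b^2/(4a) (requires a<0);
    a vertex time outside the observed window is flagged, not rejected.
    Logistic label: K is the asymptote parameter.  An exponential-labeled
    site still yields a K when a quadratic or logistic alternative has
    ΔAICc below ``delta_threshold`` — from whichever of the two is better
    supported.

    Returns ``(K, K_source, flags)``; K is None when no valid source exists.
    """
    flags: list[str] = []
    label = comp.label
    source_family = None
    if label in ("quadratic", "logistic"):
        source_family = label
    elif label == "exponential":
        cands = [
            (comp.delta_aicc[f], f)
            for f in ("quadratic", "logistic")
            if f in comp.delta_aicc and comp.delta_aicc[f] < delta_threshold
        ]
        if cands:
            source_family = min(cands)[1]
    if source_family is None:
        return None, None, flags

    fit = comp.fits[source_family]
    if source_family == "logistic":
        K = fit.params["K_asym"]
        if K <= 0:
            flags.append("logistic_nonconvergent")
            return None, None, flags
        return float(K), "logistic_asymptote", flags

    a, b, c = fit.params["a"], fit.params["b"], fit.params["c"]
    if a >= 0:
        flags.append("no_interior_maximum")
        return None, None, flags
    t_vertex = -b / (2 * a)
    K = c - b * b / (4 * a)
    t0, t1 = fit.t_window
    if not (t0 <= t_vertex <= t1):
        flags.append("vertex_outside_window")
    if K <= 0:
        flags.append("nonpositive_vertex")
        return None, None, flags
    return float(K), "quadratic_vertex", flags


def extract_growth_rate(
    ts: AbundanceTimeSeries,
    comp: ModelComparison,
    delta_threshold: float = 2.0,
    log_offset: float = 0.5,
):
    """Exponential growth rate r where the exponential model has support.

    r is the OLS slope of log abundance on year, computed only when the
    exponential family's ΔAICc is strictly below ``delta_threshold``.
    Leading years before the first positive count are dropped
    (pre-detection zeros carry no growth signal); the small additive
    offset is applied only when interior zeros remain, so strictly
    positive series give the exact log-linear slope.  Returns
    ``(r, flags)``.
    """
    flags: list[str] = []
    d = comp.delta_aicc.get("exponential")
    if d is None or not (d < delta_threshold):
        return None, flags
    y = ts.counts
    nz = np.nonzero(y > 0)[0]
    if nz.size == 0:
        flags.append("all_zero_counts")
        return None, flags
    years = np.asarray(ts.years, dtype=float)[nz[0]:]
    counts = y[nz[0]:]
    if years.size < 3:
        flags.append("too_few_points_for_r")
        return None, flags
    offset = log_offset if np.any(counts == 0) else 0.0
    slope = np.polyfit(years, np.log(counts + offset), 1)[0]
    return float(slope), flags


@dataclass
class FilterResult:
    eligible: list
    exclusions: dict  # site_id -> reason
    counts: dict


def filter_sites(series_list, comparisons=None, min_years: int = 8) -> FilterResult:
    """Apply the eligibility filters, recording one exclusion reason per site.

    Sites with fewer than ``min_years`` observations are excluded first
    (too_few_years); among the rest, sites whose comparison label is
    ``decreasing`` are excluded (discarded_decreasing) and unresolved sites
    are excluded (nonconvergent).  Reasons are mutually exclusive.
    """
    comparisons = comparisons or {}
    eligible, exclusions = [], {}
    for ts in series_list:
        if len(ts) < min_years:
            exclusions[ts.site_id] = "too_few_years"
            continue
        comp = comparisons.get(ts.site_id)
        if comp is not None:
            if comp.label == "decreasing":
                exclusions[ts.site_id] = "discarded_decreasing"
                continue
            if comp.label == "unresolved":
                exclusions[ts.site_id] = "nonconvergent"
                continue
        eligible.append(ts.site_id)
    counts = {"eligible": len(eligible)}
    for reason in ("too_few_years", "discarded_decreasing", "nonconvergent"):
        counts[reason] = sum(1 for v in exclusions.values() if v == reason)
    return FilterResult(eligible=eligible, exclusions=exclusions, counts=counts)


def analyze_site(ts: AbundanceTimeSeries, delta_threshold: float = 2.0):
    """Fit all families, compare, classify, and extract K and r for one site.

    Returns ``(comparison, SitePopulationParameters)``.
    """
    comp = compare_models(fit_all_families(ts))
    params = SitePopulationParameters(site_id=ts.site_id, label=comp.label)
    if comp.label in ("exponential", "quadratic", "logistic"):
        K, src, kflags = extract_carrying_capacity(comp, delta_threshold)
        r, rflags = extract_growth_rate(ts, comp, delta_threshold)
        params.K, params.K_source, params.r = K, src, r
        params.flags = kflags + rflags
    return comp, params
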