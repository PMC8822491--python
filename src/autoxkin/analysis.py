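"""Inference of inhibition kinetics from oxygen-uptake traces.

The analysis mirrors the classical induction-period method.  A
chain-breaking antioxidant suppresses the uptake rate until it (and its
trapping-competent products) is exhausted; the trace then breaks to the
uninhibited rate.  From a trace one extracts:

* the induction time ``tau`` (two-segment continuous piecewise-linear fit);
* the inhibited and post-induction rates ``R_inh`` and ``R_ox2`` (window
  regressions);
* the initiation flux ``R_i = n_ref [ArOH]_0 / tau_ref`` from a reference
  antioxidant of known stoichiometry (tocopherol-like, n = 2);
* the stoichiometric factor ``n = R_i tau / [ArOH]_0``;
* the inhibition rate constant ``k_inh`` by inverting the integrated
  inhibited-rate law  Delta[O2] = -(k_p [LH]/k_inh) ln(1 - t/tau);
* the kinetic chain length ``nu_inh = R_inh / R_i``; and, for equimolar
  mixtures, the co-antioxidant stoichiometry
  ``n_co = R_i (tau_mix - tau_ref) / [co]``.

:class:`InhibitionModel` wraps the pipeline for a single trace in a
model/fit/results idiom; :func:`analyze_experiment` orchestrates a whole
set of paired traces into a results table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .errors import (AutoxkinWarning, FitFailureError, InsufficientDataError,
                     MissingReferenceError, NoBreakpointError)
from .params import MEDIUM_KP
from .trace import Trace

__all__ = [
    "BreakpointFit", "piecewise_linear_fit", "estimate_tau",
    "estimate_phase_rates", "compute_Ri", "compute_n", "estimate_kinh",
    "correct_kinh", "compute_nu", "synergy_n", "classify",
    "InhibitionMetrics", "SynergyMetrics", "InhibitionModel",
    "InhibitionResults", "ExperimentAnalysis", "analyze_experiment",
]


# ---------------------------------------------------------------------------
# two-segment continuous piecewise-linear breakpoint fit
# ---------------------------------------------------------------------------

@dataclass
class BreakpointFit:
    """Best two-segment continuous piecewise-linear fit of (t, y)."""

    index: int                 # grid index of the breakpoint
    tau: float                 # breakpoint abscissa (same origin as t)
    intercept: float
    slope1: float              # induction-phase slope
    slope2: float              # post-induction slope
    sse1: float                # one-segment residual sum of squares
    sse2: float                # two-segment residual sum of squares
    fstat: float
    pvalue: float
    found: bool                # breakpoint significant and accelerating
    t: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def fitted(self) -> np.ndarray:
        r = np.maximum(self.t - self.tau, 0.0)
        return self.intercept + self.slope1 * self.t + \
            (self.slope2 - self.slope1) * r

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.fitted


def _scan_sse(tn: np.ndarray, yn: np.ndarray,
              cand: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SSE of the continuous two-segment fit for every candidate index.

    Normal equations assembled from suffix cumulative sums; O(n) overall.
    Returns (sse, coefs) with coefs[:, 2] the slope-change term.
    """
    n = tn.size
    yy = float(yn @ yn)
    st, st2 = tn.sum(), float(tn @ tn)
    sy, sty = yn.sum(), float(tn @ yn)

    # suffix sums over i > k
    def suffix(a):
        c = np.cumsum(a[::-1])[::-1]
        return np.concatenate([c[1:], [0.0]])

    Ns = suffix(np.ones(n))[cand]
    T1 = suffix(tn)[cand]
    T2 = suffix(tn * tn)[cand]
    Y1 = suffix(yn)[cand]
    TY = suffix(tn * yn)[cand]
    tc = tn[cand]

    Sr = T1 - tc * Ns
    Sr2 = T2 - 2.0 * tc * T1 + tc * tc * Ns
    Str = T2 - tc * T1
    Syr = TY - tc * Y1

    m = cand.size
    M = np.empty((m, 3, 3))
    M[:, 0, 0] = n
    M[:, 0, 1] = M[:, 1, 0] = st
    M[:, 0, 2] = M[:, 2, 0] = Sr
    M[:, 1, 1] = st2
    M[:, 1, 2] = M[:, 2, 1] = Str
    M[:, 2, 2] = Sr2
    v = np.stack([np.full(m, sy), np.full(m, sty), Syr], axis=1)
    # tiny ridge keeps near-singular candidates finite without moving minima
    M[:, [0, 1, 2], [0, 1, 2]] += 1.0e-12 * n
    coefs = np.linalg.solve(M, v[..., None])[..., 0]
    sse = yy - np.einsum("ij,ij->i", coefs, v)
    return np.maximum(sse, 0.0), coefs


def piecewise_linear_fit(t: np.ndarray, y: np.ndarray,
                         alpha: float = 1.0e-4,
                         candidates: np.ndarray | None = None) -> BreakpointFit:
    """Exhaustive breakpoint search on the sampling grid.

    Fits ``y = a + b1 t + (b2 - b1) max(t - t_k, 0)`` by least squares for
    every candidate grid point ``t_k`` and keeps the minimum-SSE candidate.
    The breakpoint is accepted (``found``) when the two-segment model beats
    the single straight line by an F-test at level ``alpha`` (2 extra
    parameters) and the post-break slope exceeds the induction slope.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = t.size
    if n < 7:
        raise InsufficientDataError(f"need >= 7 points, got {n}")
    tspan = t[-1] - t[0]
    yscale = max(float(np.max(np.abs(y))), 1.0e-300)
    tn = (t - t[0]) / tspan
    yn = y / yscale

    if candidates is None:
        cand = np.arange(2, n - 2)
    else:
        cand = np.asarray(candidates, dtype=int)
        cand = cand[(cand >= 2) & (cand <= n - 3)]
        if cand.size == 0:
            raise InsufficientDataError("no admissible breakpoint candidates")

    sse, coefs = _scan_sse(tn, yn, cand)
    # the induction period ends with an *acceleration* of the uptake, so
    # only slope-increasing candidates compete for the breakpoint
    accel = coefs[:, 2] > 0.0
    if np.any(accel):
        masked = np.where(accel, sse, np.inf)
        best = int(np.argmin(masked))
    else:
        best = int(np.argmin(sse))
    k = int(cand[best])
    a, b1, b2 = coefs[best]

    # one-segment reference fit
    X1 = np.stack([np.ones(n), tn], axis=1)
    c1, res1, *_ = np.linalg.lstsq(X1, yn, rcond=None)
    sse1 = float(res1[0]) if res1.size else float(np.sum((yn - X1 @ c1) ** 2))
    sse2 = float(sse[best])

    tiny = 1.0e-24 * n
    dof2 = n - 4
    num = max(sse1 - sse2, 0.0) / 2.0
    den = max(sse2, tiny) / dof2
    fstat = num / den if den > 0 else np.inf
    pvalue = float(f_dist.sf(fstat, 2, dof2)) if np.isfinite(fstat) else 0.0
    found = bool(sse1 > tiny and b2 > 0.0 and pvalue < alpha)

    sc = yscale / tspan
    return BreakpointFit(
        index=k, tau=float(t[k]),
        intercept=float(a * yscale - (b1 * sc) * t[0]),
        slope1=float(b1 * sc), slope2=float((b1 + b2) * sc),
        sse1=sse1 * yscale ** 2, sse2=sse2 * yscale ** 2,
        fstat=float(fstat), pvalue=pvalue, found=found, t=t, y=y)


def _tangent_refine(t: np.ndarray, y: np.ndarray, tau0: float,
                    inh_window: tuple[float, float] = (0.15, 0.85),
                    post_window: tuple[float, float] = (1.1, 2.0),
                    n_iter: int = 3) -> float:
    """Refine a breakpoint by the graphical tangent-intersection rule.

    Intersects the induction-phase regression line (over
    ``[0.15 tau, 0.85 tau]``) with the post-induction line (over
    ``[1.1 tau, 2 tau]``), iterating a few times.  Both windows are local,
    which makes the refined tau insensitive to how long the record runs
    past the induction period.  Falls back to ``tau0`` if a window
    degenerates or the post slope does not exceed the induction slope.
    """
    tau = tau0
    for _ in range(n_iter):
        m1 = (t >= inh_window[0] * tau) & (t <= inh_window[1] * tau)
        m2 = (t >= post_window[0] * tau) & (t <= post_window[1] * tau)
        if int(m1.sum()) < 3 or int(m2.sum()) < 3:
            return tau
        s1, a1 = np.polyfit(t[m1], y[m1], 1)
        s2, a2 = np.polyfit(t[m2], y[m2], 1)
        if s2 <= s1:
            return tau
        new = (a1 - a2) / (s2 - s1)
        if not (t[0] < new < t[-1]):
            return tau
        if abs(new - tau) < 1.0e-9 * max(tau, 1.0):
            return new
        tau = new
    return tau


def estimate_tau(trace: Trace, n_boot: int = 200, seed: int = 0,
                 alpha: float = 1.0e-4, min_points: int = 20,
                 refine: bool = True) -> tuple[float, float]:
    """Induction time and its bootstrap SD from an uptake trace.

    A two-segment continuous piecewise-linear model (exhaustive breakpoint
    search, F-test against a single line) detects the induction period;
    the breakpoint is then polished by the classical graphical rule --
    intersection of the induction-rate and post-induction-rate tangents --
    which keeps ``tau`` independent of how far the record extends beyond
    the break (``refine=False`` reports the raw piecewise breakpoint).
    ``tau`` is measured from the antioxidant injection.  ``tau_sd`` comes
    from ``n_boot`` residual-resampling replicates refitted over a window
    of candidates around the original breakpoint (NaN when ``n_boot`` =
    0).

    Raises
    ------
    NoBreakpointError
        If the two-segment model is not significantly better than a single
        straight line (the trace shows retardation or no inhibition).
    InsufficientDataError
        Fewer than ``min_points`` samples after the injection.
    """
    t, y = trace.post_injection()
    if t.size < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} points after injection, got {t.size}")
    fit = piecewise_linear_fit(t, y, alpha=alpha)
    if not fit.found:
        raise NoBreakpointError(
            f"no induction-period breakpoint (F = {fit.fstat:.3g}, "
            f"p = {fit.pvalue:.3g})")
    tau = _tangent_refine(t, y, fit.tau) if refine else fit.tau
    if n_boot <= 0:
        return tau, float("nan")

    rng = np.random.default_rng(seed)
    resid = fit.residuals
    yhat = fit.fitted
    half = max(10, int(round(0.2 * fit.index)))
    cand = np.arange(max(2, fit.index - half),
                     min(t.size - 2, fit.index + half + 1))
    taus = np.empty(n_boot)
    for b in range(n_boot):
        yb = yhat + rng.choice(resid, size=resid.size, replace=True)
        fb = piecewise_linear_fit(t, yb, alpha=alpha, candidates=cand)
        taus[b] = _tangent_refine(t, yb, fb.tau) if refine else fb.tau
    return tau, float(np.std(taus, ddof=1))


# ---------------------------------------------------------------------------
# phase rates and the algebraic inference chain
# ---------------------------------------------------------------------------

def _window_slope(t: np.ndarray, y: np.ndarray, lo: float, hi: float,
                  min_pts: int = 5) -> float:
    mask = (t >= lo) & (t <= hi)
    if int(mask.sum()) < min_pts:
        raise InsufficientDataError(
            f"rate window [{lo:g}, {hi:g}] s has {int(mask.sum())} points "
            f"(need >= {min_pts})")
    return float(np.polyfit(t[mask], y[mask], 1)[0])


def estimate_phase_rates(trace: Trace, tau: float | None,
                         inh_window: tuple[float, float] = (0.15, 0.85),
                         post_start: float = 1.1) -> tuple[float, float]:
    """Inhibited-phase and post-induction uptake rates (M/s).

    ``R_inh`` is the least-squares slope over ``[0.15 tau, 0.85 tau]``
    after injection (the whole post-injection record when ``tau`` is None,
    i.e. for retarded traces, where it is a rate of retardation), and
    ``R_ox2`` the slope over ``[1.1 tau, end]`` (NaN without a breakpoint).
    """
    t, y = trace.post_injection()
    if tau is None:
        return _window_slope(t, y, t[0], t[-1]), float("nan")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    r_inh = _window_slope(t, y, inh_window[0] * tau, inh_window[1] * tau)
    r_ox2 = _window_slope(t, y, post_start * tau, t[-1])
    return r_inh, r_ox2


def compute_Ri(tau_ref: float, n_ref: float, conc_ref: float) -> float:
    """Initiation flux from a reference antioxidant of known stoichiometry:
    ``R_i = n_ref [ArOH]_0 / tau_ref`` (the induction-period relation
    solved for R_i).  The tocopherol analogue PMHC with n = 2 is the
    conventional reference."""
    if tau_ref <= 0:
        raise ZeroDivisionError("tau_ref must be > 0")
    if n_ref <= 0 or conc_ref <= 0:
        raise ValueError("n_ref and conc_ref must be > 0")
    return n_ref * conc_ref / tau_ref


def compute_n(tau: float, R_i: float, conc: float) -> float:
    """Stoichiometric factor ``n = R_i tau / [ArOH]_0``: peroxyl radicals
    trapped per antioxidant molecule."""
    if conc <= 0:
        raise ZeroDivisionError("conc must be > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return R_i * tau / conc


def estimate_kinh(trace: Trace, tau: float, k_p: float, LH: float,
                  window: tuple[float, float] = (0.15, 0.85),
                  min_pts: int = 5, refine_tau: bool = True) -> float:
    """Inhibition rate constant by inverting the integrated rate law.

    Regresses the measured uptake against ``-ln(1 - t/tau)`` through the
    origin over ``[0.15 tau, 0.85 tau]`` after injection; the slope equals
    ``k_p [LH] / k_inh``.

    The graphical breakpoint systematically undershoots the exhaustion
    time on soft knees, which propagates into k_inh; with ``refine_tau``
    (default) the exhaustion time entering the rate law is re-fitted
    within the window by minimizing the residual of the integrated-law
    regression itself, and is adopted only where it clearly improves the
    fit.  The fit window remains anchored at the supplied ``tau``.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t, y = trace.post_injection()
    mask = (t >= window[0] * tau) & (t <= window[1] * tau) & (t < tau)
    if int(mask.sum()) < min_pts:
        raise InsufficientDataError(
            f"k_inh window has {int(mask.sum())} points (need >= {min_pts})")
    tw, yw = t[mask], y[mask]

    def fit(tau_trial: float) -> tuple[float, float]:
        x = -np.log1p(-tw / tau_trial)
        slope = float(x @ yw) / float(x @ x)
        return slope, float(np.sum((yw - slope * x) ** 2))

    slope, sse0 = fit(tau)
    if refine_tau and sse0 > 1e-20 * float(yw @ yw) * yw.size:
        from scipy.optimize import minimize_scalar
        lo = max(1.0001 * tw[-1], 0.7 * tau)
        hi = 1.6 * tau
        res = minimize_scalar(lambda s: fit(s)[1], bounds=(lo, hi),
                              method="bounded")
        if res.success:
            slope_r, sse_r = fit(float(res.x))
            # adopt only a decisive improvement: the integrated law is
            # exact for a single-phenol induction, so the refit residual
            # collapses there; a modest gain means model mismatch (e.g. a
            # dimer cascade), where the supplied tau is the safer anchor
            if sse_r < 0.05 * sse0:
                slope = slope_r
    if slope <= 0:
        raise FitFailureError("non-positive slope in k_inh regression")
    return k_p * LH / slope


def correct_kinh(k_inh: float, n: float) -> float:
    """Capacity-corrected inhibition rate constant ``k_inh n / 2``.

    The integrated rate law assumes a two-radical trap; for antioxidants
    with n > 2 it yields a minimal, apparent k_inh which is rescaled by
    n/2.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    return k_inh * n / 2.0


def compute_nu(R_inh: float, R_i: float) -> float:
    """Kinetic chain length during inhibition, ``nu_inh = R_inh / R_i``."""
    if R_i <= 0:
        raise ZeroDivisionError("R_i must be > 0")
    return R_inh / R_i


def synergy_n(tau_mix: float, tau_ref: float, R_i: float,
              conc_co: float) -> float:
    """Co-antioxidant stoichiometric factor in a binary mixture:
    ``n_co = R_i (tau_mix - tau_ref) / [co]``, the extra induction time of
    the mixture over the reference alone expressed as radicals trapped per
    co-antioxidant molecule."""
    if conc_co <= 0:
        raise ZeroDivisionError("conc_co must be > 0")
    if tau_mix < tau_ref:
        warnings.warn(
            "tau_mix < tau_ref: negative co-antioxidant stoichiometry",
            AutoxkinWarning, stacklevel=2)
    return R_i * (tau_mix - tau_ref) / conc_co


def classify(slowdown: float, breakpoint_found: bool,
             inhibition_threshold: float = 3.0,
             retardation_threshold: float = 1.3) -> str:
    """Classify antioxidant behaviour from the slow-down factor.

    ``"inhibition"`` requires a detected breakpoint and a slow-down
    R_ox/R_inh of at least ``inhibition_threshold``; a slow-down of at
    least ``retardation_threshold`` without a qualifying breakpoint is
    ``"retardation"``; anything else is ``"none"``.  The thresholds are
    operational conventions and are configurable.
    """
    if not np.isfinite(slowdown):
        raise MissingReferenceError(
            "slow-down factor unavailable (missing uninhibited reference)")
    if breakpoint_found and slowdown >= inhibition_threshold:
        return "inhibition"
    if slowdown >= retardation_threshold:
        return "retardation"
    return "none"


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class InhibitionMetrics:
    """Per-run derived quantities (one row of a results table)."""

    tau: float = float("nan")            # s, from injection
    tau_sd: float = float("nan")         # s, bootstrap
    n: float = float("nan")              # stoichiometric factor
    R_inh: float = float("nan")          # M/s
    R_ox: float = float("nan")           # M/s, matched uninhibited rate
    R_ox2: float = float("nan")          # M/s, post-induction rate
    slowdown: float = float("nan")       # R_ox / R_inh
    k_inh: float = float("nan")          # M^-1 s^-1 (apparent)
    k_inh_corrected: float = float("nan")  # n/2-scaled
    nu_inh: float = float("nan")         # R_inh / R_i
    classification: str | None = None
    breakpoint_found: bool = False


@dataclass
class SynergyMetrics:
    """Mixture-vs-individual induction comparison."""

    tau_mix: float                       # s
    tau_ref: float                       # s, reference antioxidant alone
    tau_sum: float = float("nan")        # s, tau_ref + tau_co
    hyper_ratio: float = float("nan")    # tau_mix / tau_sum
    n_co: float = float("nan")           # co-antioxidant stoichiometry
    complete: bool = False               # both single references available


class InhibitionModel:
    """Induction-period analysis of one inhibited oxygen-uptake trace.

    Parameters
    ----------
    trace : Trace
        The inhibited uptake record.
    uninhibited : Trace, optional
        Matched uninhibited record at the same medium/pH, used for the
        slow-down factor and classification.
    conc : float, optional
        Total antioxidant concentration (M).  Taken from the trace
        metadata roster when omitted.
    k_p, LH : float, optional
        Propagation rate constant and lipid concentration for the k_inh
        inversion.  Defaulted from the trace metadata (medium) when
        omitted.
    R_i : float, optional
        Initiation flux (M/s).  When given, the stoichiometric factor and
        kinetic chain length are computed; it is usually calibrated from a
        reference run via :func:`compute_Ri`.

    Examples
    --------
    >>> res = InhibitionModel(trace, uninhibited=blank, R_i=4.6e-9).fit()
    >>> res.tau, res.n, res.classification   # doctest: +SKIP
    """

    def __init__(self, trace: Trace, uninhibited: Trace | None = None,
                 conc: float | None = None, k_p: float | None = None,
                 LH: float | None = None, R_i: float | None = None,
                 alpha: float = 1.0e-4,
                 inh_window: tuple[float, float] = (0.15, 0.85),
                 post_start: float = 1.1,
                 thresholds: tuple[float, float] = (3.0, 1.3)):
        self.trace = trace
        self.uninhibited = uninhibited
        roster = trace.compounds()
        self.compounds = roster
        self.is_mixture = len(roster) > 1
        if conc is None and len(roster) == 1:
            conc = next(iter(roster.values()))
        self.conc = conc
        medium = trace.metadata.get("medium")
        if k_p is None:
            k_p = float(trace.metadata.get("k_p",
                                           MEDIUM_KP.get(medium, np.nan)))
        if LH is None:
            LH = float(trace.metadata.get("LH0", np.nan))
        self.k_p = k_p
        self.LH = LH
        self.R_i = R_i
        self.alpha = alpha
        self.inh_window = inh_window
        self.post_start = post_start
        self.thresholds = thresholds

    def fit(self, n_boot: int = 200, seed: int = 0) -> "InhibitionResults":
        m = InhibitionMetrics()
        tau: float | None = None
        try:
            tau, m.tau_sd = estimate_tau(self.trace, n_boot=n_boot,
                                         seed=seed, alpha=self.alpha)
            m.tau = tau
            m.breakpoint_found = True
        except NoBreakpointError:
            m.breakpoint_found = False

        m.R_inh, m.R_ox2 = estimate_phase_rates(
            self.trace, tau, inh_window=self.inh_window,
            post_start=self.post_start)

        if self.uninhibited is not None:
            t, y = self.uninhibited.post_injection()
            m.R_ox = _window_slope(t, y, t[0], t[-1])
            m.slowdown = m.R_ox / m.R_inh if m.R_inh > 0 else float("inf")
            m.classification = classify(m.slowdown, m.breakpoint_found,
                                        *self.thresholds)

        if self.R_i is not None:
            if m.breakpoint_found and self.conc:
                m.n = compute_n(m.tau, self.R_i, self.conc)
            m.nu_inh = compute_nu(m.R_inh, self.R_i)

        # k_inh is meaningful only for genuine inhibition: a faint
        # breakpoint on a retarded trace does not probe the rate law
        qualifies = (m.classification == "inhibition"
                     if m.classification is not None else m.breakpoint_found)
        if (m.breakpoint_found and qualifies and not self.is_mixture
                and self.conc and np.isfinite(self.k_p)
                and np.isfinite(self.LH)):
            try:
                m.k_inh = estimate_kinh(self.trace, m.tau, self.k_p, self.LH)
                if np.isfinite(m.n) and m.n > 0:
                    m.k_inh_corrected = correct_kinh(m.k_inh, m.n)
            except (FitFailureError, InsufficientDataError) as exc:
                warnings.warn(f"k_inh estimation failed: {exc}",
                              AutoxkinWarning, stacklevel=2)
        return InhibitionResults(model=self, metrics=m)


@dataclass
class InhibitionResults:
    """Fitted induction-period quantities for one trace."""

    model: InhibitionModel
    metrics: InhibitionMetrics

    def __getattr__(self, name):
        try:
            return getattr(self.__dict__["metrics"], name)
        except (KeyError, AttributeError):
            raise AttributeError(name) from None

    def summary(self) -> str:
        m = self.metrics
        roster = ", ".join(f"{k} {v * 1e6:g} uM"
                           for k, v in self.model.compounds.items()) or "none"
        lines = [
            "Inhibited autoxidation analysis",
            "=" * 46,
            f"antioxidants:        {roster}",
            f"medium/pH:           "
            f"{self.model.trace.metadata.get('medium', '?')} / "
            f"{self.model.trace.metadata.get('pH', '?')}",
            f"classification:      {m.classification}",
            f"tau (min):           "
            + (f"{m.tau / 60:.2f} +/- {m.tau_sd / 60:.2f}"
               if m.breakpoint_found else "no induction period"),
            f"n:                   {m.n:.2f}" if np.isfinite(m.n) else
            "n:                   -",
            f"R_inh (nM/s):        {m.R_inh * 1e9:.1f}",
            f"R_ox (nM/s):         {m.R_ox * 1e9:.1f}"
            if np.isfinite(m.R_ox) else "R_ox (nM/s):         -",
            f"R_ox/R_inh:          {m.slowdown:.1f}"
            if np.isfinite(m.slowdown) else "R_ox/R_inh:          -",
            f"k_inh (M^-1 s^-1):   {m.k_inh:.3g}"
            if np.isfinite(m.k_inh) else "k_inh (M^-1 s^-1):   -",
            f"nu_inh:              {m.nu_inh:.1f}"
            if np.isfinite(m.nu_inh) else "nu_inh:              -",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# experiment-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentAnalysis:
    """Tables produced by :func:`analyze_experiment`."""

    metrics: pd.DataFrame
    synergy: pd.DataFrame
    results: dict = field(default_factory=dict, repr=False)


def _group_key(trace: Trace):
    return (str(trace.metadata.get("medium", "?")),
            float(trace.metadata.get("pH", np.nan)))


def analyze_experiment(traces: list[Trace], reference: str = "PMHC",
                       n_ref: float = 2.0, n_boot: int = 200, seed: int = 0,
                       thresholds: tuple[float, float] = (3.0, 1.3),
                       alpha: float = 1.0e-4) -> ExperimentAnalysis:
    """Run the full induction-period pipeline over a set of traces.

    Traces are grouped by (medium, pH label).  Within each group the
    uninhibited trace supplies R_ox, the ``reference`` antioxidant run
    (known stoichiometry ``n_ref``) calibrates R_i, every inhibited trace
    yields one metrics row, and mixture traces additionally yield synergy
    metrics against the reference and, when available, the co-antioxidant
    run alone.

    Returns an :class:`ExperimentAnalysis` with ``metrics`` (one row per
    trace) and ``synergy`` (one row per mixture) DataFrames.
    """
    groups: dict = {}
    for tr in traces:
        groups.setdefault(_group_key(tr), []).append(tr)

    rows, syn_rows = [], []
    results: dict = {}
    idx = 0
    for key in sorted(groups, key=lambda k: (k[0], k[1])):
        medium, ph = key
        members = groups[key]
        blank = next((t for t in members if not t.compounds()), None)
        singles = {next(iter(t.compounds())): t for t in members
                   if len(t.compounds()) == 1}
        mixtures = [t for t in members if len(t.compounds()) > 1]

        # R_i calibration from the reference antioxidant at this condition
        R_i = None
        tau_ref = None
        if reference in singles:
            try:
                tau_ref, _ = estimate_tau(singles[reference], n_boot=0,
                                          alpha=alpha)
                conc_ref = next(iter(singles[reference].compounds().values()))
                R_i = compute_Ri(tau_ref, n_ref, conc_ref)
            except (NoBreakpointError, InsufficientDataError) as exc:
                warnings.warn(
                    f"R_i unavailable at {medium}/pH {ph}: {exc}",
                    AutoxkinWarning, stacklevel=2)
        else:
            warnings.warn(
                f"R_i unavailable at {medium}/pH {ph}: no {reference!r} run",
                AutoxkinWarning, stacklevel=2)

        for tr in members:
            roster = tr.compounds()
            label = "+".join(roster) if roster else "none"
            base = {"medium": medium, "pH": ph, "compounds": label}
            if not roster:
                t, y = tr.post_injection()
                r_ox = _window_slope(t, y, t[0], t[-1])
                rows.append({**base, "classification": "uninhibited",
                             "R_ox_nM_s": r_ox * 1e9})
                continue
            model = InhibitionModel(tr, uninhibited=blank, R_i=R_i,
                                    thresholds=thresholds, alpha=alpha)
            res = model.fit(n_boot=n_boot, seed=seed + idx)
            idx += 1
            results[(medium, ph, label)] = res
            m = res.metrics
            rows.append({
                **base,
                "classification": m.classification,
                "tau_min": m.tau / 60.0 if m.breakpoint_found else np.nan,
                "tau_sd_min": m.tau_sd / 60.0 if m.breakpoint_found else np.nan,
                "n": m.n,
                "R_inh_nM_s": m.R_inh * 1e9,
                "R_ox_nM_s": m.R_ox * 1e9,
                "slowdown": m.slowdown,
                "k_inh_M_s": m.k_inh,
                "k_inh_corrected_M_s": m.k_inh_corrected,
                "nu_inh": m.nu_inh,
            })

            if len(roster) > 1:
                syn = _synergy_row(tr, m, roster, reference, tau_ref, R_i,
                                   singles, alpha)
                if syn is not None:
                    syn_rows.append({**base, **syn})

    metrics = pd.DataFrame(rows)
    synergy = pd.DataFrame(syn_rows)
    return ExperimentAnalysis(metrics=metrics, synergy=synergy,
                              results=results)


def _synergy_row(trace, m: InhibitionMetrics, roster: dict, reference: str,
                 tau_ref, R_i, singles: dict, alpha: float):
    if not m.breakpoint_found:
        return {"tau_mix_min": np.nan, "tau_sum_min": np.nan,
                "hyper_ratio": np.nan, "n_co": np.nan, "complete": False,
                "note": "no breakpoint in mixture trace"}
    if reference not in roster or tau_ref is None or R_i is None:
        return {"tau_mix_min": m.tau / 60.0, "tau_sum_min": np.nan,
                "hyper_ratio": np.nan, "n_co": np.nan, "complete": False,
                "note": "missing reference run"}
    co_names = [c for c in roster if c != reference]
    co = co_names[0]
    n_co = synergy_n(m.tau, tau_ref, R_i, roster[co])
    tau_sum = np.nan
    complete = False
    note = ""
    if co in singles:
        try:
            tau_co, _ = estimate_tau(singles[co], n_boot=0, alpha=alpha)
            tau_sum = tau_ref + tau_co
            complete = True
        except NoBreakpointError:
            note = f"no breakpoint in {co} run"
    else:
        note = f"missing {co} run"
    return {"tau_mix_min": m.tau / 60.0,
            "tau_sum_min": tau_sum / 60.0 if complete else np.nan,
            "hyper_ratio": m.tau / tau_sum if complete else np.nan,
            "n_co": n_co, "complete": complete, "note": note}
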