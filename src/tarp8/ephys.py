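"""Kinetic analysis of fast-agonist-application AMPAR current sweeps.

The protocol analysed here is a 5-s glutamate application: the current
rises rapidly to a peak, desensitizes with a biexponential time course over
the first 200 ms, settles to a steady-state plateau and — for receptors
carrying a resensitizing auxiliary subunit — slowly regrows over seconds.
The summary statistics are::

    steady_state_pct    = I(200 ms) / I_peak x 100
    resensitization_pct = (I(5 s) - I(200 ms)) / I_peak x 100
    tau_w               = (a1*tau1 + a2*tau2) / (a1 + a2)

with I(200 ms) read 200 ms after the peak, I(5 s) at the end of the
application, and (a1, tau1, a2, tau2) from a constrained two-exponential
fit of the first 200 ms after the peak.  Currents are inward (negative);
all amplitudes are reported as magnitudes.  I(200 ms) and I(5 s) are 5-ms
window means by default (a 0-length window gives an interpolated point
read).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import optimize, stats

from .errors import AnalysisError, DegeneratePeakError
from .mol_io import SweepTrace

__all__ = [
    "KineticsResult",
    "DesensFit",
    "StabilityResult",
    "PairedMeasurement",
    "ComparisonReport",
    "baseline_subtract",
    "measure_peak",
    "rise_time",
    "fit_desensitization",
    "steady_state_pct",
    "resensitization_pct",
    "stability_filter",
    "paired_compare",
    "analyze_sweep",
    "wilcoxon_signed_rank",
]

BASELINE_WINDOW_S = 0.050
PEAK_SEARCH_S = 0.100
DESENS_WINDOW_S = 0.200
READ_WINDOW_S = 0.005
MIN_APPLICATION_S = 5.0

_TAU_LO_MS, _TAU_HI_MS = 0.1, 1000.0


@dataclass
class KineticsResult:
    """Per-sweep kinetic summary (amplitudes pA, taus ms, t_peak s from onset)."""

    i_peak: float
    t_peak: float
    i_200ms: float
    i_5s: float
    a1: float
    a2: float
    tau1: float
    tau2: float
    tau_w: float
    steady_state_pct: float
    resensitization_pct: float
    rise_10_90: float
    fit_ok: bool


@dataclass
class DesensFit:
    """Constrained biexponential fit of desensitization entry."""

    a1: float
    tau1: float
    a2: float
    tau2: float
    c: float
    tau_w: float
    fit_ok: bool
    resid_rms: float


@dataclass
class StabilityResult:
    """Outcome of the consecutive-sweep peak-stability screen."""

    accepted: bool
    start: int | None  # first sweep index of the qualifying run
    stop: int | None  # one past the last qualifying sweep
    peaks: list[float]


@dataclass
class PairedMeasurement:
    """One cell's pre/post value pair for a named metric."""

    cell_id: str
    metric: str
    pre: float
    post: float

    @property
    def normalized_pct(self) -> float:
        if self.pre == 0:
            raise ZeroDivisionError("pre value is zero; normalized_pct undefined")
        return self.post / self.pre * 100.0


@dataclass
class ComparisonReport:
    """Paired pre/post statistics: Wilcoxon on raw pairs, t vs 100% on normalized."""

    n: int
    wilcoxon_stat: float
    wilcoxon_p: float
    wilcoxon_exact: bool
    degenerate: bool
    t_stat: float
    t_p: float
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    normalized_mean: float
    normalized_sd: float


# ---------------------------------------------------------------------------
# Single-sweep measurements
# ---------------------------------------------------------------------------

def _pre_window(trace: SweepTrace, window_s: float) -> np.ndarray:
    mask = (trace.times >= trace.app_on - window_s) & (trace.times < trace.app_on)
    return trace.current[mask]


def baseline_subtract(trace: SweepTrace, window_s: float = BASELINE_WINDOW_S) -> SweepTrace:
    """Subtract the mean of the pre-application window ending at ``app_on``."""
    if trace.app_on - trace.times[0] < window_s - trace.period / 2:
        raise AnalysisError(
            f"need {window_s * 1e3:.0f} ms of pre-application samples, "
            f"trace starts {trace.app_on - trace.times[0]:.4f} s before onset"
        )
    pre = _pre_window(trace, window_s)
    if pre.size == 0:
        raise AnalysisError("no samples in the pre-application baseline window")
    return trace.with_current(trace.current - pre.mean())


PEAK_SMOOTH_S = 0.0005  # boxcar width for the peak read


def smooth_boxcar(values: np.ndarray, rate: float, width_s: float) -> np.ndarray:
    """Centered moving average of odd sample width (identity for width 0)."""
    k = int(round(width_s * rate))
    if k < 2:
        return values
    if k % 2 == 0:
        k += 1
    return np.convolve(values, np.full(k, 1.0 / k), mode="same")


def measure_peak(
    trace: SweepTrace,
    search_s: float = PEAK_SEARCH_S,
    floor_sd: float = 5.0,
    smooth_s: float = PEAK_SMOOTH_S,
) -> tuple[float, float]:
    """Locate the peak response in the first ``search_s`` after onset.

    Returns ``(i_peak, t_peak)`` with ``i_peak`` the magnitude of the
    largest absolute smoothed current in the window and ``t_peak`` its
    absolute sample time.  A short boxcar (default 0.5 ms; ``smooth_s=0``
    disables it) keeps single noise excursions from inflating the peak
    read.  The search window is restricted to just after onset so a late
    resensitization maximum is never mistaken for the peak.  A peak below
    the noise floor (``floor_sd`` baseline SDs, minimum 1e-9 pA) raises
    :class:`DegeneratePeakError`.
    """
    mask = (trace.times >= trace.app_on) & (trace.times <= trace.app_on + search_s)
    if not mask.any():
        raise AnalysisError("no samples in the peak search window")
    seg = smooth_boxcar(trace.current, trace.rate, smooth_s)[mask]
    idx = int(np.argmax(np.abs(seg)))
    i_peak = float(np.abs(seg[idx]))
    pre = _pre_window(trace, BASELINE_WINDOW_S)
    floor = max(floor_sd * (float(pre.std()) if pre.size else 0.0), 1e-9)
    if i_peak <= floor:
        raise DegeneratePeakError(
            f"peak {i_peak:.3g} pA does not exceed the noise floor {floor:.3g} pA"
        )
    t_peak = float(trace.times[mask][idx])
    return i_peak, t_peak


def _polarity(trace: SweepTrace, t_peak: float) -> float:
    """Sign of the response at the peak (-1 for inward currents)."""
    i_at = np.interp(t_peak, trace.times, trace.current)
    return -1.0 if i_at < 0 else 1.0


def _window_amp(
    trace: SweepTrace, t_end: float, window_s: float, sign: float
) -> float:
    """Response magnitude as a window mean ending at ``t_end`` (point read if 0)."""
    if window_s <= 0:
        return sign * float(np.interp(t_end, trace.times, trace.current))
    period = trace.period
    if t_end > trace.times[-1] + period / 2 or t_end - window_s < trace.times[0]:
        raise AnalysisError(f"read window ending at {t_end:.4f} s lies outside the trace")
    mask = (trace.times > t_end - window_s) & (trace.times <= t_end + period / 2)
    if not mask.any():
        raise AnalysisError(f"no samples in read window ending at {t_end:.4f} s")
    return sign * float(trace.current[mask].mean())


def rise_time(trace: SweepTrace, i_peak: float, t_peak: float) -> float:
    """10-90% rise time (ms) with linear interpolation between samples."""
    mask = (trace.times >= trace.app_on) & (trace.times <= t_peak)
    t = trace.times[mask]
    amp = _polarity(trace, t_peak) * trace.current[mask]
    lo, hi = 0.1 * i_peak, 0.9 * i_peak

    def first_crossing(level: float) -> float:
        above = amp >= level
        if not above.any():
            raise AnalysisError(f"rise never reaches {level:.3g} pA before the peak")
        k = int(np.argmax(above))
        if k == 0:
            return float(t[0])
        # linear interpolation between samples k-1 and k
        frac = (level - amp[k - 1]) / (amp[k] - amp[k - 1])
        return float(t[k - 1] + frac * (t[k] - t[k - 1]))

    return (first_crossing(hi) - first_crossing(lo)) * 1e3


def _biexp(dt_ms: np.ndarray, a1: float, tau1: float, a2: float, tau2: float, c: float):
    return a1 * np.exp(-dt_ms / tau1) + a2 * np.exp(-dt_ms / tau2) + c


def fit_desensitization(
    trace: SweepTrace, t_peak: float, window_s: float = DESENS_WINDOW_S
) -> DesensFit:
    """Constrained biexponential fit of the first 200 ms after the peak.

    Fits ``a1 exp(-dt/tau1) + a2 exp(-dt/tau2) + c`` to the response
    magnitude on dt in (0, 200 ms], with a1, a2 >= 0 and 0.1 ms <= tau1 <=
    tau2 <= 1000 ms, and reports the amplitude-weighted time constant.  A
    deterministic multi-start grid (log-linear seed plus fixed tau guesses)
    makes the result reproducible; an essentially flat segment returns
    ``fit_ok=False`` rather than raising.  ``fit_ok`` is also false when the
    residual RMS is large relative to the fitted decay or a tau sits at its
    bounds.
    """
    period = trace.period
    mask = (trace.times > t_peak) & (trace.times <= t_peak + window_s + period / 2)
    t = trace.times[mask]
    if t.size < 10 or t[-1] - t_peak < window_s - period:
        raise AnalysisError(
            f"need {window_s * 1e3:.0f} ms of samples after the peak for the fit"
        )
    sign = _polarity(trace, t_peak)
    y = sign * trace.current[mask]
    dt_ms = (t - t_peak) * 1e3

    c0 = float(y[dt_ms > dt_ms[-1] - 5.0].mean())  # plateau guess: last 5 ms
    amp0 = float(y[0] - c0)
    if abs(amp0) < 1e-9 and float(y.std()) < 1e-9:
        return DesensFit(0.0, np.nan, 0.0, np.nan, c0, np.nan, False, 0.0)

    # log-linear seed for the dominant tau, on the early positive part
    tau_seed = 20.0
    resid = y - c0
    pos = resid > max(1e-12, 0.05 * abs(amp0))
    if pos.sum() >= 5:
        slope = np.polyfit(dt_ms[pos], np.log(resid[pos]), 1)[0]
        if slope < 0:
            tau_seed = float(np.clip(-1.0 / slope, _TAU_LO_MS * 2, _TAU_HI_MS / 10))

    starts = [(0.7 * amp0, tau_seed, 0.3 * amp0, 5 * tau_seed, c0)]
    for tau1_0 in (2.0, 5.0, 10.0, 20.0, 50.0, 100.0):
        starts.append((0.5 * amp0, tau1_0, 0.5 * amp0, 5 * tau1_0, c0))

    lb = [0.0, _TAU_LO_MS, 0.0, _TAU_LO_MS, -np.inf]
    ub = [np.inf, _TAU_HI_MS, np.inf, _TAU_HI_MS, np.inf]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        try:
            res = optimize.least_squares(
                lambda p: _biexp(dt_ms, *p) - y, x0, bounds=(lb, ub), method="trf"
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    if best is None:
        return DesensFit(0.0, np.nan, 0.0, np.nan, c0, np.nan, False, float(y.std()))

    a1, tau1, a2, tau2, c = best.x
    if tau2 < tau1:  # enforce tau1 <= tau2 by relabelling
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    if a1 + a2 > 0:
        tau_w = (a1 * tau1 + a2 * tau2) / (a1 + a2)
    else:
        tau_w = np.nan
    resid_rms = float(np.sqrt(2 * best.cost / y.size))
    decay_amp = max(abs(a1 + a2), 1e-12)
    taus = [tau for a, tau in ((a1, tau1), (a2, tau2)) if a > 1e-9 * decay_amp]
    at_bounds = any(
        tau < _TAU_LO_MS * 1.01 or tau > _TAU_HI_MS * 0.99 for tau in taus
    )
    fit_ok = (
        np.isfinite(tau_w)
        and not at_bounds
        and resid_rms < 0.5 * decay_amp
    )
    return DesensFit(float(a1), float(tau1), float(a2), float(tau2), float(c),
                     float(tau_w), bool(fit_ok), resid_rms)


def steady_state_pct(
    trace: SweepTrace, i_peak: float, t_peak: float, window_s: float = READ_WINDOW_S
) -> float:
    """Current remaining 200 ms after the peak, as % of peak."""
    sign = _polarity(trace, t_peak)
    i200 = _window_amp(trace, t_peak + DESENS_WINDOW_S, window_s, sign)
    return i200 / i_peak * 100.0


def resensitization_pct(
    trace: SweepTrace, i_peak: float, t_peak: float, window_s: float = READ_WINDOW_S
) -> float:
    """Current regrowth between 200 ms post-peak and the end of application, % of peak.

    Requires an application of at least 5 s; may be negative if the current
    sags instead of resensitizing.
    """
    if trace.app_off - trace.app_on < MIN_APPLICATION_S - trace.period:
        raise AnalysisError(
            f"application lasts {trace.app_off - trace.app_on:.3f} s; "
            f"resensitization needs >= {MIN_APPLICATION_S:g} s"
        )
    sign = _polarity(trace, t_peak)
    i200 = _window_amp(trace, t_peak + DESENS_WINDOW_S, window_s, sign)
    i5s = _window_amp(trace, trace.app_off, window_s, sign)
    return (i5s - i200) / i_peak * 100.0


def analyze_sweep(
    trace: SweepTrace, read_window_s: float = READ_WINDOW_S
) -> KineticsResult:
    """Full single-sweep analysis: baseline, peak, rise, fit, percentages."""
    trace = baseline_subtract(trace)
    i_peak, t_peak = measure_peak(trace)
    sign = _polarity(trace, t_peak)
    try:
        rise = rise_time(trace, i_peak, t_peak)
    except AnalysisError:
        rise = np.nan
    fit = fit_desensitization(trace, t_peak)
    ss = steady_state_pct(trace, i_peak, t_peak, read_window_s)
    try:
        resens = resensitization_pct(trace, i_peak, t_peak, read_window_s)
        i5s = _window_amp(trace, trace.app_off, read_window_s, sign)
    except AnalysisError:
        resens, i5s = np.nan, np.nan
    i200 = _window_amp(trace, t_peak + DESENS_WINDOW_S, read_window_s, sign)
    return KineticsResult(
        i_peak=i_peak,
        t_peak=t_peak - trace.app_on,
        i_200ms=i200,
        i_5s=i5s,
        a1=fit.a1,
        a2=fit.a2,
        tau1=fit.tau1,
        tau2=fit.tau2,
        tau_w=fit.tau_w,
        steady_state_pct=ss,
        resensitization_pct=resens,
        rise_10_90=rise,
        fit_ok=fit.fit_ok,
    )


# ---------------------------------------------------------------------------
# Multi-sweep screening and paired statistics
# ---------------------------------------------------------------------------

def stability_filter(
    sweeps: list[SweepTrace], tolerance: float = 0.10, min_run: int = 3
) -> StabilityResult:
    """Screen for a run of >= ``min_run`` consecutive sweeps with stable peaks.

    A window qualifies when every peak lies within ``tolerance`` (default
    +-10%) of that window's mean peak.  The earliest qualifying window is
    returned, extended as far as the stability condition keeps holding.
    Fewer than ``min_run`` sweeps simply yields ``accepted=False``.
    """
    peaks = [measure_peak(baseline_subtract(s))[0] for s in sweeps]
    n = len(peaks)

    def qualifies(i: int, j: int) -> bool:
        win = peaks[i:j]
        mean = sum(win) / len(win)
        return all(abs(p - mean) <= tolerance * mean for p in win)

    for i in range(0, n - min_run + 1):
        if qualifies(i, i + min_run):
            j = i + min_run
            while j < n and qualifies(i, j + 1):
                j += 1
            return StabilityResult(True, i, j, peaks)
    return StabilityResult(False, None, None, peaks)


def wilcoxon_signed_rank(diffs: np.ndarray) -> tuple[float, float, bool, bool]:
    """Two-sided Wilcoxon signed-rank test of paired differences.

    Zero differences are dropped (classical convention) and tied absolute
    differences receive averaged ranks.  For n <= 25 retained pairs the
    exact null distribution of W+ is computed by dynamic programming (valid
    with tie-averaged ranks); larger n uses the tie-corrected normal
    approximation.  The two-sided p is ``min(1, 2 * min(P(W <= w), P(W >= w)))``.

    Returns ``(W+, p, exact, degenerate)``; ``degenerate`` is set (p = nan)
    when every difference is zero.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, np.nan, True, True
    ranks = stats.rankdata(np.abs(d))  # averaged ties
    w_plus = float(ranks[d > 0].sum())

    if n <= 25:
        # exact null: every sign pattern equally likely; work in half-rank
        # integer units (2 * rank is integral even with averaged ties)
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: total + 1 - r].copy()
        counts /= counts.sum()
        w2 = int(round(2 * w_plus))
        cdf = counts[: w2 + 1].sum()
        sf = counts[w2:].sum()
        p = min(1.0, 2.0 * min(cdf, sf))
        return w_plus, float(p), True, False

    mean = n * (n + 1) / 4.0
    tie_counts = np.unique(np.abs(d), return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mean) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return w_plus, float(min(1.0, p)), False, False


def paired_compare(pre: np.ndarray, post: np.ndarray) -> ComparisonReport:
    """Paired pre/post comparison of one metric across cells.

    Runs a two-sided Wilcoxon signed-rank test on the raw pairs and a
    one-sample two-sided t-test of the normalized values (post/pre x 100)
    against 100%.  Summaries are mean +- SD (sample SD, ddof=1).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D arrays")
    n = pre.size
    if n < 3:
        raise ValueError("paired comparison needs n >= 3")
    if np.any(pre == 0):
        raise ValueError("pre values must be non-zero for normalization")
    w, p, exact, degenerate = wilcoxon_signed_rank(post - pre)
    normalized = post / pre * 100.0
    if np.allclose(normalized.std(ddof=1), 0.0):
        # zero-variance normalized values: t is 0 at the null, +-inf otherwise
        delta = normalized.mean() - 100.0
        t_stat, t_p = (0.0, 1.0) if abs(delta) < 1e-12 else (np.sign(delta) * np.inf, 0.0)
    else:
        t_stat, t_p = stats.ttest_1samp(normalized, 100.0)
    return ComparisonReport(
        n=n,
        wilcoxon_stat=w,
        wilcoxon_p=p,
        wilcoxon_exact=exact,
        degenerate=degenerate,
        t_stat=float(t_stat),
        t_p=float(t_p),
        pre_mean=float(pre.mean()),
        pre_sd=float(pre.std(ddof=1)),
        post_mean=float(post.mean()),
        post_sd=float(post.std(ddof=1)),
        normalized_mean=float(normalized.mean()),
        normalized_sd=float(normalized.std(ddof=1)),
    )
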