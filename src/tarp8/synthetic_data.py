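"""Ground-truthed synthetic inputs for both analysis arms.

Nothing from the original recordings or MD trajectories is deposited
anywhere, so validation rests on simulated stand-ins that carry their own
ground truth:

* :func:`gen_trace` — a phenomenological 5-s fast-application AMPAR sweep:
  fast rise, biexponential desensitization, steady-state plateau and a slow
  resensitization component, plus i.i.d. Gaussian noise.  The noise-free
  normalized response is::

      I(dt)/I_peak = (1 - exp(-dt/tau_rise))
                     * [f1 exp(-dt/tau1) + f2 exp(-dt/tau2) + s
                        + r (1 - exp(-dt/tau_res))]

  with f1 + f2 + s = 1 so the bracket equals 1 at dt = 0.  Defaults emulate
  a vehicle-condition TARP-gamma-8-associated receptor: tau_w ~ 26 ms,
  steady state ~ 18% of peak, resensitization ~ 7% of peak.

* :func:`gen_trajectory` — a ligand diffusing near a breathing two-helix
  pocket: the two anchor Cα atoms oscillate sinusoidally about a fixed
  centre, the ligand follows an Euler–Maruyama random walk with a harmonic
  attraction inside a capture well, and a donor/H pair snaps to H-bond
  geometry against a fixed acceptor whenever the ligand is in the well.

* :func:`gen_model_scores` — a random model-score table with one strict
  energy minimum as designated ground truth.

All randomness flows from one explicit seed per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .mol_io import Atom, Frame, SweepTrace, Trajectory, mass_of
from .model_selection import ModelScore

__all__ = [
    "TraceParams",
    "TraceTruth",
    "TrajParams",
    "TrajTruth",
    "gen_trace",
    "gen_trajectory",
    "gen_model_scores",
]


# ---------------------------------------------------------------------------
# Current sweeps
# ---------------------------------------------------------------------------

@dataclass
class TraceParams:
    """Parameters of the synthetic sweep (amplitudes pA, taus ms unless noted)."""

    i_peak: float = 500.0  # pA (magnitude; emitted current is inward/negative)
    tau_rise: float = 0.2  # ms; ~0.44 ms 10-90% rise, fast perfusion regime
    f1: float = 0.57  # fast desensitization fraction
    f2: float = 0.28  # slow desensitization fraction
    tau1: float = 10.0  # ms
    tau2: float = 60.0  # ms; with f1/f2 above, tau_w = 26.5 ms
    s: float = 0.15  # steady-state fraction (f1 + f2 + s = 1)
    r: float = 0.10  # resensitization amplitude, fraction of peak
    tau_res: float = 1.0  # s
    sigma: float = 25.0  # noise SD, pA (SNR 20 at the default peak)
    rate: float = 10_000.0  # Hz
    pre_s: float = 0.2  # baseline before application
    app_s: float = 5.0  # application length
    tail_s: float = 0.3  # recorded tail after application
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.f1 + self.f2 + self.s - 1.0) > 1e-9:
            raise ParameterError(
                f"f1 + f2 + s must equal 1, got {self.f1 + self.f2 + self.s}"
            )
        if min(self.f1, self.f2, self.s, self.r) < 0:
            raise ParameterError("fractions must be non-negative")
        if min(self.tau_rise, self.tau1, self.tau2, self.tau_res, self.rate) <= 0:
            raise ParameterError("time constants and rate must be positive")

    @property
    def tau_w(self) -> float:
        """Amplitude-weighted desensitization tau of the generating mixture (ms)."""
        if self.f1 + self.f2 == 0:
            return np.nan
        return (self.f1 * self.tau1 + self.f2 * self.tau2) / (self.f1 + self.f2)

    def normalized_response(self, dt_s: np.ndarray) -> np.ndarray:
        """Noise-free I(dt)/i_peak for dt >= 0 seconds after onset."""
        dt_ms = np.asarray(dt_s, dtype=float) * 1e3
        decay = (
            self.f1 * np.exp(-dt_ms / self.tau1)
            + self.f2 * np.exp(-dt_ms / self.tau2)
            + self.s
            + self.r * (1.0 - np.exp(-np.asarray(dt_s) / self.tau_res))
        )
        return (1.0 - np.exp(-dt_ms / self.tau_rise)) * decay


@dataclass
class TraceTruth:
    """Exact values of every analyzer statistic on the noise-free sweep.

    Computed from the closed-form model evaluated on the sample grid with
    the same measurement definitions the analyzer applies (peak in the
    first 100 ms, 5-ms window reads), independently of the analyzer code.
    ``tau_w`` is the generating mixture's closed form.
    """

    i_peak: float
    t_peak: float  # s, relative to application onset
    i_200ms: float
    i_5s: float
    steady_state_pct: float
    resensitization_pct: float
    tau_w: float
    rise_10_90: float


def _trace_truth(p: TraceParams, times: np.ndarray) -> TraceTruth:
    app_on = p.pre_s
    dt = np.clip(times - app_on, 0.0, None)
    clean = p.i_peak * p.normalized_response(dt)  # magnitude
    # the peak read is a 0.5-ms boxcar (the analyzer's anti-noise definition)
    k_box = int(round(0.0005 * p.rate))
    if k_box >= 2:
        if k_box % 2 == 0:
            k_box += 1
        smoothed = np.convolve(clean, np.full(k_box, 1.0 / k_box), mode="same")
    else:
        smoothed = clean
    in_search = (times >= app_on) & (times <= app_on + 0.1)
    k = int(np.argmax(smoothed[in_search]))
    i_pk = float(smoothed[in_search][k])
    t_pk = float(times[in_search][k])

    def window_mean(t_end: float) -> float:
        mask = (times > t_end - 0.005) & (times <= t_end + 0.5 / p.rate)
        return float(clean[mask].mean())

    i200 = window_mean(t_pk + 0.2)
    i5s = window_mean(app_on + p.app_s)
    # 10-90% rise time of the continuous model, by bisection on dt
    target = lambda frac: frac * i_pk

    def crossing(level: float) -> float:
        lo, hi = 0.0, t_pk - app_on
        for _ in range(80):
            mid = (lo + hi) / 2
            if p.i_peak * p.normalized_response(np.array([mid]))[0] < level:
                lo = mid
            else:
                hi = mid
        return hi

    rise = (crossing(target(0.9)) - crossing(target(0.1))) * 1e3
    return TraceTruth(
        i_peak=i_pk,
        t_peak=t_pk - app_on,
        i_200ms=i200,
        i_5s=i5s,
        steady_state_pct=i200 / i_pk * 100.0,
        resensitization_pct=(i5s - i200) / i_pk * 100.0,
        tau_w=p.tau_w,
        rise_10_90=rise,
    )


def gen_trace(params: TraceParams) -> tuple[SweepTrace, TraceTruth]:
    """Generate one synthetic sweep and its ground truth.

    The emitted current is inward (negative) with i.i.d. Gaussian noise of
    SD ``sigma`` on every sample.  Identical parameters (including the
    seed) give bit-identical output.
    """
    p = params
    n = int(round((p.pre_s + p.app_s + p.tail_s) * p.rate)) + 1
    times = np.arange(n) / p.rate
    app_on, app_off = p.pre_s, p.pre_s + p.app_s
    clean = np.zeros(n)
    during = times >= app_on
    clean[during] = p.i_peak * p.normalized_response(times[during] - app_on)
    post = times > app_off
    if post.any():  # deactivation after agonist removal, fast single exponential
        level = p.i_peak * p.normalized_response(np.array([p.app_s]))[0]
        clean[post] = level * np.exp(-(times[post] - app_off) * 1e3 / 3.0)
    rng = np.random.default_rng(p.seed)
    current = -clean + rng.normal(0.0, p.sigma, size=n)
    trace = SweepTrace(
        times=times,
        current=current,
        rate=p.rate,
        app_on=app_on,
        app_off=app_off,
        cell_id="synthetic",
        condition="synthetic",
    )
    return trace, _trace_truth(p, times)


# ---------------------------------------------------------------------------
# Binding trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajParams:
    """Parameters of the synthetic pocket-binding trajectory (nm, ns)."""

    n_frames: int = 2000
    dt: float = 0.25  # ns between frames (default run spans 500 ns)
    pocket_width: float = 0.85  # mean anchor Cα–Cα separation
    breathing_amp: float = 0.15  # sinusoidal half-amplitude of the width
    breathing_period: float = 50.0  # ns
    ligand_start: tuple[float, float, float] = (1.5, 0.0, 0.0)
    diffusion: float = 0.02  # nm^2/ns
    well_depth: float = 0.5  # harmonic spring constant, 1/ns
    well_radius: float = 0.6  # capture radius around the site centre
    bond_offset: float = 0.20  # H-to-acceptor distance when bound
    box_radius: float = 3.0  # reflecting sphere confining the ligand
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.well_radius <= 0:
            raise ParameterError("dt and well_radius must be positive")
        if self.n_frames < 1:
            raise ParameterError("need at least one frame")
        if self.diffusion < 0:
            raise ParameterError("diffusion must be non-negative")


@dataclass
class TrajTruth:
    """Per-frame ground truth emitted alongside the coordinates."""

    times: np.ndarray  # ns
    engagement: np.ndarray  # ligand heavy-atom COM to site centre, nm
    pocket_width: np.ndarray  # anchor separation, nm
    in_well: np.ndarray  # bool, ligand inside the capture well
    hbond_distance: np.ndarray  # H to acceptor, nm
    bound_fraction: float
    bound_intervals: list[tuple[float, float]]

    def occupancy(self, cutoff: float) -> float:
        """Time-weighted H-bond occupancy at ``cutoff`` (trapezoid weights)."""
        t, v = self.times, self.hbond_distance
        if len(t) == 1:
            return float(v[0] < cutoff)
        w = np.empty_like(t)
        w[0] = (t[1] - t[0]) / 2
        w[-1] = (t[-1] - t[-2]) / 2
        if len(t) > 2:
            w[1:-1] = (t[2:] - t[:-2]) / 2
        return float(w[v < cutoff].sum() / w.sum())


def _runs_to_intervals(times: np.ndarray, flags: np.ndarray) -> list[tuple[float, float]]:
    out, start = [], None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - 1 > start:
                out.append((float(times[start]), float(times[i - 1])))
            start = None
    if start is not None and len(flags) - 1 > start:
        out.append((float(times[start]), float(times[-1])))
    return out


def gen_trajectory(params: TrajParams) -> tuple[Trajectory, TrajTruth]:
    """Generate a synthetic pocket-binding trajectory with ground truth.

    Topology (6 atoms): the two pocket anchors (VAL 176 CA and GLY 209 CA,
    chain T), a fixed acceptor (ASN 172 OD1, chain T) and a three-atom
    ligand (C1/N1/H1, residue LIG, chain L).  The ligand's heavy-atom
    centre of mass follows the random walk exactly (the carbon position
    compensates for the donor nitrogen), so analyzer engagement distances
    can be checked against the emitted ground truth to machine precision.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    times = np.arange(p.n_frames) * p.dt
    center = np.zeros(3)
    axis = np.array([1.0, 0.0, 0.0])
    acceptor_pos = center + np.array([0.0, 0.30, 0.0])

    width = p.pocket_width + p.breathing_amp * np.sin(2 * np.pi * times / p.breathing_period)

    # Euler–Maruyama walk: harmonic drift toward the centre inside the well,
    # free diffusion outside, reflecting sphere at box_radius.
    x = np.array(p.ligand_start, dtype=float)
    step_sd = np.sqrt(2.0 * p.diffusion * p.dt)
    positions = np.empty((p.n_frames, 3))
    for i in range(p.n_frames):
        positions[i] = x
        disp = x - center
        dist = np.linalg.norm(disp)
        drift = -p.well_depth * disp * p.dt if dist < p.well_radius else np.zeros(3)
        x = x + drift + step_sd * rng.standard_normal(3)
        d = np.linalg.norm(x - center)
        if d > p.box_radius:
            x = center + (x - center) * (2 * p.box_radius / d - 1.0)  # reflect

    engagement = np.linalg.norm(positions - center, axis=1)
    in_well = engagement < p.well_radius

    m_c, m_n, m_h = mass_of("C"), mass_of("N"), mass_of("H")
    atoms = [
        Atom(1, "CA", "C", "VAL", 176, "T", m_c),
        Atom(2, "CA", "C", "GLY", 209, "T", m_c),
        Atom(3, "OD1", "O", "ASN", 172, "T", mass_of("O")),
        Atom(4, "C1", "C", "LIG", 1, "L", m_c),
        Atom(5, "N1", "N", "LIG", 1, "L", m_n),
        Atom(6, "H1", "H", "LIG", 1, "L", m_h),
    ]

    frames = []
    hbond = np.empty(p.n_frames)
    for i in range(p.n_frames):
        com = positions[i]
        anchor_a = center - axis * width[i] / 2
        anchor_b = center + axis * width[i] / 2
        if in_well[i]:
            # snap donor/H onto H-bond geometry against the fixed acceptor
            toward = com - acceptor_pos
            norm = np.linalg.norm(toward)
            u = toward / norm if norm > 1e-12 else np.array([0.0, -1.0, 0.0])
            h_pos = acceptor_pos + u * p.bond_offset
            n_pos = acceptor_pos + u * (p.bond_offset + 0.10)
        else:
            n_pos = com + np.array([0.15, 0.0, 0.0])
            h_pos = com + np.array([0.25, 0.0, 0.0])
        # place the carbon so the ligand heavy-atom COM equals the walk
        c_pos = ((m_c + m_n) * com - m_n * n_pos) / m_c
        hbond[i] = np.linalg.norm(h_pos - acceptor_pos)
        frames.append(
            Frame(
                time=float(times[i]),
                coords=np.vstack([anchor_a, anchor_b, acceptor_pos, c_pos, n_pos, h_pos]),
            )
        )

    truth = TrajTruth(
        times=times,
        engagement=engagement,
        pocket_width=width,
        in_well=in_well,
        hbond_distance=hbond,
        bound_fraction=float(in_well.mean()),
        bound_intervals=_runs_to_intervals(times, in_well),
    )
    return Trajectory(atoms=atoms, frames=frames), truth


# ---------------------------------------------------------------------------
# Model-score fixtures
# ---------------------------------------------------------------------------

def gen_model_scores(
    n: int, seed: int = 0, dope_mean: float = -227_000.0, dope_sd: float = 800.0
) -> tuple[list[ModelScore], int]:
    """Random model-score table with one designated, strictly best model.

    Returns ``(scores, best_id)`` where ``best_id`` has a DOPE score
    strictly below every other model's.
    """
    if n < 1:
        raise ParameterError("need at least one model")
    rng = np.random.default_rng(seed)
    dope = np.round(rng.normal(dope_mean, dope_sd, size=n))
    rmsd = np.round(rng.uniform(1.0, 1.2, size=n), 2)
    best = int(rng.integers(n))
    dope[best] = dope.min() - 500.0  # strict minimum by construction
    scores = [
        ModelScore(model_id=i + 1, rmsd=float(rmsd[i]), dope=float(dope[i]))
        for i in range(n)
    ]
    return scores, best + 1
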