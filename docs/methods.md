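# Methods

This note documents the models, parameter choices and numerical decisions
behind `tarp8`, and what the synthetic-data validation does and does not
establish.

## Units and containers

The canonical internal length unit is the nanometre (MD convention);
conversion from the ångström-based PDB format is an exact ×0.1 at the file
boundary, and only superposition RMSD is reported in Å, following
structural-biology convention. Trajectories are a lightweight
topology-plus-frames container; frame times are in ns. PDB `MODEL` blocks
carry no time axis, so multi-model files are stamped 0, 1, 2, … ns.
Current sweeps are time/current arrays in s/pA with inward current
negative; all reported amplitudes are magnitudes.

PDB parsing is a dedicated fixed-width reader because the error contract
(parse failures name the offending line) and the alternate-location policy
(keep blank/"A", warn and skip others) must be deterministic; coordinates
are cross-checked against an independent reader in the test suite. Binary
acquisition and MD formats (ABF, XTC, DCD) are out of scope; adapters can
construct the containers directly.

## Trajectory analytics

**Pocket width** is the distance between the two anchor Cα atoms (in TARP
γ8: Val-176 on M3 and Gly-209 on M4); **engagement** is the distance
between the ligand's centre of mass and the anchor midpoint. The ligand
COM uses heavy atoms only by default (configurable): hydrogens contribute
little mass and their placement is the least reliable part of modelled
ligands. Both series are rigid-motion invariant (property-tested).

**Hydrogen bonds** are scored by distance alone, no angular term: < 0.25 nm
hydrogen-to-acceptor for at least a weak bond, or < 0.36 nm heavy-to-heavy
when the bonding hydrogen is not the measured atom (e.g. N-to-N
measurements). **Occupancy** is time-weighted — each sample owns half the
interval to each neighbour, the two ends half-intervals only — so unevenly
spaced snapshots do not bias the estimate. Occupancy is 0 at cutoff → 0,
1 at cutoff → ∞ and monotone non-decreasing in the cutoff.

**Bound intervals** are maximal runs of engagement samples below a cutoff
(default 0.8 nm — a COM distance above ~0.8 nm marks a broken pocket
contact), converted to the time span from the run's first to last sample
and kept only if that span reaches `min_dwell` (default 5 ns). A
single-frame contact has zero measurable span and is always dropped; with
typical frame spacings this removes only transient touches. Both
parameters are configurable.

**Snapshot selection** returns the frame of maximal pocket width (earliest
frame on ties) — the rule used to pick dilated-pocket conformations as
docking substrates.

**Superposition RMSD** is plain least-squares over all supplied atom pairs
(Kabsch, proper rotation enforced, via `scipy.spatial.transform`), with no
iterative outlier rejection: deterministic and directly checkable against
a numerical-minimisation oracle. It is symmetric and never exceeds the
unsuperposed RMSD.

**Model ranking** sorts candidate structural models by DOPE energy
ascending with RMSD as tie-break and model id as final tie-break. The two
criteria can genuinely disagree (the shipped ten-row example has its
smallest-RMSD model distinct from its lowest-energy one); energy-primary
is the only deterministic lexicographic rule consistent with selecting the
lowest-energy model, and the tie-break order is this package's decision.

## Sweep kinetics

All measurements assume a baseline-subtracted trace (mean of the 50 ms
before application onset).

- **Peak**: largest absolute current within 100 ms of onset, read after a
  0.5-ms centered boxcar. The short window prevents a late resensitization
  maximum from being mistaken for the peak (solution exchange in the
  emulated protocol is ~200 µs, so the true peak is early); the boxcar
  prevents single noise excursions from inflating the peak read, a bias of
  order the noise SD times the expected maximum of several standard
  normals that would otherwise propagate into every percentage statistic.
  Both are configurable (`smooth_s=0` disables smoothing).
- **Rise time**: 10–90% of peak, first crossings before the peak, linear
  interpolation between samples.
- **Desensitization fit**: `a1·exp(-dt/τ1) + a2·exp(-dt/τ2) + c` on
  dt ∈ (0, 200 ms] after the peak, with a1, a2 ≥ 0 and 0.1 ms ≤ τ1 ≤ τ2 ≤
  1000 ms. The offset `c` is included because these traces do not decay to
  zero (a steady-state plateau exists). Initialisation is deterministic:
  `c` from the last 5 ms of the window, a log-linear fit seeding τ1, plus
  a fixed grid of six further starts (τ1 ∈ {2, 5, 10, 20, 50, 100} ms,
  τ2 = 5τ1); the lowest-cost solution wins, so results are reproducible
  without random restarts. `fit_ok` is false — never an exception — for
  flat segments, residual RMS above half the fitted decay amplitude, or a
  τ pinned at its bounds. τw = (a1τ1 + a2τ2)/(a1 + a2) is always within
  [τ1, τ2].
- **Percentages**: `I_200ms` is read 200 ms after the measured peak and
  `I_5s` at the end of the application, each as a 5-ms window mean
  (configurable; 0 gives an interpolated point read) — window means resist
  sampling noise where single-point reads do not. Steady state is
  `I_200ms/I_peak×100`; resensitization is `(I_5s−I_200ms)/I_peak×100`,
  requires a ≥5-s application, and may be negative if the current sags.
  Both are invariant under current rescaling and baseline shifts.
- **Stability screen**: a cell qualifies when some run of ≥3 consecutive
  sweeps has every peak within ±10% of that run's mean (the ±10% figure is
  this package's choice, exposed as a parameter); the earliest qualifying
  run is returned, extended while the condition keeps holding.
- **Paired statistics**: two-sided Wilcoxon signed-rank on raw pre/post
  pairs — zeros dropped, tied absolute differences given averaged ranks,
  exact null distribution by dynamic programming for n ≤ 25 (the DP runs
  in half-rank integer units, so averaged ties are handled exactly; the
  usual exact implementations refuse ties), tie-corrected normal
  approximation beyond; and a one-sample two-sided t-test of post/pre×100
  against 100%. All-zero differences are reported as degenerate rather
  than raising. Summaries are mean ± SD (ddof = 1).

## Synthetic data: the stated world

**Sweeps.** The trace model is phenomenological, not a kinetic gating
scheme — it reproduces exactly the statistical structure the analyses
read. The normalized noise-free response after onset is

    I(dt)/I_peak = (1 − e^(−dt/τ_rise)) ·
                   [f1 e^(−dt/τ1) + f2 e^(−dt/τ2) + s + r (1 − e^(−dt/τ_res))]

with f1 + f2 + s = 1. Defaults emulate a vehicle-condition γ8-associated
receptor: I_peak = 500 pA, τ_rise = 0.2 ms (≈0.44 ms 10–90% rise, the
fast-perfusion regime), f1 = 0.57, τ1 = 10 ms, f2 = 0.28, τ2 = 60 ms
(mixture τw = 26.5 ms), s = 0.15, r = 0.10, τ_res = 1 s (resensitization
develops over seconds), σ = 25 pA (SNR 20), 10 kHz sampling, 0.2 s
baseline, 5 s application, 0.3 s tail with a fast (3 ms) deactivation
decay. All randomness comes from the one seed in the parameter set.

Each generated sweep carries a ground-truth record: the exact value of
every analyzer statistic on the noise-free model, computed independently
of the analyzer code but with the same stated measurement definitions
(grid peak after the 0.5-ms boxcar, 5-ms window reads). Referencing truth
to the noise-free waveform rather than to the bracketed decay formula
matters: the measured peak sits on the rising envelope ~6% below I_peak,
so formula-referenced percentages would differ from any achievable
measurement by ~1 percentage point for reasons unrelated to noise.
τw truth is the mixture closed form (f1τ1 + f2τ2)/(f1 + f2).

**Known limitation — τw bias.** On noise-free default-world traces the
200-ms biexponential fit recovers τw ≈ 24.7 ms versus the mixture's
26.5 ms (−6.5%): the rise envelope and peak-referencing push it up ~3%,
and the resensitization ramp inside the fit window — which a
two-exponential-plus-offset model cannot represent — pushes it down ~10%.
This is protocol-intrinsic model mismatch, not an optimizer failure (the
fit residual on clean data is <0.2 pA), and any real recording with
resensitization carries the same bias. At SNR 20 the mean recovered τw
over 100 seeded replicates is within 5% of the mixture truth.

**Trajectories.** The two anchors oscillate sinusoidally about a fixed
centre (mean width 0.85 nm, half-amplitude 0.15 nm, period 50 ns —
spanning the compact-to-dilated range of the pocket), so the site centre
is exactly the origin. The ligand COM follows an Euler–Maruyama walk
(default D = 0.02 nm²/ns, dt = 0.25 ns, 2000 frames = 500 ns, the length
of the emulated production runs) with a harmonic drift (spring 0.5/ns)
inside a 0.6-nm capture well and free diffusion outside, reflected at a
3-nm sphere. The ligand is three atoms (C, N, H), not an all-atom
molecule: the carbon is placed so the heavy-atom COM equals the walk
exactly, and whenever the ligand is in the well the H/N pair snaps to
bond geometry (H at 0.20 nm from a fixed acceptor, N 0.10 nm further).
Emitted ground truth: per-frame engagement, width, in-well flags, H-bond
distances, bound fraction and intervals.

**What a green test establishes.** Synthetic traces are stationary in
noise, have no drift, rundown, series-resistance error, stimulus artefacts
or cell-to-cell kinetic variability; synthetic trajectories have no
force-field physics, solvent, membrane or ligand internal degrees of
freedom. Green recovery tests therefore establish that the analyzers
measure what they claim on data with the stated structure — not that the
stated structure captures every property of experimental data. The
reference-structure pocket-width check (8.5 Å between the anchor Cα atoms)
requires the published cryo-EM coordinates, which are not redistributed
here; that test fails with an explanatory message unless the file is
supplied at `tests/data/6QKC.pdb`.

## Reproducibility

Every generator takes an explicit seed and identical seeds give
bit-identical output; no global random state is used or mutated. CLI
reports are JSON/TSV without timestamps, so identical invocations are
byte-identical. `scripts/acceptance.py --seed N --out f.json` recomputes
the model-ranking outcome from the published ten-row score table at run
time.
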