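# Methods

`dbsloop` is a desk-scale workbench for model-based closed-loop deep
brain stimulation (DBS) in a parkinsonian basal ganglia model.  It has
three layers: conductance-based cell and network models (the *plant*),
an unscented Kalman filter (UKF) that tracks hidden thalamic state and
unobserved synaptic inputs from noisy voltage (the *observer*), and a
family of stimulation control laws scored by relay reliability,
control energy and a reliability-minus-weighted-energy cost.

## Cell models

Four cell types are implemented with Hodgkin-Huxley-style kinetics
(units fixed throughout: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2):

* **Full thalamocortical (TC) relay cell** — leak, fast Na, rectifying
  K and low-threshold T-type Ca currents, with the Rinzel reductions
  (`m = m_inf(v)`, `n = 1 - h`).  State `[v, h, r, Ca]` (the Ca pool is
  inert for this type).  Silent at rest; fires tonically when
  depolarized; rebound-bursts after release from hyperpolarization
  because hyperpolarization deinactivates the T current (anode-break
  excitation).
* **STN, GPe, GPi cells** — leak, Na, K (independent `n` gate),
  T-type Ca, high-threshold Ca and a Ca-activated
  after-hyperpolarization (AHP) K current; a single first-order Ca pool
  integrates influx from the two Ca currents minus first-order removal.
  The STN cell is spontaneously active (~3 Hz) and accelerates with
  depolarizing drive.  The GPe cell fires continuously under its
  baseline drive and switches to clustered, AHP-terminated firing
  episodes under inhibitory (striatal) drive; with `g_AHP = 0` the
  episodes no longer terminate.  The GPi file differs from GPe by a
  weaker AHP conductance so it tends to fire faster.
* **Reduced TC cell** — the two-variable caricature `[v, w]` in which
  the fast spike currents are removed and `w` is the *availability* of
  the T current (the gate multiplying `I_T`; the literature also calls
  it "T-current inactivation" — we keep the availability reading: high
  `w`, more current).  GPi inhibition is a true synaptic current
  `g_GiTh * s_Gi * (v - E_GiTh)`, so it fluctuates with voltage even at
  constant drive.  Relay events are slow T-current excitability bumps,
  detected as upward crossings of -40 mV with 25 ms separation.

Numeric parameter values are not printed in the source material; the
parameter files shipped in `dbsloop/params/` follow the published
conventions of the underlying subthalamopallidal and thalamic relay
models, with conductances and gating midpoints calibrated once so each
cell type reproduces its qualitative repertoire above, and frozen.
Where calibration was needed the target behaviours — not any test
statistic — were the criterion.

### Reduced-cell calibration and its consequences

The reduced cell was calibrated to reproduce, with a 10 Hz periodic
sensorimotor (SM) pulse train (5 ms, 1.2 uA/cm^2):

* **normal** (constant drive `s_Gi = 10`): every pulse relayed;
* **parkinsonian** (square-wave drive 10 <-> 30, 250 ms period, 50%
  duty — a 4 Hz fluctuation in the tremor band): pulses fail while
  inhibition is high, rebound events appear at release, reliability
  ~0.4 with ~8 bad spikes per 4 s run;
* **perfect DBS** (constant drive 30): about half of pulses relayed —
  the cell alternates because each relay event depletes `w` and
  recovery at the hyperpolarized DBS operating point takes more than
  one SM period.

This calibration has a genuine dynamical quirk: at intermediate drive
levels (roughly `s_Gi` 12–28) a depolarized attractor coexists with
the relay regime, so *partially* filling the parkinsonian troughs, or
filling them with the wrong phase (error beyond ~20 ms), abolishes
relay.  We kept it deliberately: the source material itself reports
that the largest constant current that can be *added* to the
fluctuating parkinsonian drive is stability-limited, and this plant
reproduces that behaviour exactly (open-loop added drive is
destabilizing at every amplitude we tried).

## Network

The three STN-GPe topologies (sparse random, sparse structured, tight
structured) are built on a ring with periodic boundaries; "closest"
means circular index distance with ties toward the lower index.  The
sparse-structured skip rule places one GPe->STN contact on each side at
ring distance 4, which avoids direct reciprocal STN<->GPe pairs.  On a
ring of exactly 8 the two contacts coincide (the antipode), so scaled
experiments use 10+10+10+2 cells, the smallest non-degenerate size.
The GPi receives STN excitation with the same footprint as the GPe and
fixed striatal-type drive; its summed synaptic output, scaled by the
GPi->TC conductance, inhibits every TC cell.  Synapses are first-order
(`ds/dt = alpha*H(v_pre)*(1-s) - beta*s`, sigmoid H), with a faster
decay for the excitatory STN synapse.

The regime switch changes exactly two quantities: the parkinsonian
state increases the inhibitory striatal drive onto GPe (baseline bias
1.0 -> net -0.5 uA/cm^2) and scales the intra-GPe conductance by 0.1.
Under the parkinsonian regime the GPe cells fire clustered episodes at
~4 /s; through the STN stage this modulates the GPi population, whose
summed synaptic output acquires a dominant spectral peak in the 3-8 Hz
tremor band (the normal regime shows no such peak and a smaller
smoothed fluctuation, on average over matched seeds).  The cells are
not tightly phase-locked at this scale — the tremor peak reflects
common per-cell rhythmicity, which is all the downstream thalamic
metrics need.

## Engine

Classical fixed-step RK4 (default dt 0.01 ms for the full models,
0.05 ms for the reduced cell), zero-order-hold inputs, bit-exact
determinism, with a loud failure (no silent clamping) if a gate leaves
[0, 1] beyond 1e-9.  Event detection is an upward threshold crossing
with a minimum separation (-20 mV / 2 ms for sodium spikes, -40 mV /
25 ms for reduced-model excitability events); every metric summary
reports the thresholds used.

## Metrics

A sensorimotor pulse is *transmitted* if at least one relay event falls
in `(onset, onset + window]` (window 25 ms for the reduced cell, 10 ms
for full-model relays; windows may not overlap).  Events attributable
to no pulse are *bad spikes*.  The error index is
`(misses + bad) / pulses` (it can exceed 1); the running reliability at
each pulse is the success fraction of the last 10 pulses (fewer early
on) — bad spikes affect the error index but not the running
reliability.  Control energy is the running sum of squared control
samples on the 1 ms control grid.  Control reliability is the fraction
of samples at which the on/off control state correctly mirrors the
troughs/peaks of the true two-valued drive (snapped with 1%
tolerance).  The DBS cost is `reliability - cost_weight * energy`.
Population synchrony averages the zero-normalized pairwise
cross-correlation peak and the mean autocorrelation sideband peak of
binned spike trains; the exact combination (arithmetic mean of the two
terms) is this package's interpretation.

## Assimilation

The UKF state is `[v, w, s_Gi, I_SM]`; only noisy voltage (sd 2 mV) is
observed.  The two inputs follow random-walk dynamics whose per-step
variances `Q_sGi`, `Q_SM` decide which of the two nearly-symmetric
input currents the filter resolves; granting variance to the drive and
starving the SM input (Q = 30 vs 0.01) resolves the square-wave drive
rhythm, the reverse apportionment does not, and a balanced 10 vs 0.01
does at least as well.  Because the drive enters through a conductance
(voltage-dependent) while the SM input is additive, the symmetry is
only approximate: with equal moderate Q on both, the *net* input is
still tracked better than either component.

Choices worth naming: sigma points use the classical Julier-Uhlmann
construction with `kappa = 3 - n`; the observation model is linear
(`h(x) = v`), so the measurement update is computed exactly from the
predicted covariance; the filter/observation/control step is 1 ms with
the plant sub-stepped at the engine dt inside the propagator (at the
raw engine step the per-step voltage increment of the drive is far
below the observation noise and nothing is resolved); covariance
inflation is multiplicative on the full predicted covariance and
defaults to 1.0 — any persistent inflation leaks variance into the
deliberately starved process-noise component and destroys the
apportionment ordering; `w` estimates are clipped to [0, 1] after the
update with a counter; tiny negative eigenvalues from the negative
central sigma weight are repaired, genuine indefiniteness raises.
Estimated drive magnitudes are biased upward (the non-negativity clamp
on drive sigma points is asymmetric), so only waveform correlation —
never absolute scale — is asserted anywhere.

Nullcline estimation evaluates the analytic v-nullcline at sigma
points of the scalar drive estimate, giving a mean curve and an
uncertainty band; the w-nullcline is `w_inf(v)` and does not depend on
the drive.

## Control

All controllers add a non-negative drive `u` to the plant's `s_Gi`
channel (stimulation can add inhibition, never subtract it) on a 1 ms
update interval; the filter is told the applied `u`, so its drive
estimate stays net of the stimulation.  Ties in every threshold
comparison resolve to off.

* `perfect_dbs` — oracle trough filler `u = max(0, target - drive)`
  using the true drive.
* `w_feedback` — `u = min(amplitude, gain * max(0, w_ref - MA_35ms(w_hat)))`.
  The saturation gives the law its on/off character at high gain.  The
  coded default `w_ref` is the normal-regime steady-state availability,
  but in this calibration that value (0.03) makes the controller nearly
  inactive; the tuned configuration uses `w_ref = 0.15` with gain 200
  and amplitude 14, obtained as the interior optimum of the
  transmitted-spike gain sweep with the amplitude cap chosen by the
  same criterion (ties toward lower energy).
* `dual_moving_average` — constant-amplitude stimulation while the
  50 ms moving average of the drive estimate sits below its 500 ms
  moving average.
* `reliability_threshold` — on/off on the running relay reliability
  (computed online from the filtered voltage); `direct` stimulates when
  reliability drops below the threshold, `inverse` when it rises above
  it, exploiting the delay of the reliability average to anticipate the
  next inhibition trough.

### What the closed loop does and does not reproduce

On the parkinsonian scenario (medians over seeds): uncontrolled
reliability 0.40; perfect DBS 0.50 with energy 8.0e5 (1 ms samples);
tuned w-feedback energy ~0.51 of perfect DBS; dual-moving-average
control reliability ~72%; reliability-threshold controllers ~51-52%
control reliability in both modes.  The tuned w-feedback *reliability*
(0.30) does not exceed perfect DBS in this calibration: the plant only
tolerates trough-filling phase errors up to ~20 ms, while the
estimate-driven switch lags 30-50 ms (w kinetics plus averaging), and
the intermediate-drive attractor punishes partial filling.  This is a
known limitation of the calibrated plant, reported as measured; the
energy halving and every on/off phase metric are reproduced.

## Synthetic data and scope

Every input is generated internally: periodic or refractory-Poisson SM
pulse trains, piecewise-constant drive profiles, seeded Gaussian
observation noise.  The generator emulates idealized study conditions —
noise only on the observable, perfectly square pathological drive,
stationary parameters — and none of the nonstationarity, electrode
artefacts, model mismatch or spatial effects of real recordings, so
passing tests demonstrate internal consistency of the method under its
own assumptions, not clinical performance.  Problem sizes are the
package's defaults: 4 s reduced-cell runs (40 SM pulses), 4-5 s
network runs with 10-16 cells per nucleus, 20 seeds for stochastic
summaries.

## Known limitations

* The reduced cell's normal operating point sits close to the event
  threshold; relay events there are near-threshold T-boosted
  excursions rather than full rebound spikes, and the calibration is
  sensitive to the drive conductance.
* The w-feedback reliability advantage reported in the source
  material is not reproduced (see above); the energy advantage is.
* Network synchrony at desk scale is rhythmic but not phase-locked;
  wave phenomena of the tight topology are out of scope.
* Estimated drive scale is biased; use correlations, not magnitudes.
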