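# dbsloop

Model-based closed-loop deep brain stimulation (DBS) workbench for
parkinsonian basal ganglia dynamics.

In Parkinson's disease the internal globus pallidus (GPi) bombards the
thalamus with inhibition that fluctuates in the 3–8 Hz tremor band
instead of staying steady.  Thalamocortical (TC) relay neurons caught
in that fluctuation stop transmitting sensorimotor input faithfully:
inhibition peaks suppress responses, and each release from inhibition
triggers post-inhibitory rebound spikes powered by the low-threshold
T-type calcium current, whose slow inactivation gate `w` (its
*availability*) is the key hidden variable.  `dbsloop` lets you
simulate this pathology, observe it the way an implanted electrode
would (noisy voltage only), reconstruct the hidden state with an
unscented Kalman filter (UKF), and close the loop with a family of
stimulation control laws.

The package is aimed at computational neuroscientists and control
engineers prototyping estimator-based DBS strategies at desk scale.

## What is inside

* **Cells** (`dbsloop.cells`): conductance-based STN, GPe, GPi and full
  TC relay neurons (Hodgkin–Huxley formalism with Rinzel reductions for
  the TC cell), plus the two-variable reduced TC cell

      C dv/dt = −g_L (v−E_L) − g_T p∞²(v) w (v−E_T) − g_GiTh s_Gi (v−E_GiTh) + I_SM
      dw/dt   = φ (w∞(v) − w) / τ_w(v)

  whose relay events are slow T-current excitability bumps.
* **Network** (`dbsloop.network`): the three STN–GPe ring topologies
  (sparse random / sparse structured / tight structured), first-order
  synapses, and the normal→parkinsonian regime switch (more striatal
  inhibition of GPe, weaker intra-GPe coupling) that turns the GPi
  output rhythmic in the tremor band.
* **Assimilation** (`dbsloop.assimilation`): UKF over the augmented
  state `[v, w, s_Gi, I_SM]` from noisy voltage alone; the
  process-noise split (Q_sGi vs Q_SM) decides which of the two
  symmetric inputs is reconstructed; nullcline estimation with
  uncertainty bands.
* **Control** (`dbsloop.control`): perfect (oracle) trough-filling DBS,
  proportional feedback on the estimated availability `w`, a dual
  moving-average on/off law on the estimated GPi drive, and direct /
  inverse reliability-threshold controllers — all scored by relay
  reliability, control energy, control reliability, and
  `reliability − cost_weight · energy`.

## Worked example

```python
from dbsloop.control import (ControllerSpec, TUNED_W_FEEDBACK,
                             PARKINSONIAN_SCENARIO, closed_loop_run)

for spec in (ControllerSpec(kind="none"),
             ControllerSpec(kind="perfect_dbs"),
             TUNED_W_FEEDBACK):
    res = closed_loop_run(spec, PARKINSONIAN_SCENARIO, seed=1)
    s = res.summary
    print(f"{spec.kind:12s} reliability={s['reliability']:.2f} "
          f"bad={s['n_bad']} energy={s['total_energy']:.0f}")
```

prints

```
none         reliability=0.40 bad=8 energy=0
perfect_dbs  reliability=0.50 bad=0 energy=800000
w_feedback   reliability=0.30 bad=11 energy=407735
```

Uncontrolled, the parkinsonian square-wave inhibition lets only 40% of
sensorimotor pulses through and produces 8 rebound ("bad") spikes at
the inhibition releases.  The oracle trough-filler restores half the
pulses and eliminates rebounds at an energy of 8.0e5 (squared drive
units on the 1 ms control grid).  The tuned availability-feedback
controller spends about half that energy; in this calibration its
relay reliability stays below the oracle's (see
`docs/methods.md` for why, and for every modelling choice).

There is also a CLI (`dbsloop simulate|track|control|sweep`) that
writes trajectory, estimate, metric and config-snapshot artifacts; a
run is reproducible bit-for-bit from its snapshot and seed.

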