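# ribofret

Single-molecule FRET analysis of ribosome intersubunit rotation, with a
ground-truth trace simulator for end-to-end validation.

## What it is for

Pre-translocation 80S ribosomes assembled on the CrPV IGR IRES exchange
between a semi-rotated and a non-rotated conformation, and the translocase
eEF2 drives both forward and reverse rotation. With a donor dye on the
small subunit (h44) and an acceptor on the large subunit (h101), this
exchange appears as two-state hopping of the FRET efficiency
E = I_A / (I_A + I_D) between ~0.22 (semi-rotated) and ~0.34 (non-rotated),
with the eEF2·GDPNP-locked fully rotated state near 0.17. `ribofret` turns
raw two-channel intensity trajectories of such experiments into kinetic
parameters:

- **trace processing** — background subtraction, ratiometric FRET,
  single-step photobleach QC, 60S-arrival detection with censoring;
- **idealization** — pooled Gaussian-emission HMM (EM + Viterbi) with
  penalized-likelihood state-count selection;
- **dwell kinetics** — censoring-, dead-time- and missed-event-aware
  exponential-mixture MLE of dwell times τ (single vs double exponential by
  BIC), pseudo-first-order arrival fits k_obs = k_on·[60S] with the
  bimolecular slope k_on in μM⁻¹s⁻¹, hyperbolic saturation
  k(c) = k_max·c/(K_half + c), rotating fractions, first-event times and
  wash-off transition counting;
- **FRET distributions** — one/two-component Gaussian decomposition and
  post-synchronized density heatmaps;
- **simulation** — an alternating-renewal trace generator (exponential-
  mixture dwells, static subpopulation, photobleaching, camera frame
  integration, detector noise) that carries its continuous-time ground
  truth, so every stage above is testable by parameter recovery.

Because camera integration hides dwells shorter than ~2 frames and every
hidden dwell merges its neighbors, the dwell estimator models the record
process explicitly (calibrated retention and duration-error kernels, and a
closed-form geometric-compound likelihood for merged dwells); see
`docs/methods.md` for the statistical details.

## Worked example

Simulate the spontaneous-rotation experiment (pre-formed 80S complexes
imaged at 25 ms) with 60 molecules and run the full analysis:

```python
import ribofret as rf

cfg = rf.generate_fixtures("figure2_spontaneous", n_molecules=60)
cfg.seed = 11
report = rf.run_pipeline(cfg, stages=("simulate", "process", "idealize", "kinetics"))

s = report["conditions"]["spontaneous_25ms"]
print(f"QC-passed molecules : {s['n_qc_passed']} / {cfg.conditions[0].n_molecules}")
print(f"FRET state means    : {s['hmm']['means'][0]:.3f} / {s['hmm']['means'][1]:.3f}")
print(f"rotating fraction   : {s['rotating_fraction']:.2f}")
print(f"transitions / trace : {s['transitions_per_trace']:.1f}")
for state, label in (("SEMI", "semi-rotated"), ("NON", "non-rotated")):
    d = s["dwells"][state]
    print(f"{label:>12s} dwell : mean {d['mean_corrected_s']:.2f} s "
          f"(model median {d['median_model_s']:.3f} s, {d['model']}, n = {d['n']})")
```

prints

```
QC-passed molecules : 60 / 60
FRET state means    : 0.220 / 0.339
rotating fraction   : 0.80
transitions / trace : 28.8
semi-rotated dwell : mean 0.83 s (model median 0.380 s, double-exp, n = 902)
 non-rotated dwell : mean 0.35 s (model median 0.042 s, double-exp, n = 772)
```

The simulator's ground truth for this fixture has state FRET 0.22 / 0.34,
a 17% static subpopulation, and dwell mixtures with means 0.97 s
(semi-rotated) and 0.38 s (non-rotated, median 0.05 s): the recovered
emission means are exact to ±0.001, and the dwell means land within
sampling error of truth at this reduced molecule count (the full 200-
molecule fixture tightens them further). The dwell `mean` shown is the
missed-event-aware mixture mean; `model median` is the fitted
distribution's implied median.

The same pipeline is scriptable from the shell:

```
ribofret fixtures figure2_spontaneous --out fig2.yaml
ribofret run fig2.yaml --seed 11 --outdir out/
```

which writes per-condition annotations, dwell tables, ground truth and a
machine-readable `summary.json` stamped with the configuration hash and
seed.

## Fixtures

`generate_fixtures(name)` builds calibrated, ready-to-run configurations
for the canonical experiment designs: `figure1_arrival` (60S delivery at
6.25/25/50 nM, k_on = 3.5 μM⁻¹s⁻¹, 70% active complexes),
`figure2_spontaneous` (spontaneous exchange at 25 ms),
`figure3_eef2` (eEF2 series 10–1000 nM, fast/slow plateaus 1.0/0.2 s⁻¹),
`figure4_sordarin` (20-fold lower saturation concentration),
`figure5_nucleotides` (GTP/GDP/GDPNP arms, static rotated state at
FRET 0.17) and `figure6_wash` (eEF2 wash-off at 30 s).

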