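# snarefret

Analysis pipeline for single-molecule FRET (smFRET) measurements of
NSF/αSNAP-mediated SNARE-complex disassembly and reassembly, together
with a synthetic-data generator that stands in for the microscope.

## The problem

In the smFRET disassembly assay, a SNARE complex carrying a donor and an
acceptor dye is tethered to a passivated surface and imaged in two
emission channels at 10 Hz for ~200 s. The assembled four-helix bundle
puts the dyes close together (high FRET efficiency, E ≈ 0.8); NSF-driven
disassembly separates them (low FRET, E ≈ 0.2). Each molecule's trace is
a noisy two-state (or three-state, for binary t-SNARE constructs) time
series interrupted by photobleaching, and the quantities of interest are
kinetic: how long the complex dwells assembled before disassembly, how
the short-/long-lived dwell populations shift with conditions, and what
fraction of molecules never transitions at all.

`snarefret` implements each stage of that analysis as a tested library:

- **`simulate`** — continuous-time Markov conformational dynamics with
  state-specific FRET, camera-frame integration, Gaussian noise, channel
  cross-talk, stochastic two-site labeling, and per-dye exponential
  photobleaching, with a ground-truth ledger per molecule.
- **`traceio`** — long-form CSV/TSV and HDF5 trace containers.
- **`fret`** — leakage correction by 2×2 linear unmixing
  (`observed = M·true`, `M = [[1−l_DA, l_AD], [l_DA, 1−l_AD]]`, default
  l_DA = 1.7%, l_AD = 16.5%), the proximity ratio
  `E = I_A / (I_A + I_D)`, automated photobleach detection, trace
  sectioning (first dwell / interior / final high-FRET dwell), molecule
  classification, point-wise FRET histograms and Gaussian-mixture fits.
- **`hmm`** — per-molecule Gaussian-emission hidden Markov idealization:
  Baum–Welch maximum likelihood (scaled forward–backward) and Viterbi
  decoding, states reported sorted by fitted mean.
- **`kinetics`** — section-II dwell-time extraction, linear/log-timescale
  histograms, short/long partitioning at the log-histogram local minimum
  (defaults 0.56 s high-FRET, 0.32 s low-FRET), and first-order
  exponential rate fits `A·exp(−kt)` (histogram least squares, with a
  left-truncated MLE cross-check).
- **`binding`** — the equilibrium isotherm `f = L/(K_d + L)` and the
  competition-assay normalization (ligand spots per tethered complex).

## Worked example

Simulate three fields of view of 60 molecules under the reference
conditions and analyze them end to end:

```bash
cat > run.yaml <<EOF
simulation:
  n_molecules_per_field: 60
  n_fields: 3
  seed: 7
EOF
snarefret simulate --config run.yaml --out-dir sim
snarefret analyze --traces sim/traces.csv --config run.yaml --out-dir out
cat out/kinetics_summary.csv
```

```
state_label,n_dwells,partition_threshold_s,short_population,long_population,population_sd,rate_per_s,mean_dwell_s,rate_method
low,395,0.32,0.04556962025,0.9544303797,0.01321150494,0.1790275863,5.585731342,lsq_histogram
high,332,0.56,0.05722891566,0.9427710843,0.01458266333,0.08593557266,11.63662461,lsq_histogram
```

Reading the output: 129 donor-visible molecules were classified
(excluded / without transitions / with transitions); the 63
transitioning molecules were idealized by the HMM and yielded 727
interior dwells. The high-FRET (assembled) state shows a fitted
disassembly rate of 0.086 s⁻¹ (mean dwell 11.6 s) against a generative
exit rate of 0.1 s⁻¹, and the low-FRET state 0.179 s⁻¹ against 0.2 s⁻¹;
the remaining gap reflects bleach censoring and finite sampling, which
the ground-truth ledger in `sim/ledger.csv` lets you quantify exactly.
`snarefret report --analysis-dir out --out-dir out` renders diagnostic
dwell-histogram plots, and `snarefret binding --kd 1.5 --conc 0.5
--conc 20 --out-dir out` tabulates isotherm occupancies.

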