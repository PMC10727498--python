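# sensilla

Analysis of single-sensillum tip recordings and capillary feeding assays
from bumblebee (*Bombus terrestris*) mouthparts, built to ask one
question: do the gustatory receptor neurons (GRNs) of the galea and
labial palps carry enough information to let a bee taste — and avoid —
pesticides dissolved in nectar?

The package implements the full analysis chain for this kind of
experiment, plus a synthetic-recording generator so every stage can be
exercised and benchmarked without access to raw recordings:

1. **Spike detection** (`sensilla.detect`) — 300–2500 Hz second-order
   Butterworth band-pass applied forward–backward (zero phase),
   normalisation by the 99.9th-percentile absolute value, peak detection
   above a per-recording threshold (default 4 × MAD noise SD).
2. **Galeal unit classification** (`sensilla.detect`) — galeal sensilla
   fire coherent bursts from two co-active GRNs. Interspike intervals
   segment the train into bursts; the end-of-burst (EOB) spike of each
   burst is attributed to Gal2 and intra-burst spikes to Gal1; a third,
   amplitude-distinct unit (Gal3) is split off by a robust amplitude
   criterion.
3. **Waveform sorting** (`sensilla.sort`) — labial-palp spikes are cut
   into ±2 ms peak-aligned windows, projected onto the first two SVD
   components, and assigned to one or two units by k-means, the
   larger-waveform unit labelled GRN1.
4. **Temporal features** (`sensilla.features`) — firing rates in ten
   0.1-s bins over 0.1–1.1 s, average rate and log10(rate + 1),
   ISI-regression adaptation slopes, burst length and burst rate,
   across-sensilla coefficients of variation, and the control-response
   exclusion rule.
5. **Population code** (`sensilla.population`) — per animal × stimulus,
   the binned responses of all 7 GRN types (Gal1–3, LPIII1–2, LPIV1–2)
   are normalised by the animal's control response and concatenated into
   a 70-value vector; t-SNE embeds the vectors in two dimensions and
   Monte Carlo reference-based consensus clustering (PAC/RCSI) decides
   how many stimulus groups are statistically distinguishable.
6. **Feeding assay** (`sensilla.feeding`) — capillary column lengths
   convert to volume as `100 µL × X mm / 60.0 mm`; proboscis contacts
   merge into feeding bouts unless separated by ≥ 5 s; first-bout and
   cumulative bout durations and ingested dose (ng) quantify deterrence.
7. **Inference** (`sensilla.stats`) — Gaussian mixed models with a
   random intercept per bee (electrophysiology) or colony (behaviour),
   Wald F tests, Tukey-adjusted pairwise contrasts and Dunnett
   many-to-one comparisons against the control.

The discriminability decision is the scientific heart: for each
candidate cluster count k, the proportion of ambiguous consensus entries
PAC(k) — consensus values in (0.1, 0.9) over 100 k-means runs on
80%-resampled data — is compared with reference datasets drawn from a
multivariate Gaussian matching the data's mean and principal-component
covariance. The relative cluster stability index

    RCSI(k) = ln( mean PAC_null(k) / PAC_real(k) )

selects k among the candidates whose PAC is significantly below the
null; if none is, the stimuli are declared indistinguishable (k = 1).

## Worked example

```python
from sensilla import simulate, pipeline

# 12 bees, 3 sensilla per mouthpart location, 5-s stimulations with the
# oilseed-rape nectar mimic (OSR, the control) vs equimolar sucrose
cfg = simulate.SimulationConfig(seed=11, effects=simulate.panel_osr_vs_suc())
recordings = simulate.simulate_dataset(cfg)          # 216 annotated traces

spikes, features = pipeline.analyze_dataset(recordings, seed=11)
vectors, report = pipeline.population_analysis(features, seed=11)
print(report.k_optimal)
print(report.stats.round(3))
```

prints

```
2
   k  PAC_real  PAC_null_mean   RCSI  p_value  p_empirical
0  2     0.000          0.561  8.632    0.000        0.038
1  3     0.464          0.672  0.371    0.017        0.038
2  4     0.478          0.621  0.261    0.017        0.038
3  5     0.478          0.555  0.148    0.090        0.077
```

The OSR and sucrose population codes separate perfectly at k = 2
(PAC_real = 0 — no ambiguous pairs at all, against a null PAC of ~0.56);
RCSI is maximal there, so two stimulus groups are reported. Running the
same pipeline with `simulate.panel_pesticides_field()` (pesticide rate
perturbations ≤ 5%) yields `k_optimal = 1`: the population code cannot
tell those solutions from plain nectar mimic.

A command-line interface wraps the same stages:

```bash
sensilla all --seed 11 --out artifacts/ --panel osr_vs_suc
sensilla simulate --seed 1 --out recs.h5 --panel quinine
sensilla detect --traces recs.h5 --out spikes.csv
```

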