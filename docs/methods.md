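# Methods

## What the simulator emulates

Tip recordings from bumblebee mouthpart taste sensilla capture the
summed extracellular spikes of the 2–4 GRNs a sensillum houses. The
generator reproduces the response phenomenology this analysis assumes,
per 5-s stimulation at 30 kHz:

* **Galeal sensilla** — coherent bursts: burst onsets follow a renewal
  process (gamma inter-onset intervals, shape 30) at a configured burst
  rate; each burst holds ≥ 1 intra-burst (Gal1) spike with
  narrow-gamma ISIs (shape 25) around the configured intra-burst ISI
  and is terminated by exactly one end-of-burst (Gal2) spike. A
  partially generated trailing burst is dropped so every emitted burst
  is structurally complete. A third, amplitude-distinct tonic unit
  (Gal3) is active only for stimuli that flag it (the control nectar
  mimic), because that unit responds to the sugar composition of the
  mimic and not to plain sucrose.
* **Labial-palp sensilla** — two tonic units (LP1, LP2) as renewal
  processes (gamma ISIs, shape 10) whose mean ISI grows linearly in
  time (the adaptation model; see below). LP1 has twice the waveform
  amplitude of LP2 and a higher rate.
* **Stimulus effects** are per-unit multipliers on rate, adaptation
  slope, and burst length, plus the Gal3 gate. The control stimulus has
  all multipliers at 1 by contract. Shipped panels encode the
  qualitative findings the pipeline must resolve: sucrose vs nectar
  mimic (≈ 20% burst-rate contrast, longer bursts, silent Gal3);
  quinine (1 mM suppresses everything, 0.1 mM silences the LP2 units
  and doubles adaptation); extreme (0.1 mM) pesticides (≤ 10% rate
  reductions, 1.5× LP adaptation); field-relevant pesticides (≤ 5%
  rate perturbations — deliberately sub-threshold).
* **Rendering** — each spike adds its unit's waveform template
  (difference-of-Gaussians biphasic shape, 2 ms support, dominant
  extremum centred) scaled by amplitude × noise SD; overlapping
  templates sum; white Gaussian noise is added.

Defaults (units): sample rate 30 000 Hz; duration 5 s; noise SD 0.2
trace units; burst rate 8 /s; 4 intra-burst spikes per burst;
intra-burst ISI 7 ms; tonic rates Gal3 15 /s, LP1 60 /s, LP2 35 /s
(rates are means over the full stimulation; with adaptation the first
second runs faster); adaptation slopes 2–8 ms of ISI per s; amplitudes
(in noise-SD units) Gal1 5, Gal2 4.5, Gal3 10, LP1 5, LP2 2.5 — i.e. a
raw SNR of 5 for the principal units; 12 bees and 3 sensilla per
mouthpart location (within the 2–4 of the emulated design).

Tonic trains with a rate target r and ISI slope s solve the initial
mean ISI m0 from ∫₀ᴰ dt/(m0 + s·t) = r·D, so the expected spike count
always matches the configured rate regardless of adaptation.

**What the generator does not emulate** — and what passing tests
therefore cannot certify about real recordings: contact/mechanical
artifacts at stimulus onset, line-frequency interference, electrode
drift, bursty noise, waveform change during bursts, overlapping-spike
decomposition, and receptor pharmacology. Unit labels on real data rest
on the same structural assumptions (bursts, amplitude separation) but
without ground truth.

## Detection and classification conventions

* Band-pass 300–2500 Hz, 2nd-order Butterworth, applied
  forward–backward (zero phase, same length).
* Normalisation divides by the 99.9th-percentile absolute value
  (scale-invariant; constant traces are rejected).
* Default threshold 4 × MAD-estimated noise SD; thresholds are
  per-recording parameters to mirror manual practice on real data.
* Refractory separation 2 ms: the band-pass image of a 2-ms biphasic
  spike carries secondary lobes (≈ 12–19% of the peak) within ±1.5 ms;
  peak detection keeps the taller of two close peaks, so this window
  suppresses lobe double-detections while preserving genuine ISIs
  (≥ 4 ms for every modelled unit).
* End-of-burst rule: an ISI > 60 ms closes a burst (configurable; the
  criterion is inherited from prior tip-recording work and no printed
  value exists, so 60 ms is this package's default).
* Gal3 criterion: spikes whose peak amplitude deviates > 3 robust SDs
  (1.4826 × MAD) from the median intra-burst amplitude, accepted as a
  third unit only when ≥ 5 spikes qualify; the remaining spikes are
  re-segmented so every burst still ends with exactly one Gal2 spike.
  The two-sided criterion is deliberate — a third unit could be smaller
  rather than larger.
* Waveform sorting accepts the 2-means split only when the mean
  silhouette exceeds 0.5, reproducing "two (or in some cases just one)
  units per recording" deterministically. SVD runs on row-centred
  windows. Galeal recordings never pass through waveform sorting; the
  location tag enforces this.

## Feature conventions

* Analysis window [0.1, 1.1) s; ten 0.1-s left-closed bins; the average
  rate is the mean of the bins, making avg = mean(bins) an identity.
* An ISI belongs to the bin containing its second spike (causal
  convention); the regression abscissa is the per-bin mean second-spike
  time, so noiseless linear-ISI trains are recovered exactly. LP
  adaptation pools the bin-wise mean ISIs across the four labial-palp
  GRNs before regressing.
* Burst rate counts end-of-burst (Gal2) spikes in the window, so
  burst_rate ≡ Gal2 average rate; burst length averages Gal1 spikes per
  burst over bursts closing in the window.
* Across-sensilla CV uses the population-SD convention (n denominator).
* Exclusion rule: a sensillum whose summed control-stimulus rate is
  below 5 spikes/s is a non-responder and is removed from every
  stimulus (the emulated protocol states the rule but not the floor;
  5 /s is this package's quantification).

## Population code and the cluster-count decision

Vectors concatenate the 10-bin time courses of the 7 GRN types in fixed
order (Gal1, Gal2, Gal3, LPIII1, LPIII2, LPIV1, LPIV2), each divided by
the animal's mean control response for that GRN and averaged across
sensilla: 70 entries. A GRN silent under the control (or absent)
contributes zeros and is flagged, never imputed — silence is signal
here (Gal3 responds only to the nectar mimic).

t-SNE (exact gradients, PCA initialisation, Euclidean metric, fixed
seed) embeds the vectors in 2-d; default perplexity min(10, (n−1)/3)
suits the tens-of-animals sample sizes.

Consensus clustering: for k = 2…5, 100 k-means runs on random 80% row
subsets build a consensus matrix; PAC is the fraction of pair entries
in (0.1, 0.9). Twenty-five reference datasets — multivariate Gaussians
with the data's mean and principal-component covariance — yield a null
PAC sample per k. RCSI = ln(mean null PAC / observed PAC) (PACs floored
at 1e-4), and the p-value is the beta-distribution fit to the null
sample evaluated at the observed PAC, with the raw Monte-Carlo tail
proportion reported alongside. The beta fit extrapolates beyond the
resolution of 25 references; with a small point set a reference run is
occasionally itself perfectly stable (PAC = 0), and a raw tail
proportion would then never reach significance even for a perfectly
separated real clustering. k_optimal maximises RCSI among k with
p < 0.05, else 1; labels (k-means, 10 restarts, sized-ordered ids) are
attached only when k_optimal > 1.

The cluster-count decision runs on the raw 70-d vectors by default, not
on the embedding. Embeddings of a few tens of points form apparent
clumps even for structureless data, and a Gaussian null fit in
embedding space declares them significant (the null pesticide panel
came out k = 3–4 on the embedding, k = 1 on the vectors); the embedding
is retained for display and for the cluster shading. `on_embedding=True`
restores the alternative and is recorded in the report.

## Feeding assay

Volume = 100 µL × length / 60.0 mm, exact and linear; round-trip
length↔volume is identity. A gap of exactly 5 s terminates a bout
(strict "5 s or more" rule). Bout duration spans first contact start to
last contact end, including sub-5-s pauses; the contact-time-only sum
is reported alongside as a sensitivity variant. Dose (ng) = volume (µL)
× concentration (µM) × molar mass (g/mol) × 10⁻³, with a small built-in
molar-mass table (imidacloprid 255.66, thiamethoxam 291.71,
clothianidin 249.68, sulfoxaflor 277.27, quinine·HCl·2H₂O 396.91).

The trial simulator is an alternating renewal process: exponential
latency (mean 5 s), exponential bout lengths (mean 30 s), inter-bout
pauses of 5 s plus an exponential (mean 10 s), constant intake rate
0.6 µL/s while in contact; a deterrence factor in (0, 1] multiplies
bout length and intake rate. Trials are capped at the 120-s window and
the 100-µL capillary.

## Inference

Gaussian linear mixed models with a random intercept for bee
(electrophysiology) or colony (behaviour), fit by REML; fixed-effect
terms are tested with Wald F statistics using denominator df = n − p
(the number of fixed-effect parameters). This residual-df approximation
was chosen because the mixed-model machinery used here does not provide
Satterthwaite df; on balanced designs of this size the two agree
closely (a cross-check against an independent lmerTest fit is part of
the test suite), and the approximation is recorded in the output. A
non-significant interaction (p ≥ 0.05) triggers an additive refit which
is then reported; for concentration-gradient models an information
criterion rule (drop the interaction iff both AIC and BIC improve) is
available. Singular random-effect fits fall back to OLS with a logged
note. Pairwise contrasts of estimated marginal means use Tukey's
studentized-range adjustment; many-to-one comparisons against the
control use Dunnett's multivariate-t test on the group observations.
Behavioural responses are log10(x+1)-transformed when a Shapiro test on
OLS residuals rejects normality at 0.01, and the transform is recorded.
Asterisk bands follow the convention *, p < 0.05; **, p < 0.001; ***,
p < 0.0001.

## Problem sizes

Default experiment sizes (12 bees × 3 locations × 3 sensilla ×
stimuli, 5-s traces) were chosen to match the emulated design while
keeping a full pipeline run at seconds on one CPU. The discriminability
summaries report the modal cluster count over 20 independently seeded
end-to-end runs.

## Known limitations

* The consensus p-value is parametric beyond 25 references; with very
  small point sets (~20) a familywise excess of k > 1 decisions of
  roughly 10–20% remains across the four candidate k — the modal-run
  reporting absorbs this.
* Overlapping spikes are detected as single events; unit labels near
  coincidences are unreliable. Burst segmentation degrades when
  inter-burst gaps approach the 60-ms criterion.
* The Wald-F residual-df approximation is anti-conservative for
  severely unbalanced designs; the fallback OLS route ignores the
  random effect entirely (it is logged).
* The simulator's stimulus effects are qualitative presets with
  configurable magnitudes, not fitted to any recording.
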