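"""Synthetic tip-recording generator.

Emulates the statistical structure of bumblebee mouthpart recordings:
galeal sensilla produce coherent spike bursts from two co-active GRNs
(intra-burst spikes from Gal1, one end-of-burst spike from Gal2) plus a
third, large-amplitude unit (Gal3) active only for some stimuli; labial
palp sensilla house two tonically firing GRNs with linearly lengthening
interspike intervals (adaptation) and distinct waveform amplitudes.

The generator produces 5-s, 30-kHz voltage traces with ground-truth spike
times and unit labels, so every downstream stage can be benchmarked
without real recordings.  Bursts are a renewal process at a configured
burst rate; tonic trains are renewal processes whose mean ISI grows
linearly in time.  Noise is white Gaussian; no line-frequency or contact
artifacts are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import LOCATIONS, Recording, VoltageTrace

# Gamma-shape parameters of the renewal processes: large shape = regular.
_INTRA_BURST_SHAPE = 25.0  # narrow gamma around the intra-burst ISI
_INTER_BURST_SHAPE = 30.0
_TONIC_SHAPE = 10.0


@dataclass(frozen=True)
class BurstParams:
    """Burst structure of a galeal unit pair (Gal1 intra-burst, Gal2 EOB)."""

    mean_spikes_per_burst: float = 4.0
    intra_burst_isi: float = 0.007  # s
    burst_rate: float = 8.0  # bursts/s

    def __post_init__(self) -> None:
        span = self.intra_burst_isi * self.mean_spikes_per_burst
        if span >= 1.0 / self.burst_rate:
            raise ValueError("burst span must be shorter than the burst period")


@dataclass(frozen=True)
class GRNArchetype:
    """Response archetype of one GRN class.

    ``amplitude`` is the waveform peak height relative to the trace noise
    SD; ``adaptation_slope`` is the growth of the mean ISI (s of ISI per s
    of stimulation).  Galeal bursting units carry ``burst_params``; tonic
    units (Gal3, LP1, LP2) do not.
    """

    name: str
    base_rate: float  # spikes/s
    adaptation_slope: float = 0.0
    amplitude: float = 1.0
    burst_params: BurstParams | None = None
    # waveform template shape knobs (difference of Gaussians, see template())
    pos_width_ms: float = 0.15
    neg_width_ms: float = 0.30
    neg_delay_ms: float = 0.40
    neg_frac: float = 0.6

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")

    def template(self, sample_rate: float, half_support_ms: float = 1.0) -> np.ndarray:
        """Biphasic waveform template, 2 ms support, unit positive peak."""
        half = int(round(half_support_ms * 1e-3 * sample_rate))
        t = np.arange(-half, half + 1) / sample_rate * 1e3  # ms
        pos = np.exp(-0.5 * (t / self.pos_width_ms) ** 2)
        neg = np.exp(-0.5 * ((t - self.neg_delay_ms) / self.neg_width_ms) ** 2)
        w = pos - self.neg_frac * neg
        w = np.roll(w, half - int(np.argmax(w)))  # dominant extremum centred
        return w / np.max(np.abs(w))


@dataclass(frozen=True)
class StimulusEffect:
    """Per-stimulus modulation of the archetype responses.

    Multipliers are keyed by archetype name; absent keys mean 1 (no
    change).  ``rate`` scales firing/burst rate (0 = full suppression),
    ``adaptation`` scales the ISI growth slope, ``burst_length`` scales
    the mean number of intra-burst spikes.  ``gal3_active`` gates the
    third galeal unit, which responds only to some stimuli.
    """

    stimulus: str
    rate: dict[str, float] = field(default_factory=dict)
    adaptation: dict[str, float] = field(default_factory=dict)
    burst_length: dict[str, float] = field(default_factory=dict)
    gal3_active: bool = True

    def rate_multiplier(self, name: str) -> float:
        m = self.rate.get(name, 1.0)
        if m < 0:
            raise ValueError("rate multiplier must be >= 0")
        return m

    def adaptation_multiplier(self, name: str) -> float:
        m = self.adaptation.get(name, 1.0)
        if m <= 0:
            raise ValueError("adaptation multiplier must be > 0")
        return m

    def burst_length_multiplier(self, name: str) -> float:
        return self.burst_length.get(name, 1.0)


CONTROL_STIMULUS = "OSR"


def default_archetypes() -> dict[str, GRNArchetype]:
    """Archetype set for the five GRN classes.

    Rates are in the range seen for sugar responses of bumblebee mouthpart
    GRNs (tens of spikes/s over the first second); amplitudes are relative
    to the noise SD, with the larger-waveform unit of each labial palp
    sensillum (LP1) twice the height of LP2 and Gal3 clearly taller than
    the bursting pair.
    """
    bp = BurstParams(mean_spikes_per_burst=4.0, intra_burst_isi=0.007, burst_rate=8.0)
    return {
        "Gal1": GRNArchetype(
            "Gal1",
            base_rate=bp.mean_spikes_per_burst * bp.burst_rate,
            adaptation_slope=0.002,
            amplitude=5.0,
            burst_params=bp,
        ),
        "Gal2": GRNArchetype("Gal2", base_rate=bp.burst_rate, amplitude=4.5,
                             neg_delay_ms=0.35),
        "Gal3": GRNArchetype("Gal3", base_rate=15.0, adaptation_slope=0.004,
                             amplitude=10.0, pos_width_ms=0.18),
        "LP1": GRNArchetype("LP1", base_rate=60.0, adaptation_slope=0.008,
                            amplitude=5.0),
        "LP2": GRNArchetype("LP2", base_rate=35.0, adaptation_slope=0.008,
                            amplitude=2.5, pos_width_ms=0.20, neg_width_ms=0.40),
    }


# ---------------------------------------------------------------------------
# Stimulus panels.  The control (10% OSR) always has all multipliers = 1.
# ---------------------------------------------------------------------------

def panel_osr_vs_suc() -> list[StimulusEffect]:
    """OSR nectar mimic vs equimolar sucrose.

    Relative to OSR, sucrose yields a ~20% lower burst rate, longer
    bursts, and a silent Gal3.
    """
    return [
        StimulusEffect(CONTROL_STIMULUS),
        StimulusEffect(
            "SUC",
            rate={"Gal1": 1 / 1.2},
            burst_length={"Gal1": 1.2},
            gal3_active=False,
        ),
    ]


def panel_quinine() -> list[StimulusEffect]:
    """Quinine dose series in an OSR background.

    1 mM suppresses every GRN; 0.1 mM silences the LP2 units and speeds
    labial-palp and Gal1 adaptation.
    """
    return [
        StimulusEffect(CONTROL_STIMULUS),
        StimulusEffect(
            "QUI 0.1",
            rate={"LP2": 0.0},
            adaptation={"LP1": 2.0, "Gal1": 2.0},
        ),
        StimulusEffect(
            "QUI 1",
            rate={name: 0.0 for name in ("Gal1", "Gal2", "Gal3", "LP1", "LP2")},
        ),
    ]


def panel_pesticides_extreme() -> list[StimulusEffect]:
    """0.1 mM pesticides in OSR background: slight rate/adaptation shifts."""
    return [
        StimulusEffect(CONTROL_STIMULUS),
        StimulusEffect("CLO 0.1mM", rate={"Gal1": 0.95}),
        StimulusEffect(
            "IMD 0.1mM",
            rate={"Gal1": 0.95, "LP1": 0.9, "LP2": 0.9},
            adaptation={"LP1": 1.5, "LP2": 1.5},
        ),
        StimulusEffect("SFX 0.1mM"),
        StimulusEffect(
            "TMX 0.1mM", rate={"LP1": 0.9, "LP2": 0.9},
            adaptation={"LP1": 1.5, "LP2": 1.5},
        ),
    ]


def panel_pesticides_field() -> list[StimulusEffect]:
    """Field-relevant (nM) pesticides: sub-threshold rate perturbations.

    All multipliers within 5% of the control; the population code should
    not be discriminable from OSR alone.
    """
    return [
        StimulusEffect(CONTROL_STIMULUS),
        StimulusEffect("CLO 100nM", rate={"Gal1": 0.98}),
        StimulusEffect("IMD 100nM", rate={"Gal1": 0.97, "LP1": 0.98}),
        StimulusEffect("SFX 100nM", rate={"LP2": 0.99}),
        StimulusEffect("TMX 100nM", rate={"LP1": 0.96}),
    ]


@dataclass
class SimulationConfig:
    """Reproducible description of one simulated experiment."""

    seed: int
    sample_rate: float = 30_000.0
    duration: float = 5.0  # s of stimulation per trace
    noise_sd: float = 0.2
    archetypes: dict[str, GRNArchetype] = field(default_factory=default_archetypes)
    effects: list[StimulusEffect] = field(default_factory=panel_osr_vs_suc)
    n_bees: int = 12
    sensilla_per_location: int = 3

    def __post_init__(self) -> None:
        if self.duration < 1.1:
            raise ValueError("duration must be >= 1.1 s (analysis window)")
        if self.n_bees < 1:
            raise ValueError("n_bees must be >= 1")
        stimuli = [e.stimulus for e in self.effects]
        if CONTROL_STIMULUS not in stimuli:
            raise ValueError("effects must include the control stimulus")


# ---------------------------------------------------------------------------
# Spike-train generation
# ---------------------------------------------------------------------------

def _gamma_isi(rng: np.random.Generator, mean: float, shape: float) -> float:
    return rng.gamma(shape, mean / shape)


def _tonic_initial_isi(rate: float, slope: float, duration: float) -> float:
    """Initial mean ISI so the expected spike count is rate * duration.

    With mean ISI m(t) = m0 + slope*t, the expected count over [0, D] is
    integral of 1/m(t) = ln((m0 + slope*D)/m0)/slope; solve for m0.
    """
    if slope < 1e-12:
        return 1.0 / rate
    target = rate * duration

    def f(m0: float) -> float:
        return np.log((m0 + slope * duration) / m0) / slope - target

    lo, hi = 1e-6, 10.0 / rate
    while f(hi) > 0:
        hi *= 2
    return brentq(f, lo, hi)


def _tonic_train(
    rate: float, slope: float, duration: float, rng: np.random.Generator,
    shape: float = _TONIC_SHAPE,
) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    m0 = _tonic_initial_isi(rate, slope, duration)
    times: list[float] = []
    t = _gamma_isi(rng, m0, shape)
    while t < duration:
        times.append(t)
        t += _gamma_isi(rng, m0 + slope * t, shape)
    return np.asarray(times)


def _burst_train(
    bp: BurstParams,
    rate_mult: float,
    length_mult: float,
    adapt_slope: float,
    duration: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate (gal1_times, gal2_times) for one galeal sensillum.

    Burst onsets follow a renewal process at the effective burst rate;
    each burst holds >= 1 Gal1 spike at narrow-gamma intra-burst ISIs and
    is terminated by exactly one Gal2 (end-of-burst) spike.  A partially
    generated burst that would overrun the trace is dropped so every
    emitted burst is structurally complete.
    """
    burst_rate = bp.burst_rate * rate_mult
    if burst_rate <= 0:
        return np.empty(0), np.empty(0)
    mean_n = max(1.0, bp.mean_spikes_per_burst * length_mult)
    period = 1.0 / burst_rate
    span = mean_n * bp.intra_burst_isi
    gap_mean = max(period - span, 0.2 * period)

    gal1: list[float] = []
    gal2: list[float] = []
    onset = _gamma_isi(rng, gap_mean, _INTER_BURST_SHAPE)
    while onset < duration:
        isi = bp.intra_burst_isi + adapt_slope * onset
        n1 = 1 + rng.poisson(mean_n - 1.0)
        t = onset
        members = [t]
        for _ in range(n1 - 1):
            t += _gamma_isi(rng, isi, _INTRA_BURST_SHAPE)
            members.append(t)
        eob = t + _gamma_isi(rng, isi, _INTRA_BURST_SHAPE)
        if eob >= duration:
            break  # drop incomplete trailing burst
        gal1.extend(members)
        gal2.append(eob)
        onset = eob + _gamma_isi(rng, gap_mean, _INTER_BURST_SHAPE)
    return np.asarray(gal1), np.asarray(gal2)


def simulate_spike_train(
    archetype: GRNArchetype,
    effect: StimulusEffect,
    duration: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Ground-truth spike train for one archetype under one stimulus.

    Returns a table with columns ``time_s`` and ``unit``.  For a bursting
    (galeal) archetype the table holds both the intra-burst Gal1 spikes
    and the end-of-burst Gal2 spikes; tonic archetypes yield a single
    unit.  Gal3 is emitted only when the stimulus activates it.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    name = archetype.name
    if archetype.burst_params is not None:
        slope = archetype.adaptation_slope * effect.adaptation_multiplier("Gal1")
        g1, g2 = _burst_train(
            archetype.burst_params,
            effect.rate_multiplier(name),
            effect.burst_length_multiplier(name),
            slope,
            duration,
            rng,
        )
        times = np.concatenate([g1, g2])
        units = np.array(["Gal1"] * g1.size + ["Gal2"] * g2.size, dtype=object)
        order = np.argsort(times, kind="stable")
        return pd.DataFrame({"time_s": times[order], "unit": units[order]})
    if name == "Gal3" and not effect.gal3_active:
        return pd.DataFrame({"time_s": np.empty(0), "unit": np.empty(0, dtype=object)})
    rate = archetype.base_rate * effect.rate_multiplier(name)
    slope = archetype.adaptation_slope * effect.adaptation_multiplier(name)
    times = _tonic_train(rate, slope, duration, rng)
    return pd.DataFrame(
        {"time_s": times, "unit": np.full(times.size, name, dtype=object)}
    )


# ---------------------------------------------------------------------------
# Trace rendering
# ---------------------------------------------------------------------------

def render_trace(
    trains: pd.DataFrame,
    config: SimulationConfig,
    location: str,
    rng: np.random.Generator,
    bee_id: str = "",
    sensillum_id: str = "",
    stimulus: str = "",
) -> Recording:
    """Render ground-truth trains to a noisy voltage trace.

    Each spike adds its archetype's waveform template (scaled by the
    archetype amplitude, in units of the noise SD) at the spike's sample
    index; overlapping templates sum.  White Gaussian noise of
    ``config.noise_sd`` is then added.
    """
    n = int(round(config.duration * config.sample_rate))
    trace = np.zeros(n)
    bad = trains["time_s"].to_numpy() >= config.duration
    if bad.any():
        raise ValueError("spike times must be < duration")
    for unit, sub in trains.groupby("unit", sort=False):
        arch = config.archetypes[str(unit)]
        tmpl = arch.template(config.sample_rate) * arch.amplitude * config.noise_sd
        if config.noise_sd == 0:  # noiseless: keep amplitude meaningful
            tmpl = arch.template(config.sample_rate) * arch.amplitude
        half = (tmpl.size - 1) // 2
        idx = np.round(sub["time_s"].to_numpy() * config.sample_rate).astype(int)
        for i in idx:
            lo, hi = i - half, i + half + 1
            tlo, thi = max(0, -lo), tmpl.size - max(0, hi - n)
            trace[max(0, lo) : min(n, hi)] += tmpl[tlo:thi]
    if config.noise_sd > 0:
        trace = trace + rng.normal(0.0, config.noise_sd, size=n)
    vt = VoltageTrace(
        samples=trace,
        sample_rate=config.sample_rate,
        location=location,
        bee_id=bee_id,
        sensillum_id=sensillum_id,
        stimulus=stimulus,
    )
    truth = trains.sort_values("time_s", kind="stable").reset_index(drop=True)
    return Recording(trace=vt, truth=truth)


def _sensillum_trains(
    config: SimulationConfig,
    location: str,
    effect: StimulusEffect,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Trains of all GRNs housed in one sensillum at ``location``."""
    arch = config.archetypes
    if location == "Gal":
        parts = [simulate_spike_train(arch["Gal1"], effect, config.duration, rng)]
        parts.append(simulate_spike_train(arch["Gal3"], effect, config.duration, rng))
    else:
        parts = [
            simulate_spike_train(arch["LP1"], effect, config.duration, rng),
            simulate_spike_train(arch["LP2"], effect, config.duration, rng),
        ]
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values("time_s", kind="stable").reset_index(drop=True)


def simulate_dataset(config: SimulationConfig) -> list[Recording]:
    """Simulate bees x locations x sensilla x stimuli annotated traces.

    Deterministic under ``config.seed``: every trace derives its RNG from
    a seed-sequence child keyed by its position in the fixed iteration
    order, so the same config always yields bit-identical data.  Every
    sensillum is recorded under the control stimulus (required downstream
    for normalisation and the non-responder exclusion rule).
    """
    recordings: list[Recording] = []
    root = np.random.SeedSequence(config.seed)
    n_per = len(LOCATIONS) * config.sensilla_per_location * len(config.effects)
    children = root.spawn(config.n_bees * n_per)
    i = 0
    for b in range(config.n_bees):
        bee = f"bee{b:02d}"
        for location in LOCATIONS:
            for s in range(config.sensilla_per_location):
                sens = f"{location}-s{s}"
                for effect in config.effects:
                    rng = np.random.default_rng(children[i])
                    i += 1
                    trains = _sensillum_trains(config, location, effect, rng)
                    recordings.append(
                        render_trace(
                            trains,
                            config,
                            location,
                            rng,
                            bee_id=bee,
                            sensillum_id=sens,
                            stimulus=effect.stimulus,
                        )
                    )
    return recordings
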