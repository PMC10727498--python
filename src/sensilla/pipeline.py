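"""End-to-end orchestration of the recording analysis.

``process_recording`` runs one trace through filtering, detection and
unit assignment (burst structure on the galea, waveform sorting on the
labial palps) and returns the labelled spike table.  ``analyze_dataset``
maps a whole recording collection to per-sensillum features, and
``population_analysis`` carries those into population vectors and the
consensus-clustering discriminability decision.  ``run_pipeline``
executes every stage from a config dict and writes CSV/JSON artifacts
plus a manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect, features, population, simulate, sort, stats
from .core import Recording, spike_table
from .detect import DEFAULT_ISI_THRESHOLD_S
from .feeding import DeterrenceParams, simulate_trials, summarize_trial

log = logging.getLogger(__name__)

PANELS = {
    "osr_vs_suc": simulate.panel_osr_vs_suc,
    "quinine": simulate.panel_quinine,
    "pesticides_extreme": simulate.panel_pesticides_extreme,
    "pesticides_field": simulate.panel_pesticides_field,
}


def process_recording(
    rec: Recording,
    threshold: float | None = None,
    isi_threshold: float = DEFAULT_ISI_THRESHOLD_S,
    seed: int = 0,
) -> pd.DataFrame:
    """Filter, detect and label one recording; returns a spike table.

    Unit names are location-qualified: Gal1/Gal2/Gal3 on the galea (from
    burst structure and the amplitude criterion), LPIII1/LPIII2 or
    LPIV1/LPIV2 on the palps (from waveform sorting; the larger-waveform
    unit is 1).  Spikes within 2 ms of a trace edge are dropped by the
    waveform path.
    """
    trace = rec.trace
    filtered = detect.bandpass_filter(trace)
    normalized = detect.normalize_trace(filtered)
    train = detect.detect_spikes(normalized, threshold=threshold)
    if len(train) == 0:
        return spike_table(trace, np.empty(0), np.empty(0), np.empty(0, dtype=object))
    if trace.location == "Gal":
        labels, _ = detect.classify_galeal(train, isi_threshold=isi_threshold)
        return spike_table(trace, train.times, train.peak_amplitudes, labels.labels)
    result = sort.sort_lp_recording(normalized, train, seed=seed)
    kept = result.spike_indices
    units = np.array(
        [f"{trace.location}{1 if l == 'GRN1' else 2}" for l in result.labels],
        dtype=object,
    )
    return spike_table(
        trace, train.times[kept], train.peak_amplitudes[kept], units
    )


def analyze_dataset(
    recordings: list[Recording],
    threshold: float | None = None,
    isi_threshold: float = DEFAULT_ISI_THRESHOLD_S,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spike tables and per-sensillum features for a recording collection."""
    tables = []
    feature_parts = []
    for rec in recordings:
        t = rec.trace
        spikes = process_recording(
            rec, threshold=threshold, isi_threshold=isi_threshold, seed=seed
        )
        tables.append(spikes)
        meta = {
            "bee": t.bee_id,
            "location": t.location,
            "sensillum": t.sensillum_id,
            "stimulus": t.stimulus,
        }
        feature_parts.append(
            features.recording_features(spikes, t.duration, meta=meta)
        )
    return (
        pd.concat(tables, ignore_index=True),
        pd.concat(feature_parts, ignore_index=True),
    )


def population_analysis(
    sensillum_features: pd.DataFrame,
    control: str = simulate.CONTROL_STIMULUS,
    seed: int = 0,
    maxk: int = population.DEFAULT_MAXK,
    on_embedding: bool = False,
) -> tuple[pd.DataFrame, population.ClusteringReport]:
    """Exclusion, population vectors and the discriminability decision."""
    filtered, exclusions = features.exclude_nonresponders(
        sensillum_features, control=control
    )
    if not exclusions.empty:
        log.info("excluded %d non-responding sensilla", len(exclusions))
    vectors, flags = population.build_population_vectors(filtered, control=control)
    report = population.discriminability(
        vectors, seed=seed, maxk=maxk, on_embedding=on_embedding
    )
    report.params["n_flagged_grns"] = len(flags)
    return vectors, report


def run_discriminability(
    panel: str,
    seed: int,
    n_bees: int = 12,
    sensilla_per_location: int = 3,
) -> int:
    """Simulate one experiment with a stimulus panel and return the
    consensus-selected cluster count of its population code."""
    cfg = simulate.SimulationConfig(
        seed=seed,
        effects=PANELS[panel](),
        n_bees=n_bees,
        sensilla_per_location=sensilla_per_location,
    )
    recordings = simulate.simulate_dataset(cfg)
    _, sens_features = analyze_dataset(recordings, seed=seed)
    _, report = population_analysis(sens_features, seed=seed)
    return int(report.k_optimal)


def grn_census(seed: int, n_bees: int = 4, sensilla_per_location: int = 2) -> set[str]:
    """Distinct GRN classes recovered across the three sensillum locations.

    Simulates a control-stimulus dataset in which every archetype is
    active (the third galeal unit responds to the control) and runs the
    full unit-classification path: burst-structure classification on the
    galea, waveform sorting on the labial palps.
    """
    cfg = simulate.SimulationConfig(
        seed=seed,
        effects=[simulate.StimulusEffect(simulate.CONTROL_STIMULUS)],
        n_bees=n_bees,
        sensilla_per_location=sensilla_per_location,
    )
    recordings = simulate.simulate_dataset(cfg)
    spikes, _ = analyze_dataset(recordings, seed=seed)
    counts = spikes["unit"].value_counts()
    # a class must be supported by more than stray misassignments
    return set(counts[counts >= 10].index.astype(str))


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute simulate -> detect/sort -> features -> population ->
    behaviour stages from a config mapping; returns the manifest.

    Mandatory config key: ``seed``.  Optional keys: ``panel`` (one of
    osr_vs_suc, quinine, pesticides_extreme, pesticides_field), sizes
    (``n_bees``, ``sensilla_per_location``, ``duration``), detection
    (``isi_threshold``), clustering (``maxk``) and behaviour
    (``deterrence`` mapping stimulus -> multiplier, ``n_per_group``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    panel_name = config.get("panel", "osr_vs_suc")
    effects = PANELS[panel_name]()

    sim_config = simulate.SimulationConfig(
        seed=seed,
        duration=float(config.get("duration", 5.0)),
        noise_sd=float(config.get("noise_sd", 0.2)),
        effects=effects,
        n_bees=int(config.get("n_bees", 12)),
        sensilla_per_location=int(config.get("sensilla_per_location", 3)),
    )
    recordings = simulate.simulate_dataset(sim_config)
    spikes, sens_features = analyze_dataset(
        recordings,
        isi_threshold=float(config.get("isi_threshold", DEFAULT_ISI_THRESHOLD_S)),
        seed=seed,
    )
    spikes.to_csv(outdir / "spikes.csv", index=False)
    sens_features.to_csv(outdir / "features_sensillum.csv", index=False)
    animal = features.average_across_sensilla(sens_features)
    animal.to_csv(outdir / "features_animal.csv", index=False)

    vectors, report = population_analysis(
        sens_features, seed=seed, maxk=int(config.get("maxk", population.DEFAULT_MAXK))
    )
    vectors.to_csv(outdir / "population_vectors.csv", index=False)
    report.stats.to_csv(outdir / "consensus_stats.csv", index=False)

    deterrence = config.get(
        "deterrence", {"OSR": 1.0, "QUI 1": 0.1}
    )
    groups = {k: DeterrenceParams(deterrence=float(v)) for k, v in deterrence.items()}
    trials = simulate_trials(groups, int(config.get("n_per_group", 15)), seed=seed + 1)
    behaviour = pd.DataFrame(
        [
            {
                "bee": t.bee_id,
                "colony": t.colony_id,
                "stimulus": t.stimulus,
                **asdict(summarize_trial(t)),
            }
            for t in trials
        ]
    )
    behaviour.to_csv(outdir / "behaviour.csv", index=False)

    # inference: stimulus x GRN comparison of log rates, and Dunnett
    # contrasts of consumed volume against the control stimulus
    comparison = stats.fit_compare(
        animal.dropna(subset=["log_avg_rate"]),
        stats.ModelSpec(
            response="log_avg_rate",
            fixed=["stimulus", "grn_type"],
            random_intercept="bee",
        ),
    )
    comparison.anova.to_csv(outdir / "anova.csv", index=False)
    comparison.contrasts.to_csv(outdir / "contrasts.csv", index=False)
    control = simulate.CONTROL_STIMULUS
    if behaviour["stimulus"].nunique() > 1 and control in set(behaviour["stimulus"]):
        stats.dunnett_vs_control(
            behaviour, "volume_uL", "stimulus", control
        ).to_csv(outdir / "behaviour_dunnett.csv", index=False)

    manifest = {
        "seed": seed,
        "panel": panel_name,
        "n_recordings": len(recordings),
        "n_spikes": int(len(spikes)),
        "n_feature_rows": int(len(sens_features)),
        "n_population_vectors": int(len(vectors)),
        "k_optimal": int(report.k_optimal),
        "consensus_params": {
            k: v for k, v in report.params.items() if k != "pac_window"
        },
        "n_behaviour_trials": int(len(behaviour)),
        "anova_model": comparison.model_used,
        "stages": ["simulate", "detect", "sort", "features", "popcode",
                   "behaviour", "inference"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
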