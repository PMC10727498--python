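"""Per-GRN response descriptors.

All rate descriptors use the analysis window [0.1, 1.1) s after stimulus
contact: firing rates are counted in ten 0.1-s bins, the average rate is
the mean of the bins (so the two agree exactly), and the log transform is
log10(rate + 1).  Adaptation is the slope of the mean interspike interval
per 0.1-s bin regressed on time; galeal burst structure is summarised by
the burst length (Gal1 spikes per burst) and the burst rate (= Gal2
rate).  Features are computed per sensillum and then averaged across the
sensilla of each animal, with the across-sensilla coefficient of
variation retained as a replicate-consistency measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW_START = 0.1
BIN_WIDTH = 0.1
N_BINS = 10
WINDOW_END = WINDOW_START + N_BINS * BIN_WIDTH  # 1.1 s
BIN_COLUMNS = [f"bin_{i}" for i in range(N_BINS)]
#: A sensillum "responds" to the control if its total firing rate reaches
#: this floor (spikes/s); non-responders are excluded from all stimuli.
RESPONSE_FLOOR = 5.0

GALEAL_UNITS = ("Gal1", "Gal2", "Gal3")


def bin_rates(times: np.ndarray, duration: float) -> np.ndarray:
    """Firing rate (spikes/s) in ten 0.1-s bins spanning [0.1, 1.1) s.

    Bins are half-open, left-closed: a spike at exactly a bin edge counts
    in the bin it opens.  Recordings shorter than the window are an
    error, never silently truncated.
    """
    if duration < WINDOW_END:
        raise ValueError(
            f"recording of {duration} s does not cover the {WINDOW_END} s window"
        )
    times = np.asarray(times, dtype=float)
    edges = WINDOW_START + BIN_WIDTH * np.arange(N_BINS + 1)
    counts, _ = np.histogram(times, bins=edges)
    return counts / BIN_WIDTH


def average_rate(binned: np.ndarray) -> float:
    return float(np.mean(binned))


def log_rate(avg: float) -> float:
    return float(np.log10(avg + 1.0))


@dataclass
class AdaptationFit:
    slope: float  # s of ISI per s of stimulation
    se: float
    n_bins: int


def adaptation_slope(times: np.ndarray) -> AdaptationFit | None:
    """OLS slope of mean ISI per 0.1-s bin against bin-centre time.

    Each interspike interval is assigned to the bin containing the second
    spike of the pair (causal convention); the regression abscissa is the
    mean second-spike time of each bin, so a train whose ISI grows
    exactly linearly in time is recovered without binning bias.  Returns
    None when fewer than two bins contain an ISI — e.g. under strong
    suppression there is insufficient spiking to calculate adaptation.
    """
    times = np.sort(np.asarray(times, dtype=float))
    if times.size < 3:
        return None
    isis = np.diff(times)
    second = times[1:]
    keep = (second >= WINDOW_START) & (second < WINDOW_END)
    if keep.sum() < 2:
        return None
    bins = ((second[keep] - WINDOW_START) / BIN_WIDTH).astype(int)
    df = pd.DataFrame({"bin": bins, "isi": isis[keep], "t": second[keep]})
    grouped = df.groupby("bin").agg(isi=("isi", "mean"), t=("t", "mean"))
    if len(grouped) < 2:
        return None
    t = grouped["t"].to_numpy()
    y = grouped["isi"].to_numpy()
    X = np.column_stack([np.ones_like(t), t])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    dof = len(y) - 2
    if dof > 0:
        s2 = float(np.sum((y - fitted) ** 2)) / dof
        se = float(np.sqrt(s2 / np.sum((t - t.mean()) ** 2)))
    else:
        se = float("nan")
    return AdaptationFit(slope=float(beta[1]), se=se, n_bins=len(y))


def pooled_lp_adaptation(trains: list[np.ndarray]) -> AdaptationFit | None:
    """Adaptation slope pooled over labial-palp GRNs.

    Bin-wise mean ISIs are averaged across the units before the
    regression, mirroring the pooling of the four labial palp GRNs.
    """
    per_unit = []
    per_unit_t = []
    for times in trains:
        times = np.sort(np.asarray(times, dtype=float))
        if times.size < 3:
            continue
        isis = np.diff(times)
        second = times[1:]
        keep = (second >= WINDOW_START) & (second < WINDOW_END)
        if keep.sum() < 1:
            continue
        bins = ((second[keep] - WINDOW_START) / BIN_WIDTH).astype(int)
        g = pd.DataFrame({"bin": bins, "isi": isis[keep], "t": second[keep]}).groupby("bin")
        per_unit.append(g["isi"].mean())
        per_unit_t.append(g["t"].mean())
    if not per_unit:
        return None
    pooled = pd.concat(per_unit, axis=1).mean(axis=1)
    pooled_t = pd.concat(per_unit_t, axis=1).mean(axis=1)
    if len(pooled) < 2:
        return None
    t = pooled_t.to_numpy()
    y = pooled.to_numpy()
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    dof = len(y) - 2
    se = (
        float(np.sqrt(np.sum((y - fitted) ** 2) / dof / np.sum((t - t.mean()) ** 2)))
        if dof > 0
        else float("nan")
    )
    return AdaptationFit(slope=float(beta[1]), se=se, n_bins=len(y))


def burst_metrics(
    spikes: pd.DataFrame,
    window: tuple[float, float] = (WINDOW_START, WINDOW_END),
) -> tuple[float | None, float | None]:
    """(burst_length, burst_rate) from a labelled galeal spike table.

    Each Gal2 (end-of-burst) spike closes one burst; the burst's length
    is the number of Gal1 spikes since the previous Gal2.  Bursts whose
    EOB falls in the window are counted, so burst_rate equals the Gal2
    average rate by construction.  Returns (None, None) with zero bursts.
    """
    lo, hi = window
    t = spikes["time_s"].to_numpy()
    u = spikes["unit"].to_numpy()
    gal2_times = t[u == "Gal2"]
    gal1_times = t[u == "Gal1"]
    in_win = (gal2_times >= lo) & (gal2_times < hi)
    if not in_win.any():
        return None, None
    lengths = []
    for g2 in gal2_times[in_win]:
        prev = gal2_times[gal2_times < g2]
        start = prev.max() if prev.size else -np.inf
        lengths.append(int(np.sum((gal1_times > start) & (gal1_times < g2))))
    burst_rate = float(in_win.sum() / (hi - lo))
    return float(np.mean(lengths)), burst_rate


def _units_for_location(location: str) -> tuple[str, ...]:
    if location == "Gal":
        return GALEAL_UNITS
    return (f"{location}1", f"{location}2")


def recording_features(
    spikes: pd.DataFrame, duration: float, meta: dict | None = None
) -> pd.DataFrame:
    """Feature rows (one per GRN type) for one labelled recording.

    ``spikes`` is a tidy per-spike table (columns bee, location,
    sensillum, stimulus, time_s, unit) for a single sensillum x stimulus.
    Unit names in the table are already location-qualified (Gal1..Gal3,
    LPIII1, ...).  GRN types expected at the location but silent in the
    recording yield all-zero rate rows.  For a recording with no detected
    spikes (e.g. full suppression) pass the identifying fields in
    ``meta``.
    """
    if spikes.empty:
        if meta is None:
            raise ValueError("empty spike table: pass recording metadata via meta=")
    else:
        meta = spikes.iloc[0]
    location = meta["location"]
    rows = []
    for unit in _units_for_location(location):
        sub = spikes[spikes["unit"] == unit]
        times = sub["time_s"].to_numpy()
        binned = bin_rates(times, duration)
        avg = average_rate(binned)
        fit = adaptation_slope(times)
        row = {
            "bee": meta["bee"],
            "location": location,
            "sensillum": meta["sensillum"],
            "stimulus": meta["stimulus"],
            "grn_type": unit,
            **dict(zip(BIN_COLUMNS, binned)),
            "avg_rate": avg,
            "log_avg_rate": log_rate(avg),
            "adaptation_slope": fit.slope if fit else np.nan,
            "adaptation_se": fit.se if fit else np.nan,
        }
        if location == "Gal" and unit == "Gal1":
            length, rate = burst_metrics(spikes)
            row["burst_length"] = length if length is not None else np.nan
            row["burst_rate"] = rate if rate is not None else np.nan
        else:
            row["burst_length"] = np.nan
            row["burst_rate"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def dataset_features(spikes: pd.DataFrame, duration: float) -> pd.DataFrame:
    """Per-sensillum features for a whole labelled spike dataset."""
    keys = ["bee", "location", "sensillum", "stimulus"]
    parts = [
        recording_features(group, duration)
        for _, group in spikes.groupby(keys, sort=True)
    ]
    return pd.concat(parts, ignore_index=True)


def exclude_nonresponders(
    features: pd.DataFrame,
    control: str = "OSR",
    floor: float = RESPONSE_FLOOR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop sensilla that did not respond to the control stimulus.

    A sensillum's control response is the summed average rate of its GRNs
    under the control stimulus; below ``floor`` spikes/s it is removed
    from every stimulus.  Returns the filtered table and an exclusion log
    (one row per excluded sensillum with its control rate).
    """
    ctrl = features[features["stimulus"] == control]
    all_sensilla = set(map(tuple, features[["bee", "sensillum"]].drop_duplicates().to_numpy()))
    ctrl_sensilla = set(map(tuple, ctrl[["bee", "sensillum"]].drop_duplicates().to_numpy()))
    missing = all_sensilla - ctrl_sensilla
    if missing:
        raise ValueError(
            f"control stimulus {control!r} missing for sensilla: {sorted(missing)[:5]}"
        )
    total = ctrl.groupby(["bee", "sensillum"])["avg_rate"].sum()
    bad = total[total < floor]
    log = bad.rename("control_rate").reset_index()
    if bad.empty:
        return features.copy(), log
    bad_keys = set(map(tuple, log[["bee", "sensillum"]].to_numpy()))
    keep = [
        tuple(k) not in bad_keys
        for k in features[["bee", "sensillum"]].to_numpy()
    ]
    return features[keep].reset_index(drop=True), log


def average_across_sensilla(features: pd.DataFrame) -> pd.DataFrame:
    """Average per-sensillum features to one row per bee x stimulus x GRN.

    Rates (binned and average) are arithmetic means across sensilla; the
    coefficient of variation of the per-sensillum average rates
    (population-SD convention, n denominator) is reported alongside, and
    is absent (NaN) when the mean rate is zero or only one sensillum
    contributed.
    """
    value_cols = BIN_COLUMNS + [
        "avg_rate", "adaptation_slope", "burst_length", "burst_rate",
    ]
    keys = ["bee", "location", "stimulus", "grn_type"]

    def agg(group: pd.DataFrame) -> pd.Series:
        out = {c: group[c].mean() for c in value_cols}
        rates = group["avg_rate"].to_numpy()
        mean = rates.mean()
        if rates.size > 1 and mean > 0:
            out["cv_across_sensilla"] = float(rates.std(ddof=0) / mean)
        else:
            out["cv_across_sensilla"] = np.nan
        out["n_sensilla"] = len(group)
        return pd.Series(out)

    result = features.groupby(keys, sort=True).apply(agg, include_groups=False)
    result = result.reset_index()
    result["log_avg_rate"] = np.log10(result["avg_rate"] + 1.0)
    return result
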