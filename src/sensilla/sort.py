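"""Waveform-based sorting of labial-palp spikes into one or two units.

Each labial palp sensillum houses two sugar-sensitive GRNs that fire
tonically; their spikes are separated by waveform shape.  Windows of
+/-2 ms around each detected peak are stacked, row-centred, projected
onto the first two right singular vectors (SVD), and clustered with
k-means (k=2).  The two-cluster split is accepted only when the mean
silhouette exceeds a separation criterion; otherwise a single unit is
reported.  The larger-amplitude cluster is always labelled GRN1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import SpikeTrain, VoltageTrace

DEFAULT_HALF_WINDOW_S = 0.002
#: Minimum mean silhouette of the 2-means split to accept two units.
SILHOUETTE_MIN = 0.5


@dataclass
class WaveformMatrix:
    """Peak-aligned spike waveforms, one row per spike.

    ``spike_indices`` maps rows back to the source SpikeTrain (spikes too
    close to a trace edge are dropped; ``n_dropped`` counts them).
    """

    waveforms: np.ndarray  # (n_spikes, window) rows
    spike_indices: np.ndarray
    n_dropped: int = 0

    def __len__(self) -> int:
        return int(self.waveforms.shape[0])


@dataclass
class SortResult:
    """Unit assignment for one recording: labels, scores, unit count."""

    labels: np.ndarray  # per-kept-spike "GRN1"/"GRN2"
    scores: np.ndarray  # (n, 2) SVD component scores
    n_units: int
    silhouette: float | None = None
    spike_indices: np.ndarray | None = None


def extract_waveforms(
    trace: VoltageTrace,
    train: SpikeTrain,
    half_window: float = DEFAULT_HALF_WINDOW_S,
) -> WaveformMatrix:
    """Cut peak-aligned windows of +/-half_window around each spike."""
    half = int(round(half_window * trace.sample_rate))
    n = trace.samples.size
    idx = np.round(train.times * trace.sample_rate).astype(int)
    ok = (idx >= half) & (idx < n - half)
    kept = idx[ok]
    offsets = np.arange(-half, half + 1)
    wf = trace.samples[kept[:, None] + offsets[None, :]] if kept.size else np.empty(
        (0, 2 * half + 1)
    )
    return WaveformMatrix(
        waveforms=wf,
        spike_indices=np.flatnonzero(ok),
        n_dropped=int((~ok).sum()),
    )


def project_svd(matrix: WaveformMatrix) -> np.ndarray:
    """Scores of each waveform on the top-2 principal shape components.

    The row-centred matrix is decomposed with an SVD and rows are
    projected onto the first two right singular vectors; by Eckart-Young
    this is the best rank-2 summary of waveform shape in the Frobenius
    sense.
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 spikes to project")
    X = matrix.waveforms - matrix.waveforms.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return U[:, :2] * s[:2]


def assign_units(
    scores: np.ndarray,
    amplitudes: np.ndarray,
    seed: int = 0,
    silhouette_min: float = SILHOUETTE_MIN,
) -> SortResult:
    """k-means (k=2) on the component scores, with a one-unit fallback.

    Two units are reported only when the mean silhouette of the split
    exceeds ``silhouette_min``; tip recordings sometimes capture a single
    active GRN, and forcing k=2 on those would split noise.  GRN1 is the
    cluster with the larger mean absolute peak amplitude.
    """
    n = scores.shape[0]
    if n < 2:
        return SortResult(
            labels=np.full(n, "GRN1", dtype=object), scores=scores, n_units=1
        )
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    raw = km.fit_predict(scores)
    if len(np.unique(raw)) < 2:
        return SortResult(
            labels=np.full(n, "GRN1", dtype=object), scores=scores, n_units=1
        )
    sil = float(silhouette_score(scores, raw))
    if sil <= silhouette_min:
        return SortResult(
            labels=np.full(n, "GRN1", dtype=object),
            scores=scores,
            n_units=1,
            silhouette=sil,
        )
    amp0 = np.mean(np.abs(amplitudes[raw == 0]))
    amp1 = np.mean(np.abs(amplitudes[raw == 1]))
    big = 0 if amp0 >= amp1 else 1
    labels = np.where(raw == big, "GRN1", "GRN2").astype(object)
    return SortResult(labels=labels, scores=scores, n_units=2, silhouette=sil)


def sort_lp_recording(
    trace: VoltageTrace, train: SpikeTrain, seed: int = 0
) -> SortResult:
    """Full LP sorting path: windows -> SVD -> k-means.

    Galeal recordings must not pass through here (their units come from
    burst structure); enforced by the trace's location tag.
    """
    if trace.location == "Gal":
        raise ValueError("galeal recordings are classified by burst structure")
    matrix = extract_waveforms(trace, train)
    if len(matrix) < 2:
        res = SortResult(
            labels=np.full(len(matrix), "GRN1", dtype=object),
            scores=np.zeros((len(matrix), 2)),
            n_units=1,
        )
        res.spike_indices = matrix.spike_indices
        return res
    scores = project_svd(matrix)
    amplitudes = train.peak_amplitudes[matrix.spike_indices]
    res = assign_units(scores, amplitudes, seed=seed)
    res.spike_indices = matrix.spike_indices
    return res
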