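"""Population temporal code and stimulus discriminability.

For each animal and stimulus the ten-bin rate time courses of the seven
GRN types are normalised by the animal's control-stimulus response and
concatenated into a 70-value population vector.  The vectors are
embedded in two dimensions with t-SNE (Euclidean distances) and the
number of statistically distinct stimulus groups is decided by Monte
Carlo reference-based consensus clustering: for each candidate k the
stability of repeated k-means on resampled data (PAC, the proportion of
ambiguous consensus entries) is compared with the PAC of
structure-free Gaussian reference datasets sharing the data's mean and
principal-component covariance.  The relative cluster stability index
RCSI = ln(mean null PAC / observed PAC) picks k among those with a
significant Monte-Carlo p-value; when no k rejects the null the data are
declared unimodal (k = 1), i.e. the stimuli are not discriminable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.vq import kmeans2
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .core import GRN_TYPES
from .features import BIN_COLUMNS, N_BINS

VECTOR_LENGTH = N_BINS * len(GRN_TYPES)  # 70
VECTOR_COLUMNS = [f"v{i:02d}" for i in range(VECTOR_LENGTH)]

DEFAULT_MAXK = 5
DEFAULT_RESAMPLES = 100
DEFAULT_RESAMPLE_FRACTION = 0.8
DEFAULT_MC_REFS = 25
PAC_WINDOW = (0.1, 0.9)
SIGNIFICANCE = 0.05
_PAC_FLOOR = 1e-4  # guards ln() when clustering is perfectly stable


def build_population_vectors(
    features: pd.DataFrame,
    control: str = "OSR",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalised 70-bin population vectors, one per animal x stimulus.

    ``features`` is the per-sensillum feature table.  Within each animal,
    every GRN's binned rates are divided by that animal's mean control
    response for the same GRN, averaged across sensilla, and concatenated
    in the fixed GRN order (Gal1, Gal2, Gal3, LPIII1, LPIII2, LPIV1,
    LPIV2).  GRN types with a zero control mean (or absent entirely) get
    zero entries and are recorded in the returned flag table — silence is
    itself informative, so nothing is imputed.
    """
    ctrl = features[features["stimulus"] == control]
    if ctrl.empty:
        raise ValueError(f"no control stimulus {control!r} in feature table")
    ctrl_mean = ctrl.groupby(["bee", "grn_type"])["avg_rate"].mean()

    rows = []
    flags = []
    for (bee, stimulus), group in features.groupby(["bee", "stimulus"], sort=True):
        vec = np.zeros(VECTOR_LENGTH)
        for gi, grn in enumerate(GRN_TYPES):
            sub = group[group["grn_type"] == grn]
            ref = float(ctrl_mean.get((bee, grn), 0.0))
            if sub.empty or ref <= 0:
                flags.append({"bee": bee, "stimulus": stimulus, "grn_type": grn,
                              "reason": "missing" if sub.empty else "zero_control"})
                continue
            bins = sub[BIN_COLUMNS].to_numpy(dtype=float).mean(axis=0)
            vec[gi * N_BINS : (gi + 1) * N_BINS] = bins / ref
        rows.append({"bee": bee, "stimulus": stimulus,
                     **dict(zip(VECTOR_COLUMNS, vec))})
    return pd.DataFrame(rows), pd.DataFrame(flags)


def embed_tsne(
    vectors: np.ndarray | pd.DataFrame,
    perplexity: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Two-component t-SNE of the population vectors (Euclidean metric).

    Deterministic under a fixed seed (exact-gradient solver, PCA
    initialisation).  Perplexity defaults to min(10, (n-1)/3) to suit the
    small per-panel sample sizes (tens of animals).
    """
    X = _as_matrix(vectors)
    n = X.shape[0]
    if n < 3:
        raise ValueError(
            "need >= 3 vectors for t-SNE; cluster the raw vectors directly"
        )
    if perplexity is None:
        perplexity = min(10.0, (n - 1) / 3.0)
    if not perplexity < (n - 1) / 3 + 1e-9:
        raise ValueError("perplexity must be < (n - 1) / 3")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        metric="euclidean",
        method="exact",
        init="pca",
        random_state=seed,
    )
    return tsne.fit_transform(X)


def _as_matrix(vectors: np.ndarray | pd.DataFrame) -> np.ndarray:
    if isinstance(vectors, pd.DataFrame):
        cols = [c for c in VECTOR_COLUMNS if c in vectors.columns]
        if cols:
            return vectors[cols].to_numpy(dtype=float)
        return vectors.select_dtypes("number").to_numpy(dtype=float)
    return np.asarray(vectors, dtype=float)


@dataclass
class ClusteringReport:
    """Outcome of the consensus cluster-count decision."""

    k_optimal: int
    stats: pd.DataFrame  # per-k: PAC_real, PAC_null_mean, RCSI, p_value
    labels: np.ndarray | None = None
    embedding: np.ndarray | None = None
    params: dict = field(default_factory=dict)


def _consensus_pac(
    points: np.ndarray,
    k: int,
    resamples: int,
    fraction: float,
    rng: np.random.Generator,
    pac_window: tuple[float, float],
) -> float:
    """PAC of k-means consensus over row-resampled subsets.

    The consensus matrix entry (i, j) is the fraction of co-sampled draws
    in which i and j landed in the same k-means cluster; PAC is the share
    of pair entries falling in the ambiguous band.
    """
    n = points.shape[0]
    m = max(k + 1, int(np.ceil(fraction * n)))
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(resamples):
            idx = rng.choice(n, size=m, replace=False)
            sub = points[idx]
            _, lab = kmeans2(sub, k, minit="++", seed=rng, missing="warn")
            same = lab[:, None] == lab[None, :]
            sampled[np.ix_(idx, idx)] += 1.0
            together[np.ix_(idx, idx)] += same
    iu = np.triu_indices(n, k=1)
    seen = sampled[iu] > 0
    consensus = np.zeros_like(together[iu])
    consensus[seen] = together[iu][seen] / sampled[iu][seen]
    lo, hi = pac_window
    if seen.sum() == 0:
        return 1.0
    return float(np.mean((consensus[seen] > lo) & (consensus[seen] < hi)))


def _beta_p(real: float, nulls: np.ndarray) -> float:
    """P(null PAC <= observed PAC) from a beta fit to the null sample.

    A beta distribution is fit by moments to the Monte-Carlo null PACs,
    extrapolating the tail beyond the resolution of the finite reference
    sample (a perfectly stable clustering, PAC = 0, would otherwise tie
    with any reference run that also happens to be perfectly stable).
    Falls back to the empirical tail proportion when the fit degenerates.
    """
    eps = 1e-3
    x = np.clip(nulls, eps, 1 - eps)
    m, v = float(x.mean()), float(x.var(ddof=1))
    if v < 1e-10 or not 0 < m < 1:
        return float((1 + np.sum(nulls <= real)) / (len(nulls) + 1))
    common = m * (1 - m) / v - 1.0
    if common <= 0:
        return float((1 + np.sum(nulls <= real)) / (len(nulls) + 1))
    a, b = m * common, (1 - m) * common
    return float(sps.beta.cdf(np.clip(real, eps, 1 - eps), a, b))


def _reference_sample(
    points: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Structure-free Gaussian reference preserving mean and PC covariance."""
    n, d = points.shape
    mean = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    z = rng.standard_normal((n, d))
    return mean + z @ (evecs * np.sqrt(evals)).T


def consensus_cluster_count(
    points: np.ndarray | pd.DataFrame,
    maxk: int = DEFAULT_MAXK,
    resamples: int = DEFAULT_RESAMPLES,
    fraction: float = DEFAULT_RESAMPLE_FRACTION,
    mc_refs: int = DEFAULT_MC_REFS,
    seed: int = 0,
    pac_window: tuple[float, float] = PAC_WINDOW,
    alpha: float = SIGNIFICANCE,
) -> ClusteringReport:
    """Optimal cluster count by Monte Carlo reference-based consensus.

    For each k in 2..maxk the observed PAC is compared against ``mc_refs``
    Gaussian reference datasets; RCSI = ln(mean null PAC / observed PAC).
    Significance comes from a beta-distribution fit to the Monte-Carlo
    null PAC sample (the raw tail proportion is reported alongside as
    ``p_empirical``).  k_optimal maximises RCSI among significant k; if
    no k rejects the null, k_optimal = 1.
    """
    X = _as_matrix(points)
    n = X.shape[0]
    if n < 6:
        raise ValueError("need >= 6 points for consensus clustering")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if np.allclose(X, X[0]):
        return ClusteringReport(k_optimal=1, stats=pd.DataFrame(),
                                params={"degenerate": True})

    ks = list(range(2, maxk + 1))
    pac_real = {
        k: _consensus_pac(X, k, resamples, fraction, rng, pac_window) for k in ks
    }
    null_pacs: dict[int, list[float]] = {k: [] for k in ks}
    for _ in range(mc_refs):
        ref = _reference_sample(X, rng)
        for k in ks:
            null_pacs[k].append(
                _consensus_pac(ref, k, resamples, fraction, rng, pac_window)
            )
    records = []
    for k in ks:
        nulls = np.array(null_pacs[k])
        real = pac_real[k]
        rcsi = float(np.log((nulls.mean() + _PAC_FLOOR) / (real + _PAC_FLOOR)))
        p_emp = float((1 + np.sum(nulls <= real)) / (len(nulls) + 1))
        records.append(
            {"k": k, "PAC_real": real, "PAC_null_mean": float(nulls.mean()),
             "RCSI": rcsi, "p_value": _beta_p(real, nulls),
             "p_empirical": p_emp}
        )
    stats = pd.DataFrame(records)
    significant = stats[stats["p_value"] < alpha]
    if significant.empty:
        k_opt = 1
    else:
        k_opt = int(significant.loc[significant["RCSI"].idxmax(), "k"])
    return ClusteringReport(
        k_optimal=k_opt,
        stats=stats,
        params={
            "maxk": maxk, "resamples": resamples, "fraction": fraction,
            "mc_refs": mc_refs, "seed": seed, "pac_window": pac_window,
            "alpha": alpha,
        },
    )


def cluster_embedding(points: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means partition of the embedding, labels ordered by cluster size.

    Ten restarts with a fixed seed; label 0 is the largest cluster.
    """
    X = np.asarray(points, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of points")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[raw]


def discriminability(
    vectors: pd.DataFrame,
    seed: int = 0,
    maxk: int = DEFAULT_MAXK,
    on_embedding: bool = False,
    **consensus_kwargs,
) -> ClusteringReport:
    """Full decision: t-SNE embed, consensus k, and k-means labels.

    The consensus procedure runs on the raw 70-d vectors by default (the
    t-SNE embedding is kept for display and for the k-means cluster
    shading); pass ``on_embedding=True`` to run the cluster-count
    decision on the 2-d embedding instead.  Embeddings of few tens of
    points form apparent clumps even for structureless data, which
    inflates the cluster count, so the raw-vector route is the default.
    The choice is recorded in the report parameters.
    """
    X = _as_matrix(vectors)
    emb = embed_tsne(X, seed=seed)
    target = emb if on_embedding else X
    report = consensus_cluster_count(target, maxk=maxk, seed=seed, **consensus_kwargs)
    report.embedding = emb
    report.params["on_embedding"] = on_embedding
    if report.k_optimal > 1:
        report.labels = cluster_embedding(emb, report.k_optimal, seed=seed)
    return report
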