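"""Waveform features, outlier removal, clustering, and unit statistics.

Waveforms are expanded into a full orthonormal Haar wavelet decomposition
(capturing shape at every scale), reduced by PCA to the components that each
explain at least 1% of the variance, scrubbed of anomalies with the Local
Outlier Factor, and clustered with hierarchical density-based clustering
(HDBSCAN) with a minimum cluster size of 100 spikes. Each resulting unit
carries its median template and inter-spike-interval statistics; the
fraction of ISIs below the 4 ms refractory period is the standard check
that a cluster is a single neuron.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA
from sklearn.neighbors import LocalOutlierFactor

from .detection import median_template

__all__ = [
    "Unit",
    "REFRACTORY_S",
    "haar_features",
    "pca_reduce",
    "flag_outliers",
    "cluster_spikes",
    "build_units",
    "sort_events",
]

#: Neuronal refractory period used for ISI hygiene statistics.
REFRACTORY_S = 0.004

#: Padded waveform length: 29 samples edge-replicated to the next power of two.
HAAR_LEN = 32


@dataclass
class Unit:
    """A sorted putative single neuron."""

    unit_id: int
    spike_times_s: np.ndarray
    template: np.ndarray
    event_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if len(self.spike_times_s) >= 2 and np.any(np.diff(self.spike_times_s) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times_s)

    @property
    def isi_s(self) -> np.ndarray:
        return np.diff(self.spike_times_s)

    @property
    def fraction_isi_below_4ms(self) -> float:
        isi = self.isi_s
        if len(isi) == 0:
            return 0.0
        return float(np.mean(isi < REFRACTORY_S))


def haar_features(waveforms) -> np.ndarray:
    """Full-depth orthonormal Haar decomposition of each waveform.

    Waveforms (29 samples) are padded to 32 by edge replication (one sample
    on the left, two on the right); zero padding would create a spurious
    step at the boundary. The decomposition uses periodized orthonormal Haar
    filters to full depth, so the 32 output coefficients conserve the energy
    of the padded waveform exactly.
    """
    wf = np.atleast_2d(np.asarray(waveforms, dtype=float))
    n = wf.shape[1]
    target = 1 << int(np.ceil(np.log2(n)))
    pad_total = target - n
    pad_l = pad_total // 2
    pad_r = pad_total - pad_l
    padded = np.pad(wf, ((0, 0), (pad_l, pad_r)), mode="edge")
    level = int(np.log2(target))
    coeffs = pywt.wavedec(padded, "haar", mode="periodization", level=level, axis=1)
    return np.concatenate(coeffs, axis=1)


def pca_reduce(features: np.ndarray, min_explained: float = 0.01) -> tuple:
    """Keep the principal components explaining at least ``min_explained``
    of the variance (always at least one).

    Zero-variance feature columns are dropped before the decomposition.
    Returns ``(reduced, loadings)`` where ``loadings`` has one row per kept
    component over the retained feature columns.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    keep_cols = features.std(axis=0) > 0
    feats = features[:, keep_cols]
    if feats.shape[1] == 0:
        raise ValueError("all features have zero variance")
    n_comp = min(feats.shape)
    pca = PCA(n_components=n_comp)
    reduced = pca.fit_transform(feats)
    n_keep = max(int(np.sum(pca.explained_variance_ratio_ >= min_explained)), 1)
    return reduced[:, :n_keep], pca.components_[:n_keep]


def flag_outliers(features: np.ndarray, n_neighbors: int = 20) -> np.ndarray:
    """Local-Outlier-Factor anomaly mask (True = outlier, excluded downstream)."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < n_neighbors + 1:
        raise ValueError("need at least n_neighbors + 1 points")
    lof = LocalOutlierFactor(n_neighbors=n_neighbors)
    pred = lof.fit_predict(features)
    return pred == -1


def cluster_spikes(features: np.ndarray, min_cluster_size: int = 100) -> np.ndarray:
    """Hierarchical density-based clustering; -1 labels noise.

    Every reported cluster has at least ``min_cluster_size`` members; with
    fewer points than that in total, everything is noise. Cluster labels are
    renumbered by order of first appearance (for time-sorted inputs: by
    first spike time).
    """
    features = np.asarray(features, dtype=float)
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    n = features.shape[0]
    if n < min_cluster_size:
        return np.full(n, -1, dtype=int)
    labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(features)
    if not np.any(labels >= 0):
        # excess-of-mass selection never reports the hierarchy root, so a
        # recording dominated by a single unit would yield zero clusters;
        # retry allowing one cluster before declaring everything noise
        labels = HDBSCAN(
            min_cluster_size=min_cluster_size, copy=True, allow_single_cluster=True
        ).fit_predict(features)
    # deterministic relabeling by first occurrence
    out = np.full(n, -1, dtype=int)
    next_id = 0
    mapping = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = next_id
            next_id += 1
        out[i] = mapping[lab]
    return out


def build_units(events: list, labels: np.ndarray) -> list:
    """Assemble :class:`Unit` objects from labeled spike events.

    ``labels`` aligns with ``events``; label -1 (noise) is skipped. Events
    must carry waveforms (for the median template).
    """
    labels = np.asarray(labels)
    if len(labels) != len(events):
        raise ValueError("labels must align with events")
    units = []
    for lab in sorted(set(labels.tolist()) - {-1}):
        idx = np.nonzero(labels == lab)[0]
        times = np.array([events[i].t_s for i in idx])
        order = np.argsort(times)
        idx = idx[order]
        wf = [events[i].waveform for i in idx]
        if any(w is None for w in wf):
            raise ValueError("events must have waveforms attached")
        units.append(
            Unit(
                unit_id=int(lab),
                spike_times_s=times[order],
                template=median_template(wf),
                event_indices=idx,
            )
        )
    return units


def sort_events(
    events: list,
    min_explained: float = 0.01,
    lof_neighbors: int = 20,
    min_cluster_size: int = 100,
) -> tuple:
    """Feature extraction, outlier removal and clustering in one call.

    Returns ``(units, labels, outlier_mask)`` where ``labels`` covers all
    input events (-1 for noise and for LOF outliers, which never enter
    clustering).
    """
    if not events:
        return [], np.empty(0, dtype=int), np.empty(0, dtype=bool)
    waveforms = np.array([ev.waveform for ev in events])
    feats = haar_features(waveforms)
    reduced, _ = pca_reduce(feats, min_explained)
    outliers = flag_outliers(reduced, lof_neighbors)
    labels = np.full(len(events), -1, dtype=int)
    inlier_idx = np.nonzero(~outliers)[0]
    if len(inlier_idx):
        labels[inlier_idx] = cluster_spikes(reduced[inlier_idx], min_cluster_size)
    units = build_units(events, labels)
    return units, labels, outliers
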