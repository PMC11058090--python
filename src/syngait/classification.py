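"""Classification of extracted synergies into the four fundamental synergies.

Activation patterns pooled across participants (or cycles) are max-normalized
and clustered with k-means. The cluster count is chosen by an elbow rule on
the within-cluster sum of squares (WSS): k-means is run for k = 1..13 (one
per recorded muscle), the WSS-versus-k curve is normalized by the total sum
of squares, and the selected count is the smallest k from which the
remaining curve fits a least-squares line with mean squared error below
1e-3.

Clusters are labeled weight_acceptance < propulsion < early_swing <
late_swing by ascending centroid center of activity from stance onset. A
synergy is *fundamental* when its pattern has a single main activation peak;
synergies failing that test, or lying too far from their cluster centroid,
are flagged non_classifiable and excluded from metric aggregation (their
fraction is always reported, never silently dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .extraction import SynergySet
from .metrics import center_of_activity, cosine_similarity

__all__ = [
    "FUNDAMENTAL_LABELS",
    "NON_CLASSIFIABLE",
    "ClassificationResult",
    "choose_cluster_count",
    "is_fundamental",
    "classify_patterns",
    "classify_synergies",
]

FUNDAMENTAL_LABELS: tuple[str, ...] = (
    "weight_acceptance",
    "propulsion",
    "early_swing",
    "late_swing",
)
NON_CLASSIFIABLE = "non_classifiable"

# canonical gait-phase placements used to label clusters when the elbow rule
# does not return exactly four clusters
_CANONICAL_COA = {
    "weight_acceptance": 2.0 * np.pi * 0.10,
    "propulsion": 2.0 * np.pi * 0.40,
    "early_swing": 2.0 * np.pi * 0.60,
    "late_swing": 2.0 * np.pi * 0.90,
}


def _max_normalize(patterns: np.ndarray) -> np.ndarray:
    X = np.asarray(patterns, dtype=float)
    peaks = X.max(axis=1, keepdims=True)
    if np.any(peaks <= 0):
        raise ValueError("patterns must have a positive maximum to be clustered")
    return X / peaks


def choose_cluster_count(
    patterns: np.ndarray,
    max_k: int = 13,
    seed: int = 0,
    n_init: int = 10,
    flat_mse: float = 1e-3,
) -> tuple[int, np.ndarray]:
    """Elbow rule on the WSS-versus-k curve of pooled activation patterns.

    Runs seeded k-means for k = 1..max_k on max-normalized patterns and
    returns the smallest k from which the WSS curve, normalized by the total
    sum of squares, fits a least-squares line with MSE below ``flat_mse``.
    Also returns the normalized WSS curve for audit.
    """
    X = _max_normalize(patterns)
    if X.shape[0] < max_k:
        warnings.warn(
            f"only {X.shape[0]} patterns available; reducing max_k from {max_k}"
        )
        max_k = X.shape[0]
    wss = np.empty(max_k)
    for k in range(1, max_k + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        km.fit(X)
        wss[k - 1] = km.inertia_
    tss = wss[0]
    if tss == 0:  # all patterns identical
        return 1, np.zeros(max_k)
    curve = wss / tss
    for k in range(1, max_k + 1):
        y = curve[k - 1 :]
        if y.size <= 2:
            return k, curve
        x = np.arange(y.size, dtype=float)
        coef = np.polyfit(x, y, 1)
        if float(np.mean((y - np.polyval(coef, x)) ** 2)) < flat_mse:
            return k, curve
    return max_k, curve


def _circular_local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices that are strict-or-plateau local maxima on the circle."""
    left = np.roll(x, 1)
    right = np.roll(x, -1)
    return np.nonzero((x >= left) & (x > right))[0]


def is_fundamental(
    pattern,
    height_frac: float = 0.5,
    min_separation: int = 20,
    smooth_window: int = 5,
) -> bool:
    """True iff the pattern has exactly one main activation peak.

    The pattern is smoothed with a circular moving average
    (``smooth_window`` points); circular local maxima reaching at least
    ``height_frac`` of the global maximum and separated by at least
    ``min_separation`` points count as main peaks. An all-zero pattern is
    not fundamental.
    """
    x = np.asarray(pattern, dtype=float)
    if x.max() <= 0:
        warnings.warn("all-zero pattern cannot be fundamental")
        return False
    kernel = np.ones(smooth_window) / smooth_window
    n = x.size
    sm = np.convolve(np.concatenate([x[-smooth_window:], x, x[:smooth_window]]), kernel, mode="same")[
        smooth_window : smooth_window + n
    ]
    peaks = _circular_local_maxima(sm)
    peaks = peaks[sm[peaks] >= height_frac * sm.max()]
    if peaks.size == 0:
        return False
    # merge peaks closer than min_separation on the circle, keeping the highest
    order = peaks[np.argsort(sm[peaks])[::-1]]
    kept: list[int] = []
    for idx in order:
        if all(
            min((idx - k) % n, (k - idx) % n) >= min_separation for k in kept
        ):
            kept.append(int(idx))
    return len(kept) == 1


@dataclass
class ClassificationResult:
    """Labels and audit trail of one pooled classification."""

    labels: list[str]
    k: int
    wss_curve: np.ndarray
    centroids: np.ndarray
    cluster_labels: list[str]
    assignments: np.ndarray
    centroid_similarity: np.ndarray
    fraction_non_classifiable: float = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.fraction_non_classifiable = (
            sum(lab == NON_CLASSIFIABLE for lab in self.labels) / n if n else 0.0
        )


def _label_clusters(centroids: np.ndarray) -> list[str]:
    """Name clusters by gait phase.

    With exactly four clusters, labels follow ascending centroid CoA from
    stance onset (weight acceptance < propulsion < early swing < late swing).
    Otherwise each fundamental label goes to the cluster whose centroid CoA
    is circularly closest to the label's canonical phase; leftover clusters
    are non-classifiable.
    """
    coas = np.array([center_of_activity(c) for c in centroids])
    k = len(centroids)
    labels = [NON_CLASSIFIABLE] * k
    if k == 4:
        for lab, idx in zip(FUNDAMENTAL_LABELS, np.argsort(coas)):
            labels[idx] = lab
        return labels
    warnings.warn(
        f"elbow rule chose {k} clusters (expected 4); assigning fundamental "
        f"labels to the best-matching clusters by center of activity"
    )
    taken: set[int] = set()
    for lab in FUNDAMENTAL_LABELS:
        target = _CANONICAL_COA[lab]
        dist = np.array(
            [
                np.inf
                if i in taken or not np.isfinite(coas[i])
                else abs((coas[i] - target + np.pi) % (2 * np.pi) - np.pi)
                for i in range(k)
            ]
        )
        if np.all(np.isinf(dist)):
            break
        best = int(np.argmin(dist))
        labels[best] = lab
        taken.add(best)
    return labels


def classify_patterns(
    patterns: np.ndarray,
    seed: int = 0,
    max_k: int = 13,
    similarity_floor: float = 0.75,
    n_init: int = 10,
) -> ClassificationResult:
    """Cluster pooled activation patterns and label each one.

    Patterns are max-normalized (classification is amplitude-invariant), the
    cluster count comes from :func:`choose_cluster_count`, and each pattern
    takes its cluster's phase label — unless the pattern is not fundamental
    (no single main peak) or its cosine similarity to the cluster centroid
    falls below ``similarity_floor``, in which case it is non-classifiable.
    """
    X = _max_normalize(patterns)
    k, wss = choose_cluster_count(X, max_k=max_k, seed=seed, n_init=n_init)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assign = km.fit_predict(X)
    centroids = np.maximum(km.cluster_centers_, 0.0)
    cluster_labels = _label_clusters(centroids)

    labels: list[str] = []
    sims = np.empty(X.shape[0])
    for i, row in enumerate(X):
        c = assign[i]
        sims[i] = cosine_similarity(row, np.maximum(centroids[c], 1e-12))
        lab = cluster_labels[c]
        if lab != NON_CLASSIFIABLE and (
            not is_fundamental(row) or sims[i] < similarity_floor
        ):
            lab = NON_CLASSIFIABLE
        labels.append(lab)
    return ClassificationResult(
        labels=labels,
        k=k,
        wss_curve=wss,
        centroids=centroids,
        cluster_labels=cluster_labels,
        assignments=assign,
        centroid_similarity=sims,
    )


def classify_synergies(
    synergy_sets: list[SynergySet],
    seed: int = 0,
    **kwargs,
) -> tuple[list[list[str]], ClassificationResult]:
    """Pool the activation patterns of many synergy sets and classify them.

    Pooling is order-invariant; the returned nested list mirrors the input
    structure (one label per synergy of each set).
    """
    pooled = np.vstack([s.P for s in synergy_sets])
    result = classify_patterns(pooled, seed=seed, **kwargs)
    labels: list[list[str]] = []
    pos = 0
    for s in synergy_sets:
        labels.append(result.labels[pos : pos + s.rank])
        pos += s.rank
    return labels, result
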