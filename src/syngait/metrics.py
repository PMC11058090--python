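"""Spatiotemporal synergy metrics: cosine similarity, FWHM, center of activity.

Cosine similarity (CS) compares a cycle's muscle-weight vector (length 13)
or activation pattern (length 200) with the matched synergy of a reference
cycle; 1 means the same direction, -1 the opposite.

FWHM here is a point count, not an interval: after subtracting the pattern
minimum, it is the number of grid points whose value strictly exceeds half
of the (min-subtracted) maximum; the points need not be contiguous.

The center of activity (CoA) treats the 200-point cycle as a circular
distribution, point i at angle theta_i = 2*pi*i/200 with theta = 0 at
touchdown, and returns the angle of the first trigonometric moment
(the direction of the distribution's center of mass), mapped to [0, 2*pi).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from scipy.optimize import linear_sum_assignment

from .extraction import SynergySet

__all__ = [
    "cosine_similarity",
    "fwhm",
    "center_of_activity",
    "circular_difference",
    "similarity_series",
]


def cosine_similarity(A, B) -> float:
    """dot(A, B) / (|A| |B|); scale-invariant, in [-1, 1]."""
    a = np.asarray(A, dtype=float).ravel()
    b = np.asarray(B, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    aa = float(a @ a)
    bb = float(b @ b)
    if aa == 0 or bb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    # clamp the one-ulp overshoot of floating-point rounding to the bound
    return min(1.0, max(-1.0, float(a @ b) / math.sqrt(aa * bb)))


def fwhm(pattern) -> int:
    """Count of points strictly above half-maximum after min subtraction.

    Invariant to positive scaling and to adding a constant. A constant
    pattern has no peak and returns 0 with a warning.
    """
    x = np.asarray(pattern, dtype=float)
    x = x - x.min()
    peak = x.max()
    if peak == 0:
        warnings.warn("FWHM of a constant pattern is undefined; returning 0")
        return 0
    return int(np.sum(x > 0.5 * peak))


def center_of_activity(pattern) -> float:
    """Circular first-moment angle of the activation pattern, in [0, 2*pi).

    Returns NaN with a warning when the resultant vector vanishes (e.g. a
    uniform pattern), where the center of a circular distribution is
    undefined.
    """
    a = np.asarray(pattern, dtype=float)
    total = float(a.sum())
    if total <= 0:
        raise ValueError("center of activity requires positive total mass")
    theta = 2.0 * np.pi * np.arange(a.size) / a.size
    s = float(np.sum(a * np.sin(theta)))
    c = float(np.sum(a * np.cos(theta)))
    if math.hypot(s, c) < 1e-12 * total:
        warnings.warn("zero resultant: center of activity undefined")
        return float("nan")
    return float(np.arctan2(s, c) % (2.0 * np.pi))


def circular_difference(a: float, b: float) -> float:
    """Signed circular difference a - b wrapped to (-pi, pi]."""
    d = (a - b) % (2.0 * np.pi)
    return float(d - 2.0 * np.pi if d > np.pi else d)


def _match_to_reference(ref: SynergySet, cur: SynergySet) -> np.ndarray:
    ref_n = ref.M / (np.linalg.norm(ref.M, axis=0, keepdims=True) + 1e-12)
    cur_n = cur.M / (np.linalg.norm(cur.M, axis=0, keepdims=True) + 1e-12)
    _, cols = linear_sum_assignment(-(ref_n.T @ cur_n))
    return cols


def similarity_series(
    synergy_sets: list[SynergySet],
    reference_index: int = 0,
    labels: list[list[str]] | None = None,
    non_classifiable: str = "non_classifiable",
) -> pd.DataFrame:
    """Per-cycle, per-synergy CS/FWHM/CoA relative to a reference cycle.

    The reference is the first unperturbed cycle of the series (the cycle
    most remote from the perturbation). Synergies are matched across cycles
    by their classification ``labels`` when given; otherwise by optimal
    assignment on the cosine similarity of muscle-weight columns against the
    reference cycle. A synergy missing in a cycle (non-classifiable) yields a
    row of NaN sentinels rather than being dropped.

    Returns a tidy frame with columns cycle, synergy, label, cs_weights,
    cs_patterns, fwhm_points, coa_rad.
    """
    ref = synergy_sets[reference_index]
    if labels is not None:
        ref_labels = labels[reference_index]
    else:
        ref_labels = [f"synergy_{j}" for j in range(ref.rank)]

    rows = []
    for c, syn in enumerate(synergy_sets):
        if labels is None:
            perm = _match_to_reference(ref, syn)
            lookup = {ref_labels[j]: perm[j] for j in range(ref.rank)}
        else:
            lookup = {}
            for j, lab in enumerate(labels[c]):
                if lab != non_classifiable and lab not in lookup:
                    lookup[lab] = j
        for j, lab in enumerate(ref_labels):
            if lab == non_classifiable or lab not in lookup:
                rows.append(
                    dict(
                        cycle=c,
                        synergy=j,
                        label=lab,
                        cs_weights=np.nan,
                        cs_patterns=np.nan,
                        fwhm_points=np.nan,
                        coa_rad=np.nan,
                    )
                )
                continue
            k = lookup[lab]
            ref_j = j if labels is None else _label_index(ref_labels, lab)
            rows.append(
                dict(
                    cycle=c,
                    synergy=j,
                    label=lab,
                    cs_weights=cosine_similarity(ref.M[:, ref_j], syn.M[:, k]),
                    cs_patterns=cosine_similarity(ref.P[ref_j], syn.P[k]),
                    fwhm_points=fwhm(syn.P[k]),
                    coa_rad=center_of_activity(syn.P[k]),
                )
            )
    return pd.DataFrame(rows)


def _label_index(ref_labels: list[str], lab: str) -> int:
    return ref_labels.index(lab)
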