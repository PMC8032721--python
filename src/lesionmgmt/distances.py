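"""Distances between probabilistic predictions and one-hot targets.

Four measures compare a predicted management distribution with the one-hot
encoding of the reference label, per test case:

* ``cosine`` — 1 minus the cosine similarity;
* ``jensen_shannon`` — Jensen-Shannon divergence with base-2 logarithms,
  so its range is [0, 1];
* ``wasserstein`` — 1-D Wasserstein-1 over the ordered management
  categories, by default at unit-spaced severity positions
  NONE=0 < CLNC=1 < EXC=2;
* ``hellinger`` — sqrt(1 - Bhattacharyya coefficient), equivalently
  (1/sqrt(2)) * ||sqrt(p) - sqrt(q)||_2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MEASURES = ("cosine", "jensen_shannon", "wasserstein", "hellinger")


def _check_pair(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("length mismatch")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative entries")
    return p, q


def cosine_distance(p: np.ndarray, q: np.ndarray) -> float:
    p, q = _check_pair(p, q)
    np_, nq = np.linalg.norm(p), np.linalg.norm(q)
    if np_ == 0 or nq == 0:
        raise ValueError("zero vector")
    return float(np.clip(1.0 - (p @ q) / (np_ * nq), 0.0, 1.0))


def jensen_shannon(p: np.ndarray, q: np.ndarray) -> float:
    p, q = _check_pair(p, q)
    m = (p + q) / 2.0

    def kl2(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float((a[mask] * np.log2(a[mask] / b[mask])).sum())

    return float(np.clip(0.5 * kl2(p, m) + 0.5 * kl2(q, m), 0.0, 1.0))


def wasserstein_categorical(
    p: np.ndarray, q: np.ndarray, positions: np.ndarray | None = None
) -> float:
    """W1 between distributions over ordered categories at the given
    (strictly increasing) positions: sum |F_p - F_q| * delta-position."""
    p, q = _check_pair(p, q)
    if positions is None:
        positions = np.arange(p.size, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.size != p.size:
        raise ValueError("one position per category required")
    dx = np.diff(positions)
    if (dx <= 0).any():
        raise ValueError("positions must be strictly increasing")
    cdf_diff = np.cumsum(p - q)[:-1]
    return float(np.abs(cdf_diff) @ dx)


def hellinger(p: np.ndarray, q: np.ndarray) -> float:
    p, q = _check_pair(p, q)
    bc = float(np.sqrt(p * q).sum())
    return float(np.sqrt(max(0.0, 1.0 - min(bc, 1.0))))


_MEASURE_FNS = {
    "cosine": cosine_distance,
    "jensen_shannon": jensen_shannon,
    "wasserstein": wasserstein_categorical,
    "hellinger": hellinger,
}


@dataclass
class DistanceProfile:
    """Per-case distances of one measure over a set of predictions."""

    measure: str
    values: np.ndarray
    case_ids: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def to_frame(self) -> pd.DataFrame:
        ids = self.case_ids or [f"case_{i:05d}" for i in range(self.values.size)]
        return pd.DataFrame(
            {"case_id": ids, "measure": self.measure, "value": self.values}
        )


def distance_profile(
    pred: np.ndarray,
    targets: np.ndarray,
    measure: str,
    case_ids: list[str] | None = None,
    positions: np.ndarray | None = None,
) -> DistanceProfile:
    """Distance between each predicted row and the matching one-hot target
    row, for one of the four measures."""
    if measure not in _MEASURE_FNS:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    P = np.asarray(pred, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if P.shape != Y.shape:
        raise ValueError("prediction/target shape mismatch")
    fn = _MEASURE_FNS[measure]
    if measure == "wasserstein":
        values = [fn(P[i], Y[i], positions) for i in range(P.shape[0])]
    else:
        values = [fn(P[i], Y[i]) for i in range(P.shape[0])]
    return DistanceProfile(measure, np.asarray(values), case_ids)
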