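"""Diagnosis-to-management mappings.

Two routes from a diagnosis prediction to a management decision:

* the *binary* malignancy rule — MEL and BCC map to EXC, every other
  diagnosis to NOEXC;
* the *data-driven* route — marginalize the predicted diagnosis
  distribution against the empirical conditional priors
  P(MGMT = m | DIAG = d) estimated from the training split:

      P(MGMT = m | x) = sum_d p(DIAG = d | x) * p(MGMT = m | DIAG = d).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import DEFAULT_LABEL_SPACE, LabelSpace, MALIGNANT_DIAGNOSES


@dataclass
class PriorMatrix:
    """P(MGMT = m | DIAG = d): one row per diagnosis, rows sum to 1."""

    table: np.ndarray  # n_diagnoses x n_managements
    source_counts: np.ndarray
    smoothing: float = 0.0
    label_space: LabelSpace = field(default_factory=lambda: DEFAULT_LABEL_SPACE)

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if (t < -1e-12).any() or (t > 1 + 1e-12).any():
            raise ValueError("prior entries must lie in [0, 1]")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("prior rows must sum to 1")
        self.table = t

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.table,
            index=self.label_space.diagnosis_labels,
            columns=self.label_space.management_labels,
        )
        df.index.name = "diagnosis"
        df.to_csv(path)
        meta = {
            "source_counts": np.asarray(self.source_counts).tolist(),
            "smoothing": self.smoothing,
        }
        Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))


def estimate_priors(
    diagnosis: np.ndarray,
    management: np.ndarray,
    smoothing: float = 0.0,
    label_space: LabelSpace = DEFAULT_LABEL_SPACE,
) -> PriorMatrix:
    """Empirical conditional priors from labelled training cases.

    table[d, m] = (count(d, m) + smoothing) / (count(d) + smoothing * n_mgmt).
    With smoothing 0, a diagnosis with no training cases is an error (its
    row would be undefined).
    """
    diagnosis = np.asarray(diagnosis, dtype=np.int64)
    management = np.asarray(management, dtype=np.int64)
    if diagnosis.size == 0:
        raise ValueError("empty training subset")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    nd, nm = label_space.n_diagnosis, label_space.n_management
    counts = np.zeros((nd, nm), dtype=np.int64)
    np.add.at(counts, (diagnosis, management), 1)
    row_tot = counts.sum(axis=1)
    if smoothing == 0 and (row_tot == 0).any():
        empty = [label_space.diagnosis_labels[d] for d in np.flatnonzero(row_tot == 0)]
        raise ValueError(f"no training cases for diagnoses {empty} and smoothing is 0")
    table = (counts + smoothing) / (row_tot + smoothing * nm)[:, None]
    return PriorMatrix(table, counts, smoothing, label_space)


def marginalize_management(diag_probs: np.ndarray, priors: PriorMatrix) -> np.ndarray:
    """P(m | x) = sum_d p(d | x) * p(m | d), per case; rows sum to 1."""
    P = np.asarray(diag_probs, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    if P.shape[1] != priors.table.shape[0]:
        raise ValueError(
            f"diagnosis probability columns ({P.shape[1]}) do not match the "
            f"prior's diagnosis rows ({priors.table.shape[0]})"
        )
    return P @ priors.table


def map_diagnosis_to_binary(
    diag_labels: np.ndarray, label_space: LabelSpace = DEFAULT_LABEL_SPACE
) -> np.ndarray:
    """Malignancy rule: MEL and BCC -> EXC (1); NEV, MISC, SK -> NOEXC (0)."""
    diag_labels = np.asarray(diag_labels, dtype=np.int64)
    if diag_labels.size and (
        diag_labels.min() < 0 or diag_labels.max() >= label_space.n_diagnosis
    ):
        raise ValueError("unknown diagnosis label index")
    malignant = np.array(
        [name in MALIGNANT_DIAGNOSES for name in label_space.diagnosis_labels]
    )
    return malignant[diag_labels].astype(np.int64)


def collapse_management_to_binary(
    mgmt: np.ndarray, label_space: LabelSpace = DEFAULT_LABEL_SPACE
) -> np.ndarray:
    """Group CLNC and NONE into NOEXC; keep EXC.

    Accepts label vectors (1-D int) or probability matrices (2-D), where
    P(NOEXC) = P(NONE) + P(CLNC) and P(EXC) is unchanged.
    """
    arr = np.asarray(mgmt)
    exc = label_space.management_index["EXC"]
    if arr.ndim == 1:
        arr = arr.astype(np.int64)
        if arr.size and (arr.min() < 0 or arr.max() >= label_space.n_management):
            raise ValueError("unknown management label index")
        return (arr == exc).astype(np.int64)
    if arr.ndim == 2:
        noexc_cols = [i for i in range(label_space.n_management) if i != exc]
        return np.column_stack([arr[:, noexc_cols].sum(axis=1), arr[:, exc]])
    raise ValueError("expected a label vector or a probability matrix")


def decide_label(probs: np.ndarray, tie_rule: str = "most_severe") -> np.ndarray:
    """Most-likely-label decision per case.

    Exact ties default to the most severe label (highest index in the
    NONE < CLNC < EXC severity order), the clinically conservative choice;
    ``tie_rule='first'`` keeps the lowest index instead.
    """
    P = np.asarray(probs, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    if np.isnan(P).any():
        raise ValueError("NaN probabilities")
    if tie_rule == "most_severe":
        # argmax on the reversed column order returns the highest tied index
        return P.shape[1] - 1 - np.argmax(P[:, ::-1], axis=1)
    if tie_rule == "first":
        return np.argmax(P, axis=1)
    raise ValueError(f"unknown tie rule {tie_rule!r}")
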