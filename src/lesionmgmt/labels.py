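"""Label spaces and the packaged cohort fixture.

The three vocabularies are fixed, ordered categoricals:

* management — NONE (no further examination), CLNC (clinical follow-up),
  EXC (excision), ordered by increasing severity of the intervention;
* diagnosis — BCC, NEV, MEL, MISC, SK, the five grouped diagnosis classes;
* binary management — NOEXC, EXC.

``TABLE1_JOINT_COUNTS`` and ``TABLE1_SPLIT_COUNTS`` package the published
1011-case seven-point-checklist cohort breakdown (management x diagnosis
joint counts and the management-stratified 413:203:395 train/valid/test
split) that the synthetic generator reproduces exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MANAGEMENT_LABELS: tuple[str, ...] = ("NONE", "CLNC", "EXC")
DIAGNOSIS_LABELS: tuple[str, ...] = ("BCC", "NEV", "MEL", "MISC", "SK")
BINARY_LABELS: tuple[str, ...] = ("NOEXC", "EXC")
SPLIT_NAMES: tuple[str, ...] = ("train", "valid", "test")

#: Diagnosis classes mapped to excision under the malignancy rule.
MALIGNANT_DIAGNOSES: frozenset[str] = frozenset({"BCC", "MEL"})

# Management (rows: NONE, CLNC, EXC) x diagnosis (cols: BCC, NEV, MEL, MISC, SK).
TABLE1_JOINT_COUNTS = np.array(
    [
        [0, 29, 0, 50, 31],
        [0, 268, 0, 24, 4],
        [42, 278, 252, 23, 10],
    ],
    dtype=np.int64,
)

# Management (rows: NONE, CLNC, EXC) x split (cols: train, valid, test).
TABLE1_SPLIT_COUNTS = np.array(
    [
        [45, 25, 40],
        [133, 51, 112],
        [235, 127, 243],
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class LabelSpace:
    """Fixed label vocabularies shared by every pipeline stage."""

    management_labels: tuple[str, ...] = MANAGEMENT_LABELS
    diagnosis_labels: tuple[str, ...] = DIAGNOSIS_LABELS
    binary_labels: tuple[str, ...] = BINARY_LABELS
    #: index of each label, per vocabulary
    management_index: dict[str, int] = field(init=False)
    diagnosis_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        for labels in (self.management_labels, self.diagnosis_labels, self.binary_labels):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate label names in {labels}")
        object.__setattr__(
            self, "management_index", {l: i for i, l in enumerate(self.management_labels)}
        )
        object.__setattr__(
            self, "diagnosis_index", {l: i for i, l in enumerate(self.diagnosis_labels)}
        )

    @property
    def n_management(self) -> int:
        return len(self.management_labels)

    @property
    def n_diagnosis(self) -> int:
        return len(self.diagnosis_labels)


DEFAULT_LABEL_SPACE = LabelSpace()
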