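"""Synthetic skin-lesion cohort generator.

The generator emulates the label structure of the published 1011-case
seven-point-checklist cohort: a fixed management x diagnosis joint count
table, management-stratified train/valid/test splits, patient metadata
(sex, lesion site, lesion elevation), seven integer-scored dermoscopic
criteria, and surrogate numeric feature vectors standing in for clinical
and dermoscopic image features.

The key modelled mechanism is a latent per-case *severity* in [0, 1] that
management depends on **within** a diagnosis: severities are drawn from
per-management Beta laws and, within each diagnosis, management labels are
reassigned by severity rank so that the least severe cases fill the NONE
quota and the most severe fill the EXC quota. Severity leaks into the
feature vectors along a direction orthogonal to the diagnosis class means,
with strength ``severity_weight``. A diagnosis-only model therefore cannot
recover the within-diagnosis management variability, while a direct
management model can — unless ``severity_weight`` is zero, in which case
management is conditionally independent of the features given diagnosis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import (
    DEFAULT_LABEL_SPACE,
    LabelSpace,
    MALIGNANT_DIAGNOSES,
    SPLIT_NAMES,
    TABLE1_JOINT_COUNTS,
    TABLE1_SPLIT_COUNTS,
)

SEX_LEVELS: tuple[str, ...] = ("female", "male")
SITE_LEVELS: tuple[str, ...] = (
    "head_neck",
    "back",
    "chest",
    "abdomen",
    "upper_limbs",
    "lower_limbs",
    "acral",
    "genital",
)
ELEVATION_LEVELS: tuple[str, ...] = ("flat", "palpable", "nodular")

# Per-management Beta(a, b) severity laws, ordered NONE, CLNC, EXC.
# Means 0.25 / 0.50 / 0.75: more severe management tiers see higher severity.
SEVERITY_BETA_PARAMS: tuple[tuple[float, float], ...] = ((2.0, 6.0), (4.0, 4.0), (6.0, 2.0))

CRITERIA_NAMES: tuple[str, ...] = tuple(f"criterion_{k}" for k in range(1, 8))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort generator.

    Defaults reproduce the published cohort's label structure exactly and
    place a strong severity signal (severity_weight=6, unit noise) in both
    surrogate image modalities, with diagnosis class means separated enough
    for a realistic (partially confusable) diagnosis task.
    """

    joint_counts: np.ndarray = field(
        default_factory=lambda: TABLE1_JOINT_COUNTS.copy()
    )  # management x diagnosis
    split_counts: np.ndarray | None = field(
        default_factory=lambda: TABLE1_SPLIT_COUNTS.copy()
    )  # management x (train, valid, test); None leaves splits unassigned
    severity_weight: float = 6.0
    feature_dim_clinical: int = 8
    feature_dim_dermoscopic: int = 8
    noise_sd: float = 1.0
    class_mean_scale: float = 0.9
    #: which modality carries the severity direction: "both", "clinical",
    #: "dermoscopic", or "none"
    severity_modality: str = "both"
    n_criteria_categories: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        joint = np.asarray(self.joint_counts, dtype=np.int64)
        object.__setattr__(self, "joint_counts", joint)
        if joint.ndim != 2 or joint.shape[0] != 3:
            raise ValueError(f"joint_counts must be 3 x n_diagnoses, got {joint.shape}")
        if (joint < 0).any():
            raise ValueError("joint_counts must be non-negative")
        if self.split_counts is not None:
            split = np.asarray(self.split_counts, dtype=np.int64)
            object.__setattr__(self, "split_counts", split)
            if split.shape != (3, 3):
                raise ValueError(f"split_counts must be 3 x 3, got {split.shape}")
            if (split < 0).any():
                raise ValueError("split_counts must be non-negative")
            if not np.array_equal(split.sum(axis=1), joint.sum(axis=1)):
                raise ValueError(
                    "split_counts row sums must equal joint_counts row sums "
                    f"({split.sum(axis=1)} vs {joint.sum(axis=1)})"
                )
        if self.severity_weight < 0:
            raise ValueError("severity_weight must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.feature_dim_clinical < 6 or self.feature_dim_dermoscopic < 6:
            # 5 dims for diagnosis class means + 1 orthogonal severity direction
            raise ValueError("feature dimensions must be >= 6")
        if self.severity_modality not in ("both", "clinical", "dermoscopic", "none"):
            raise ValueError(f"unknown severity_modality {self.severity_modality!r}")
        if self.n_criteria_categories < 2:
            raise ValueError("n_criteria_categories must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["joint_counts"] = self.joint_counts.tolist()
        d["split_counts"] = None if self.split_counts is None else self.split_counts.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["joint_counts"] = np.asarray(d["joint_counts"], dtype=np.int64)
        if d.get("split_counts") is not None:
            d["split_counts"] = np.asarray(d["split_counts"], dtype=np.int64)
        return cls(**d)


@dataclass
class Cohort:
    """A synthetic cohort: one manifest row per case plus per-modality features.

    ``manifest`` columns: case_id, split, diagnosis (index), management
    (index), criterion_1..criterion_7, sex, site, elevation, severity.
    ``severity`` is the generator-only latent; downstream models never see it.
    """

    manifest: pd.DataFrame
    features_clinical: np.ndarray
    features_dermoscopic: np.ndarray
    config: GeneratorConfig
    label_space: LabelSpace = field(default_factory=lambda: DEFAULT_LABEL_SPACE)

    def __post_init__(self) -> None:
        n = len(self.manifest)
        if self.features_clinical.shape[0] != n or self.features_dermoscopic.shape[0] != n:
            raise ValueError("feature row counts must match the manifest")

    def __len__(self) -> int:
        return len(self.manifest)

    @property
    def diagnosis(self) -> np.ndarray:
        return self.manifest["diagnosis"].to_numpy()

    @property
    def management(self) -> np.ndarray:
        return self.manifest["management"].to_numpy()

    @property
    def criteria(self) -> np.ndarray:
        return self.manifest[list(CRITERIA_NAMES)].to_numpy()

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return Cohort(
            manifest=self.manifest.iloc[idx].reset_index(drop=True),
            features_clinical=self.features_clinical[idx],
            features_dermoscopic=self.features_dermoscopic[idx],
            config=self.config,
            label_space=self.label_space,
        )

    def split(self, name: str) -> "Cohort":
        return self.subset((self.manifest["split"] == name).to_numpy())


@dataclass
class RaterPanel:
    """Raters x cases binary recommendation matrix (1 = EXC, 0 = NOEXC)."""

    recommendations: np.ndarray
    rater_ids: list[str]
    case_ids: list[str]

    def __post_init__(self) -> None:
        rec = np.asarray(self.recommendations, dtype=np.int64)
        if rec.ndim != 2:
            raise ValueError("recommendations must be 2-D (raters x cases)")
        if not np.isin(rec, (0, 1)).all():
            raise ValueError("recommendations must be binary")
        if rec.shape != (len(self.rater_ids), len(self.case_ids)):
            raise ValueError("recommendation matrix shape must match id lists")
        self.recommendations = rec

    @property
    def n_raters(self) -> int:
        return self.recommendations.shape[0]

    @property
    def n_cases(self) -> int:
        return self.recommendations.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.recommendations, index=self.rater_ids, columns=self.case_ids)
        df.index.name = "rater_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RaterPanel":
        df = pd.read_csv(path, index_col=0)
        return cls(
            recommendations=df.to_numpy(dtype=np.int64),
            rater_ids=[str(r) for r in df.index],
            case_ids=[str(c) for c in df.columns],
        )


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child streams from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _assemble(
    config: GeneratorConfig,
    diagnosis: np.ndarray,
    management: np.ndarray,
    rngs: list[np.random.Generator],
) -> Cohort:
    """Severity, features, criteria and metadata for given label arrays."""
    rng_sev, rng_feat, rng_crit, rng_meta = rngs
    n = diagnosis.size
    n_diag = config.joint_counts.shape[1]

    # severity ~ Beta law of the table-assigned management ...
    a = np.array([p[0] for p in SEVERITY_BETA_PARAMS])[management]
    b = np.array([p[1] for p in SEVERITY_BETA_PARAMS])[management]
    severity = rng_sev.beta(a, b)
    # ... then, within each diagnosis, reassign management by severity rank so
    # quotas are filled from least severe (NONE) to most severe (EXC).
    management = management.copy()
    for d in range(n_diag):
        idx = np.flatnonzero(diagnosis == d)
        if idx.size == 0:
            continue
        order = idx[np.argsort(severity[idx], kind="stable")]
        counts = np.bincount(management[idx], minlength=3)
        tiers = np.repeat(np.arange(3), counts)
        management[order] = tiers

    def modality_features(dim: int, carries_severity: bool) -> np.ndarray:
        X = rng_feat.normal(0.0, config.noise_sd, size=(n, dim))
        X[np.arange(n), diagnosis] += config.class_mean_scale
        if carries_severity and config.severity_weight > 0:
            # severity direction: basis vector orthogonal to the class-mean span
            X[:, n_diag] += config.severity_weight * severity
        return X

    Xc = modality_features(
        config.feature_dim_clinical, config.severity_modality in ("both", "clinical")
    )
    Xd = modality_features(
        config.feature_dim_dermoscopic, config.severity_modality in ("both", "dermoscopic")
    )

    malignant = np.isin(
        diagnosis,
        [DEFAULT_LABEL_SPACE.diagnosis_index[d] for d in MALIGNANT_DIAGNOSES],
    )
    p_crit = np.clip(0.15 + 0.5 * severity + 0.2 * malignant, 0.01, 0.99)
    criteria = rng_crit.binomial(
        config.n_criteria_categories - 1, p_crit[:, None], size=(n, 7)
    )

    sex = rng_meta.choice(len(SEX_LEVELS), size=n)
    site = rng_meta.choice(len(SITE_LEVELS), size=n)
    p_elev = np.clip(0.15 + 0.6 * severity, 0.01, 0.99)
    elevation = rng_meta.binomial(len(ELEVATION_LEVELS) - 1, p_elev)

    manifest = pd.DataFrame(
        {
            "case_id": [f"case_{i:05d}" for i in range(n)],
            "split": "unassigned",
            "diagnosis": diagnosis,
            "management": management,
        }
    )
    for k, name in enumerate(CRITERIA_NAMES):
        manifest[name] = criteria[:, k]
    manifest["sex"] = np.asarray(SEX_LEVELS)[sex]
    manifest["site"] = np.asarray(SITE_LEVELS)[site]
    manifest["elevation"] = np.asarray(ELEVATION_LEVELS)[elevation]
    manifest["severity"] = severity

    return Cohort(manifest, Xc, Xd, config)


def generate_exact_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a cohort whose (management, diagnosis) cell counts match
    ``config.joint_counts`` exactly; splits assigned when split_counts given.
    """
    joint = config.joint_counts
    total = int(joint.sum())
    if total == 0:
        raise ValueError("joint_counts sum to zero")
    rngs = _child_rngs(config.seed, 6)
    mgmt_cells, diag_cells = np.nonzero(joint)
    counts = joint[mgmt_cells, diag_cells]
    management = np.repeat(mgmt_cells, counts)
    diagnosis = np.repeat(diag_cells, counts)
    cohort = _assemble(config, diagnosis, management, rngs[1:5])
    if config.split_counts is not None:
        cohort = assign_splits(cohort, config.split_counts, rng=rngs[5])
    return cohort


def generate_sampled_cohort(config: GeneratorConfig, n: int) -> Cohort:
    """Generate ``n`` cases with labels drawn i.i.d. from the normalized
    joint table (empirical frequencies converge to the table as n grows)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    joint = config.joint_counts.astype(float)
    total = joint.sum()
    if total == 0:
        raise ValueError("joint_counts sum to zero")
    probs = (joint / total).ravel()
    rngs = _child_rngs(config.seed, 6)
    flat = rngs[0].choice(probs.size, size=n, p=probs)
    management, diagnosis = np.unravel_index(flat, joint.shape)
    return _assemble(config, diagnosis, management, rngs[1:5])


def assign_splits(
    cohort: Cohort,
    split_counts: np.ndarray,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Assign train/valid/test splits stratified by management label.

    Per management stratum, cases are permuted and the per-split quotas of
    ``split_counts`` (management x [train, valid, test]) are filled exactly.
    """
    split_counts = np.asarray(split_counts, dtype=np.int64)
    if rng is None:
        rng = np.random.default_rng(seed)
    management = cohort.management
    per_mgmt = np.bincount(management, minlength=3)
    if not np.array_equal(split_counts.sum(axis=1), per_mgmt):
        raise ValueError(
            f"split_counts row sums {split_counts.sum(axis=1)} do not match "
            f"cohort per-management counts {per_mgmt}"
        )
    split = np.empty(len(cohort), dtype=object)
    for m in range(3):
        idx = rng.permutation(np.flatnonzero(management == m))
        bounds = np.cumsum(split_counts[m])[:-1]
        for part, name in zip(np.split(idx, bounds), SPLIT_NAMES):
            split[part] = name
    manifest = cohort.manifest.copy()
    manifest["split"] = split
    return Cohort(
        manifest, cohort.features_clinical, cohort.features_dermoscopic, cohort.config,
        cohort.label_space,
    )


def simulate_rater_panel(
    true_binary: np.ndarray,
    n_raters: int,
    sensitivity: float,
    specificity: float,
    seed: int,
) -> RaterPanel:
    """Simulate independent raters voting EXC with probability ``sensitivity``
    on true-EXC cases and ``1 - specificity`` on true-NOEXC cases."""
    true_binary = np.asarray(true_binary, dtype=np.int64)
    if true_binary.size == 0:
        raise ValueError("empty label vector")
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    rng = np.random.default_rng(seed)
    p_exc = np.where(true_binary == 1, sensitivity, 1.0 - specificity)
    votes = (rng.random((n_raters, true_binary.size)) < p_exc).astype(np.int64)
    return RaterPanel(
        recommendations=votes,
        rater_ids=[f"rater_{r:03d}" for r in range(n_raters)],
        case_ids=[f"case_{c:05d}" for c in range(true_binary.size)],
    )


# ---------------------------------------------------------------------------
# metadata encoding and manifest I/O

METADATA_DIM = len(SEX_LEVELS) + len(SITE_LEVELS) + len(ELEVATION_LEVELS)


def encode_metadata(manifest: pd.DataFrame) -> np.ndarray:
    """One-hot encode sex, site and elevation (missing -> all-zero block)."""
    blocks = []
    for col, levels in (
        ("sex", SEX_LEVELS),
        ("site", SITE_LEVELS),
        ("elevation", ELEVATION_LEVELS),
    ):
        codes = pd.Categorical(manifest[col], categories=levels).codes
        block = np.zeros((len(manifest), len(levels)))
        known = codes >= 0
        block[np.flatnonzero(known), codes[known]] = 1.0
        blocks.append(block)
    return np.hstack(blocks)


def design_matrix(cohort: Cohort, modalities: str = "CDM") -> np.ndarray:
    """Concatenate the requested modality blocks: C (clinical features),
    D (dermoscopic features), M (one-hot metadata)."""
    if not modalities or any(ch not in "CDM" for ch in modalities):
        raise ValueError(f"modalities must be a non-empty subset of 'CDM', got {modalities!r}")
    blocks = []
    if "C" in modalities:
        blocks.append(cohort.features_clinical)
    if "D" in modalities:
        blocks.append(cohort.features_dermoscopic)
    if "M" in modalities:
        blocks.append(encode_metadata(cohort.manifest))
    return np.hstack(blocks)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write manifest CSV, per-modality feature CSVs and a JSON sidecar
    recording the generator configuration and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    manifest["diagnosis"] = [cohort.label_space.diagnosis_labels[d] for d in manifest["diagnosis"]]
    manifest["management"] = [
        cohort.label_space.management_labels[m] for m in manifest["management"]
    ]
    manifest.drop(columns=["severity"]).to_csv(outdir / "manifest.csv", index=False)
    for name, X in (
        ("features_clinical", cohort.features_clinical),
        ("features_dermoscopic", cohort.features_dermoscopic),
    ):
        pd.DataFrame(X, columns=[str(j) for j in range(X.shape[1])]).to_csv(
            outdir / f"{name}.csv", index=False
        )
    with open(outdir / "generator_config.json", "w") as fh:
        json.dump(cohort.config.to_dict(), fh, indent=2)


def read_cohort(outdir: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (severity is not
    persisted; it is a generator-only latent)."""
    outdir = Path(outdir)
    with open(outdir / "generator_config.json") as fh:
        config = GeneratorConfig.from_dict(json.load(fh))
    manifest = pd.read_csv(outdir / "manifest.csv")
    space = DEFAULT_LABEL_SPACE
    manifest["diagnosis"] = [space.diagnosis_index[d] for d in manifest["diagnosis"]]
    manifest["management"] = [space.management_index[m] for m in manifest["management"]]
    manifest["severity"] = np.nan
    Xc = pd.read_csv(outdir / "features_clinical.csv").to_numpy()
    Xd = pd.read_csv(outdir / "features_dermoscopic.csv").to_numpy()
    return Cohort(manifest, Xc, Xd, config)
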