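"""Feature-curve assembly and reference-anchored normalization.

A *feature curve* is the sequence of one radiomic feature's values over the
frames of the cardiac cycle, for one subject and one noise instance.  To
make curves of the same subject comparable across noise instances, every
curve is normalized by the mean and standard deviation of the subject's
*reference* (noise-free) curve, so the reference maps to mean 0 / std 1 and
noisy curves are measured in reference-std units.  Features whose reference
curve is constant (zero std) cannot be normalized and are excluded for that
subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CompletenessError, MissingReferenceError

__all__ = [
    "FeatureCurve",
    "NormalizationParams",
    "build_curves",
    "normalize_curves",
    "normalize_all",
]

REFERENCE_LABEL = "reference"


@dataclass
class FeatureCurve:
    """One feature's value over all frames, for one subject and instance."""

    subject_id: str
    feature_id: str
    level_label: str
    replicate_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def is_reference(self) -> bool:
        return self.level_label == REFERENCE_LABEL


@dataclass(frozen=True)
class NormalizationParams:
    """Reference-curve statistics used to normalize a subject+feature."""

    subject_id: str
    feature_id: str
    mu_ref: float
    sigma_ref: float
    excluded: bool


def build_curves(feature_table: pd.DataFrame) -> list[FeatureCurve]:
    """Assemble long-format feature rows into per-instance curves.

    The table must be complete: every (subject, instance) must provide every
    feature at every frame.  Rows may arrive in any order; curves are sorted
    by frame index.
    """
    required = {
        "subject_id",
        "level_label",
        "replicate_index",
        "frame_index",
        "feature_id",
        "value",
    }
    missing_cols = required - set(feature_table.columns)
    if missing_cols:
        raise CompletenessError(f"feature table lacks columns {sorted(missing_cols)}")

    curves: list[FeatureCurve] = []
    for subject_id, sub in feature_table.groupby("subject_id", sort=True):
        frame_idx = np.sort(sub["frame_index"].unique())
        n_frames = frame_idx.size
        expected_frames = set(range(n_frames))
        if set(frame_idx.tolist()) != expected_frames:
            raise CompletenessError(
                f"subject {subject_id}: frame indices are not contiguous 0..T-1"
            )
        feature_ids = np.sort(sub["feature_id"].unique())
        for (level, rep), inst in sub.groupby(
            ["level_label", "replicate_index"], sort=True
        ):
            pivot = inst.pivot_table(
                index="frame_index", columns="feature_id", values="value", dropna=False
            )
            pivot = pivot.reindex(index=range(n_frames), columns=feature_ids)
            if pivot.isna().any().any():
                stacked = pivot.isna().stack()
                frame, fid = stacked[stacked].index[0]
                raise CompletenessError(
                    f"missing value: subject={subject_id} instance=({level},{rep}) "
                    f"frame={frame} feature={fid}"
                )
            for fid in feature_ids:
                curves.append(
                    FeatureCurve(
                        subject_id=subject_id,
                        feature_id=str(fid),
                        level_label=str(level),
                        replicate_index=int(rep),
                        values=pivot[fid].to_numpy(),
                    )
                )
    return curves


def normalize_curves(
    curves: list[FeatureCurve],
) -> tuple[list[FeatureCurve], NormalizationParams]:
    """Normalize all curves of one subject+feature by the reference curve.

    ``mu_ref`` and ``sigma_ref`` (population form, denominator T) come from
    the reference curve alone; the same affine map is applied to every
    instance.  If ``sigma_ref == 0`` the feature is flagged excluded and no
    normalized curves are returned.
    """
    if not curves:
        raise MissingReferenceError("no curves given")
    subject_id = curves[0].subject_id
    feature_id = curves[0].feature_id
    for c in curves:
        if c.subject_id != subject_id or c.feature_id != feature_id:
            raise MissingReferenceError(
                "normalize_curves expects curves of a single subject+feature"
            )
    ref = [c for c in curves if c.is_reference]
    if not ref:
        raise MissingReferenceError(
            f"no reference curve for subject={subject_id} feature={feature_id}"
        )
    ref_values = ref[0].values
    mu_ref = float(ref_values.mean())
    sigma_ref = float(ref_values.std())  # ddof=0: population form
    if sigma_ref == 0.0:
        params = NormalizationParams(subject_id, feature_id, mu_ref, 0.0, True)
        return [], params
    params = NormalizationParams(subject_id, feature_id, mu_ref, sigma_ref, False)
    normalized = [
        FeatureCurve(
            subject_id=c.subject_id,
            feature_id=c.feature_id,
            level_label=c.level_label,
            replicate_index=c.replicate_index,
            values=(c.values - mu_ref) / sigma_ref,
        )
        for c in curves
    ]
    return normalized, params


def normalize_all(
    curves: list[FeatureCurve],
) -> tuple[list[FeatureCurve], pd.DataFrame]:
    """Normalize every (subject, feature) group of a curve collection.

    Returns the surviving normalized curves and an exclusion report with one
    row per (subject, feature): columns subject_id, feature_id, mu_ref,
    sigma_ref, excluded.
    """
    groups: dict[tuple[str, str], list[FeatureCurve]] = {}
    for c in curves:
        groups.setdefault((c.subject_id, c.feature_id), []).append(c)
    normalized: list[FeatureCurve] = []
    rows = []
    for (sid, fid) in sorted(groups):
        norm, params = normalize_curves(groups[(sid, fid)])
        normalized.extend(norm)
        rows.append(
            {
                "subject_id": sid,
                "feature_id": fid,
                "mu_ref": params.mu_ref,
                "sigma_ref": params.sigma_ref,
                "excluded": params.excluded,
            }
        )
    report = pd.DataFrame(rows, columns=["subject_id", "feature_id", "mu_ref", "sigma_ref", "excluded"])
    return normalized, report


def curves_to_table(curves: list[FeatureCurve], normalized: bool = True) -> pd.DataFrame:
    """Serialize curves to the long-format CSV schema."""
    records = []
    for c in curves:
        for t, v in enumerate(c.values):
            records.append(
                (c.subject_id, c.level_label, c.replicate_index, t, c.feature_id, v, normalized)
            )
    return pd.DataFrame(
        records,
        columns=[
            "subject_id",
            "level_label",
            "replicate_index",
            "frame_index",
            "feature_id",
            "value",
            "normalized",
        ],
    )
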