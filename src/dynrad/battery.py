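"""Designed feature battery with known, strictly ordered noise sensitivity.

Validation tooling for the stability pipeline: from a subject's noise
instances it derives a family of synthetic features, all sharing the
reference ROI-mean curve but with the noise-induced deviation amplified by
a known multiplier m:

    battery_m(t) = ref_mean(t) + m * (instance_mean(t) - ref_mean(t))

Because the reference curve — and hence the normalization — is identical
across the battery, the mean pairwise MAE scales exactly linearly in m, so
a correct stability ranking must recover the multiplier order.  A literal
scaled copy m*curve would NOT work: the reference-anchored normalization
divides it back out.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .phantom import NoiseInstance

__all__ = ["battery_feature_table"]

DEFAULT_MULTIPLIERS = (1, 2, 4, 8)


def _roi_mean_curve(instance: NoiseInstance) -> np.ndarray:
    seq = instance.sequence
    return np.array(
        [seq.frames[t][seq.masks[t].astype(bool)].mean() for t in range(seq.n_frames)]
    )


def battery_feature_table(
    instances: Sequence[NoiseInstance],
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
) -> pd.DataFrame:
    """Long-format feature table of the amplified-noise battery.

    Feature ids are ``battery_mean_x<m>``; the table plugs directly into
    :func:`dynrad.curves.build_curves`.
    """
    reference = [i for i in instances if i.level_label == "reference"]
    if len(reference) != 1:
        raise ValueError("expected exactly one reference instance")
    ref_curve = _roi_mean_curve(reference[0])
    records = []
    for inst in instances:
        inst_curve = _roi_mean_curve(inst)
        for m in multipliers:
            values = ref_curve + m * (inst_curve - ref_curve)
            fid = f"battery_mean_x{m:g}"
            for t, v in enumerate(values):
                records.append(
                    (
                        inst.subject_id,
                        inst.level_label,
                        inst.replicate_index,
                        t,
                        fid,
                        float(v),
                    )
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
        ],
    )
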