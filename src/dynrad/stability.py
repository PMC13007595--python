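"""Feature-curve stability scores, rankings and the cross-subject consensus.

The stability of a feature for one subject is the mean pairwise MAE
(mpMAE) of its normalized curves over all unordered pairs of noise
instances — 0 is perfect stability, larger values mean the curve is
perturbed more by noise.  Restricting the pairs to instances of the same
noise level yields the within-level mpMAE, which separates sensitivity to
the *amount* of noise from sensitivity to the specific noise realization:
a feature whose curves shift deterministically with noise level but agree
within a level has a small within-level score and a large overall score.

Per-subject rankings (fractional ranks on mpMAE, 1 = most stable) are
compared across subjects with Spearman correlation and aggregated into a
consensus by ordering features on their median rank.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .curves import FeatureCurve
from .errors import (
    AlignmentError,
    EmptyConsensusError,
    EmptyRankingError,
    InsufficientInstancesError,
)

__all__ = [
    "curve_mae",
    "mean_pairwise_mae",
    "within_level_mae",
    "compute_stability",
    "rank_features",
    "spearman_rho",
    "correlation_matrix",
    "consensus_ranking",
]


def curve_mae(f: FeatureCurve | np.ndarray, g: FeatureCurve | np.ndarray) -> float:
    """Mean absolute error between two curves of equal length."""
    fv = f.values if isinstance(f, FeatureCurve) else np.asarray(f, dtype=np.float64)
    gv = g.values if isinstance(g, FeatureCurve) else np.asarray(g, dtype=np.float64)
    if fv.shape != gv.shape:
        raise AlignmentError(f"curve lengths differ: {fv.shape} vs {gv.shape}")
    return float(np.mean(np.abs(fv - gv)))


def mean_pairwise_mae(curves: list[FeatureCurve]) -> tuple[float, int]:
    """Mean of curve MAE over all unordered instance pairs.

    The reference counts as an instance; with the conventional 41 instances
    this is a mean over 820 pairs.  Returns ``(mpMAE, n_pairs)``.
    """
    if len(curves) < 2:
        raise InsufficientInstancesError(
            f"need >= 2 instances, got {len(curves)}"
        )
    values = np.stack([c.values for c in curves])
    total = 0.0
    n_pairs = 0
    for a, b in combinations(range(len(curves)), 2):
        total += float(np.mean(np.abs(values[a] - values[b])))
        n_pairs += 1
    return total / n_pairs, n_pairs


def within_level_mae(curves: list[FeatureCurve]) -> tuple[float, int]:
    """mpMAE restricted to pairs sharing a noise level (pair-weighted).

    The single reference instance contributes no pairs.  If no level has
    two replicates the score is undefined: returns ``(nan, 0)`` rather than
    raising, so callers can record the missing value.
    """
    by_level: dict[str, list[FeatureCurve]] = {}
    for c in curves:
        by_level.setdefault(c.level_label, []).append(c)
    total = 0.0
    n_pairs = 0
    for level, group in by_level.items():
        for a, b in combinations(group, 2):
            total += curve_mae(a, b)
            n_pairs += 1
    if n_pairs == 0:
        return float("nan"), 0
    return total / n_pairs, n_pairs


def compute_stability(
    normalized: list[FeatureCurve], exclusions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Stability table over all (subject, feature) groups of a cohort.

    Columns: subject_id, feature_id, mpMAE, within_level_mpMAE, n_pairs,
    n_within_pairs, rank, within_level_rank, excluded.  Excluded features
    (from the normalization report) appear with NaN scores and no rank.
    """
    groups: dict[tuple[str, str], list[FeatureCurve]] = {}
    for c in normalized:
        groups.setdefault((c.subject_id, c.feature_id), []).append(c)
    rows = []
    for (sid, fid) in sorted(groups):
        mp, n_pairs = mean_pairwise_mae(groups[(sid, fid)])
        wl, n_wl = within_level_mae(groups[(sid, fid)])
        rows.append(
            {
                "subject_id": sid,
                "feature_id": fid,
                "mpMAE": mp,
                "within_level_mpMAE": wl,
                "n_pairs": n_pairs,
                "n_within_pairs": n_wl,
                "excluded": False,
            }
        )
    if exclusions is not None:
        for _, r in exclusions[exclusions["excluded"]].iterrows():
            rows.append(
                {
                    "subject_id": r["subject_id"],
                    "feature_id": r["feature_id"],
                    "mpMAE": np.nan,
                    "within_level_mpMAE": np.nan,
                    "n_pairs": 0,
                    "n_within_pairs": 0,
                    "excluded": True,
                }
            )
    table = pd.DataFrame(rows).sort_values(["subject_id", "feature_id"], ignore_index=True)
    ranks = []
    wl_ranks = []
    for sid, sub in table.groupby("subject_id"):
        included = sub[~sub["excluded"]]
        if len(included) >= 2:
            r = rank_features(included.set_index("feature_id")["mpMAE"])
            wr = included.set_index("feature_id")["within_level_mpMAE"].rank(method="average")
        else:
            r = pd.Series(dtype=float)
            wr = pd.Series(dtype=float)
        ranks.append(sub["feature_id"].map(r))
        wl_ranks.append(sub["feature_id"].map(wr))
    table["rank"] = pd.concat(ranks).sort_index()
    table["within_level_rank"] = pd.concat(wl_ranks).sort_index()
    return table


def rank_features(mpmae: pd.Series) -> pd.Series:
    """Ascending fractional ranks (ties share the mean positional rank)."""
    valid = mpmae.dropna()
    if len(valid) < 2:
        raise EmptyRankingError("need >= 2 non-excluded features to rank")
    return valid.rank(method="average")


def spearman_rho(x: pd.Series, y: pd.Series) -> float:
    """Spearman coefficient (Pearson correlation of fractional ranks).

    Restricted to the index shared by both series; returns NaN when fewer
    than 3 pairs remain or either rank vector is constant.
    """
    shared = x.index.intersection(y.index)
    if len(shared) < 3:
        return float("nan")
    xs = stats.rankdata(x.loc[shared].to_numpy())
    ys = stats.rankdata(y.loc[shared].to_numpy())
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    return float(stats.pearsonr(xs, ys).statistic)


def correlation_matrix(
    rankings: dict[str, pd.Series],
) -> tuple[pd.DataFrame, float]:
    """Pairwise Spearman matrix of per-subject stability rankings.

    ``rankings`` maps subject_id -> Series of mpMAE (or ranks) indexed by
    feature_id.  Returns the symmetric matrix (diagonal 1) and the median
    off-diagonal coefficient (NaN cells excluded).
    """
    subjects = sorted(rankings)
    if len(subjects) < 2:
        raise InsufficientInstancesError("need >= 2 subjects for a correlation matrix")
    n = len(subjects)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    off: list[float] = []
    for i, j in combinations(range(n), 2):
        rho = spearman_rho(rankings[subjects[i]], rankings[subjects[j]])
        mat[i, j] = mat[j, i] = rho
        if not np.isnan(rho):
            off.append(rho)
    median_off = float(np.median(off)) if off else float("nan")
    return pd.DataFrame(mat, index=subjects, columns=subjects), median_off


def consensus_ranking(stability_table: pd.DataFrame) -> pd.DataFrame:
    """Median-rank consensus over subjects.

    Features non-excluded in *all* subjects are ordered by median rank
    ascending, ties broken by median mpMAE then feature_id; they receive
    consensus ranks 1..K and a parallel within-level consensus rank (from
    the within-level rank medians).  Features excluded for at least one
    subject are appended with NaN consensus ranks and their
    ``n_subjects_present`` count.
    """
    n_subjects = stability_table["subject_id"].nunique()
    grouped = stability_table.groupby("feature_id")
    rows = []
    for fid, sub in grouped:
        present = sub[~sub["excluded"]]
        rows.append(
            {
                "feature_id": fid,
                "n_subjects_present": len(present),
                "in_all": len(present) == n_subjects,
                "median_rank": float(present["rank"].median()) if len(present) else np.nan,
                "median_mpMAE": float(present["mpMAE"].median()) if len(present) else np.nan,
                "median_within_level_rank": (
                    float(present["within_level_rank"].median()) if len(present) else np.nan
                ),
                "median_within_level_mpMAE": (
                    float(present["within_level_mpMAE"].median()) if len(present) else np.nan
                ),
            }
        )
    df = pd.DataFrame(rows)
    core = df[df["in_all"]].copy()
    if core.empty:
        raise EmptyConsensusError("no feature is non-excluded in every subject")
    core = core.sort_values(
        ["median_rank", "median_mpMAE", "feature_id"], ignore_index=True
    )
    core["consensus_rank"] = np.arange(1, len(core) + 1)
    wl = core.sort_values(
        ["median_within_level_rank", "median_within_level_mpMAE", "feature_id"]
    )
    wl_rank = pd.Series(
        np.arange(1, len(wl) + 1), index=wl["feature_id"].to_numpy()
    )
    core["within_level_consensus_rank"] = core["feature_id"].map(wl_rank)
    rest = df[~df["in_all"]].copy()
    rest["consensus_rank"] = np.nan
    rest["within_level_consensus_rank"] = np.nan
    out = pd.concat([core, rest], ignore_index=True).drop(columns=["in_all"])
    cols = [
        "feature_id",
        "consensus_rank",
        "median_rank",
        "median_mpMAE",
        "within_level_consensus_rank",
        "median_within_level_rank",
        "median_within_level_mpMAE",
        "n_subjects_present",
    ]
    return out[cols]
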