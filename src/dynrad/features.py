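"""Self-contained 2D radiomic feature engine.

Computes named per-frame feature vectors from an intensity image and a
binary region-of-interest mask.  Three image filters (identity, single-level
undecimated Haar wavelet sub-bands, rotation-invariant uniform local binary
patterns) feed three feature families (first-order intensity statistics,
grey level co-occurrence matrix, grey level size zone matrix).  Feature
identifiers follow the ``<filter>_<family>_<FeatureName>`` convention, e.g.
``wavelet-LH_glcm_Idn`` or ``original_firstorder_Mean``.

Exact conventions (pinned so results are reproducible to the bit):

* Discretization: fixed bin *count* ``B`` over the per-frame ROI min-max;
  ``level(v) = min(B, floor((v - min) * B / (max - min)) + 1)``; a constant
  ROI maps to level 1 everywhere.
* Wavelet: orthonormal Haar kernels ``[1, 1]/sqrt(2)`` (low) and
  ``[1, -1]/sqrt(2)`` (high), undecimated, periodic boundary; sub-band names
  give the row filter first (``LH`` = low-pass rows, high-pass columns).
* LBP: ``P`` circularly interpolated neighbours at the given radius
  (bilinear, periodic wrap); rotation-invariant uniform codes ``0..P+1``
  with ``P+1`` for non-uniform patterns.
* GLCM: per-offset pair counts over in-mask pixel pairs, symmetrized by
  adding the transpose, normalized to sum 1; features are averaged over
  offsets.
* GLSZM: zones are connected components (8-connectivity by default) of
  equal-level in-mask pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import DegenerateROIError, EmptyROIError, ParameterError
from .phantom import NoiseInstance

__all__ = [
    "ExtractionConfig",
    "discretize",
    "wavelet_subbands",
    "lbp_map",
    "first_order_features",
    "glcm_matrix",
    "glcm_features",
    "glszm_matrix",
    "glszm_features",
    "extract_frame",
    "extract_instance",
    "extract_instances",
    "feature_ids",
]

_SQRT2 = np.sqrt(2.0)

FIRSTORDER_NAMES = (
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Minimum",
    "Maximum",
    "Median",
    "10Percentile",
    "90Percentile",
    "RootMeanSquared",
    "Energy",
    "MeanAbsoluteDeviation",
    "Entropy",
)
GLCM_NAMES = (
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "Contrast",
    "Correlation",
    "Idm",
    "Idn",
    "Imc1",
    "Imc2",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "SizeZoneNonUniformity",
    "ZonePercentage",
    "ZoneEntropy",
)
_FAMILY_NAMES = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glszm": GLSZM_NAMES,
}


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the feature engine.

    ``filters`` selects the pre-processing images ("original", "wavelet"
    expands to the four sub-bands, "lbp2d"); ``families`` selects the
    feature families computed on each filtered image.
    """

    n_bins: int = 32
    glcm_offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
    glcm_symmetric: bool = True
    zone_connectivity: int = 8
    lbp_radius: float = 1.0
    lbp_points: int = 8
    filters: tuple[str, ...] = ("original", "wavelet", "lbp2d")
    families: tuple[str, ...] = ("firstorder", "glcm", "glszm")

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ParameterError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.lbp_points < 4:
            raise ParameterError(f"lbp_points must be >= 4, got {self.lbp_points}")
        if self.lbp_radius < 1:
            raise ParameterError(f"lbp_radius must be >= 1, got {self.lbp_radius}")
        if self.zone_connectivity not in (4, 8):
            raise ParameterError("zone_connectivity must be 4 or 8")
        seen: set[tuple[int, int]] = set()
        for off in self.glcm_offsets:
            dr, dc = off
            if (dr, dc) == (0, 0):
                raise ParameterError("GLCM offsets must be nonzero")
            if (-dr, -dc) in seen:
                raise ParameterError(f"offsets {off} and {(-dr, -dc)} are opposite")
            seen.add((dr, dc))
        unknown = set(self.filters) - {"original", "wavelet", "lbp2d"}
        if unknown:
            raise ParameterError(f"unknown filters: {sorted(unknown)}")
        unknown = set(self.families) - set(_FAMILY_NAMES)
        if unknown:
            raise ParameterError(f"unknown families: {sorted(unknown)}")

    @property
    def filter_labels(self) -> tuple[str, ...]:
        labels: list[str] = []
        for f in self.filters:
            if f == "original":
                labels.append("original")
            elif f == "wavelet":
                labels.extend(f"wavelet-{b}" for b in ("LL", "LH", "HL", "HH"))
            elif f == "lbp2d":
                labels.append("lbp2d")
        return tuple(labels)


def feature_ids(config: ExtractionConfig) -> list[str]:
    """The ordered identifier set produced by :func:`extract_frame`."""
    ids = []
    for filt in config.filter_labels:
        for family in config.families:
            for name in _FAMILY_NAMES[family]:
                ids.append(f"{filt}_{family}_{name}")
    return ids


# --------------------------------------------------------------------------
# Discretization
# --------------------------------------------------------------------------

def discretize(roi_values: np.ndarray, n_bins: int) -> np.ndarray:
    """Map intensities onto integer grey levels ``1..n_bins``."""
    v = np.asarray(roi_values, dtype=np.float64)
    if v.size == 0:
        raise EmptyROIError("cannot discretize an empty ROI")
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    m, M = v.min(), v.max()
    if M == m:
        return np.ones(v.shape, dtype=np.int64)
    levels = np.floor((v - m) * n_bins / (M - m)).astype(np.int64) + 1
    return np.minimum(levels, n_bins)


# --------------------------------------------------------------------------
# Filters
# --------------------------------------------------------------------------

def _haar_pass(img: np.ndarray, axis: int, high: bool) -> np.ndarray:
    nxt = np.roll(img, -1, axis=axis)
    return (img - nxt) / _SQRT2 if high else (img + nxt) / _SQRT2


def wavelet_subbands(frame: np.ndarray) -> dict[str, np.ndarray]:
    """Single-level undecimated 2D Haar transform, periodic boundary.

    Returns same-shape sub-bands keyed LL, LH, HL, HH; the first letter is
    the filter applied along rows (axis 0), the second along columns.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or min(frame.shape) < 2:
        raise ParameterError("wavelet_subbands requires a 2D image of at least 2x2")
    lo0 = _haar_pass(frame, 0, high=False)
    hi0 = _haar_pass(frame, 0, high=True)
    return {
        "LL": _haar_pass(lo0, 1, high=False),
        "LH": _haar_pass(lo0, 1, high=True),
        "HL": _haar_pass(hi0, 1, high=False),
        "HH": _haar_pass(hi0, 1, high=True),
    }


def lbp_map(frame: np.ndarray, radius: float = 1.0, n_points: int = 8) -> np.ndarray:
    """Rotation-invariant uniform LBP codes per pixel, periodic boundary.

    Codes 0..P: number of neighbours >= centre for uniform patterns (at most
    two 0/1 transitions around the circle); P+1 marks non-uniform patterns.
    Neighbour samples at non-integer positions are bilinearly interpolated
    with periodic wrapping; offsets within 1e-9 of an integer are snapped to
    avoid interpolation ties on quantized images.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if radius < 1 or n_points < 4:
        raise ParameterError("require radius >= 1 and n_points >= 4")
    H, W = frame.shape
    rows, cols = np.mgrid[0:H, 0:W].astype(np.float64)
    signs = np.empty((n_points, H, W), dtype=bool)
    for p in range(n_points):
        theta = 2.0 * np.pi * p / n_points
        dr = radius * np.sin(theta)
        dc = radius * np.cos(theta)
        if abs(dr - round(dr)) < 1e-9:
            dr = round(dr)
        if abs(dc - round(dc)) < 1e-9:
            dc = round(dc)
        if float(dr).is_integer() and float(dc).is_integer():
            neigh = np.roll(frame, (-int(dr), -int(dc)), axis=(0, 1))
        else:
            neigh = ndi.map_coordinates(
                frame, [rows + dr, cols + dc], order=1, mode="grid-wrap"
            )
        signs[p] = neigh >= frame
    s = signs.astype(np.int8)
    transitions = np.abs(s - np.roll(s, 1, axis=0)).sum(axis=0)
    ones = s.sum(axis=0)
    codes = np.where(transitions <= 2, ones, n_points + 1)
    return codes.astype(np.int64)


# --------------------------------------------------------------------------
# First-order statistics
# --------------------------------------------------------------------------

def first_order_features(
    roi_values: np.ndarray, levels: np.ndarray | None = None, n_bins: int = 32
) -> dict[str, float]:
    """First-order intensity statistics of the in-mask values.

    ``Variance`` uses denominator N; ``Kurtosis`` is excess (Fisher);
    percentiles interpolate linearly between order statistics; ``Entropy``
    is the Shannon entropy (bits) of the discretized level histogram.
    Skewness and kurtosis of a constant ROI are reported as 0.
    """
    v = np.asarray(roi_values, dtype=np.float64).ravel()
    if v.size == 0:
        raise EmptyROIError("first-order features require a nonempty ROI")
    if levels is None:
        levels = discretize(v, n_bins)
    mean = float(v.mean())
    centered = v - mean
    if v.min() == v.max():
        centered = np.zeros_like(v)  # exact zeros: no float residue on a constant ROI
    var = float(np.mean(centered**2))
    if var > 0:
        skew = float(np.mean(centered**3) / var**1.5)
        kurt = float(np.mean(centered**4) / var**2 - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    counts = np.bincount(np.asarray(levels, dtype=np.int64))[1:]
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Minimum": float(v.min()),
        "Maximum": float(v.max()),
        "Median": float(np.median(v)),
        "10Percentile": float(np.percentile(v, 10)),
        "90Percentile": float(np.percentile(v, 90)),
        "RootMeanSquared": float(np.sqrt(np.mean(v**2))),
        "Energy": float(np.sum(v**2)),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(centered))),
        "Entropy": entropy,
    }


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def glcm_matrix(
    levels_image: np.ndarray,
    mask: np.ndarray,
    n_bins: int,
    offsets: Sequence[tuple[int, int]] = ((0, 1), (1, 0), (1, 1), (1, -1)),
    symmetric: bool = True,
) -> list[np.ndarray]:
    """Per-offset grey level co-occurrence probability matrices.

    Counts ordered in-mask pixel pairs for each offset, optionally adds the
    transpose (symmetric co-occurrence) and normalizes each offset's matrix
    to sum 1.  Offsets with no valid pair are dropped; if no offset has a
    valid pair a :class:`DegenerateROIError` is raised.
    """
    lev = np.asarray(levels_image, dtype=np.int64)
    msk = np.asarray(mask, dtype=bool)
    if not msk.any():
        raise EmptyROIError("GLCM requires a nonempty mask")
    H, W = lev.shape
    matrices: list[np.ndarray] = []
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), min(H, H - dr))
        c0 = slice(max(0, -dc), min(W, W - dc))
        r1 = slice(max(0, dr), min(H, H + dr))
        c1 = slice(max(0, dc), min(W, W + dc))
        valid = msk[r0, c0] & msk[r1, c1]
        if not valid.any():
            continue
        a = lev[r0, c0][valid] - 1
        b = lev[r1, c1][valid] - 1
        mat = np.zeros((n_bins, n_bins), dtype=np.float64)
        np.add.at(mat, (a, b), 1.0)
        if symmetric:
            mat = mat + mat.T
        matrices.append(mat / mat.sum())
    if not matrices:
        raise DegenerateROIError("no in-mask pixel pair for any GLCM offset")
    return matrices


def glcm_features(matrices: Sequence[np.ndarray]) -> dict[str, float]:
    """Haralick-style features averaged over the per-offset matrices.

    ``Correlation`` of a single-level ROI (zero marginal variance) is
    reported as 1 by convention so feature curves stay finite.  ``Idn``
    normalizes the level difference by the matrix size B.
    """
    accum = {name: 0.0 for name in GLCM_NAMES}
    for p in matrices:
        B = p.shape[0]
        i = np.arange(1, B + 1, dtype=np.float64)[:, None]
        j = np.arange(1, B + 1, dtype=np.float64)[None, :]
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        nz = p > 0
        joint_avg = float((i * p).sum())
        joint_energy = float((p**2).sum())
        hxy = float(-(p[nz] * np.log2(p[nz])).sum())
        contrast = float(((i - j) ** 2 * p).sum())
        mu_x = float((np.arange(1, B + 1) * px).sum())
        mu_y = float((np.arange(1, B + 1) * py).sum())
        sig_x = float(np.sqrt(((np.arange(1, B + 1) - mu_x) ** 2 * px).sum()))
        sig_y = float(np.sqrt(((np.arange(1, B + 1) - mu_y) ** 2 * py).sum()))
        if sig_x * sig_y > 0:
            corr = float(((i * j * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
        else:
            corr = 1.0
        idm = float((p / (1.0 + (i - j) ** 2)).sum())
        idn = float((p / (1.0 + np.abs(i - j) / B)).sum())
        pxpy = px[:, None] * py[None, :]
        nz2 = pxpy > 0
        hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
        hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
        hxy1 = float(-(p[nz2] * np.log2(pxpy[nz2])).sum())
        hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
        denom = max(hx, hy)
        imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
        for name, val in (
            ("JointAverage", joint_avg),
            ("JointEnergy", joint_energy),
            ("JointEntropy", hxy),
            ("Contrast", contrast),
            ("Correlation", corr),
            ("Idm", idm),
            ("Idn", idn),
            ("Imc1", imc1),
            ("Imc2", imc2),
        ):
            accum[name] += val
    n = len(matrices)
    return {name: val / n for name, val in accum.items()}


# --------------------------------------------------------------------------
# GLSZM
# --------------------------------------------------------------------------

def glszm_matrix(
    levels_image: np.ndarray, mask: np.ndarray, connectivity: int = 8
) -> np.ndarray:
    """Grey level size zone matrix ``s[i-1, j-1]`` = #zones of level i, size j.

    A zone is a connected component (4- or 8-connectivity) of in-mask pixels
    sharing the same discretized level.
    """
    lev = np.asarray(levels_image, dtype=np.int64)
    msk = np.asarray(mask, dtype=bool)
    if not msk.any():
        raise EmptyROIError("GLSZM requires a nonempty mask")
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = ndi.generate_binary_structure(2, 1)
    else:
        raise ParameterError("connectivity must be 4 or 8")
    # crop to the mask bounding box: labelling cost scales with the crop
    rows = np.any(msk, axis=1)
    cols = np.any(msk, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    lev = lev[r0 : r1 + 1, c0 : c1 + 1]
    msk = msk[r0 : r1 + 1, c0 : c1 + 1]

    present = np.unique(lev[msk])
    max_level = int(present.max())
    zone_sizes: dict[int, list[int]] = {}
    max_size = 1
    for lvl in present:
        lab, n_zones = ndi.label((lev == lvl) & msk, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zone_sizes[int(lvl)] = sizes.tolist()
        max_size = max(max_size, int(sizes.max()))
    s = np.zeros((max_level, max_size), dtype=np.float64)
    for lvl, sizes in zone_sizes.items():
        for size in sizes:
            s[lvl - 1, size - 1] += 1.0
    return s


def glszm_features(zone_matrix: np.ndarray, n_pixels: int) -> dict[str, float]:
    """Size-zone features from the zone matrix and the ROI pixel count."""
    s = np.asarray(zone_matrix, dtype=np.float64)
    n_z = s.sum()
    if n_z == 0:
        raise DegenerateROIError("zone matrix has no zones")
    j = np.arange(1, s.shape[1] + 1, dtype=np.float64)[None, :]
    sae = float((s / j**2).sum() / n_z)
    lae = float((s * j**2).sum() / n_z)
    gln = float((s.sum(axis=1) ** 2).sum() / n_z)
    szn = float((s.sum(axis=0) ** 2).sum() / n_z)
    zp = float(n_z / n_pixels)
    pz = s[s > 0] / n_z
    zent = float(-(pz * np.log2(pz)).sum())
    return {
        "SmallAreaEmphasis": sae,
        "LargeAreaEmphasis": lae,
        "GrayLevelNonUniformity": gln,
        "SizeZoneNonUniformity": szn,
        "ZonePercentage": zp,
        "ZoneEntropy": zent,
    }


# --------------------------------------------------------------------------
# Frame / instance extraction
# --------------------------------------------------------------------------

def _filter_images(frame: np.ndarray, config: ExtractionConfig) -> dict[str, np.ndarray]:
    images: dict[str, np.ndarray] = {}
    for f in config.filters:
        if f == "original":
            images["original"] = np.asarray(frame, dtype=np.float64)
        elif f == "wavelet":
            for band, img in wavelet_subbands(frame).items():
                images[f"wavelet-{band}"] = img
        elif f == "lbp2d":
            images["lbp2d"] = lbp_map(
                frame, radius=config.lbp_radius, n_points=config.lbp_points
            ).astype(np.float64)
    return images


def extract_frame(
    frame: np.ndarray, mask: np.ndarray, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """All enabled filter x family features of one frame.

    Each filtered image is discretized over its own in-mask min-max before
    the texture matrices are built.  The identifier set depends only on the
    configuration, never on the data.
    """
    if config is None:
        config = ExtractionConfig()
    msk = np.asarray(mask, dtype=bool)
    if not msk.any():
        raise EmptyROIError("extract_frame requires a nonempty mask")
    out: dict[str, float] = {}
    n_pixels = int(msk.sum())
    for label, img in _filter_images(frame, config).items():
        roi = img[msk]
        levels = discretize(roi, config.n_bins)
        levels_image = np.zeros(img.shape, dtype=np.int64)
        levels_image[msk] = levels
        for family in config.families:
            try:
                if family == "firstorder":
                    feats = first_order_features(roi, levels, config.n_bins)
                elif family == "glcm":
                    mats = glcm_matrix(
                        levels_image,
                        msk,
                        config.n_bins,
                        offsets=config.glcm_offsets,
                        symmetric=config.glcm_symmetric,
                    )
                    feats = glcm_features(mats)
                else:
                    zm = glszm_matrix(levels_image, msk, config.zone_connectivity)
                    feats = glszm_features(zm, n_pixels)
            except (EmptyROIError, DegenerateROIError) as exc:
                raise type(exc)(f"{label}_{family}: {exc}") from exc
            for name, val in feats.items():
                out[f"{label}_{family}_{name}"] = val
    return out


def extract_instance(
    instance: NoiseInstance, config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Long-format feature table for every frame of one noise instance."""
    if config is None:
        config = ExtractionConfig()
    seq = instance.sequence
    records: list[tuple] = []
    for t in range(seq.n_frames):
        feats = extract_frame(seq.frames[t], seq.masks[t], config)
        for fid, val in feats.items():
            records.append(
                (
                    instance.subject_id,
                    instance.level_label,
                    instance.replicate_index,
                    t,
                    fid,
                    val,
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


def extract_instances(
    instances: Iterable[NoiseInstance], config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Concatenate :func:`extract_instance` over many noise instances."""
    frames = [extract_instance(inst, config) for inst in instances]
    return pd.concat(frames, ignore_index=True)
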