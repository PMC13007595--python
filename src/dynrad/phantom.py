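"""Synthetic contracting-phantom generator for cine cardiac MRI.

This module produces seeded 2D+t short-axis phantoms of the left ventricle:
a bright circular blood pool surrounded by an annular myocardium that
contracts and thickens periodically over the cardiac cycle, on a darker
background.  A smooth, subject-specific sinusoidal texture field is baked
into every frame so that radiomic features vary over the cycle even without
noise, mimicking myocardial trabeculation at the resolution of a cine scan.

The generator stands in for scanner data: the downstream stability analysis
only needs (i) a region of interest that deforms over a closed cycle,
(ii) an intensity texture inside it, and (iii) controlled zero-mean Gaussian
noise at known standard deviation with seeded replicates.  Wall-motion
physiology, coil profiles, k-space sampling and Rician magnitude statistics
are deliberately out of scope.

Conventions
-----------
* Images are ``float64`` arrays of shape ``(T, H, W)``; masks are ``uint8``
  of the same shape with 1 marking the myocardial annulus.
* Noise standard deviations are fractions of the ``[0, 1]`` rescaled
  intensity range (so the conventional levels 0.010-0.040 are meaningful
  regardless of the subject's raw intensity scale).
* All randomness is driven by explicit integer seeds; generation is a pure
  function of its arguments.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import FlatImageError, GeometryError, ParameterError

__all__ = [
    "PhantomParams",
    "CineSequence",
    "NoiseInstance",
    "CohortSubject",
    "CLASS_GEOMETRY",
    "generate_phantom",
    "generate_cohort",
    "rescale_to_unit",
    "add_gaussian_noise",
    "make_noise_instances",
    "empirical_snr",
    "stable_seed",
    "endocardial_radius",
    "epicardial_radius",
]

#: Default noise levels (fraction of the [0,1] intensity range).
DEFAULT_NOISE_LEVELS = (0.010, 0.020, 0.030, 0.040)
#: Default number of replicates per noise level.
DEFAULT_REPLICATES = 10


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of one synthetic subject.

    Radii are end-diastolic (frame 0) values in pixels; the wall contracts
    inward by ``contraction_fraction`` of the endocardial radius at
    mid-cycle, and the epicardial radius follows so that the annulus area
    is conserved (incompressible myocardium).
    """

    grid_size: int = 128
    n_frames: int = 25
    center: tuple[float, float] | None = None
    r_endo_ed: float = 20.0
    r_epi_ed: float = 30.0
    contraction_fraction: float = 0.3
    mu_background: float = 50.0
    mu_myocardium: float = 200.0
    mu_bloodpool: float = 400.0
    texture_amplitude: float = 20.0
    texture_seed: int = 0
    pixel_spacing: float = 1.5

    def __post_init__(self) -> None:
        if self.n_frames < 12:
            raise ParameterError(f"n_frames must be >= 12, got {self.n_frames}")
        if not (0.0 < self.r_endo_ed < self.r_epi_ed < self.grid_size / 2):
            raise GeometryError(
                "require 0 < r_endo_ed < r_epi_ed < grid_size/2, got "
                f"r_endo_ed={self.r_endo_ed}, r_epi_ed={self.r_epi_ed}, "
                f"grid_size={self.grid_size}"
            )
        if not (0.0 <= self.contraction_fraction < 1.0):
            raise ParameterError(
                f"contraction_fraction must be in [0, 1), got {self.contraction_fraction}"
            )
        for name in ("mu_background", "mu_myocardium", "mu_bloodpool"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.pixel_spacing <= 0:
            raise ParameterError("pixel_spacing must be > 0")

    @property
    def centre(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        c = (self.grid_size - 1) / 2.0
        return (c, c)


@dataclass
class CineSequence:
    """One subject's 2D+t image stack with per-frame myocardial masks."""

    subject_id: str
    frames: np.ndarray  # (T, H, W) float64
    masks: np.ndarray  # (T, H, W) uint8, values {0, 1}
    pixel_spacing: float
    intensity_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.masks = np.asarray(self.masks, dtype=np.uint8)
        if self.frames.shape != self.masks.shape:
            raise GeometryError(
                f"frames shape {self.frames.shape} != masks shape {self.masks.shape}"
            )
        if self.frames.ndim != 3:
            raise GeometryError("expected a (T, H, W) stack")
        vals = np.unique(self.masks)
        if not np.all(np.isin(vals, [0, 1])):
            raise GeometryError(f"masks must be binary, found values {vals}")
        fg = self.masks.reshape(self.n_frames, -1).sum(axis=1)
        if (fg < 16).any():
            t = int(np.argmax(fg < 16))
            raise GeometryError(f"mask of frame {t} has only {fg[t]} foreground pixels")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def copy(self) -> "CineSequence":
        return CineSequence(
            subject_id=self.subject_id,
            frames=self.frames.copy(),
            masks=self.masks.copy(),
            pixel_spacing=self.pixel_spacing,
            intensity_range=self.intensity_range,
        )


@dataclass
class NoiseInstance:
    """One noisy realization of a subject's cine sequence.

    The noise-free original is the instance with ``level_label="reference"``
    and ``replicate_index=0``.
    """

    subject_id: str
    level_label: str
    noise_std: float
    replicate_index: int
    seed: int
    sequence: CineSequence

    def __post_init__(self) -> None:
        if self.level_label == "reference" and not (
            self.noise_std == 0.0 and self.replicate_index == 0
        ):
            raise ParameterError("reference instance must have std 0 and replicate 0")


def endocardial_radius(params: PhantomParams, t: int) -> float:
    """Endocardial radius (pixels) at frame ``t`` of the closed cycle.

    Follows a raised-cosine contraction: maximal at t=0 (end-diastole),
    minimal at t=T/2 (end-systole), periodic with period T.
    """
    T = params.n_frames
    phase = (1.0 - np.cos(2.0 * np.pi * t / T)) / 2.0
    return params.r_endo_ed - params.contraction_fraction * params.r_endo_ed * phase


def epicardial_radius(params: PhantomParams, t: int) -> float:
    """Epicardial radius at frame ``t``, conserving the annulus area.

    pi*(r_epi^2 - r_endo^2) is constant, so the wall thickens as the cavity
    shrinks, as incompressible myocardium does.
    """
    r_endo = endocardial_radius(params, t)
    return float(np.sqrt(params.r_epi_ed**2 - params.r_endo_ed**2 + r_endo**2))


def _texture_field(params: PhantomParams) -> np.ndarray:
    """Smooth low-frequency sinusoidal modulation, fixed by texture_seed."""
    rng = np.random.default_rng(params.texture_seed)
    G = params.grid_size
    rows, cols = np.mgrid[0:G, 0:G].astype(np.float64)
    field_sum = np.zeros((G, G))
    n_components = 3
    for _ in range(n_components):
        a, b = rng.integers(1, 5, size=2)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        field_sum += np.sin(2.0 * np.pi * (a * rows + b * cols) / G + phi)
    return field_sum / n_components


def generate_phantom(params: PhantomParams, subject_id: str | None = None) -> CineSequence:
    """Render the contracting-annulus phantom for one subject.

    Deterministic given ``params``.  Raises :class:`GeometryError` if the
    annulus becomes empty at any frame or its pixelized area drifts by more
    than 2% across the cycle.
    """
    G, T = params.grid_size, params.n_frames
    cy, cx = params.centre
    rows, cols = np.mgrid[0:G, 0:G].astype(np.float64)
    dist = np.hypot(rows - cy, cols - cx)
    # stable distance order, reused every frame: the annulus of frame t is
    # the target_area nearest pixels outside the endocardial radius, which
    # conserves the pixelized wall area exactly (the epicardial boundary is
    # defined by area conservation, so it absorbs the quantization error)
    order = np.argsort(dist.ravel(), kind="stable")
    dist_sorted = dist.ravel()[order]
    target_area = int(
        ((dist >= params.r_endo_ed) & (dist < params.r_epi_ed)).sum()
    )
    if target_area < 16:
        raise GeometryError(
            f"annulus of only {target_area} pixels at end-diastole; "
            "geometry too thin for the grid"
        )
    texture = params.texture_amplitude * _texture_field(params)

    frames = np.empty((T, G, G), dtype=np.float64)
    masks = np.empty((T, G, G), dtype=np.uint8)
    for t in range(T):
        r_endo = endocardial_radius(params, t)
        n_inside = int(np.searchsorted(dist_sorted, r_endo, side="left"))
        if n_inside + target_area > order.size:
            raise GeometryError(f"annulus does not fit the grid at frame {t}")
        annulus_idx = order[n_inside : n_inside + target_area]
        annulus = np.zeros(G * G, dtype=bool)
        annulus[annulus_idx] = True
        annulus = annulus.reshape(G, G)
        blood = dist < r_endo
        img = np.full((G, G), params.mu_background)
        img[blood] = params.mu_bloodpool
        img[annulus] = params.mu_myocardium
        img += texture
        frames[t] = img
        masks[t] = annulus.astype(np.uint8)
    if subject_id is None:
        subject_id = f"phantom-{params.texture_seed}"
    return CineSequence(
        subject_id=subject_id,
        frames=frames,
        masks=masks,
        pixel_spacing=params.pixel_spacing,
    )


def rescale_to_unit(seq: CineSequence) -> CineSequence:
    """Affinely map the sequence's global intensity range onto [0, 1].

    The (min, max) of the input is recorded in ``intensity_range`` so noise
    standard deviations expressed as fractions of the range are meaningful.
    """
    lo = float(seq.frames.min())
    hi = float(seq.frames.max())
    if hi == lo:
        raise FlatImageError(f"subject {seq.subject_id}: max == min == {lo}")
    out = seq.copy()
    out.frames = (seq.frames - lo) / (hi - lo)
    out.intensity_range = (lo, hi)
    return out


def add_gaussian_noise(seq: CineSequence, noise_std: float, seed: int) -> CineSequence:
    """Add iid zero-mean Gaussian noise of the given std to every pixel.

    ``noise_std == 0`` returns a bitwise-identical copy.  Masks are never
    touched.  Reproducible given ``seed``.
    """
    if noise_std < 0:
        raise ParameterError(f"noise_std must be >= 0, got {noise_std}")
    out = seq.copy()
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        out.frames = seq.frames + rng.normal(0.0, noise_std, size=seq.frames.shape)
    return out


def stable_seed(base_seed: int, subject_id: str, level_index: int, replicate_index: int) -> int:
    """Deterministic per-instance seed, independent of Python hash randomization."""
    key = f"{base_seed}|{subject_id}|{level_index}|{replicate_index}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def make_noise_instances(
    seq: CineSequence,
    levels: Sequence[float],
    replicates: int,
    base_seed: int,
) -> list[NoiseInstance]:
    """Produce the reference plus ``len(levels) * replicates`` noisy instances.

    Levels must be strictly increasing and non-negative; labels L1..Ln are
    assigned in increasing-std order.  With the conventional four levels and
    ten replicates this yields 41 instances per subject.
    """
    levels = list(levels)
    if not levels:
        raise ParameterError("levels must be nonempty")
    if any(s < 0 for s in levels):
        raise ParameterError("noise levels must be >= 0")
    if len(set(levels)) != len(levels):
        raise ParameterError(f"duplicate noise levels: {levels}")
    if sorted(levels) != levels:
        raise ParameterError("levels must be strictly increasing")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")

    instances = [
        NoiseInstance(
            subject_id=seq.subject_id,
            level_label="reference",
            noise_std=0.0,
            replicate_index=0,
            seed=stable_seed(base_seed, seq.subject_id, 0, 0),
            sequence=seq.copy(),
        )
    ]
    for li, std in enumerate(levels, start=1):
        for rep in range(1, replicates + 1):
            seed = stable_seed(base_seed, seq.subject_id, li, rep)
            noisy = add_gaussian_noise(seq, std, seed)
            instances.append(
                NoiseInstance(
                    subject_id=seq.subject_id,
                    level_label=f"L{li}",
                    noise_std=float(std),
                    replicate_index=rep,
                    seed=seed,
                    sequence=noisy,
                )
            )
    return instances


def empirical_snr(seq: CineSequence, noise_std: float) -> float:
    """Mean in-ROI intensity over all frames divided by the noise std."""
    if noise_std == 0:
        raise ParameterError("SNR undefined for noise_std == 0")
    roi_mean = float(seq.frames[seq.masks.astype(bool)].mean())
    return roi_mean / noise_std


# --------------------------------------------------------------------------
# Cohort emulation
# --------------------------------------------------------------------------

#: Per-class geometry ranges (uniform draws): endocardial radius, wall
#: thickness (both px at end-diastole) and contraction fraction.  The five
#: classes caricature the standard cine-CMR diagnostic groups: normal (NOR),
#: myocardial infarction (MI, hypokinetic), hypertrophic cardiomyopathy
#: (HCM, thick wall / small cavity), dilated cardiomyopathy (DCM, large
#: cavity / thin wall / poor function) and abnormal right ventricle (ARV,
#: near-normal LV).
CLASS_GEOMETRY: dict[str, dict[str, tuple[float, float]]] = {
    "NOR": {"r_endo": (18, 22), "wall": (8, 10), "contraction": (0.30, 0.40)},
    "MI": {"r_endo": (20, 24), "wall": (7, 9), "contraction": (0.12, 0.22)},
    "HCM": {"r_endo": (12, 16), "wall": (14, 18), "contraction": (0.30, 0.40)},
    "DCM": {"r_endo": (26, 30), "wall": (5, 7), "contraction": (0.06, 0.16)},
    "ARV": {"r_endo": (16, 20), "wall": (7, 9), "contraction": (0.38, 0.48)},
}


@dataclass(frozen=True)
class CohortSubject:
    """A cohort member: identifier, diagnostic class and phantom geometry."""

    subject_id: str
    class_label: str
    params: PhantomParams


def generate_cohort(
    n_per_class: dict[str, int] | None = None,
    n_subjects: int | None = None,
    frame_range: tuple[int, int] = (12, 50),
    cohort_seed: int = 0,
) -> list[CohortSubject]:
    """Draw per-subject geometry for a synthetic cohort.

    Either ``n_per_class`` (class label -> count, keys from
    :data:`CLASS_GEOMETRY`) or a flat ``n_subjects`` (all labelled NOR-style
    but spanning the pooled geometry ranges) must be given.  Frame counts
    are drawn uniformly from ``frame_range`` to emulate the heterogeneous
    temporal resolution of clinical cine acquisitions.
    """
    if (n_per_class is None) == (n_subjects is None):
        raise ParameterError("give exactly one of n_per_class / n_subjects")
    lo_T, hi_T = frame_range
    if lo_T < 12 or hi_T < lo_T:
        raise ParameterError(f"invalid frame_range {frame_range}")

    rng = np.random.default_rng(cohort_seed)
    subjects: list[CohortSubject] = []

    def draw(label: str, idx: int, geo: dict[str, tuple[float, float]]) -> CohortSubject:
        r_endo = rng.uniform(*geo["r_endo"])
        wall = rng.uniform(*geo["wall"])
        cf = rng.uniform(*geo["contraction"])
        T = int(rng.integers(lo_T, hi_T + 1))
        sid = f"{label}{idx:03d}"
        params = PhantomParams(
            n_frames=T,
            r_endo_ed=r_endo,
            r_epi_ed=r_endo + wall,
            contraction_fraction=cf,
            texture_seed=int(rng.integers(0, 2**31)),
        )
        return CohortSubject(subject_id=sid, class_label=label, params=params)

    if n_per_class is not None:
        unknown = set(n_per_class) - set(CLASS_GEOMETRY)
        if unknown:
            raise ParameterError(f"unknown class labels: {sorted(unknown)}")
        for label in sorted(n_per_class):
            for idx in range(1, n_per_class[label] + 1):
                subjects.append(draw(label, idx, CLASS_GEOMETRY[label]))
    else:
        pooled = {
            "r_endo": (14, 26),
            "wall": (6, 14),
            "contraction": (0.15, 0.45),
        }
        for idx in range(1, n_subjects + 1):
            subjects.append(draw("SUB", idx, pooled))

    return subjects
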