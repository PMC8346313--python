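"""Synthetic cardiac-phantom images, paired degradation datasets, and cohorts.

The phantom is a deliberately simple stand-in for a four-chamber cardiac
view: a dark background, bright elliptical myocardium rings, and darker
chamber interiors.  Degradation follows the physical imaging chain: a
Gaussian point-spread blur acts on the clean reflectivity, then a unit-mean
multiplicative speckle factor (squared-Gaussian model), then additive
Gaussian electronic noise, then clipping to ``[0, 1]``.

Cohort sampling draws per-patient echocardiographic indices from normal
distributions (truncated to physiologic bounds by resampling) so the
rule-based diagnosis stage can run on synthetic subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .diagnosis import PatientRecord, Sex
from .image import EchoImage

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "DegradationSpec",
    "IndexDist",
    "CohortParams",
    "generate_phantom",
    "degrade",
    "make_paired_dataset",
    "sample_cohort",
    "default_phantom_spec",
    "control_cohort_params",
    "experimental_cohort_params",
]

_SPECKLE_EPS = 1e-6
# S = 1 + sigma * (S0 - 1)/sd(S0) with S0 = (G^2 + eps)/(1 + eps) stays
# positive only for sigma below sd(S0)'s reciprocal support bound, sqrt(2).
_MAX_SPECKLE_SIGMA = math.sqrt(2.0)


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: ``((r-cr)/a)^2 + ((c-cc)/b)^2 <= 1``."""

    center_row: float
    center_col: float
    semi_axis_a: float  # row half-extent, pixels
    semi_axis_b: float  # column half-extent, pixels
    intensity: float

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"ellipse intensity must be in [0, 1], got {self.intensity}")


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 64
    width: int = 64
    background_level: float = 0.08
    chambers: tuple[Ellipse, ...] = ()
    myocardium_ring_width: float = 3.0
    myocardium_intensity: float = 0.75

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError(f"image must be at least 16x16, got {self.height}x{self.width}")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must be in [0, 1]")
        if not 0.0 <= self.myocardium_intensity <= 1.0:
            raise ValueError("myocardium_intensity must be in [0, 1]")
        if self.myocardium_ring_width < 0:
            raise ValueError("myocardium_ring_width must be >= 0")
        chambers = tuple(self.chambers)
        for ell in chambers:
            ra = ell.semi_axis_a + self.myocardium_ring_width
            rb = ell.semi_axis_b + self.myocardium_ring_width
            if (
                ell.center_row - ra < 0
                or ell.center_row + ra > self.height - 1
                or ell.center_col - rb < 0
                or ell.center_col + rb > self.width - 1
            ):
                raise ValueError(
                    f"ellipse at ({ell.center_row}, {ell.center_col}) with ring "
                    f"extends outside the {self.height}x{self.width} image"
                )
        object.__setattr__(self, "chambers", chambers)


@dataclass(frozen=True)
class DegradationSpec:
    """Blur -> multiplicative speckle -> additive noise -> clip, seeded."""

    speckle_sigma: float = 0.2
    blur_sigma: float = 1.0
    additive_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("speckle_sigma", "blur_sigma", "additive_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.speckle_sigma >= _MAX_SPECKLE_SIGMA:
            raise ValueError(
                f"speckle_sigma must be < sqrt(2) ~ 1.414 to keep the speckle "
                f"factor positive, got {self.speckle_sigma}"
            )


def _ellipse_mask(height: int, width: int, ell: Ellipse, grow: float = 0.0) -> np.ndarray:
    rows = np.arange(height, dtype=np.float64)[:, None]
    cols = np.arange(width, dtype=np.float64)[None, :]
    a = ell.semi_axis_a + grow
    b = ell.semi_axis_b + grow
    return ((rows - ell.center_row) / a) ** 2 + ((cols - ell.center_col) / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> EchoImage:
    """Render the clean phantom: background, then rings, then chamber interiors.

    Deterministic; all randomness in this module lives in :func:`degrade`
    and the jitter of :func:`make_paired_dataset`.
    """
    img = np.full((spec.height, spec.width), spec.background_level, dtype=np.float64)
    for ell in spec.chambers:
        img[_ellipse_mask(spec.height, spec.width, ell, grow=spec.myocardium_ring_width)] = (
            spec.myocardium_intensity
        )
    for ell in spec.chambers:
        img[_ellipse_mask(spec.height, spec.width, ell)] = ell.intensity
    return EchoImage(img)


def _speckle_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean positive multiplicative speckle with standard deviation ``sigma``.

    Squared-Gaussian model: ``S0 = (G^2 + eps)/(1 + eps)`` with ``G ~ N(0,1)``
    has mean 1 and SD ``sqrt(2)/(1 + eps)``; the field is ``1 + sigma *
    (S0 - 1)/sd(S0)``, which keeps mean 1, SD ``sigma`` and positivity for
    ``sigma < sqrt(2)``.
    """
    g = rng.standard_normal(shape)
    s0 = (g**2 + _SPECKLE_EPS) / (1.0 + _SPECKLE_EPS)
    sd0 = math.sqrt(2.0) / (1.0 + _SPECKLE_EPS)
    return 1.0 + sigma * (s0 - 1.0) / sd0


def _apply_chain(image: EchoImage, deg: DegradationSpec, rng: np.random.Generator) -> EchoImage:
    out = image.pixels
    if deg.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=deg.blur_sigma, mode="reflect")
    if deg.speckle_sigma > 0:
        out = out * _speckle_field(out.shape, deg.speckle_sigma, rng)
    if deg.additive_sigma > 0:
        out = out + deg.additive_sigma * rng.standard_normal(out.shape)
    return EchoImage(np.clip(out, 0.0, 1.0), bit_depth=image.bit_depth)


def degrade(image: EchoImage, deg: DegradationSpec) -> EchoImage:
    """Apply the seeded degradation chain to a clean image."""
    return _apply_chain(image, deg, np.random.default_rng(deg.seed))


def default_phantom_spec(height: int = 64, width: int = 64) -> PhantomSpec:
    """Four-chamber-view style default: four ellipses on a dark field."""
    h, w = height, width
    chambers = (
        Ellipse(0.34 * h, 0.32 * w, 0.17 * h, 0.14 * w, 0.12),  # left ventricle
        Ellipse(0.34 * h, 0.68 * w, 0.15 * h, 0.12 * w, 0.10),  # right ventricle
        Ellipse(0.72 * h, 0.34 * w, 0.11 * h, 0.11 * w, 0.15),  # left atrium
        Ellipse(0.72 * h, 0.68 * w, 0.10 * h, 0.10 * w, 0.13),  # right atrium
    )
    return PhantomSpec(height=h, width=w, chambers=chambers, myocardium_ring_width=0.04 * h)


def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Randomly perturb ellipse geometry, rejecting out-of-bounds draws."""
    for _ in range(100):
        chambers = []
        for ell in spec.chambers:
            chambers.append(
                Ellipse(
                    center_row=ell.center_row + rng.uniform(-2.0, 2.0),
                    center_col=ell.center_col + rng.uniform(-2.0, 2.0),
                    semi_axis_a=ell.semi_axis_a * rng.uniform(0.85, 1.15),
                    semi_axis_b=ell.semi_axis_b * rng.uniform(0.85, 1.15),
                    intensity=float(np.clip(ell.intensity + rng.uniform(-0.03, 0.03), 0.0, 1.0)),
                )
            )
        try:
            return replace(spec, chambers=tuple(chambers))
        except ValueError:
            continue
    raise ValueError("could not jitter phantom inside image bounds after 100 tries")


def make_paired_dataset(
    n: int,
    spec: PhantomSpec,
    deg: DegradationSpec,
    jitter_seed: int = 0,
) -> list[tuple[EchoImage, EchoImage]]:
    """``n`` (clean, noisy) phantom pairs with seeded geometry jitter.

    Pair ``i``'s noisy member is :func:`degrade` of its clean member with an
    independent child seed spawned from ``deg.seed``.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    jitter_rng = np.random.default_rng(jitter_seed)
    child_seeds = np.random.SeedSequence(deg.seed).spawn(n)
    pairs = []
    for i in range(n):
        clean = generate_phantom(_jitter_spec(spec, jitter_rng))
        noisy = _apply_chain(clean, deg, np.random.default_rng(child_seeds[i]))
        pairs.append((clean, noisy))
    return pairs


@dataclass(frozen=True)
class IndexDist:
    """Mean/SD pair for one normally distributed index."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class CohortParams:
    """Sampling parameters for one synthetic patient group.

    Echo indices are required; sarcopenia measurements are optional per-sex
    distributions (defaults chosen so most subjects screen sarcopenia
    positive, matching a cohort recruited for that diagnosis).
    """

    n_patients: int
    lvef: IndexDist
    lvdd: IndexDist
    lad: IndexDist
    sex_ratio: float = 119 / 259  # fraction male
    seed: int = 0
    smi: Optional[dict[str, IndexDist]] = None
    grip: Optional[dict[str, IndexDist]] = None
    gait: Optional[IndexDist] = None

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")


_DEFAULT_SMI = {"male": IndexDist(6.3, 0.5), "female": IndexDist(4.9, 0.4)}
_DEFAULT_GRIP = {"male": IndexDist(22.0, 3.0), "female": IndexDist(15.0, 2.5)}
_DEFAULT_GAIT = IndexDist(0.70, 0.10)


def _truncated_normal(
    rng: np.random.Generator,
    n: int,
    dist: IndexDist,
    low: float = 0.0,
    high: float = math.inf,
) -> np.ndarray:
    """Normal draws truncated to ``(low, high]`` by resampling, not clipping."""
    if dist.sd == 0.0:
        values = np.full(n, dist.mean)
        if np.any((values <= low) | (values > high)):
            raise ValueError(f"degenerate mean {dist.mean} outside bounds ({low}, {high}]")
        return values
    values = rng.normal(dist.mean, dist.sd, size=n)
    for _ in range(1000):
        bad = (values <= low) | (values > high)
        if not bad.any():
            return values
        values[bad] = rng.normal(dist.mean, dist.sd, size=int(bad.sum()))
    raise ValueError("truncated sampling did not converge; check bounds vs distribution")


def sample_cohort(params: CohortParams) -> list[PatientRecord]:
    """Draw a synthetic patient group, reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    male = rng.random(n) < params.sex_ratio
    lvef = _truncated_normal(rng, n, params.lvef, high=100.0)
    lvdd = _truncated_normal(rng, n, params.lvdd)
    lad = _truncated_normal(rng, n, params.lad)
    smi_dists = params.smi or _DEFAULT_SMI
    grip_dists = params.grip or _DEFAULT_GRIP
    gait_dist = params.gait or _DEFAULT_GAIT
    smi = {
        sex: _truncated_normal(rng, n, smi_dists[sex]) for sex in ("male", "female")
    }
    grip = {
        sex: _truncated_normal(rng, n, grip_dists[sex]) for sex in ("male", "female")
    }
    gait = _truncated_normal(rng, n, gait_dist)

    records = []
    for i in range(n):
        sex = "male" if male[i] else "female"
        records.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                sex=Sex(sex),
                lad=float(lad[i]),
                lvdd=float(lvdd[i]),
                lvef=float(lvef[i]),
                smi=float(smi[sex][i]),
                grip=float(grip[sex][i]),
                gait_speed=float(gait[i]),
            )
        )
    return records


def control_cohort_params(n_patients: int = 259, seed: int = 0) -> CohortParams:
    """Unprocessed-image group: sampling truth for the simulated cohort."""
    return CohortParams(
        n_patients=n_patients,
        lvef=IndexDist(54.05, 4.79),
        lvdd=IndexDist(51.35, 3.97),
        lad=IndexDist(33.45, 4.01),
        seed=seed,
    )


def experimental_cohort_params(n_patients: int = 259, seed: int = 0) -> CohortParams:
    """Processed-image group: sampling truth for the simulated cohort."""
    return CohortParams(
        n_patients=n_patients,
        lvef=IndexDist(60.09, 4.34),
        lvdd=IndexDist(56.05, 3.09),
        lad=IndexDist(40.05, 4.12),
        seed=seed,
    )
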