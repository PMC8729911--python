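"""Acuity from anatomy and geometry: lens optics, stimulus design,
resolvable distances, and Fourier acuity filtering of images.

In teleost fishes the focal length f is tied to lens size by Matthiessen's
ratio, f = 2.55 * lens radius.  The retinal magnification — the visual angle
subtended by 1 mm of retina — is then alpha = (180/pi)/f degrees (small-angle
form; an arctan variant is selectable).  With a peak areal ganglion-cell
density D (cells/mm^2), the linear density is PDG = sqrt(D) cells/mm, and
since two ganglion cells are needed per resolvable cycle, the anatomical
acuity is

    acuity = PDG / (2 * alpha)   cycles per degree.

The same angular bookkeeping converts spatial frequencies to stripe widths at
a viewing distance, gives the distance at which a feature of a given size
subtends the minimum resolvable angle, and drives the Fourier low-pass filter
that renders an image as a viewer of given acuity could resolve it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MATTHIESSEN_RATIO",
    "OpticsSpec",
    "AcuityEstimate",
    "StimulusSpec",
    "ImageSpec",
    "anatomical_acuity",
    "resolvable_distance",
    "stimulus_geometry",
    "grey_match",
    "acuity_filter_image",
]

#: teleost focal length / lens radius (Matthiessen's ratio)
MATTHIESSEN_RATIO = 2.55
#: Gaussian attenuation constant of the smooth acuity filter
SMOOTH_FILTER_CONSTANT = 3.56


@dataclass(frozen=True)
class OpticsSpec:
    """Lens geometry; focal length derives from Matthiessen's ratio."""

    lens_diameter_mm: float
    matthiessen_ratio: float = MATTHIESSEN_RATIO

    def __post_init__(self) -> None:
        if self.lens_diameter_mm <= 0:
            raise ValueError("lens_diameter_mm must be positive")
        if self.matthiessen_ratio <= 0:
            raise ValueError("matthiessen_ratio must be positive")

    @property
    def focal_length_mm(self) -> float:
        return self.matthiessen_ratio * self.lens_diameter_mm / 2.0


@dataclass(frozen=True)
class AcuityEstimate:
    """An acuity value (cpd) with its provenance.

    ``alpha_deg_per_mm`` and ``pdg_cells_per_mm`` are populated for
    anatomical estimates only.
    """

    value_cpd: float
    method: str  # "anatomical" | "optomotor" | "choice"
    alpha_deg_per_mm: float | None = None
    pdg_cells_per_mm: float | None = None
    metadata: dict = field(default_factory=dict)


def anatomical_acuity(
    optics: OpticsSpec,
    peak_areal_density: float,
    angle_form: str = "small-angle",
    spacing_correction: float = 1.0,
) -> AcuityEstimate:
    """Upper-limit acuity from lens optics and peak RGC density.

    ``angle_form`` selects how the angle subtended by 1 mm of retina is
    computed: ``"small-angle"`` (default) uses (180/pi)/f; ``"arctan"`` uses
    2*arctan(0.5/f).  ``spacing_correction`` multiplies the linear density for
    non-square lattice assumptions (1.0 = square lattice).
    """
    if peak_areal_density <= 0:
        raise ValueError("peak_areal_density must be positive")
    f = optics.focal_length_mm
    if angle_form == "small-angle":
        alpha = math.degrees(1.0 / f)
    elif angle_form == "arctan":
        alpha = 2.0 * math.degrees(math.atan(0.5 / f))
    else:
        raise ValueError("angle_form must be 'small-angle' or 'arctan'")
    pdg = math.sqrt(peak_areal_density) * spacing_correction
    return AcuityEstimate(
        value_cpd=pdg / (2.0 * alpha),
        method="anatomical",
        alpha_deg_per_mm=alpha,
        pdg_cells_per_mm=pdg,
        metadata={
            "focal_length_mm": f,
            "angle_form": angle_form,
            "spacing_correction": spacing_correction,
        },
    )


def resolvable_distance(feature_size: float, acuity_cpd: float) -> float:
    """Distance at which a feature subtends exactly the minimum resolvable angle.

    The minimum resolvable angle is theta = 1/acuity degrees; the feature of
    linear size s subtends theta at d = s / (2 tan(theta/2)).  Inputs and
    output share the same length unit.  Beyond this distance the feature can
    no longer be resolved.
    """
    if feature_size <= 0:
        raise ValueError("feature_size must be positive")
    if acuity_cpd <= 0:
        raise ValueError("acuity_cpd must be positive")
    theta = math.radians(1.0 / acuity_cpd)
    return feature_size / (2.0 * math.tan(theta / 2.0))


@dataclass(frozen=True)
class StimulusSpec:
    """A square-wave grating stimulus at a viewing distance."""

    frequency_cpd: float
    viewing_distance_cm: float
    cycle_period_mm: float  # one black+white pair, flat-target geometry
    stripe_width_mm: float


def stimulus_geometry(frequency_cpd: float, viewing_distance_cm: float = 17.5) -> StimulusSpec:
    """Linear size of one grating cycle at the viewing distance.

    One cycle subtends 1/frequency degrees, so its linear period on a flat
    target is 2 d tan(1/(2 f) degrees).
    """
    if frequency_cpd <= 0:
        raise ValueError("frequency_cpd must be positive")
    if viewing_distance_cm <= 0:
        raise ValueError("viewing_distance_cm must be positive")
    d_mm = viewing_distance_cm * 10.0
    period = 2.0 * d_mm * math.tan(math.radians(1.0 / (2.0 * frequency_cpd)))
    return StimulusSpec(
        frequency_cpd=frequency_cpd,
        viewing_distance_cm=viewing_distance_cm,
        cycle_period_mm=period,
        stripe_width_mm=period / 2.0,
    )


def grey_match(
    white_reflectance: float,
    black_reflectance: float,
    convention: str = "midpoint",
) -> dict:
    """Grey reflectance matching the mean luminance of a black/white grating.

    ``"midpoint"`` (default) returns the arithmetic mean (white + black)/2.
    ``"half-range"`` returns (white - black)/2, a convention that reproduces
    some published grey values; the discrepancy between the two conventions
    is surfaced in the returned metadata rather than silently resolved.
    """
    if not (0 <= black_reflectance < white_reflectance <= 100):
        if black_reflectance == white_reflectance:
            pass  # degenerate limit handled below
        else:
            raise ValueError("need 0 <= black < white <= 100")
    midpoint = (white_reflectance + black_reflectance) / 2.0
    half_range = (white_reflectance - black_reflectance) / 2.0
    if convention == "midpoint":
        value = midpoint
    elif convention == "half-range":
        value = half_range
    else:
        raise ValueError("convention must be 'midpoint' or 'half-range'")
    return {
        "target_grey_reflectance": value,
        "convention": convention,
        "midpoint": midpoint,
        "half_range": half_range,
        "conventions_differ_by": midpoint - half_range,
    }


@dataclass
class ImageSpec:
    """A raster image with its real-world width and the viewing distance.

    Linear intensity is assumed (no gamma handling).  The angular width is
    2 arctan(w / 2d).
    """

    raster: np.ndarray  # (H, W) or (H, W, C), grayscale or RGB
    real_width_cm: float
    viewing_distance_cm: float

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.ndim not in (2, 3) or self.raster.size == 0:
            raise ValueError("raster must be a nonempty 2-D or 3-D array")
        if self.real_width_cm <= 0:
            raise ValueError("real_width_cm must be positive")
        if self.viewing_distance_cm <= 0:
            raise ValueError("viewing_distance_cm must be positive (viewer in front of the image plane)")

    @property
    def angular_width_deg(self) -> float:
        return 2.0 * math.degrees(
            math.atan(self.real_width_cm / (2.0 * self.viewing_distance_cm))
        )

    @property
    def angular_height_deg(self) -> float:
        h, w = self.raster.shape[:2]
        real_h = self.real_width_cm * h / w
        return 2.0 * math.degrees(math.atan(real_h / (2.0 * self.viewing_distance_cm)))


def _filter_channel(channel: np.ndarray, gain: np.ndarray) -> np.ndarray:
    spec = np.fft.fft2(channel)
    return np.real(np.fft.ifft2(spec * gain))


def acuity_filter_image(
    image: ImageSpec,
    acuity_cpd: float,
    filter_shape: str = "sharp",
    clip: bool = True,
) -> np.ndarray:
    """Remove spatial frequencies a viewer of the given acuity cannot resolve.

    The image is transformed to frequency space; each frequency bin is mapped
    to cycles/degree through the image's angular size.  ``"sharp"`` zeroes
    every frequency above the cutoff (idempotent); ``"smooth"`` attenuates by
    exp(-3.56 (nu/nu_c)^2).  The DC term — the mean intensity — is preserved
    exactly.  The result is clipped to the input's valid intensity range
    (0..255 for uint8 input, 0..1 for floats in [0, 1]).
    """
    if acuity_cpd <= 0:
        raise ValueError("acuity_cpd must be positive")
    if image.angular_width_deg >= 180.0 or image.angular_height_deg >= 180.0:
        raise ValueError("image subtends >= 180 degrees; viewer lies in the image plane")
    raster = np.asarray(image.raster)
    was_int = np.issubdtype(raster.dtype, np.integer)
    arr = raster.astype(float)
    h, w = arr.shape[:2]

    fx = np.fft.fftfreq(w) * w / image.angular_width_deg  # cycles per degree
    fy = np.fft.fftfreq(h) * h / image.angular_height_deg
    nu = np.hypot(*np.meshgrid(fx, fy))

    if filter_shape == "sharp":
        gain = (nu <= acuity_cpd).astype(float)
    elif filter_shape == "smooth":
        gain = np.exp(-SMOOTH_FILTER_CONSTANT * (nu / acuity_cpd) ** 2)
    else:
        raise ValueError("filter_shape must be 'sharp' or 'smooth'")
    gain[0, 0] = 1.0  # DC (mean intensity) preserved exactly

    if arr.ndim == 2:
        out = _filter_channel(arr, gain)
    else:
        out = np.stack(
            [_filter_channel(arr[..., c], gain) for c in range(arr.shape[-1])], axis=-1
        )
    if clip:
        hi = 255.0 if was_int or raster.max() > 1.5 else 1.0
        out = np.clip(out, 0.0, hi)
    if was_int:
        out = np.round(out).astype(raster.dtype)
    return out
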