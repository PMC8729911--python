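"""Ground-truth synthetic retinas and simulated behavioural observers.

Real retinal whole-mounts and behavioural subjects cannot ship with the
package, so every downstream stage is exercised against synthetic inputs with
known answers:

* a **retina** is an inhomogeneous Poisson point pattern of ganglion-cell
  somata inside a whole-mount outline.  The intensity field is a baseline
  density plus anisotropic Gaussian "areas" (concentric specialisations), a
  Gaussian-profile ridge along a line segment (the horizontal "streak"), and
  a zero-density optic-nerve disc — the simplest parametric family that
  reproduces the centro-temporal elongated area, nasal area and weak
  horizontal streak seen in small poeciliid fishes;
* an **observer** produces 2AFC choices from a logistic psychometric function
  on log spatial frequency, and optomotor tracking that switches from
  near-certain below its threshold to a small false-positive rate above it.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .behaviour import ChoiceTrial, OptomotorRotation

__all__ = [
    "GaussianArea",
    "Streak",
    "OpticDisc",
    "RetinaSpec",
    "SyntheticRetina",
    "SyntheticObserver",
    "make_retina_truth",
    "simulate_choice_trials",
    "simulate_optomotor_session",
    "default_retina_spec",
    "ellipse_outline",
]


@dataclass(frozen=True)
class GaussianArea:
    """Anisotropic Gaussian density component (a retinal 'area').

    ``axes`` are the principal-axis standard deviations in mm; ``amplitude``
    is the added density at the centre in cells/mm^2.
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    orientation_deg: float
    amplitude: float


@dataclass(frozen=True)
class Streak:
    """Ridge component: Gaussian profile perpendicular to a line segment."""

    start: tuple[float, float]
    end: tuple[float, float]
    half_width: float  # Gaussian sigma of the cross-profile, mm
    amplitude: float  # added density on the axis, cells/mm^2


@dataclass(frozen=True)
class OpticDisc:
    """Zero-density disc where the optic nerve exits."""

    center: tuple[float, float]
    radius: float


@dataclass
class RetinaSpec:
    """Parametric ground-truth density field on a whole-mount outline.

    Total density at a point = baseline + sum of components, forced to zero
    inside the optic-nerve disc.  All coordinates in mm, densities in
    cells/mm^2.
    """

    outline: np.ndarray  # (N, 2) closed polygon vertices, mm
    baseline_density: float
    areas: tuple[GaussianArea, ...] = ()
    streak: Streak | None = None
    optic_nerve: OpticDisc | None = None

    def __post_init__(self) -> None:
        self.outline = np.asarray(self.outline, dtype=float)
        if self.outline.ndim != 2 or self.outline.shape[1] != 2 or len(self.outline) < 3:
            raise ValueError("outline must be an (N, 2) array of vertices, N >= 3")
        poly = self.polygon
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("outline must be a simple polygon with positive area")
        if self.baseline_density < 0:
            raise ValueError("baseline_density must be >= 0")
        for a in self.areas:
            if a.amplitude < 0:
                raise ValueError("area amplitudes must be >= 0 (density field would go negative)")
            if min(a.axes) <= 0:
                raise ValueError("area principal axes must be positive")
        if self.streak is not None:
            if self.streak.amplitude < 0:
                raise ValueError("streak amplitude must be >= 0")
            if self.streak.half_width <= 0:
                raise ValueError("streak half-width must be positive")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.outline)

    def density(self, xy: np.ndarray) -> np.ndarray:
        """Evaluate the density field (cells/mm^2) at points ``xy`` (M, 2)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d = np.full(len(xy), float(self.baseline_density))
        for a in self.areas:
            th = np.deg2rad(a.orientation_deg)
            c, s = np.cos(th), np.sin(th)
            dx = xy[:, 0] - a.center[0]
            dy = xy[:, 1] - a.center[1]
            u = c * dx + s * dy
            v = -s * dx + c * dy
            d += a.amplitude * np.exp(-0.5 * ((u / a.axes[0]) ** 2 + (v / a.axes[1]) ** 2))
        if self.streak is not None:
            seg = LineString([self.streak.start, self.streak.end])
            pts = shapely.points(xy[:, 0], xy[:, 1])
            r = shapely.distance(pts, seg)
            d += self.streak.amplitude * np.exp(-0.5 * (r / self.streak.half_width) ** 2)
        if self.optic_nerve is not None:
            cx, cy = self.optic_nerve.center
            inside = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2 <= self.optic_nerve.radius**2
            d[inside] = 0.0
        return d

    def density_bound(self) -> float:
        """A true upper bound on the density field (sum of component maxima)."""
        b = self.baseline_density + sum(a.amplitude for a in self.areas)
        if self.streak is not None:
            b += self.streak.amplitude
        return b

    # -- serialisation -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "outline": self.outline.tolist(),
            "baseline_density": self.baseline_density,
            "areas": [asdict(a) for a in self.areas],
            "streak": asdict(self.streak) if self.streak else None,
            "optic_nerve": asdict(self.optic_nerve) if self.optic_nerve else None,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RetinaSpec":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        return cls(
            outline=np.asarray(payload["outline"], dtype=float),
            baseline_density=payload["baseline_density"],
            areas=tuple(
                GaussianArea(
                    center=tuple(a["center"]),
                    axes=tuple(a["axes"]),
                    orientation_deg=a["orientation_deg"],
                    amplitude=a["amplitude"],
                )
                for a in payload["areas"]
            ),
            streak=(
                Streak(
                    start=tuple(payload["streak"]["start"]),
                    end=tuple(payload["streak"]["end"]),
                    half_width=payload["streak"]["half_width"],
                    amplitude=payload["streak"]["amplitude"],
                )
                if payload.get("streak")
                else None
            ),
            optic_nerve=(
                OpticDisc(
                    center=tuple(payload["optic_nerve"]["center"]),
                    radius=payload["optic_nerve"]["radius"],
                )
                if payload.get("optic_nerve")
                else None
            ),
        )


@dataclass
class SyntheticRetina:
    """A realised retina: cell positions plus the ground truth behind them."""

    spec: RetinaSpec
    cells: np.ndarray  # (N, 2) mm
    true_total: int
    true_peak_density: float  # cells/mm^2, max of the density field
    true_peak_location: tuple[float, float]
    seed: int

    def cells_to_csv(self, path: str | Path) -> None:
        np.savetxt(
            path,
            self.cells,
            delimiter=",",
            header="x_mm,y_mm",
            comments="",
            fmt="%.6f",
        )


def ellipse_outline(a: float, b: float, n: int = 64, center=(0.0, 0.0)) -> np.ndarray:
    """Polygonal approximation of an ellipse with semi-axes ``a``, ``b`` mm."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + a * np.cos(t), center[1] + b * np.sin(t)])


def default_retina_spec() -> RetinaSpec:
    """The package's fixture retina.

    ~30 mm^2 elliptical outline, baseline 5,000 cells/mm^2, an elongated
    centro-temporal area peaking near 36,000 cells/mm^2, a smaller nasal area,
    a weak horizontal streak, and an optic-nerve disc.  Expected total is
    ~213,000 cells.  Temporal is +x, ventral is -y (right-eye convention).
    """
    return RetinaSpec(
        outline=ellipse_outline(3.4, 2.85, n=96),
        baseline_density=5_000.0,
        areas=(
            GaussianArea(center=(1.2, -0.8), axes=(0.6, 0.35), orientation_deg=20.0, amplitude=31_000.0),
            GaussianArea(center=(-1.8, 0.3), axes=(0.3, 0.3), orientation_deg=0.0, amplitude=12_000.0),
        ),
        streak=Streak(start=(-2.6, 0.0), end=(2.6, 0.0), half_width=0.35, amplitude=3_000.0),
        optic_nerve=OpticDisc(center=(0.0, 0.0), radius=0.25),
    )


def _peak_of_field(spec: RetinaSpec, resolution: float = 0.02) -> tuple[float, tuple[float, float]]:
    """Max of the density field over the outline, found on a fine grid."""
    minx, miny, maxx, maxy = spec.polygon.bounds
    xs = np.arange(minx, maxx + resolution, resolution)
    ys = np.arange(miny, maxy + resolution, resolution)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = shapely.contains_xy(spec.polygon, pts[:, 0], pts[:, 1])
    pts = pts[inside]
    d = spec.density(pts)
    i = int(np.argmax(d))
    return float(d[i]), (float(pts[i, 0]), float(pts[i, 1]))


def make_retina_truth(spec: RetinaSpec, seed: int) -> SyntheticRetina:
    """Draw a retina from the spec's inhomogeneous Poisson intensity field.

    Cells are generated by rejection thinning of a homogeneous Poisson process
    at the field's upper bound over the outline's bounding box: candidates are
    kept inside the outline with probability density/bound.  Identical seeds
    give identical cell lists.
    """
    poly = spec.polygon  # validation happens in RetinaSpec.__post_init__
    rng = np.random.default_rng(seed)
    bound = spec.density_bound()
    minx, miny, maxx, maxy = poly.bounds
    bbox_area = (maxx - minx) * (maxy - miny)
    n_cand = rng.poisson(bound * bbox_area)
    xy = np.column_stack(
        [rng.uniform(minx, maxx, n_cand), rng.uniform(miny, maxy, n_cand)]
    )
    u = rng.uniform(0.0, bound, n_cand)
    inside = shapely.contains_xy(poly, xy[:, 0], xy[:, 1])
    keep = inside & (u < spec.density(xy))
    cells = xy[keep]
    peak, loc = _peak_of_field(spec)
    return SyntheticRetina(
        spec=spec,
        cells=cells,
        true_total=int(len(cells)),
        true_peak_density=peak,
        true_peak_location=loc,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Simulated observers


@dataclass
class SyntheticObserver:
    """Psychophysical ground truth for a simulated fish.

    ``threshold_cpd`` is the spatial frequency at the psychometric midpoint;
    ``slope`` is the logistic steepness on the log-frequency axis; ``lapse``
    is the error rate at the easiest stimulus; ``chance`` the asymptote for
    unresolvable stimuli (0.5 for 2AFC); ``optomotor_false_positive`` the
    probability of spurious tracking above threshold.
    """

    threshold_cpd: float
    slope: float = 6.0
    lapse: float = 0.02
    chance: float = 0.5
    optomotor_false_positive: float = 0.02

    def __post_init__(self) -> None:
        if self.threshold_cpd <= 0:
            raise ValueError("threshold_cpd must be positive")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        if self.lapse + self.chance > 1:
            raise ValueError("lapse + chance must not exceed 1")

    def p_correct(self, frequency_cpd) -> np.ndarray:
        """Analytic P(correct) at the given spatial frequencies.

        chance + (1 - chance - lapse) * logistic(slope * (log T - log f)):
        non-increasing in f, equal to the mid-asymptote average at threshold.
        """
        f = np.asarray(frequency_cpd, dtype=float)
        x = self.slope * (np.log(self.threshold_cpd) - np.log(f))
        return self.chance + (1.0 - self.chance - self.lapse) / (1.0 + np.exp(-x))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticObserver":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


def simulate_choice_trials(
    observer: SyntheticObserver,
    frequencies: Sequence[float],
    trials_per_frequency: int,
    seed: int,
    subject: str = "sim",
) -> list[ChoiceTrial]:
    """Simulate 2AFC trials; side assignment is randomised per trial."""
    if trials_per_frequency < 1:
        raise ValueError("trials_per_frequency must be >= 1")
    frequencies = [float(f) for f in frequencies]
    if any(f <= 0 for f in frequencies):
        raise ValueError("frequencies must be positive")
    rng = np.random.default_rng(seed)
    trials: list[ChoiceTrial] = []
    for f in frequencies:
        p = float(observer.p_correct(f))
        sides = np.where(rng.random(trials_per_frequency) < 0.5, "left", "right")
        correct = rng.random(trials_per_frequency) < p
        for side, ok in zip(sides, correct):
            chosen = side if ok else ("right" if side == "left" else "left")
            trials.append(
                ChoiceTrial(
                    subject=subject,
                    frequency_cpd=f,
                    positive_side=str(side),
                    chosen_side=str(chosen),
                )
            )
    return trials


def simulate_optomotor_session(
    observer: SyntheticObserver,
    frequencies: Sequence[float],
    rotations_per_frequency: int = 4,
    seed: int = 0,
    subject: str = "sim",
    stress_rate: float = 0.05,
    include_control: bool = True,
) -> list[OptomotorRotation]:
    """Simulate an optomotor session.

    Tracking probability is ``1 - lapse`` below the observer's threshold and
    ``optomotor_false_positive`` at or above it.  Each frequency is shown for
    alternating cw/ccw rotations; stress flags are drawn at ``stress_rate``
    (default 0.05, the empirical exclusion rate of this assay).  When
    ``include_control`` a grey-control block of the same length is appended,
    with tracking at the false-positive rate.
    """
    if rotations_per_frequency < 4:
        raise ValueError("rotations_per_frequency must be >= 4 (assay design)")
    frequencies = [float(f) for f in frequencies]
    if any(f <= 0 for f in frequencies):
        raise ValueError("frequencies must be positive")
    rng = np.random.default_rng(seed)
    directions = ["cw", "ccw"]
    out: list[OptomotorRotation] = []

    def _block(freq: float | None, p_track: float) -> None:
        for i in range(rotations_per_frequency):
            tracked = rng.random() < p_track
            stress = rng.random() < stress_rate
            if tracked:
                eye = bool(rng.random() < 0.5)
                cat = "1/2-1" if rng.random() < 0.6 else ">1"
            else:
                eye = False
                cat = "<1/4" if rng.random() < 0.7 else "1/4-1/2"
            out.append(
                OptomotorRotation(
                    subject=subject,
                    frequency_cpd=freq,
                    direction=directions[i % 2],
                    eye_tracking=eye,
                    turn_category=cat,
                    stress=stress,
                )
            )

    for f in frequencies:
        p = (1.0 - observer.lapse) if f < observer.threshold_cpd else observer.optomotor_false_positive
        _block(f, p)
    if include_control:
        _block(None, observer.optomotor_false_positive)
    return out
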