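"""Core domain types for dentin chronology analysis.

Conventions used throughout the package:

* all physical lengths are in micrometres (μm);
* image pixel coordinates are 0-based at pixel centres, ``(x, y)`` with
  ``x`` the column and ``y`` the row, origin at the top-left pixel;
* intensity is "higher = brighter"; stained incremental lines are dark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class SchemaError(ValueError):
    """A table is missing a required column or has the wrong layout."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


SEXES = frozenset({"F", "M", "unknown"})
PREPARATIONS = frozenset({"demineralized", "ground"})


@dataclass(frozen=True)
class GLGRecord:
    """Identity and metadata of one Growth Layer Group (GLG).

    A GLG is the coarse repeating dentin layer pair used for age
    estimation in odontocete teeth; each record is one measured GLG of
    one specimen (``glg_label`` distinguishes GLGs within a tooth).
    """

    specimen_id: str
    glg_label: str
    thickness_um: float
    sex: str = "unknown"
    tooth_position: int = 1
    whale_length_cm: Optional[float] = None
    preparation: str = "demineralized"

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValidationError("specimen_id must be non-empty")
        if not self.glg_label:
            raise ValidationError("glg_label must be non-empty")
        if not (self.thickness_um > 0):
            raise ValidationError(
                f"thickness_um must be > 0, got {self.thickness_um!r}"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {sorted(SEXES)}, got {self.sex!r}")
        if int(self.tooth_position) < 1:
            raise ValidationError("tooth_position must be >= 1")
        if self.preparation not in PREPARATIONS:
            raise ValidationError(
                f"preparation must be one of {sorted(PREPARATIONS)}, got {self.preparation!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.specimen_id, self.glg_label)


@dataclass(frozen=True)
class SpacingMeasurement:
    """One centre-to-centre spacing between consecutive dark incremental lines.

    ``position_um`` is the arc length from the start of the GLG (along
    the tubule direction) at which the spacing was measured.
    """

    glg_ref: tuple[str, str]
    position_um: float
    spacing_um: float

    def __post_init__(self) -> None:
        if not (self.spacing_um > 0):
            raise ValidationError(f"spacing_um must be > 0, got {self.spacing_um!r}")
        if self.position_um < 0:
            raise ValidationError(f"position_um must be >= 0, got {self.position_um!r}")


@dataclass(frozen=True)
class GLGSummary:
    """Per-GLG spacing statistics: n, mean, sd, SE, 3·SE and summed length."""

    n: int
    mean_um: float
    sd_um: float
    se_um: float
    three_se_um: float
    sum_um: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("n >= 2 required for the standard error to be defined")
        if not (self.mean_um > 0):
            raise ValidationError("mean_um must be > 0")
        if self.sd_um < 0 or self.se_um < 0:
            raise ValidationError("sd_um and se_um must be >= 0")
        if not np.isclose(self.three_se_um, 3.0 * self.se_um, rtol=1e-6, atol=1e-9):
            raise ValidationError("three_se_um must equal 3 * se_um")


@dataclass(frozen=True)
class DayEstimate:
    """Estimated days in a GLG with asymmetric bounds.

    The estimate is thickness / mean spacing; because days vary as 1/x in
    the mean, propagating a symmetric ±3·SE through the division yields
    asymmetric bounds with ``err_plus >= err_minus``.
    """

    days: float
    err_minus: float
    err_plus: float

    def __post_init__(self) -> None:
        if not (self.days > 0):
            raise ValidationError("days must be > 0")
        if self.err_minus < 0 or self.err_plus < 0:
            raise ValidationError("error bounds must be >= 0")
        if self.err_plus + 1e-12 < self.err_minus:
            raise ValidationError("err_plus must be >= err_minus (convexity of 1/x)")

    @property
    def lower(self) -> float:
        return self.days - self.err_minus

    @property
    def upper(self) -> float:
        return self.days + self.err_plus


@dataclass(frozen=True)
class PredictionPair:
    """Predicted daily-line spacing under 1 GLG/yr and 2 GLG/yr deposition."""

    pred_1glg_um: float
    pred_2glg_um: float

    def __post_init__(self) -> None:
        if not np.isclose(self.pred_2glg_um, 2.0 * self.pred_1glg_um, rtol=1e-9):
            raise ValidationError("pred_2glg_um must equal 2 * pred_1glg_um")


@dataclass(frozen=True)
class HypothesisResult:
    """Which deposition hypothesis the mean spacing supports for one GLG.

    Distances are |observed mean − predicted| in units of 3·SE; coverage
    flags say whether the day interval contains 365 (annual) or 182.5
    (semi-annual) days.
    """

    supported: str  # "annual" | "semiannual" | "tie"
    dist_1glg_in_3se: float
    dist_2glg_in_3se: float
    covers_365: bool
    covers_182: bool

    def __post_init__(self) -> None:
        if self.supported not in ("annual", "semiannual", "tie"):
            raise ValidationError(f"unknown hypothesis label {self.supported!r}")
        if self.dist_1glg_in_3se < 0 or self.dist_2glg_in_3se < 0:
            raise ValidationError("distances must be >= 0")


@dataclass(frozen=True)
class ChronologyConstants:
    """Calendar constants and the error multiplier for interval bounds."""

    days_per_year: float = 365.0
    days_per_half_year: float = 182.5
    error_multiplier: float = 3.0


DEFAULT_CONSTANTS = ChronologyConstants()


@dataclass
class ImageWithScale:
    """A grayscale raster (2-D, or 3-D ``(plane, row, col)`` z-stack) with μm/px scale."""

    pixels: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValidationError(
                f"pixels must be 2-D or 3-D grayscale, got ndim={self.pixels.ndim}"
            )
        if not (self.um_per_px > 0):
            raise ValidationError(f"um_per_px must be > 0, got {self.um_per_px!r}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixel intensities must be finite")

    @property
    def is_stack(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[-2], self.pixels.shape[-1]


@dataclass
class GrowthPath:
    """Measurement polyline in pixel coordinates, following the tubule direction."""

    vertices: np.ndarray  # (N, 2) as (x, y)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValidationError("vertices must be an (N>=2, 2) array of (x, y)")
        seg = np.diff(v, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValidationError("consecutive vertices must be distinct")
        self.vertices = v

    def length_px(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def reversed(self) -> "GrowthPath":
        return GrowthPath(self.vertices[::-1].copy())


@dataclass
class Profile:
    """An arc-length-parameterized intensity trace along a growth path."""

    s_um: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.s_um = np.asarray(self.s_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.s_um.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("s_um and intensity must be 1-D")
        if self.s_um.size != self.intensity.size:
            raise ValidationError("s_um and intensity must have equal length")
        if self.s_um.size >= 2 and not np.all(np.diff(self.s_um) > 0):
            raise ValidationError("s_um must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.s_um.size)

    @property
    def length_um(self) -> float:
        return float(self.s_um[-1] - self.s_um[0]) if self.n >= 2 else 0.0

    def median_step_um(self) -> float:
        if self.n < 2:
            raise ValidationError("profile too short to have a step")
        return float(np.median(np.diff(self.s_um)))


@dataclass
class LineCenters:
    """Detected dark-line centre positions (arc length, μm) with prominences."""

    s_um: np.ndarray
    prominence: np.ndarray

    def __post_init__(self) -> None:
        self.s_um = np.asarray(self.s_um, dtype=float)
        self.prominence = np.asarray(self.prominence, dtype=float)
        if self.s_um.size != self.prominence.size:
            raise ValidationError("s_um and prominence must have equal length")
        if self.s_um.size >= 2 and not np.all(np.diff(self.s_um) > 0):
            raise ValidationError("centre positions must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.s_um.size)


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs for dark-line detection on a detrended profile.

    ``min_separation_um`` rejects sub-daily texture (default ≈ half the
    smallest plausible daily spacing); ``prominence_rel`` is the required
    dip prominence as a fraction of the interquartile intensity range;
    ``detrend_window_um`` is the running-mean baseline width and must be
    much longer than the expected line period; ``normal_window_px`` is
    how many pixels are averaged perpendicular to the path;
    ``smooth_um`` is the sigma of a Gaussian low-pass matched to the
    line width, applied before peak picking to keep pixel noise from
    seeding spurious minima (0 disables it).
    """

    min_separation_um: float = 0.8
    prominence_rel: float = 0.1
    detrend_window_um: float = 20.0
    normal_window_px: int = 5
    smooth_um: float = 0.25

    def __post_init__(self) -> None:
        if not (self.min_separation_um > 0):
            raise ValidationError("min_separation_um must be > 0")
        if not (0 < self.prominence_rel):
            raise ValidationError("prominence_rel must be > 0")
        if not (self.detrend_window_um > 0):
            raise ValidationError("detrend_window_um must be > 0")
        if int(self.normal_window_px) < 1:
            raise ValidationError("normal_window_px must be >= 1")
        if self.smooth_um < 0:
            raise ValidationError("smooth_um must be >= 0")
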