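"""Gaze-contingent relative central scotoma rendering.

Simulates the central vision loss of progressed binocular macular
degeneration on video: a soft-edged, irregular, roughly semi-circular alpha
mask is anchored to the point of gaze, and the video under the mask is
replaced by a Gaussian-blurred version (a *relative* scotoma — degraded, not
absent, vision). The blur's amplitude response falls to one half at a
configurable spatial-frequency cutoff (full width at half maximum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ScreenGeometry",
    "ScotomaMask",
    "DEFAULT_SCREEN",
    "MASK_WIDTH_PX",
    "MASK_HEIGHT_PX",
    "ORIENTATIONS",
    "pixels_per_degree",
    "blur_sigma_degrees",
    "build_scotoma_mask",
    "gaussian_lowpass_frame",
    "composite_scotoma",
    "render_degraded_clip",
]

#: Scotoma mask bounding box, width x height in pixels (about 17 x 11.5 deg).
MASK_WIDTH_PX = 731
MASK_HEIGHT_PX = 497

ORIENTATIONS = ("original", "h-flip", "v-flip", "hv-flip")


@dataclass(frozen=True)
class ScreenGeometry:
    """Display size in pixels and degrees of visual angle."""

    width_px: int = 1920
    height_px: int = 1080
    width_deg: float = 43.0
    height_deg: float = 24.8

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) <= 0:
            raise ValueError("pixel dimensions must be positive")
        if min(self.width_deg, self.height_deg) <= 0:
            raise ValueError("angular dimensions must be positive")

    @property
    def diagonal_deg(self) -> float:
        """Screen diagonal in degrees of visual angle."""
        return float(np.hypot(self.width_deg, self.height_deg))


#: The 24.5-inch experimental display: 1920 x 1080 px spanning 43 x 24.8 deg.
DEFAULT_SCREEN = ScreenGeometry()


def pixels_per_degree(g: ScreenGeometry, axis: str = "horizontal") -> float:
    """Pixels per degree of visual angle along the given axis."""
    if axis == "horizontal":
        return g.width_px / g.width_deg
    if axis == "vertical":
        return g.height_px / g.height_deg
    raise ValueError("axis must be 'horizontal' or 'vertical'")


@dataclass(frozen=True)
class ScotomaMask:
    """Soft-edged alpha mask anchored to gaze by its bounding-box center."""

    alpha: np.ndarray  # (height, width), values in [0, 1]
    orientation: str = "original"

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.min() < 0 or alpha.max() > 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        object.__setattr__(self, "alpha", alpha)

    @property
    def anchor(self) -> tuple:
        """(x, y) mask pixel aligned to the point of gaze."""
        h, w = self.alpha.shape
        return (w // 2, h // 2)

    def flipped(self, horizontal: bool = False, vertical: bool = False) -> "ScotomaMask":
        alpha = self.alpha
        if horizontal:
            alpha = alpha[:, ::-1]
        if vertical:
            alpha = alpha[::-1, :]
        return ScotomaMask(np.ascontiguousarray(alpha), self.orientation)


def build_scotoma_mask(
    seed: int = 0,
    orientation: str = "original",
    width_px: int = MASK_WIDTH_PX,
    height_px: int = MASK_HEIGHT_PX,
    edge_px: float = 40.0,
) -> ScotomaMask:
    """Generate the irregular, semi-circular, soft-edged scotoma mask.

    The base boundary is an ellipse filling the bounding box, flattened on
    one side into a near-vertical edge (semi-circular silhouette) and
    perturbed by seeded low-order sinusoids in polar angle. The perturbation
    vanishes at the four cardinal directions so the non-zero footprint's
    bounding box is exactly ``width_px x height_px``. Alpha is 1 in the
    core and decays to 0 over a raised-cosine ring of ``edge_px`` pixels.

    Deterministic for a fixed seed.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    rng = np.random.default_rng(seed)
    amps = 0.04 + 0.08 * rng.random(3)
    phases = 2 * np.pi * rng.random(3)

    cx = (width_px - 1) / 2.0
    cy = (height_px - 1) / 2.0
    # semi-axes spanning the full box; the extra half pixel puts the zero
    # crossing just outside the outermost pixel row/column, so the non-zero
    # footprint is exactly width_px x height_px
    a = width_px / 2.0
    b = height_px / 2.0
    y, x = np.mgrid[0:height_px, 0:width_px]
    u = (x - cx) / a
    v = (y - cy) / b
    theta = np.arctan2(v, u)

    # left half circular, right half flattened toward a vertical edge
    u_right = np.where(u > 0, u, 0.0)
    rho = np.where(
        u > 0,
        (u_right**6 + np.abs(v) ** 6) ** (1.0 / 6.0),
        np.hypot(u, v),
    )

    # irregular boundary; sin(2*theta)^2 factor pins the cardinal points
    wobble = sum(
        amp * np.sin((k + 3) * theta + ph)
        for k, (amp, ph) in enumerate(zip(amps, phases))
    )
    rho_b = 1.0 - np.abs(wobble) * np.sin(2 * theta) ** 2

    # distance inside the boundary, in approximate pixels
    r_px = np.hypot((x - cx), (y - cy))
    with np.errstate(divide="ignore", invalid="ignore"):
        d_px = np.where(rho > 0, (rho_b - rho) / rho * r_px, edge_px)
    d_px = np.clip(d_px, 0.0, edge_px)
    alpha = 0.5 * (1.0 - np.cos(np.pi * d_px / edge_px))

    mask = ScotomaMask(alpha, "original")
    if orientation in ("h-flip", "hv-flip"):
        mask = mask.flipped(horizontal=True)
    if orientation in ("v-flip", "hv-flip"):
        mask = mask.flipped(vertical=True)
    return ScotomaMask(mask.alpha, orientation)


def blur_sigma_degrees(cutoff_cpd: float) -> float:
    """Gaussian sigma (deg) whose amplitude response is 0.5 at ``cutoff_cpd``.

    Solves exp(-2 pi^2 sigma^2 f^2) = 1/2.
    """
    if cutoff_cpd <= 0:
        raise ValueError("cutoff must be positive")
    return float(np.sqrt(np.log(2.0)) / (np.sqrt(2.0) * np.pi * cutoff_cpd))


def gaussian_lowpass_frame(
    frame: np.ndarray,
    cutoff_cpd: float,
    geometry: ScreenGeometry = DEFAULT_SCREEN,
) -> np.ndarray:
    """Isotropic Gaussian blur with FWHM amplitude cutoff ``cutoff_cpd``.

    Uses the horizontal pixels-per-degree scale for both axes (the screen is
    near-isotropic) and reflective padding at frame edges so the mean
    intensity is preserved.
    """
    frame = np.asarray(frame, dtype=float)
    sigma_px = blur_sigma_degrees(cutoff_cpd) * pixels_per_degree(geometry)
    if sigma_px > max(frame.shape[0], frame.shape[1]):
        raise ValueError(
            "cutoff too low: blur kernel would exceed the frame size"
        )
    sigma = (sigma_px, sigma_px) + (0.0,) * (frame.ndim - 2)
    return ndimage.gaussian_filter(frame, sigma=sigma, mode="reflect")


def composite_scotoma(
    frame: np.ndarray,
    blurred: np.ndarray,
    mask: ScotomaMask,
    gaze_px: tuple,
) -> np.ndarray:
    """Alpha-blend ``blurred`` over ``frame`` with the mask centered on gaze.

    ``out = (1 - alpha) * frame + alpha * blurred``. The mask may fall
    partially or fully off-screen; off-screen parts are cropped.
    """
    frame = np.asarray(frame, dtype=float)
    blurred = np.asarray(blurred, dtype=float)
    if frame.shape != blurred.shape:
        raise ValueError("frame and blurred must have the same shape")
    fh, fw = frame.shape[:2]
    mh, mw = mask.alpha.shape
    ax, ay = mask.anchor
    gx = int(round(gaze_px[0]))
    gy = int(round(gaze_px[1]))

    left = gx - ax
    top = gy - ay
    x0, x1 = max(0, left), min(fw, left + mw)
    y0, y1 = max(0, top), min(fh, top + mh)
    out = frame.copy()
    if x0 >= x1 or y0 >= y1:
        return out
    sub = mask.alpha[y0 - top : y1 - top, x0 - left : x1 - left]
    if frame.ndim == 3:
        sub = sub[..., np.newaxis]
    out[y0:y1, x0:x1] = (1.0 - sub) * frame[y0:y1, x0:x1] + sub * blurred[
        y0:y1, x0:x1
    ]
    return out


def render_degraded_clip(
    frames,
    frame_times_ms,
    gaze_times_ms,
    gaze_xy_px,
    mask: ScotomaMask,
    geometry: ScreenGeometry = DEFAULT_SCREEN,
    cutoff_cpd: float = 0.15,
):
    """Render a gaze-contingent degraded clip.

    Each frame is composited using the gaze sample whose timestamp is
    nearest the frame's timestamp; the mask orientation is fixed within the
    clip (one trial). Returns the list of degraded frames.
    """
    gaze_times_ms = np.asarray(gaze_times_ms, dtype=float)
    gaze_xy_px = np.asarray(gaze_xy_px, dtype=float)
    if gaze_times_ms.size == 0:
        raise ValueError("gaze trace is empty")
    out = []
    for frame, t in zip(frames, frame_times_ms):
        k = int(np.argmin(np.abs(gaze_times_ms - t)))
        blurred = gaussian_lowpass_frame(frame, cutoff_cpd, geometry)
        out.append(composite_scotoma(frame, blurred, mask, tuple(gaze_xy_px[k])))
    return out
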