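"""Absolute head-to-cursor mapping.

The controller is memoryless: a given head orientation always produces
the same airplane position.  The per-sample orientation ``R_S`` is first
referred to the calibrated neutral posture ``R_cal``,

    R_T = R_cal⁻¹ · R_S,

so the neutral posture lands exactly on the screen centre, and the YZX
Euler angles of ``R_T`` drive the cursor linearly:

    y = −R_V · α / α_T        (flexion moves the plane down)
    x =  R_H · β / β_T        (β = lateral inclination or axial rotation)

where ``R_H``/``R_V`` are the horizontal/vertical screen extents in
pixels and ``α_T``/``β_T`` the range of motion, in degrees, needed to
reach them.  Positions are clamped to the screen so the airplane never
leaves the play area.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rotation import RotationState, decompose_yzx

__all__ = [
    "MappingConfig",
    "CursorPosition",
    "relative_rotation",
    "cursor_from_orientation",
    "angles_for_position",
]

HORIZONTAL_SOURCES = ("inclination", "rotation")
MODES = ("1D-vertical", "1D-horizontal", "2D")


@dataclass(frozen=True)
class CursorPosition:
    """Airplane position in pixels; origin at screen centre, x right, y up."""

    x: float
    y: float


@dataclass(frozen=True)
class MappingConfig:
    """Geometry and sensitivity of the head-pointer mapping.

    Parameters
    ----------
    r_h, r_v:
        Horizontal and vertical half-extents of the target field in
        pixels, measured from the screen centre.
    alpha_t:
        Flexion-extension range of motion, degrees, that moves the
        cursor to the vertical extent ``r_v``.  The study protocol uses
        an easy level of 20–30°; the default sits mid-range.
    beta_t:
        Range of motion on the horizontal-control axis reaching ``r_h``.
    horizontal_source:
        Which cervical motion drives x: ``"inclination"`` (lateral
        tilt, the study default) or ``"rotation"`` (axial turn).
    mode:
        ``"2D"`` or the single-axis modes ``"1D-vertical"`` /
        ``"1D-horizontal"``, in which the unused coordinate is pinned
        to zero.
    screen_w, screen_h:
        Screen size in pixels; the cursor is clamped to its bounds.
    """

    r_h: float = 400.0
    r_v: float = 300.0
    alpha_t: float = 25.0
    beta_t: float = 25.0
    horizontal_source: str = "inclination"
    mode: str = "2D"
    screen_w: int = 1280
    screen_h: int = 720

    def __post_init__(self) -> None:
        if self.r_h <= 0 or self.r_v <= 0:
            raise ValueError("screen extents r_h, r_v must be positive")
        if not (0 < self.alpha_t <= 90) or not (0 < self.beta_t <= 90):
            raise ValueError("alpha_t and beta_t must lie in (0, 90] degrees")
        if self.horizontal_source not in HORIZONTAL_SOURCES:
            raise ValueError(
                f"horizontal_source must be one of {HORIZONTAL_SOURCES}"
            )
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.r_h > self.screen_w / 2 or self.r_v > self.screen_h / 2:
            raise ValueError("extents must fit inside the screen")


def relative_rotation(r_cal: RotationState, r_s: RotationState) -> RotationState:
    """Head orientation relative to the calibrated neutral posture.

    ``R_T = R_cal⁻¹ · R_S``; at the neutral posture (``R_S = R_cal``)
    this is the identity, anchoring the absolute mapping at the screen
    centre.
    """
    return r_cal.inverse() @ r_s


def cursor_from_orientation(r_t: RotationState, cfg: MappingConfig) -> CursorPosition:
    """Map a calibrated-relative orientation to an airplane position.

    Raises the gimbal-lock error of :func:`~cervigame.rotation.decompose_yzx`
    for degenerate orientations (axial rotation at ±90°).
    """
    e = decompose_yzx(r_t)
    beta = e.incl if cfg.horizontal_source == "inclination" else e.rot
    x = cfg.r_h * beta / cfg.beta_t
    y = -cfg.r_v * e.alpha / cfg.alpha_t
    if cfg.mode == "1D-vertical":
        x = 0.0
    elif cfg.mode == "1D-horizontal":
        y = 0.0
    half_w, half_h = cfg.screen_w / 2.0, cfg.screen_h / 2.0
    return CursorPosition(
        x=min(half_w, max(-half_w, x)), y=min(half_h, max(-half_h, y))
    )


def angles_for_position(pos: CursorPosition, cfg: MappingConfig) -> tuple[float, float]:
    """Invert the linear law: (alpha, beta) in degrees reaching ``pos``.

    Used by the target generator and the simulated user to express
    on-screen goals as head angles; valid inside the screen (the clamp
    is not invertible).
    """
    alpha = -pos.y * cfg.alpha_t / cfg.r_v
    beta = pos.x * cfg.beta_t / cfg.r_h
    return alpha, beta
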