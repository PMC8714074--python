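"""Starfield stimulus geometry and per-frame stimulus traces.

The stimulus is a 3-D cloud of small spheres placed uniformly in a cube
centred on the animal and projected onto a flat screen in front of it.
Roll optic flow rotates the cloud about the body axis (the axis through
the animal, perpendicular to the screen); lift translates it vertically.
Sphere distance is coded on screen by circle size (closer = larger) and
brightness (linear from black at 6 cm to white at 2 m).

Coordinate frame: x right, y up, z toward the screen, origin at the
animal.  Positive roll is counter-clockwise on the screen; positive lift
moves spheres downward on the screen (the excitatory direction for the
neurons this protocol targets).

The analysis pipeline consumes only :class:`StimulusTrace` objects — the
per-frame signed roll/lift increments — never rendered pixels; rendering
(:func:`project_sphere`) exists for geometry checks and inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "StarfieldWorld",
    "FlowCondition",
    "StimulusTrace",
    "RenderedCircle",
    "make_world",
    "transform_world",
    "project_sphere",
    "count_rendered",
    "compose_trace",
    "default_conditions",
]

# Rendering distance limits (m): spheres closer than MIN_RENDER_DISTANCE
# are not drawn; at MAX_RENDER_DISTANCE a sphere is white on the white
# background, i.e. invisible, so more distant spheres are not drawn either.
MIN_RENDER_DISTANCE = 0.06
MAX_RENDER_DISTANCE = 2.0


@dataclass(frozen=True)
class ScreenGeometry:
    """Viewing geometry of the stimulus display."""

    view_distance: float = 6.5        # cm, eye to screen
    pixel_width: int = 2560
    pixel_height: int = 1440
    azimuth_extent: float = 155.0     # deg subtended horizontally
    elevation_extent: float = 138.0   # deg subtended vertically
    frame_rate: float = 165.0         # Hz

    def __post_init__(self) -> None:
        if not (0 < self.azimuth_extent < 180 and 0 < self.elevation_extent < 180):
            raise ValueError("angular extents must lie in (0, 180) deg")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_width <= 0 or self.pixel_height <= 0:
            raise ValueError("pixel counts must be positive")
        if self.view_distance <= 0:
            raise ValueError("view_distance must be positive")

    @property
    def half_width_cm(self) -> float:
        return self.view_distance * np.tan(np.radians(self.azimuth_extent / 2))

    @property
    def half_height_cm(self) -> float:
        return self.view_distance * np.tan(np.radians(self.elevation_extent / 2))


@dataclass
class StarfieldWorld:
    """A cube of randomly placed spheres in a fly-centred frame (metres)."""

    cube_side: float = 4.0            # m
    density: float = 100.0            # spheres / m^3
    sphere_diameter: float = 2.0      # cm
    positions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3))
    )

    @property
    def n_spheres(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class FlowCondition:
    """One experimental condition: impulse size plus constant flow.

    ``base_impulse`` is the rotation (deg) of each m-sequence impulse.
    ``constant_roll`` (deg/s, + = excitatory/counter-clockwise) and
    ``constant_lift`` (cm/s, + = excitatory/downward-on-screen) are added
    on top of the impulse train.
    """

    base_impulse: float
    constant_roll: float = 0.0
    constant_lift: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.base_impulse < 0:
            raise ValueError("base_impulse must be >= 0")


@dataclass
class StimulusTrace:
    """Per-frame stimulus increments for one trial."""

    sign_sequence: np.ndarray        # ±1 per frame
    roll_increment: np.ndarray       # deg per frame, signed
    lift_increment: np.ndarray       # cm per frame, signed
    frame_times: np.ndarray          # s, frame onsets
    condition: FlowCondition
    frame_log: np.ndarray            # bool, frame actually presented
    frame_rate: float = 165.0
    period: int = 255                # final impulses entering the analysis

    @property
    def n_frames(self) -> int:
        return len(self.sign_sequence)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def analysis_start(self) -> int:
        """Index of the first frame of the final full m-sequence period."""
        return self.n_frames - self.period

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "frame_index": np.arange(self.n_frames),
                "time_s": self.frame_times,
                "sign": self.sign_sequence,
                "roll_increment_deg": self.roll_increment,
                "lift_increment_cm": self.lift_increment,
                "presented": self.frame_log.astype(int),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, condition: FlowCondition,
        frame_rate: float = 165.0, period: int = 255
    ) -> "StimulusTrace":
        df = pd.read_csv(path)
        return cls(
            sign_sequence=df["sign"].to_numpy(np.int8),
            roll_increment=df["roll_increment_deg"].to_numpy(float),
            lift_increment=df["lift_increment_cm"].to_numpy(float),
            frame_times=df["time_s"].to_numpy(float),
            condition=condition,
            frame_log=df["presented"].to_numpy(bool),
            frame_rate=frame_rate,
            period=period,
        )


@dataclass(frozen=True)
class RenderedCircle:
    """Screen-space rendering of one sphere."""

    center: tuple[float, float]      # pixel coordinates (x, y)
    diameter: float                  # pixels
    gray: float                      # 0 = black, 1 = white

    def __post_init__(self) -> None:
        if not 0.0 <= self.gray <= 1.0:
            raise ValueError("gray must lie in [0, 1]")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")


def make_world(
    rng: np.random.Generator,
    cube_side: float = 4.0,
    density: float = 100.0,
    sphere_diameter: float = 2.0,
) -> StarfieldWorld:
    """Place ``round(density * cube_side**3)`` spheres uniformly in the cube."""
    if cube_side <= 0 or density < 0 or sphere_diameter <= 0:
        raise ValueError("cube_side and sphere_diameter must be positive, "
                         "density nonnegative")
    n = int(round(density * cube_side**3))
    half = cube_side / 2
    positions = rng.uniform(-half, half, size=(n, 3))
    return StarfieldWorld(cube_side, density, sphere_diameter, positions)


def transform_world(
    world: StarfieldWorld, roll_deg: float, lift_cm: float
) -> StarfieldWorld:
    """Roll about the body (z) axis then translate along y, wrapping at faces.

    Positive ``roll_deg`` is counter-clockwise on the screen; positive
    ``lift_cm`` moves spheres downward on the screen (−y).  Wrapping the
    positions modulo the cube keeps the sphere density stationary over a
    trial.
    """
    if not (np.isfinite(roll_deg) and np.isfinite(lift_cm)):
        raise ValueError("increments must be finite")
    theta = np.radians(roll_deg)
    c, s = np.cos(theta), np.sin(theta)
    pos = world.positions.copy()
    x = pos[:, 0] * c - pos[:, 1] * s
    y = pos[:, 0] * s + pos[:, 1] * c
    pos[:, 0] = x
    pos[:, 1] = y - lift_cm / 100.0
    half = world.cube_side / 2
    pos = np.mod(pos + half, world.cube_side) - half
    return replace(world, positions=pos)


def _project_batch(
    positions: np.ndarray, screen: ScreenGeometry, world: StarfieldWorld
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised gnomonic projection; returns (visible, px, py, d)."""
    pos = np.atleast_2d(positions)
    x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
    d = np.linalg.norm(pos, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # screen-plane coordinates in cm
        sx = screen.view_distance * np.where(z > 0, x / np.where(z > 0, z, 1), np.inf)
        sy = screen.view_distance * np.where(z > 0, y / np.where(z > 0, z, 1), np.inf)
    px_per_cm_x = (screen.pixel_width / 2) / screen.half_width_cm
    px_per_cm_y = (screen.pixel_height / 2) / screen.half_height_cm
    px = screen.pixel_width / 2 + sx * px_per_cm_x
    py = screen.pixel_height / 2 - sy * px_per_cm_y
    visible = (
        (z > 0)
        & (d >= MIN_RENDER_DISTANCE)
        & (d <= MAX_RENDER_DISTANCE)
        & (px >= 0)
        & (px < screen.pixel_width)
        & (py >= 0)
        & (py < screen.pixel_height)
    )
    return visible, px, py, d


def project_sphere(
    position: np.ndarray, screen: ScreenGeometry, world: StarfieldWorld
) -> RenderedCircle | None:
    """Project one sphere onto the screen, or return None if not rendered.

    A sphere is rendered only if it lies in front of the animal, at a
    straight-line distance within [6 cm, 2 m], and its projected centre
    falls on the pixel raster.  Brightness interpolates linearly from
    black at 6 cm to white at 2 m; the drawn diameter shrinks with
    distance (angular size mapped through the centre pixel scale).
    """
    position = np.asarray(position, dtype=float)
    visible, px, py, d = _project_batch(position[None, :], screen, world)
    if not visible[0]:
        return None
    d_m = float(d[0])
    gray = float(
        np.clip(
            (d_m - MIN_RENDER_DISTANCE)
            / (MAX_RENDER_DISTANCE - MIN_RENDER_DISTANCE),
            0.0,
            1.0,
        )
    )
    ang_radius = np.arctan((world.sphere_diameter / 100 / 2) / d_m)
    px_per_cm_x = (screen.pixel_width / 2) / screen.half_width_cm
    diameter = 2 * screen.view_distance * np.tan(ang_radius) * px_per_cm_x
    return RenderedCircle(
        center=(float(px[0]), float(py[0])), diameter=float(diameter),
        gray=gray,
    )


def count_rendered(world: StarfieldWorld, screen: ScreenGeometry) -> int:
    """Number of spheres of the world rendered on the screen."""
    if world.n_spheres == 0:
        return 0
    visible, _, _, _ = _project_batch(world.positions, screen, world)
    return int(np.sum(visible))


def compose_trace(
    extended_sequence: np.ndarray,
    condition: FlowCondition,
    screen: ScreenGeometry | None = None,
    period: int | None = None,
) -> StimulusTrace:
    """Build the per-frame stimulus trace for one trial.

    Each frame rotates the starfield by ``sign * base_impulse`` plus the
    constant-roll increment ``constant_roll / frame_rate``, and translates
    it by ``constant_lift / frame_rate``.  Exact increments are used
    internally (printed stimulus descriptions round them to 2 decimals).
    """
    if screen is None:
        screen = ScreenGeometry()
    seq = np.asarray(extended_sequence)
    if not np.all(np.isin(seq, (-1, 1))):
        raise ValueError("extended_sequence must contain only -1 and +1")
    if period is None:
        # largest 2**n - 1 that fits: the final full m-sequence period
        period = 2 ** int(np.floor(np.log2(len(seq) + 1))) - 1
    n = len(seq)
    fr = screen.frame_rate
    roll_inc = seq * condition.base_impulse + condition.constant_roll / fr
    lift_inc = np.full(n, condition.constant_lift / fr)
    return StimulusTrace(
        sign_sequence=seq.astype(np.int8),
        roll_increment=roll_inc,
        lift_increment=lift_inc,
        frame_times=np.arange(n) / fr,
        condition=condition,
        frame_log=np.ones(n, dtype=bool),
        frame_rate=fr,
        period=period,
    )


def default_conditions() -> list[FlowCondition]:
    """The nine standard conditions of the roll m-sequence protocol.

    Three impulse sizes (Roll 18/33/48), Roll 33 with constant inhibitory
    or excitatory roll at 25 and 50 deg/s, and Roll 33 with constant lift
    at 50 cm/s in the neutral (upward) or excitatory (downward) direction.
    """
    return [
        FlowCondition(0.18, 0.0, 0.0, "roll18"),
        FlowCondition(0.33, 0.0, 0.0, "roll33"),
        FlowCondition(0.48, 0.0, 0.0, "roll48"),
        FlowCondition(0.33, -25.0, 0.0, "ir25"),
        FlowCondition(0.33, -50.0, 0.0, "ir50"),
        FlowCondition(0.33, 25.0, 0.0, "er25"),
        FlowCondition(0.33, 50.0, 0.0, "er50"),
        FlowCondition(0.33, 0.0, -50.0, "lift_neutral"),
        FlowCondition(0.33, 0.0, 50.0, "lift_excitatory"),
    ]
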