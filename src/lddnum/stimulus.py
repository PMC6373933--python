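"""Limited-dot-lifetime display (LDD) stimulus engine.

An LDD is a dynamic dot array in which a fixed number of dots is visible
at every moment, but each individual dot lives only for a brief fixed
duration (300 ms by default).  When a dot's lifetime elapses it is removed
and a new dot appears simultaneously at a fresh random location, so the
display can be viewed for arbitrarily long without the dots being
countable.  Dots are scattered uniformly over one or two square regions
subject to a minimum center-to-center distance, may carry per-group sizes
and colors, and may translate coherently or in two opposed directions.

Coordinates are degrees of visual angle, origin at the midpoint of the
array region, y pointing up.  Time is in milliseconds and is simulated on
a fixed tick (60 ticks/s by default): a dot expires at the first tick at
or after its scheduled expiry time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "DEFAULT_LIFETIME_MS",
    "DEFAULT_MIN_DIST_DEG",
    "DEFAULT_TICK_RATE_HZ",
    "BASELINE_AREA_DEG2",
    "BASELINE_DOT_DIAMETER_DEG",
    "PackingError",
    "RegionGeometry",
    "StimulusSpec",
    "Dot",
    "DotField",
    "assign_group_sizes",
    "sample_layout",
    "init_phases",
    "make_motion_assignment",
    "advance",
    "simulate",
    "events_to_frame",
    "completed_life_durations",
    "min_distance_at_spawns",
    "render_frame",
]

DEFAULT_LIFETIME_MS = 300.0
DEFAULT_MIN_DIST_DEG = 0.80
DEFAULT_TICK_RATE_HZ = 60.0

#: Area of the standard one-group 8 x 8 deg stimulus region.
BASELINE_AREA_DEG2 = 64.0
#: Diameter of the standard (response-array) dot.
BASELINE_DOT_DIAMETER_DEG = 0.50

_MAX_TRIES_PER_DOT = 400
_MAX_LAYOUT_RESTARTS = 40


class PackingError(RuntimeError):
    """Raised when dots cannot be placed at the requested density."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionGeometry:
    """One or two axis-defined square areas, optionally rigidly rotated.

    ``centers`` and ``sides`` are given in the unrotated frame; the whole
    layout is rotated by ``rotation_rad`` about the origin (the midpoint
    of the array region).  In the two-group spatially-clustered condition
    the two squares have 32 deg^2 each and centers 8 deg apart.
    """

    centers: tuple[tuple[float, float], ...] = (((0.0, 0.0)),)
    sides: tuple[float, ...] = (8.0,)
    rotation_rad: float = 0.0

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.sides):
            raise ValueError("centers and sides must have equal length")
        if len(self.centers) not in (1, 2):
            raise ValueError("a region holds one or two squares")
        if any(s <= 0 for s in self.sides):
            raise ValueError("square sides must be positive")

    @classmethod
    def single_square(cls, side: float = 8.0) -> "RegionGeometry":
        return cls(centers=((0.0, 0.0),), sides=(side,))

    @classmethod
    def two_squares(
        cls,
        area_each_deg2: float = 32.0,
        separation_deg: float = 8.0,
        rotation_rad: float = 0.0,
    ) -> "RegionGeometry":
        side = math.sqrt(area_each_deg2)
        half = separation_deg / 2.0
        return cls(
            centers=((-half, 0.0), (half, 0.0)),
            sides=(side, side),
            rotation_rad=rotation_rad,
        )

    @property
    def n_squares(self) -> int:
        return len(self.centers)

    @property
    def total_area_deg2(self) -> float:
        return float(sum(s * s for s in self.sides))

    def rotated_center(self, i: int) -> tuple[float, float]:
        cx, cy = self.centers[i]
        c, s = math.cos(self.rotation_rad), math.sin(self.rotation_rad)
        return (c * cx - s * cy, s * cx + c * cy)

    def sample_point(
        self, square: int, rng: np.random.Generator, inset: float = 0.0
    ) -> tuple[float, float]:
        """Uniform point in square ``square``, shrunk by ``inset`` per edge."""
        half = self.sides[square] / 2.0 - inset
        if half <= 0:
            raise PackingError(
                f"inset {inset:.3f} deg exceeds square half-side "
                f"{self.sides[square] / 2.0:.3f} deg"
            )
        cx, cy = self.centers[square]
        x = cx + rng.uniform(-half, half)
        y = cy + rng.uniform(-half, half)
        c, s = math.cos(self.rotation_rad), math.sin(self.rotation_rad)
        return (c * x - s * y, s * x + c * y)


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusSpec:
    """Full parameterization of one dot array.

    ``dot_diameter_deg`` and ``color_labels`` hold one value for one-group
    arrays and one value per group for two-group arrays (the two-group
    size condition uses diameters (0.25, 1.0) deg; the two-group color
    condition uses ('yellow', 'blue')).
    """

    n_dots: int
    region: RegionGeometry = field(default_factory=RegionGeometry.single_square)
    dot_diameter_deg: float | tuple[float, float] = BASELINE_DOT_DIAMETER_DEG
    color_labels: tuple[str, ...] = ("blue",)
    motion_speed_deg_per_s: float = 0.0
    motion_mode: str = "none"  # {none, coherent, opposed-groups}
    lifetime_ms: float = DEFAULT_LIFETIME_MS
    min_dist_deg: float = DEFAULT_MIN_DIST_DEG
    n_groups: int = 1
    grouping_feature: str = "none"  # {none, spatial, size, color, motion}
    randomize_rotation: bool = False

    def __post_init__(self) -> None:
        if self.n_dots < 1:
            raise ValueError("n_dots must be >= 1")
        if self.lifetime_ms <= 0:
            raise ValueError("lifetime_ms must be > 0")
        if self.min_dist_deg < 0:
            raise ValueError("min_dist_deg must be >= 0")
        if self.n_groups not in (1, 2):
            raise ValueError("n_groups must be 1 or 2")
        if self.n_groups == 2 and self.grouping_feature == "none":
            raise ValueError("two-group arrays need a grouping feature")
        if self.motion_mode not in ("none", "coherent", "opposed-groups"):
            raise ValueError(f"unknown motion_mode {self.motion_mode!r}")
        if self.motion_mode == "opposed-groups" and self.n_groups != 2:
            raise ValueError("opposed-groups motion requires two groups")

    def diameter_for_group(self, group_id: int) -> float:
        d = self.dot_diameter_deg
        if isinstance(d, (tuple, list)):
            return float(d[group_id]) if len(d) > 1 else float(d[0])
        return float(d)

    def color_for_group(self, group_id: int) -> str:
        labels = self.color_labels
        return labels[group_id] if len(labels) > 1 else labels[0]

    def square_for_group(self, group_id: int) -> int:
        return group_id if self.region.n_squares == 2 else 0

    @property
    def total_area_deg2(self) -> float:
        return self.region.total_area_deg2

    @property
    def mean_dot_diameter_deg(self) -> float:
        """Geometric mean of the per-group diameters (a scalar size summary)."""
        d = self.dot_diameter_deg
        if isinstance(d, (tuple, list)):
            return float(np.exp(np.mean(np.log(np.asarray(d, dtype=float)))))
        return float(d)

    @property
    def spawn_inset_deg(self) -> float:
        """Margin keeping a moving dot inside its square for a full life."""
        if self.motion_mode == "none" or self.motion_speed_deg_per_s == 0:
            return 0.0
        return self.motion_speed_deg_per_s * self.lifetime_ms / 1000.0


# ---------------------------------------------------------------------------
# Dots and fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dot:
    x: float
    y: float
    birth_time_ms: float
    death_time_ms: float  # scheduled expiry (first life: the phase offset)
    group_id: int
    diameter_deg: float
    color_label: str
    vx: float
    vy: float
    life_id: int

    @property
    def phase_offset_ms(self) -> float:
        return self.death_time_ms - self.birth_time_ms


@dataclass
class DotField:
    """The live set of dots at one time point."""

    dots: list[Dot]
    time_ms: float
    spec: StimulusSpec
    _next_life_id: int = 0

    @property
    def n_alive(self) -> int:
        return len(self.dots)

    def positions(self) -> np.ndarray:
        return np.array([(d.x, d.y) for d in self.dots], dtype=float)

    def min_pairwise_distance(self) -> float:
        p = self.positions()
        if len(p) < 2:
            return math.inf
        diff = p[:, None, :] - p[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        iu = np.triu_indices(len(p), k=1)
        return float(dist[iu].min())


def assign_group_sizes(n_total: int, rng: np.random.Generator) -> tuple[int, int]:
    """Split an even total into two group counts of half +/- {0,1,2} dots.

    One group receives ``n_total/2 + k`` dots with ``k`` drawn uniformly
    from {-2, -1, 0, 1, 2}; the other group receives the remainder.
    """
    if n_total % 2 != 0:
        raise ValueError(f"two-group assignment needs an even total, got {n_total}")
    offset = int(rng.integers(-2, 3))
    n1 = n_total // 2 + offset
    if n1 < 0 or n1 > n_total:
        raise ValueError(f"offset {offset} infeasible for n_total={n_total}")
    return n1, n_total - n1


def make_motion_assignment(
    spec: StimulusSpec, rng: np.random.Generator
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Per-group velocity vectors (deg/s).

    opposed-groups: group 0 moves in a uniformly random direction, group 1
    exactly antiparallel.  coherent: both groups share one random
    direction.  none: zero vectors.
    """
    if spec.motion_mode == "none" or spec.motion_speed_deg_per_s == 0:
        return ((0.0, 0.0), (0.0, 0.0))
    theta = rng.uniform(0.0, 2.0 * math.pi)
    v = spec.motion_speed_deg_per_s
    v0 = (v * math.cos(theta), v * math.sin(theta))
    if spec.motion_mode == "opposed-groups":
        return (v0, (-v0[0], -v0[1]))
    return (v0, v0)


def _density_message(spec: StimulusSpec) -> str:
    area = spec.total_area_deg2
    disc = math.pi * (spec.min_dist_deg / 2.0) ** 2
    return (
        f"cannot place {spec.n_dots} dots at min distance "
        f"{spec.min_dist_deg:.2f} deg in {area:.1f} deg^2 "
        f"(exclusion-disc density {spec.n_dots * disc / area:.2f})"
    )


def _place_one(
    spec: StimulusSpec,
    square: int,
    occupied: Sequence[tuple[float, float]],
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Rejection-sample one position >= min_dist from all occupied points."""
    inset = spec.spawn_inset_deg
    md2 = spec.min_dist_deg**2
    occ = np.asarray(occupied, dtype=float) if occupied else None
    for _ in range(_MAX_TRIES_PER_DOT):
        x, y = spec.region.sample_point(square, rng, inset=inset)
        if occ is None or len(occ) == 0:
            return (x, y)
        dx = occ[:, 0] - x
        dy = occ[:, 1] - y
        if float(np.min(dx * dx + dy * dy)) >= md2:
            return (x, y)
    raise PackingError(_density_message(spec))


def sample_layout(
    spec: StimulusSpec,
    rng: np.random.Generator,
    group_sizes: Optional[tuple[int, int]] = None,
) -> DotField:
    """Scatter a fresh field of dots at time 0.

    Positions are uniform over the allowed region conditional on every
    pairwise center-to-center distance being at least ``min_dist_deg``
    (rejection sampling; a whole-layout restart on failure keeps the
    conditional distribution exchangeable).  Temporal phases are
    initialized uniformly on [0, lifetime) so that replacements are
    desynchronized from the start.
    """
    spec = _maybe_rotate(spec, rng)
    if spec.n_groups == 2:
        if group_sizes is None:
            group_sizes = assign_group_sizes(spec.n_dots, rng)
        groups = [0] * group_sizes[0] + [1] * group_sizes[1]
    else:
        groups = [0] * spec.n_dots
    velocities = make_motion_assignment(spec, rng)

    for _ in range(_MAX_LAYOUT_RESTARTS):
        placed: list[tuple[float, float]] = []
        try:
            for g in groups:
                placed.append(_place_one(spec, spec.square_for_group(g), placed, rng))
        except PackingError:
            continue
        dots = []
        for i, (g, (x, y)) in enumerate(zip(groups, placed)):
            vx, vy = velocities[g]
            dots.append(
                Dot(
                    x=x,
                    y=y,
                    birth_time_ms=0.0,
                    death_time_ms=0.0,  # set by init_phases
                    group_id=g,
                    diameter_deg=spec.diameter_for_group(g),
                    color_label=spec.color_for_group(g),
                    vx=vx,
                    vy=vy,
                    life_id=i,
                )
            )
        fld = DotField(dots=dots, time_ms=0.0, spec=spec, _next_life_id=len(dots))
        return init_phases(fld, rng)
    raise PackingError(_density_message(spec))


def _maybe_rotate(spec: StimulusSpec, rng: np.random.Generator) -> StimulusSpec:
    if not spec.randomize_rotation:
        return spec
    angle = rng.uniform(0.0, 2.0 * math.pi)
    return replace(spec, region=replace(spec.region, rotation_rad=angle))


def init_phases(fld: DotField, rng: np.random.Generator) -> DotField:
    """Draw each dot's first expiry uniformly on [now, now + lifetime).

    The random phase offsets desynchronize replacements; after its first
    (truncated) life every dot lives exactly one full lifetime per life.
    """
    lifetime = fld.spec.lifetime_ms
    dots = [
        replace(d, death_time_ms=fld.time_ms + float(rng.uniform(0.0, lifetime)))
        for d in fld.dots
    ]
    return DotField(dots=dots, time_ms=fld.time_ms, spec=fld.spec,
                    _next_life_id=fld._next_life_id)


_EXPIRY_EPS_MS = 1e-9


def advance(
    fld: DotField,
    dt_ms: float,
    rng: np.random.Generator,
    events: Optional[list] = None,
) -> DotField:
    """Advance the field by one time step.

    Moving dots are displaced by velocity * dt.  Dots whose scheduled
    expiry falls at or before the new time are removed and replaced, at
    the same instant, by a new dot in the same group at a fresh position
    satisfying the minimum-distance constraint against all other alive
    dots, with a fresh full lifetime.  The alive count never changes.

    ``events`` (optional list) collects tuples
    ``(time_ms, life_id, event, x, y, group_id)`` with event in
    {"spawn", "expire"} for replay and analysis.
    """
    if dt_ms <= 0:
        raise ValueError("dt_ms must be > 0")
    spec = fld.spec
    t_new = fld.time_ms + dt_ms
    dt_s = dt_ms / 1000.0
    moved: list[Dot] = []
    expiring: list[int] = []
    for i, d in enumerate(fld.dots):
        if d.vx != 0.0 or d.vy != 0.0:
            d = replace(d, x=d.x + d.vx * dt_s, y=d.y + d.vy * dt_s)
        moved.append(d)
        if d.death_time_ms <= t_new + _EXPIRY_EPS_MS:
            expiring.append(i)

    next_id = fld._next_life_id
    for i in expiring:
        old = moved[i]
        if events is not None:
            events.append((t_new, old.life_id, "expire", old.x, old.y, old.group_id))
        others = [(q.x, q.y) for j, q in enumerate(moved) if j != i]
        x, y = _place_one(spec, spec.square_for_group(old.group_id), others, rng)
        new = Dot(
            x=x,
            y=y,
            birth_time_ms=t_new,
            death_time_ms=t_new + spec.lifetime_ms,
            group_id=old.group_id,
            diameter_deg=old.diameter_deg,
            color_label=old.color_label,
            vx=old.vx,
            vy=old.vy,
            life_id=next_id,
        )
        next_id += 1
        moved[i] = new
        if events is not None:
            events.append((t_new, new.life_id, "spawn", x, y, new.group_id))
    return DotField(dots=moved, time_ms=t_new, spec=spec, _next_life_id=next_id)


def simulate(
    spec: StimulusSpec,
    duration_ms: float,
    rng: np.random.Generator,
    tick_rate_hz: float = DEFAULT_TICK_RATE_HZ,
    on_frame: Optional[Callable[[DotField], None]] = None,
) -> tuple[DotField, list]:
    """Run a full LDD presentation and return (final field, event list).

    Expiries occur at the first tick at or after their scheduled time.
    Initial dots are logged as spawns at t = 0.
    """
    fld = sample_layout(spec, rng)
    events = [(0.0, d.life_id, "spawn", d.x, d.y, d.group_id) for d in fld.dots]
    if on_frame is not None:
        on_frame(fld)
    tick_ms = 1000.0 / tick_rate_hz
    n_ticks = int(round(duration_ms / tick_ms))
    for k in range(1, n_ticks + 1):
        dt = k * tick_ms - fld.time_ms
        fld = advance(fld, dt, rng, events=events)
        if on_frame is not None:
            on_frame(fld)
    return fld, events


def events_to_frame(events: Sequence[tuple]):
    """Event list -> tidy DataFrame (time_ms, life_id, event, x, y, group)."""
    import pandas as pd

    return pd.DataFrame(
        events, columns=["time_ms", "life_id", "event", "x_deg", "y_deg", "group"]
    )


def completed_life_durations(events: Sequence[tuple]) -> np.ndarray:
    """Spawn-to-expiry durations (ms) of full dot lives.

    Only lives born after t = 0 count: the initial scatter's first lives
    are deliberately truncated by the random phase offsets.
    """
    spawn: dict[int, float] = {}
    durations: list[float] = []
    for t, life, ev, _x, _y, _g in events:
        if ev == "spawn":
            spawn[life] = t
        elif ev == "expire" and life in spawn and spawn[life] > 0.0:
            durations.append(t - spawn[life])
    return np.asarray(durations, dtype=float)


def min_distance_at_spawns(
    spec: StimulusSpec,
    duration_ms: float,
    rng: np.random.Generator,
    tick_rate_hz: float = DEFAULT_TICK_RATE_HZ,
) -> tuple[float, int]:
    """Min pairwise center distance over every frame in which a dot spawns.

    Returns ``(min_distance_deg, n_spawn_events)`` over one simulated
    presentation, including the initial scatter.
    """
    state = {"min": math.inf, "n": 0}

    def check(fld: DotField) -> None:
        born_now = any(d.birth_time_ms == fld.time_ms for d in fld.dots)
        if born_now:
            n_new = sum(d.birth_time_ms == fld.time_ms for d in fld.dots)
            state["n"] += n_new
            state["min"] = min(state["min"], fld.min_pairwise_distance())

    simulate(spec, duration_ms, rng, tick_rate_hz=tick_rate_hz, on_frame=check)
    return state["min"], state["n"]


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

_COLOR_RGB = {
    "blue": (60, 110, 235),
    "yellow": (240, 210, 50),
    "white": (255, 255, 255),
}


def render_frame(
    fld: DotField,
    pixels_per_deg: float = 20.0,
    margin_deg: float = 1.0,
) -> np.ndarray:
    """Rasterize a field to an RGB uint8 image (filled discs on black).

    Intended for inspection and video export, not hardware-faithful
    presentation.
    """
    if pixels_per_deg <= 0:
        raise ValueError("pixels_per_deg must be positive")
    region = fld.spec.region
    ext = max(
        (abs(c) + s / 2.0)
        for (cx, cy), s in zip(region.centers, region.sides)
        for c in (cx, cy)
    ) if fld.dots or True else 4.0
    half = ext + margin_deg
    npix = int(math.ceil(2 * half * pixels_per_deg))
    img = np.zeros((npix, npix, 3), dtype=np.uint8)
    for d in fld.dots:
        r_px = d.diameter_deg / 2.0 * pixels_per_deg
        # y-up degrees -> row-down pixels
        cx = (d.x + half) * pixels_per_deg
        cy = (half - d.y) * pixels_per_deg
        rgb = _COLOR_RGB.get(d.color_label, (200, 200, 200))
        lo_r = max(0, int(cy - r_px) - 1)
        hi_r = min(npix, int(cy + r_px) + 2)
        lo_c = max(0, int(cx - r_px) - 1)
        hi_c = min(npix, int(cx + r_px) + 2)
        if lo_r >= hi_r or lo_c >= hi_c:
            continue
        rows = np.arange(lo_r, hi_r)[:, None] + 0.5
        cols = np.arange(lo_c, hi_c)[None, :] + 0.5
        mask = (rows - cy) ** 2 + (cols - cx) ** 2 <= r_px**2
        img[lo_r:hi_r, lo_c:hi_c][mask] = rgb
    return img
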