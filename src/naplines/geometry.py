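"""Resolution-independent two-line stimulus geometry.

Thirteen conditions, each reduced to one scalar parameter whose boundary
value (always 0 here) is the nonaccidental configuration.  A triplet holds
the base stimulus at ``boundary + delta``, the nonaccidental (NAP) variant
at the boundary, and the metric (MP) variant at ``boundary + 2*delta`` --
equidistant from the base on the parameter axis but in opposite directions.

All coordinates are degrees of visual angle, origin at the stimulus
bounding-box center, y increasing upward.  Nothing in this module touches
pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np

__all__ = [
    "Segment",
    "ConditionSpec",
    "Stimulus",
    "Triplet",
    "StimulusConfig",
    "CONDITION_NAMES",
    "CONDITION_CATEGORIES",
    "default_specs",
    "realize",
    "make_triplet",
    "mirror",
    "generate_stimulus_set",
    "center_gap",
    "apply_jitter",
    "stimulus_extent",
    "stimulus_bbox",
]

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Segment:
    """One straight-or-curved line element.

    ``orientation`` is the chord direction in degrees counterclockwise from
    horizontal; ``sagitta`` is the signed perpendicular offset of the arc
    midpoint from the chord midpoint (positive = left of the chord
    direction; 0 = straight line).
    """

    center: tuple[float, float]
    orientation: float
    length: float
    sagitta: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment length must be > 0, got {self.length}")
        if abs(self.sagitta) >= self.length / 2:
            raise ValueError(
                f"|sagitta| {abs(self.sagitta)} must be < length/2 "
                f"{self.length / 2} (shallow-arc regime)"
            )

    @property
    def direction(self) -> np.ndarray:
        a = math.radians(self.orientation)
        return np.array([math.cos(a), math.sin(a)])

    @property
    def normal(self) -> np.ndarray:
        """Unit normal, 90 deg counterclockwise from the chord direction."""
        a = math.radians(self.orientation)
        return np.array([-math.sin(a), math.cos(a)])

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, dtype=float)
        half = 0.5 * self.length * self.direction
        return c - half, c + half

    def polyline(self, n: int = 65) -> np.ndarray:
        """Sample ``n`` points along the element (chord+sagitta arc)."""
        p0, p1 = self.endpoints()
        if self.sagitta == 0.0:
            t = np.linspace(0.0, 1.0, n)[:, None]
            return p0 * (1 - t) + p1 * t
        s = self.sagitta
        half = self.length / 2
        radius = (half * half + s * s) / (2 * abs(s))
        c = np.asarray(self.center, dtype=float)
        # circle center sits opposite the bulge along the chord normal
        center = c + (s - math.copysign(radius, s)) * self.normal
        a0 = math.atan2(*(p0 - center)[::-1])
        a1 = math.atan2(*(p1 - center)[::-1])
        # sweep the short way through the arc midpoint
        mid = c + s * self.normal
        am = math.atan2(*(mid - center)[::-1])
        # unwrap so a0 -> am -> a1 is monotone
        am = a0 + _wrap_angle(am - a0)
        a1 = am + _wrap_angle(a1 - am)
        ang = np.linspace(a0, a1, n)
        return center + radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)

    def canonical(self) -> "Segment":
        """Equivalent segment with orientation reduced to [0, 180).

        Flipping the chord direction by 180 deg negates the sagitta sign,
        so (theta, s) and (theta+180, -s) describe the same element.
        """
        theta = self.orientation % 360.0
        s = self.sagitta
        if theta >= 180.0:
            theta -= 180.0
            s = -s
        if theta == 0.0:
            theta = 0.0  # normalize -0.0
        return Segment(
            (float(self.center[0]), float(self.center[1])), theta, self.length, s
        )


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    return (a + math.pi) % (2 * math.pi) - math.pi


CONDITION_NAMES = (
    "alignment",
    "collinearity_between",
    "generic_to_L",
    "generic_to_T",
    "generic_to_X",
    "T_to_L",
    "X_to_T",
    "cotermination",
    "expansion_constant",
    "collinearity_within",
    "curvature_edges",
    "curvature_axis",
    "curvature_control",
)

CONDITION_CATEGORIES = {
    "alignment": "between_objects",
    "collinearity_between": "between_objects",
    "generic_to_L": "between_objects",
    "generic_to_T": "between_objects",
    "generic_to_X": "between_objects",
    "T_to_L": "between_objects",
    "X_to_T": "between_objects",
    "cotermination": "within_object",
    "expansion_constant": "within_object",
    "collinearity_within": "within_object",
    "curvature_edges": "within_object",
    "curvature_axis": "within_object",
    "curvature_control": "control",
}

_PARAM_NAMES = {
    "alignment": "lateral_offset_deg",
    "collinearity_between": "angular_deviation_deg",
    "generic_to_L": "slide_from_contact_deg",
    "generic_to_T": "slide_from_contact_deg",
    "generic_to_X": "slide_from_crossing_deg",
    "T_to_L": "contact_from_bar_end_deg",
    "X_to_T": "overhang_past_crossing_deg",
    "cotermination": "endpoint_gap_deg",
    "expansion_constant": "convergence_angle_deg",
    "collinearity_within": "bend_angle_deg",
    "curvature_edges": "sagitta_deg",
    "curvature_axis": "sagitta_deg",
    "curvature_control": "sagitta_deg",
}

# angle parameters in degrees of rotation, everything else in degrees of
# visual angle.  generic_to_X needs a slide larger than the crossing
# segment's half-length (0.6) so the generic variants are contact-free.
DEFAULT_DELTAS = {
    "alignment": 0.35,
    "collinearity_between": 10.0,
    "generic_to_L": 0.35,
    "generic_to_T": 0.35,
    "generic_to_X": 0.95,
    "T_to_L": 0.35,
    "X_to_T": 0.35,
    "cotermination": 0.35,
    "expansion_constant": 10.0,
    "collinearity_within": 10.0,
    "curvature_edges": 0.3,
    "curvature_axis": 0.3,
    "curvature_control": 0.3,
}


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    category: str
    param_name: str
    boundary_value: float
    delta: float
    gap: float
    extent: float = 3.0

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise ValueError(f"unknown condition name: {self.name!r}")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


@dataclass(frozen=True)
class Stimulus:
    stimulus_id: str
    condition: str
    variant: str  # base | metric | nonaccidental
    exemplar: int
    segments: tuple[Segment, ...]
    param_value: float
    mirror: str = "none"  # none | left_right | up_down | both
    pose_deg: float = 0.0


@dataclass(frozen=True)
class Triplet:
    triplet_id: str
    condition: str
    exemplar: int
    base: Stimulus
    metric: Stimulus
    nonaccidental: Stimulus

    @property
    def stimuli(self) -> tuple[Stimulus, Stimulus, Stimulus]:
        return (self.base, self.metric, self.nonaccidental)


@dataclass(frozen=True)
class StimulusConfig:
    """Generator configuration (the study conditions, not a per-run dial)."""

    gap: float = 1.5
    extent: float = 3.0
    extent_tol: float = 0.1
    deltas: dict = field(default_factory=dict)
    jitter_pos: float = 0.25
    jitter_rot: float = 5.0
    n_exemplars: int = 6
    validate_extent: bool = True

    def delta_for(self, name: str) -> float:
        return float(self.deltas.get(name, DEFAULT_DELTAS[name]))


#: larger line gap used in the paper's blocked-presentation replication
REPLICATION_CONFIG = StimulusConfig(gap=2.25, validate_extent=False)


def default_specs(config: StimulusConfig | None = None) -> dict[str, ConditionSpec]:
    config = config or StimulusConfig()
    return {
        name: ConditionSpec(
            name=name,
            category=CONDITION_CATEGORIES[name],
            param_name=_PARAM_NAMES[name],
            boundary_value=0.0,
            delta=config.delta_for(name),
            gap=config.gap,
            extent=config.extent,
        )
        for name in CONDITION_NAMES
    }


# ---------------------------------------------------------------------------
# per-condition builders
#
# Each builder returns the canonical-pose segments at parameter value p.
# One closed-form calibration constant per condition pins the BASE stimulus
# (p = delta) center gap to spec.gap exactly.


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _circle_line_reach(anchor_dist: float, cos_b: float, g: float) -> float:
    """Distance m along a ray from a point at ``anchor_dist`` from the
    origin (ray at angle with cosine ``cos_b`` to the outward direction)
    at which the ray meets the circle of radius ``g`` about the origin."""
    disc = anchor_dist * anchor_dist * (cos_b * cos_b - 1.0) + g * g
    _require(disc >= 0, "gap unreachable for this stem angle")
    return anchor_dist * cos_b + math.sqrt(disc)


def _build_alignment(p: float, spec: ConditionSpec) -> tuple[Segment, ...]:
    # two vertical, side-by-side object edges; p = vertical misalignment of
    # the shorter edge.  Side-by-side placement keeps the strokes disjoint
    # at every parameter value (the offset never makes ink overlap).
    g, E, d = spec.gap, spec.extent, spec.delta
    _require(abs(p) < g, f"|lateral_offset| must be < gap {g}")
    x = math.sqrt(g * g - d * d)
    L2 = E - 4.0 * d  # short edge stays inside the long edge's span
    _require(abs(p) + L2 / 2 <= E / 2, "offset pushes the short edge outside the extent")
    return (
        Segment((-x / 2, 0.0), 90.0, E),
        Segment((x / 2, p), 90.0, L2),
    )


def _build_collinearity_between(p: float, spec: ConditionSpec) -> tuple[Segment, ...]:
    # near ends separated by a small visible margin so the two objects
    # never fuse into one stroke at the collinear boundary
    g, E = spec.gap, spec.extent
    _require(abs(p) < 90.0, "|angular_deviation| must be < 90 deg")
    margin = min(0.02 * E, max(0.0, g - 0.2 * E))
    total = 2.0 * (E - g - margin)
    _require(total > 0, "gap too large for the configured extent")
    L1, L2 = 0.575 * total, 0.425 * total
    return (
        Segment((-g / 2, 0.0), 0.0, L1),
        Segment((g / 2, 0.0), p, L2),
    )


def _build_generic_to_L(p: float, spec: ConditionSpec) -> tuple[Segment, ...]:
    g, E, d = spec.gap, spec.extent, spec.delta
    _require(p >= 0, "slide_from_contact must be >= 0")
    r = E / 2
    beta = 70.0
    b = math.radians(beta)
    m = _circle_line_reach(r, math.cos(b), g)
    _require(m > d, "gap too small for the configured slide delta")
    L_b = 2.0 * (m - d)
    V = np.array([-r, 0.0])
    u = np.array([math.cos(b), math.sin(b)])
    c = V + (p + L_b / 2) * u
    return (
        Segment((0.0, 0.0), 0.0, 2 * r),
        Segment((c[0], c[1]), beta, L_b),
    )


def _build_generic_to_T(p: float, spec: ConditionSpec) -> tuple[Segment, ...]:
    g, E, d = spec.gap, spec.extent, spec.delta
    _require(p >= 0, "slide_from_contact must be >= 0")
    r = E / 2
    beta = 80.0
    b = math.radians(beta)
    v = -r / 3
    m = _circle_line_reach(abs(v), math.cos(b), g)
    _require(m > d, "gap too small for the configured slide delta")
    L_b = 2.0 * (m - d)
    V = np.array([v, 0.0])
    u = np.array([math.cos(b), math.sin(b)])
    c = V + (p + L_b / 2) * u
    return (
        Segment((0.0, 0.0), 0.0, 2 * r),
        Segment((c[0], c[1]), beta, L_b),
    )


def _build_generic_to_X(p: float, spec: ConditionSpec) -> tuple[Segment, ...]:
    g, E, d = spec.gap, spec.extent, spec.delta
    r = E / 2
    L_b = 0.8 * r  # crossing segment length (1.2 deg at the default extent)
    _require(
        p == 0.0 or p > L_b / 2,
        f"slide_from_crossing must be 0 (crossing) or > {L_b / 2} "
        "(contact-free); intermediate values leave a partial crossing",
    )
    beta = 80.0
    b = math.radians(beta)
    disc = g * g - d * d * math.sin(b) ** 2
    v = -d * math.cos(b) + math.sqrt(disc) if disc >= 0 else float("inf")
    if not (abs(v) <= 0.95 * r):
        # replication-style gaps: pin the crossing near the bar end and
        # solve the stem elevation instead
        v = 0.9 * r
        cos_b = (g * g - v * v - d * d) / (2 * v * d)
        _require(abs(cos_b) <= 1.0, "gap unreachable for generic_to_X")
        beta = math.degrees(math.acos(cos_b))
        b = math.radians(beta)
    u = np.array([math.cos(b), math.sin(b)])
    c = np.array([v, 0.0]) + p * u
    return (
        Segment((0.0, 0.0), 0.0, 2 * r),
        Segment((c[0], c[1]), beta, L_b),
    )


def _build_T_to_L(p: float, spec: ConditionSpec) -> tuple[Segment, ...]:
    g, E, d = spec.gap, spec.extent, spec.delta
    r = E / 2
    _require(0.0 <= p <= 2 * r, f"contact point must lie on the bar [0, {2 * r}]")
    beta = 80.0
    b = math.radians(beta)
    anchor = r - d  # |contact - bar center| at base
    h = _circle_line_reach(anchor, math.cos(b), g)
    contact = np.array([-r + p, 0.0])
    u = np.array([math.cos(b), math.sin(b)])
    c = contact + h * u
    return (
        Segment((0.0, 0.0), 0.0, 2 * r),
        Segment((c[0], c[1]), beta, 2 * h),
    )


def _build_X_to_T(p: float, spec: ConditionSpec) -> tuple[Segment, ...]:
    g, E, d = spec.gap, spec.extent, spec.delta
    r = E / 2
    L_b = 2.2 * (E / 3.0)
    _require(0.0 <= p < L_b / 2, f"overhang must be in [0, {L_b / 2})")
    beta = 85.0
    m = L_b / 2 - d  # center offset from the crossing at base
    disc = g * g - m * m * math.sin(math.radians(beta)) ** 2
    v = -m * math.cos(math.radians(beta)) + math.sqrt(disc) if disc >= 0 else float("inf")
    if not (abs(v) <= 0.95 * r):
        # adapted stem for large (replication) gaps
        v = 0.95 * r
        m = max(m, g - v + 0.3)
        L_b = 2.0 * (m + d)
        cos_b = (g * g - v * v - m * m) / (2 * v * m)
        _require(abs(cos_b) <= 1.0, "gap unreachable for X_to_T")
        beta = math.degrees(math.acos(cos_b))
    b = math.radians(beta)
    u = np.array([math.cos(b), math.sin(b)])
    V = np.array([v, 0.0])
    c = V + (L_b / 2 - p) * u
    return (
        Segment((0.0, 0.0), 0.0, 2 * r),
        Segment((c[0], c[1]), beta, L_b),
    )


def _build_cotermination(p: float, spec: ConditionSpec) -> tuple[Segment, ...]:
    g, d = spec.gap, spec.delta
    _require(p >= 0, "endpoint_gap must be >= 0")
    a1, a2 = -20.0, 29.0  # unequal arm elevations break mirror symmetry
    d1 = np.array([math.cos(math.radians(a1)), math.sin(math.radians(a1))])
    d2 = np.array([math.cos(math.radians(a2)), math.sin(math.radians(a2))])
    q = float(np.linalg.norm(d1 - d2))
    L = 2.0 * g / q - d
    _require(L > 0, "gap too small for the configured delta")
    m = p / 2 + L / 2
    c1, c2 = m * d1, m * d2
    return (
        Segment((c1[0], c1[1]), a1, L),
        Segment((c2[0], c2[1]), a2, L),
    )


def _build_expansion_constant(p: float, spec: ConditionSpec) -> tuple[Segment, ...]:
    g, E, d = spec.gap, spec.extent, spec.delta
    _require(abs(p) < 45.0, "|convergence_angle| must be < 45 deg")
    H = g + (E / 2) * math.tan(math.radians(d))
    t = math.radians(p)
    top_center = (0.0, H - (E / 2) * math.tan(t))
    return (
        Segment((0.0, 0.0), 0.0, E),
        Segment(top_center, -p, E / math.cos(t)),
    )


def _build_collinearity_within(p: float, spec: ConditionSpec) -> tuple[Segment, ...]:
    g, d = spec.gap, spec.delta
    _require(abs(p) < 90.0, "|bend_angle| must be < 90 deg")
    L = g / math.cos(math.radians(d) / 2)
    u = np.array([math.cos(math.radians(p)), math.sin(math.radians(p))])
    c2 = (L / 2) * u
    return (
        Segment((-L / 2, 0.0), 180.0, L),
        Segment((c2[0], c2[1]), p, L),
    )


def _curved_edges(p: float, spec: ConditionSpec, same_sign: bool) -> tuple[Segment, ...]:
    g, E = spec.gap, spec.extent
    _require(abs(p) < 0.4 * E, "|sagitta| too large for shallow arcs")
    x_off = 0.1 * E
    g_y = math.sqrt(g * g - x_off * x_off)
    s_bot = p if same_sign else -p
    return (
        Segment((0.0, g_y / 2), 0.0, E, p),
        Segment((x_off, -g_y / 2), 0.0, 0.8 * E, s_bot),
    )


def _build_curvature_edges(p: float, spec: ConditionSpec) -> tuple[Segment, ...]:
    return _curved_edges(p, spec, same_sign=False)


def _build_curvature_axis(p: float, spec: ConditionSpec) -> tuple[Segment, ...]:
    return _curved_edges(p, spec, same_sign=True)


def _build_curvature_control(p: float, spec: ConditionSpec) -> tuple[Segment, ...]:
    E = spec.extent
    _require(abs(p) < 0.4 * E, "|sagitta| too large for shallow arcs")
    return (Segment((0.0, 0.0), 0.0, E, p),)


_BUILDERS: dict[str, Callable[[float, ConditionSpec], tuple[Segment, ...]]] = {
    "alignment": _build_alignment,
    "collinearity_between": _build_collinearity_between,
    "generic_to_L": _build_generic_to_L,
    "generic_to_T": _build_generic_to_T,
    "generic_to_X": _build_generic_to_X,
    "T_to_L": _build_T_to_L,
    "X_to_T": _build_X_to_T,
    "cotermination": _build_cotermination,
    "expansion_constant": _build_expansion_constant,
    "collinearity_within": _build_collinearity_within,
    "curvature_edges": _build_curvature_edges,
    "curvature_axis": _build_curvature_axis,
    "curvature_control": _build_curvature_control,
}


# ---------------------------------------------------------------------------
# rigid transforms on whole stimuli


def stimulus_bbox(segments: Iterable[Segment]) -> tuple[float, float, float, float]:
    pts = np.vstack([s.polyline(129) for s in segments])
    return (
        float(pts[:, 0].min()),
        float(pts[:, 0].max()),
        float(pts[:, 1].min()),
        float(pts[:, 1].max()),
    )


def stimulus_extent(s: Stimulus | Iterable[Segment]) -> float:
    """Bounding extent: the larger side of the axis-aligned bounding box."""
    segs = s.segments if isinstance(s, Stimulus) else tuple(s)
    x0, x1, y0, y1 = stimulus_bbox(segs)
    return max(x1 - x0, y1 - y0)


def _recenter(segments: tuple[Segment, ...]) -> tuple[Segment, ...]:
    x0, x1, y0, y1 = stimulus_bbox(segments)
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    return tuple(
        replace(s, center=(s.center[0] - cx, s.center[1] - cy)) for s in segments
    )


def _rotate_segments(
    segments: tuple[Segment, ...], angle_deg: float, pivot: tuple[float, float]
) -> tuple[Segment, ...]:
    a = math.radians(angle_deg)
    R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    px = np.asarray(pivot)
    out = []
    for s in segments:
        c = px + R @ (np.asarray(s.center) - px)
        out.append(
            replace(s, center=(float(c[0]), float(c[1])), orientation=s.orientation + angle_deg)
        )
    return tuple(out)


def _mirror_segments(segments: tuple[Segment, ...], axis: str) -> tuple[Segment, ...]:
    x0, x1, y0, y1 = stimulus_bbox(segments)
    out = []
    for s in segments:
        cx, cy = s.center
        if axis == "left_right":
            c = ((x0 + x1) - cx, cy)
            theta = 180.0 - s.orientation
        elif axis == "up_down":
            c = (cx, (y0 + y1) - cy)
            theta = -s.orientation
        else:
            raise ValueError(f"unknown mirror axis: {axis!r}")
        out.append(replace(s, center=c, orientation=theta % 360.0, sagitta=-s.sagitta))
    return tuple(out)


_MIRROR_COMPOSE = {
    ("none", "left_right"): "left_right",
    ("none", "up_down"): "up_down",
    ("left_right", "left_right"): "none",
    ("left_right", "up_down"): "both",
    ("up_down", "up_down"): "none",
    ("up_down", "left_right"): "both",
    ("both", "left_right"): "up_down",
    ("both", "up_down"): "left_right",
}


def mirror(s: Stimulus, axis: str) -> Stimulus:
    """Reflect a stimulus about its bounding-box midline.

    Condition, variant and exemplar labels are preserved; only geometry and
    the ``mirror`` bookkeeping field change.  Applying the same axis twice
    returns the original geometry.
    """
    segs = _mirror_segments(s.segments, axis)
    return replace(s, segments=segs, mirror=_MIRROR_COMPOSE[(s.mirror, axis)])


# ---------------------------------------------------------------------------
# exemplar plan: (pose rotation, mirror) pairs, deduplicated per condition

_POSE_CANDIDATES: tuple[tuple[float, str], ...] = tuple(
    (pose, m)
    for pose in (0.0, 90.0, 10.0, 100.0, -10.0, 80.0)
    for m in ("none", "left_right", "up_down")
)


def _canonical_key(segments: Iterable[Segment], ndigits: int = 6) -> tuple:
    rows = []
    for s in segments:
        c = s.canonical()
        rows.append(
            (
                round(c.center[0], ndigits),
                round(c.center[1], ndigits),
                round(c.orientation % 180.0, ndigits),
                round(c.length, ndigits),
                round(c.sagitta, ndigits),
            )
        )
    return tuple(sorted(rows))


_OFFSET_CACHE: dict[ConditionSpec, tuple[float, float]] = {}


def _realize_raw(spec: ConditionSpec, param_value: float) -> tuple[Segment, ...]:
    """Construction-frame geometry shifted into the triplet's shared frame.

    All variants of a condition are placed relative to the *base*
    stimulus's bounding-box center, so the three variants of a triplet
    differ only through the manipulated parameter, never through a
    bounding-box recentering translation.  The base stimulus is therefore
    exactly origin-centered; its variants very nearly so.
    """
    builder = _BUILDERS.get(spec.name)
    if builder is None:  # pragma: no cover - ConditionSpec already validates
        raise ValueError(f"unknown condition name: {spec.name!r}")
    off = _OFFSET_CACHE.get(spec)
    if off is None:
        x0, x1, y0, y1 = stimulus_bbox(builder(spec.boundary_value + spec.delta, spec))
        off = ((x0 + x1) / 2, (y0 + y1) / 2)
        _OFFSET_CACHE[spec] = off
    return tuple(
        replace(s, center=(s.center[0] - off[0], s.center[1] - off[1]))
        for s in builder(float(param_value), spec)
    )


def _mirror_about_axes(segments: tuple[Segment, ...], axis: str) -> tuple[Segment, ...]:
    """Reflect about the shared frame's coordinate axes (not a per-stimulus
    bounding box), so a whole triplet mirrors consistently."""
    out = []
    for s in segments:
        cx, cy = s.center
        if axis == "left_right":
            c, theta = (-cx, cy), 180.0 - s.orientation
        else:
            c, theta = (cx, -cy), -s.orientation
        out.append(replace(s, center=c, orientation=theta % 360.0, sagitta=-s.sagitta))
    return tuple(out)


def _pose_segments(
    segments: tuple[Segment, ...], pose: float, mirror_axis: str
) -> tuple[Segment, ...]:
    if pose != 0.0:
        segments = _rotate_segments(segments, pose, (0.0, 0.0))
    if mirror_axis != "none":
        segments = _mirror_about_axes(segments, mirror_axis)
    return segments


_PLAN_CACHE: dict[tuple, tuple[tuple[float, str], ...]] = {}


def _exemplar_plan(spec: ConditionSpec, n_exemplars: int = 6) -> tuple[tuple[float, str], ...]:
    """Ordered (pose, mirror) pairs giving geometrically distinct triplets."""
    key = (spec, n_exemplars)
    if key in _PLAN_CACHE:
        return _PLAN_CACHE[key]
    params = (spec.boundary_value + spec.delta, spec.boundary_value,
              spec.boundary_value + 2 * spec.delta)
    raw = [_realize_raw(spec, p) for p in params]
    plan: list[tuple[float, str]] = []
    seen: set[tuple] = set()
    for pose, m in _POSE_CANDIDATES:
        k = tuple(_canonical_key(_pose_segments(segs, pose, m)) for segs in raw)
        if k in seen:
            continue
        seen.add(k)
        plan.append((pose, m))
        if len(plan) == n_exemplars:
            break
    if len(plan) < n_exemplars:
        raise ValueError(
            f"condition {spec.name!r}: only {len(plan)} distinct exemplars "
            f"available; mirror-degenerate combinations exhausted the pose list"
        )
    out = tuple(plan)
    _PLAN_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# public operations


def realize(spec: ConditionSpec, param_value: float, exemplar: int = 0) -> Stimulus:
    """Deterministically realize one stimulus of a condition.

    ``exemplar`` selects the (pose, mirror) combination from the condition's
    exemplar plan; exemplar 0 is always the canonical upright pose.
    """
    plan = _exemplar_plan(spec)
    if not 0 <= exemplar < len(plan):
        raise ValueError(f"exemplar must be in [0, {len(plan)}), got {exemplar}")
    pose, mirror_axis = plan[exemplar]
    segments = _pose_segments(_realize_raw(spec, param_value), pose, mirror_axis)
    if param_value == spec.boundary_value:
        variant = "nonaccidental"
    elif param_value == spec.boundary_value + spec.delta:
        variant = "base"
    elif param_value == spec.boundary_value + 2 * spec.delta:
        variant = "metric"
    else:
        variant = "base"
    return Stimulus(
        stimulus_id=f"{spec.name}-e{exemplar}-p{param_value:g}",
        condition=spec.name,
        variant=variant,
        exemplar=exemplar,
        segments=segments,
        param_value=float(param_value),
        mirror=mirror_axis,
        pose_deg=pose,
    )


def make_triplet(spec: ConditionSpec, exemplar: int = 0) -> Triplet:
    """Base / metric / nonaccidental triplet, equidistant on the parameter axis."""
    b = spec.boundary_value
    d = spec.delta
    names = {"base": b + d, "nonaccidental": b, "metric": b + 2 * d}
    stims = {}
    tid = f"{spec.name}-e{exemplar}"
    for variant, p in names.items():
        s = realize(spec, p, exemplar)
        stims[variant] = replace(
            s, stimulus_id=f"{tid}-{variant}", variant=variant
        )
    return Triplet(
        triplet_id=tid,
        condition=spec.name,
        exemplar=exemplar,
        base=stims["base"],
        metric=stims["metric"],
        nonaccidental=stims["nonaccidental"],
    )


def generate_stimulus_set(config: StimulusConfig | None = None) -> list[Triplet]:
    """All 13 conditions x 6 exemplars = 78 triplets.

    Raises if a condition cannot supply 6 geometrically distinct exemplars,
    or (default config) if any stimulus breaks the bounding-extent contract.
    """
    config = config or StimulusConfig()
    specs = default_specs(config)
    triplets: list[Triplet] = []
    for name in CONDITION_NAMES:
        spec = specs[name]
        for e in range(config.n_exemplars):
            t = make_triplet(spec, e)
            if config.validate_extent:
                for stim in t.stimuli:
                    ext = stimulus_extent(stim)
                    if abs(ext - config.extent) > config.extent_tol:
                        raise ValueError(
                            f"{stim.stimulus_id}: extent {ext:.3f} deviates "
                            f"from {config.extent} by more than {config.extent_tol}"
                        )
            triplets.append(t)
    return triplets


def center_gap(s: Stimulus) -> float:
    """Euclidean distance between the two segment centers, in degrees."""
    if len(s.segments) != 2:
        raise ValueError(
            f"center_gap requires a two-segment stimulus; "
            f"{s.stimulus_id!r} has {len(s.segments)}"
        )
    a, b = s.segments
    return float(math.dist(a.center, b.center))


def apply_jitter(
    s: Stimulus,
    rng: np.random.Generator,
    pos_bound: float = 0.25,
    rot_bound: float = 5.0,
    return_params: bool = False,
):
    """Whole-stimulus random translation (each coordinate within
    +-pos_bound deg) and rotation (within +-rot_bound deg about the
    stimulus center).  Deterministic under a fixed generator state.

    With ``return_params`` the drawn (dx, dy) offset and rotation are
    returned alongside the jittered stimulus.
    """
    dx, dy = rng.uniform(-pos_bound, pos_bound, size=2)
    rot = float(rng.uniform(-rot_bound, rot_bound))
    segs = _rotate_segments(s.segments, rot, (0.0, 0.0))
    segs = tuple(
        replace(g, center=(g.center[0] + dx, g.center[1] + dy)) for g in segs
    )
    out = replace(s, segments=segs)
    if return_params:
        return out, (float(dx), float(dy)), rot
    return out
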