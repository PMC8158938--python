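"""Parametric 2D wall-texture cross sections and their grid rasterization.

Six textures are modelled: a flat wall, a circular convex wall, a wall
with an aperture, a concave parabolic wall, a crenelated (square-wave)
wall and a staircase.  Each is described by a :class:`TextureSpec` in a
2D plane (horizontal for all textures, vertical for the staircase; the
solver is orientation-agnostic, the plane is metadata only) and
rasterized to a boolean occupancy grid for the acoustic solver.

Coordinate convention: the source sits at the origin, the wall occupies
the ``+x`` half plane, and cell ``(i, j)`` has its center at
``origin + (i + 0.5, j + 0.5) * spacing``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

TEXTURE_KINDS = (
    "flat",
    "circular_convex",
    "aperture",
    "parabolic_concave",
    "crenelated",
    "staircase",
)

#: Distances (m) used in the two study conditions (source to nearest wall point).
STUDY_DISTANCES = (0.81, 5.03)

# Default texture dimensions, overridable per spec.  The drawings the
# scenes are based on are not machine readable, so these are declared
# plausible architectural dimensions rather than extracted values.
_DEFAULTS: dict[str, dict[str, float]] = {
    "flat": {},
    "circular_convex": {"radius": 1.0},
    "aperture": {"aperture_width": 0.3},
    "parabolic_concave": {"focal_length": None},  # None -> focus at the source
    "crenelated": {"period": 0.3, "depth": 0.15},
    "staircase": {"n_steps": 6, "rise": 0.175, "run": 0.28},
}


@dataclass(frozen=True)
class TextureSpec:
    """Full parameterization of one textured-wall scene.

    ``wall_distance`` is measured from the source to the nearest point of
    the wall surface.  ``params`` holds kind-specific dimensions (circle
    radius, aperture width, parabola focal length, crenel period/depth,
    staircase rise/run/count), all in meters except counts.
    """

    kind: str
    wall_distance: float
    lateral_extent: float = 2.0
    thickness: float = 0.3
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TEXTURE_KINDS:
            raise ValueError(f"unknown texture kind {self.kind!r}; expected one of {TEXTURE_KINDS}")
        if self.wall_distance <= 0:
            raise ValueError("wall_distance must be positive")
        if self.lateral_extent <= 0 or self.thickness <= 0:
            raise ValueError("lateral_extent and thickness must be positive")
        for key, value in self.params.items():
            if key == "focal_length" and value is None:
                continue
            if not np.isscalar(value) or value <= 0:
                raise ValueError(f"texture parameter {key!r} must be a positive scalar, got {value!r}")

    @property
    def orientation(self) -> str:
        """Simulation plane: vertical section for the staircase, else horizontal."""
        return "vertical" if self.kind == "staircase" else "horizontal"

    def param(self, name: str) -> Any:
        return self.params[name]

    def to_dict(self) -> dict[str, Any]:
        return {
            "kind": self.kind,
            "wall_distance": self.wall_distance,
            "lateral_extent": self.lateral_extent,
            "thickness": self.thickness,
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TextureSpec":
        return cls(
            kind=d["kind"],
            wall_distance=float(d["wall_distance"]),
            lateral_extent=float(d.get("lateral_extent", 2.0)),
            thickness=float(d.get("thickness", 0.3)),
            params=dict(d.get("params", {})),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict()) if path.suffix in {".yml", ".yaml"} else json.dumps(self.to_dict(), indent=2)
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "TextureSpec":
        path = Path(path)
        raw = path.read_text()
        data = yaml.safe_load(raw) if path.suffix in {".yml", ".yaml"} else json.loads(raw)
        return cls.from_dict(data)


def make_texture(kind: str, distance: float, overrides: dict[str, Any] | None = None) -> TextureSpec:
    """Build a :class:`TextureSpec` with documented defaults.

    Parameters
    ----------
    kind : str
        One of ``flat``, ``circular_convex``, ``aperture``,
        ``parabolic_concave``, ``crenelated``, ``staircase``.
    distance : float
        Source-to-nearest-wall-point distance in meters (the study uses
        0.81 m and 5.03 m).
    overrides : dict, optional
        Any of ``lateral_extent``, ``thickness`` or a kind-specific
        dimension; unknown keys raise.
    """
    if kind not in TEXTURE_KINDS:
        raise ValueError(f"unknown texture kind {kind!r}; expected one of {TEXTURE_KINDS}")
    overrides = dict(overrides or {})
    lateral = float(overrides.pop("lateral_extent", 2.0))
    thickness = float(overrides.pop("thickness", 0.3))
    params = dict(_DEFAULTS[kind])
    for key, value in overrides.items():
        if key not in params:
            raise ValueError(f"unknown parameter {key!r} for texture {kind!r}; valid: {sorted(params)}")
        params[key] = value
    if kind == "parabolic_concave" and params["focal_length"] is None:
        params["focal_length"] = float(distance)  # focus at the source
    return TextureSpec(kind=kind, wall_distance=float(distance), lateral_extent=lateral, thickness=thickness, params=params)


@dataclass
class SceneGrid:
    """Rasterized scene: boolean solid occupancy plus source/receiver.

    ``origin`` is the position (m) of the lower-left corner of cell
    ``(0, 0)``; the cell center is half a spacing further.  ``solid``
    is indexed ``[ix, iy]``.
    """

    spacing: float
    solid: np.ndarray
    source_center: tuple[float, float]
    receiver_center: tuple[float, float]
    origin: tuple[float, float]
    spec: TextureSpec | None = None

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.solid = np.asarray(self.solid, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.solid.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.solid.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.spacing
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing
        return x, y

    def index_of(self, point: tuple[float, float]) -> tuple[int, int]:
        i = int(np.floor((point[0] - self.origin[0]) / self.spacing))
        j = int(np.floor((point[1] - self.origin[1]) / self.spacing))
        return i, j

    def without_solids(self) -> "SceneGrid":
        """Free-field copy of the scene (same domain, no wall)."""
        return SceneGrid(
            spacing=self.spacing,
            solid=np.zeros_like(self.solid),
            source_center=self.source_center,
            receiver_center=self.receiver_center,
            origin=self.origin,
            spec=self.spec,
        )

    def with_swapped_endpoints(self) -> "SceneGrid":
        return replace(self, source_center=self.receiver_center, receiver_center=self.source_center)

    def min_solid_distance(self, point: tuple[float, float] | None = None) -> float:
        """Distance from ``point`` (default: source) to the nearest solid cell center."""
        if not self.solid.any():
            return np.inf
        point = point or self.source_center
        x, y = self.cell_centers()
        ii, jj = np.nonzero(self.solid)
        d = np.hypot(x[ii] - point[0], y[jj] - point[1])
        return float(d.min())

    def export_mask(self, path: str | Path) -> None:
        """Write the occupancy mask as a plain-text PGM image (solid = black)."""
        mask = self.solid.T[::-1]  # image rows top-down, y up
        lines = [f"P2\n{mask.shape[1]} {mask.shape[0]}\n255"]
        for row in mask:
            lines.append(" ".join("0" if v else "255" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def _front_profile(spec: TextureSpec, y: np.ndarray) -> np.ndarray:
    """x-coordinate of the wall front face as a function of lateral coordinate y.

    Returns +inf outside the wall's lateral footprint.
    """
    d = spec.wall_distance
    half = spec.lateral_extent / 2.0
    x_front = np.full_like(y, np.inf, dtype=float)
    inside = np.abs(y) <= half
    if spec.kind == "flat":
        x_front[inside] = d
    elif spec.kind == "aperture":
        w = spec.param("aperture_width")
        x_front[inside & (np.abs(y) >= w / 2.0)] = d
    elif spec.kind == "parabolic_concave":
        f = spec.param("focal_length")
        x_front[inside] = d + y[inside] ** 2 / (4.0 * f)
    elif spec.kind == "crenelated":
        period = spec.param("period")
        depth = spec.param("depth")
        # ridge (near face) centered on the axis; cosine form keeps the
        # mask exactly mirror-symmetric at the ridge/groove boundaries
        ridge = np.cos(2.0 * np.pi * np.abs(y) / period) >= 0.0
        x_front[inside] = np.where(ridge[inside], d, d + depth)
    elif spec.kind == "staircase":
        n = int(spec.param("n_steps"))
        rise = spec.param("rise")
        run = spec.param("run")
        # bottom step face centered on the axis so the nearest point is at d
        k = np.floor((y + rise / 2.0) / rise)
        footprint = (k >= 0) & (k < n) & inside
        x_front[footprint] = d + k[footprint] * run
    else:
        raise AssertionError(spec.kind)
    return x_front


def _back_limit(spec: TextureSpec) -> float:
    """Rear x-coordinate of the solid region."""
    d, t = spec.wall_distance, spec.thickness
    if spec.kind == "flat" or spec.kind == "aperture":
        return d + t
    if spec.kind == "circular_convex":
        return d + 2.0 * spec.param("radius")
    if spec.kind == "parabolic_concave":
        half = spec.lateral_extent / 2.0
        return d + half**2 / (4.0 * spec.param("focal_length")) + t
    if spec.kind == "crenelated":
        return d + spec.param("depth") + t
    if spec.kind == "staircase":
        return d + int(spec.param("n_steps")) * spec.param("run") + t
    raise AssertionError(spec.kind)


def rasterize(
    spec: TextureSpec,
    spacing: float,
    margin: float = 0.4,
    receiver_offset: float = 0.035,
    max_extent: float | None = None,
) -> SceneGrid:
    """Rasterize a texture spec onto a solid-cell grid.

    The domain spans ``[-margin, back-of-wall]`` along x and the wall's
    lateral footprint plus a margin along y; the source is at the origin
    and the receiver ``receiver_offset`` meters above it (the study
    places the receiver a few cm above the transmitter).

    Parameters
    ----------
    spacing : float
        Cell size in meters (study value 1.3 mm; coarser for tests).
    margin : float
        Fluid margin (m) behind the source and beyond the wall edges.
        Must be large enough that domain-edge reflections fall outside
        the analysis window.
    max_extent : float, optional
        If given, raise when the required domain exceeds this size in
        either direction (guards against a wall that exits the domain).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if margin <= 0:
        raise ValueError("margin must be positive")

    x_lo = -margin
    x_hi = _back_limit(spec) + spacing
    half_span = spec.lateral_extent / 2.0
    if spec.kind == "staircase":
        n, rise = int(spec.param("n_steps")), spec.param("rise")
        half_span = max(half_span, n * rise)
    y_hi = half_span + margin
    y_lo = -y_hi
    if max_extent is not None and (x_hi - x_lo > max_extent or y_hi - y_lo > max_extent):
        raise ValueError(
            f"scene requires a {x_hi - x_lo:.2f} x {y_hi - y_lo:.2f} m domain, "
            f"exceeding max_extent={max_extent} m (wall exits the domain)"
        )

    nx = int(np.ceil((x_hi - x_lo) / spacing))
    ny = int(np.ceil((y_hi - y_lo) / spacing))
    x = x_lo + (np.arange(nx) + 0.5) * spacing
    # exactly sign-symmetric lateral coordinates so mirror-symmetric
    # textures rasterize to mirror-symmetric masks
    y = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    y_lo = -(ny * spacing) / 2.0
    X, Y = np.meshgrid(x, y, indexing="ij")

    if spec.kind == "circular_convex":
        r = spec.param("radius")
        cx = spec.wall_distance + r
        solid = (X - cx) ** 2 + Y**2 <= r**2
        solid &= np.abs(Y) <= spec.lateral_extent / 2.0
    else:
        front = _front_profile(spec, y)  # (ny,)
        solid = (X >= front[None, :]) & (X <= _back_limit(spec))

    scene = SceneGrid(
        spacing=spacing,
        solid=solid,
        source_center=(0.0, 0.0),
        receiver_center=(0.0, float(receiver_offset)),
        origin=(float(x_lo), float(y_lo)),
        spec=spec,
    )
    for name, point in (("source", scene.source_center), ("receiver", scene.receiver_center)):
        i, j = scene.index_of(point)
        if not (0 <= i < nx and 0 <= j < ny) or scene.solid[i, j]:
            raise ValueError(f"{name} at {point} lies outside the fluid region")
    return scene
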