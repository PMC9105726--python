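"""Sensor arrays: on-scalp OPM sites with orthogonal measurement components
and a helmet SQUID system (axial gradiometers plus derived magnetometer
layouts).

Every channel is an integration-point sensor model: a list of points with
weights (and, for gradiometers, per-point coil signs) and a single sensing
orientation.  OPM channels integrate over the 8 corners of the vapor cell
cube; SQUID channels integrate over 4 points per pickup coil.

Component naming follows the head's spherical coordinates with the +z
(inferior-superior) axis as pole: NOR is the outward surface normal,
TAN-LAT the tangent along lines of latitude, TAN-LON along lines of
longitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np

from .synthetic_head import HeadModel

__all__ = [
    "Triad",
    "Channel",
    "SensorArray",
    "OPM_COMPONENTS",
    "local_triad",
    "place_opm_sites",
    "build_opm_array",
    "build_squid_arrays",
    "remove_sensors",
    "opm_configuration_label",
    "array_to_frame",
    "array_from_frame",
]

OPM_COMPONENTS = ("NOR", "TAN-LAT", "TAN-LON")

#: default cap half-angle (degrees, from the +z pole) of the sensored part
#: of the scalp.  Calibrated once against the default head-radius range so
#: greedy packing with the 10 x 15 mm footprint yields 71-93 sites, and
#: frozen here.
DEFAULT_CAP_ANGLE = 66.0

# OPM vapor-cell geometry (m): cube edge of the sensitive cell and the
# standoff of the cell center from the housing face that rests on the scalp.
DEFAULT_CELL_EDGE = 0.003
DEFAULT_CELL_STANDOFF = 0.0065

# SQUID helmet geometry (m): gap between scalp and proximal pickup coils,
# axial gradiometer baseline, and pickup-coil radius.
DEFAULT_HELMET_GAP = 0.025
DEFAULT_BASELINE = 0.050
DEFAULT_COIL_RADIUS = 0.00775

#: cap half-angle of the SQUID helmet: a commercial whole-head system
#: covers the hemisphere down to the ears, independent of how much scalp
#: the on-scalp OPM cap spans.
DEFAULT_SQUID_CAP_ANGLE = 90.0


@dataclass(frozen=True)
class Triad:
    """Right-handed orthonormal frame at a sensor site."""

    e_nor: np.ndarray
    e_lat: np.ndarray
    e_lon: np.ndarray

    def axis(self, component: str) -> np.ndarray:
        return {"NOR": self.e_nor, "TAN-LAT": self.e_lat, "TAN-LON": self.e_lon}[component]


@dataclass(frozen=True)
class Channel:
    kind: str  # opm_magnetometer | squid_magnetometer | squid_axial_gradiometer
    points: np.ndarray  # (P, 3) m
    weights: np.ndarray  # (P,)
    orientation: np.ndarray  # unit 3-vector
    label: str
    coil_signs: np.ndarray | None = None  # (P,) +/-1, gradiometers only
    site: int = 0  # index into the parent array's site list

    @property
    def signed_weights(self) -> np.ndarray:
        if self.coil_signs is None:
            return self.weights
        return self.weights * self.coil_signs


@dataclass
class SensorArray:
    channels: list[Channel]
    configuration: str
    subject_id: str
    site_positions: np.ndarray  # (S, 3)
    site_triads: list[Triad] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    @cached_property
    def _flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenated integration points, per-point projection vectors
        (weight x sign x orientation), and per-channel start offsets into
        the point list (for segment sums)."""
        pts = np.concatenate([c.points for c in self.channels])
        proj = np.concatenate(
            [c.signed_weights[:, None] * c.orientation[None, :] for c in self.channels]
        )
        counts = np.array([len(c.points) for c in self.channels])
        offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
        return pts, proj, offsets


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


def local_triad(
    site: np.ndarray,
    sphere_center: np.ndarray,
    z_axis: np.ndarray = np.array([0.0, 0.0, 1.0]),
    pole_tol: float = 1e-6,
) -> Triad:
    """Orthonormal (normal, latitude, longitude) frame at a sensor site.

    e_nor is radial from the sphere center; e_lat = normalize(z x e_nor)
    points along lines of latitude; e_lon = e_nor x e_lat along lines of
    longitude.  Within ``pole_tol`` radians of a pole the latitude direction
    is undefined and a fixed fallback (Gram-Schmidt of the x-axis against
    e_nor) is used.
    """
    site = np.asarray(site, dtype=float)
    sphere_center = np.asarray(sphere_center, dtype=float)
    z_axis = _normalize(np.asarray(z_axis, dtype=float))
    e_nor = _normalize(site - sphere_center)
    lat = np.cross(z_axis, e_nor)
    if np.linalg.norm(lat) < pole_tol:
        x = np.array([1.0, 0.0, 0.0])
        lat = x - (x @ e_nor) * e_nor
        if np.linalg.norm(lat) < pole_tol:  # pragma: no cover - e_nor ~ x only if z ~ x
            y = np.array([0.0, 1.0, 0.0])
            lat = y - (y @ e_nor) * e_nor
        e_lat = _normalize(lat)
        # keep right-handedness: e_nor x e_lat = e_lon
        return Triad(e_nor, e_lat, np.cross(e_nor, e_lat))
    e_lat = _normalize(lat)
    e_lon = np.cross(e_nor, e_lat)
    return Triad(e_nor, e_lat, e_lon)


def _cap_mask(points: np.ndarray, center: np.ndarray, cap_angle_deg: float) -> np.ndarray:
    rel = points - center
    cosang = rel[:, 2] / np.linalg.norm(rel, axis=1)
    return cosang >= np.cos(np.deg2rad(cap_angle_deg))


def place_opm_sites(
    head: HeadModel,
    footprint: tuple[float, float] = (0.010, 0.015),
    standoff: float = 0.0,
    coverage_cap_angle: float = DEFAULT_CAP_ANGLE,
    seed: int = 0,
) -> tuple[np.ndarray, list[Triad]]:
    """Greedy maximal packing of OPM sites on the sensored scalp cap.

    Candidate sites are the scalp-mesh vertices inside the spherical cap of
    half-angle ``coverage_cap_angle`` about +z, offset outward by
    ``standoff`` along the local radial direction.  Sites are accepted in a
    seeded random order subject to a minimum center spacing equal to the
    footprint's larger dimension (conservative non-overlap: housing
    orientation on the scalp is arbitrary), until no admissible candidate
    remains.  Bigger heads therefore receive more sensors.
    """
    fx, fy = footprint
    if fx <= 0 or fy <= 0:
        raise ValueError("footprint dimensions must be positive")
    if standoff < 0:
        raise ValueError("standoff must be >= 0")
    spacing = max(fx, fy)

    verts = head.scalp.vertices
    mask = _cap_mask(verts, head.sphere_center, coverage_cap_angle)
    cand = verts[mask]
    if len(cand) == 0:
        return np.empty((0, 3)), []
    if standoff > 0:
        rel = cand - head.sphere_center
        cand = cand + standoff * rel / np.linalg.norm(rel, axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cand))
    accepted: list[np.ndarray] = []
    for i in order:
        p = cand[i]
        if all(np.linalg.norm(p - q) >= spacing for q in accepted):
            accepted.append(p)
    sites = np.array(accepted)
    # deterministic site ordering independent of the acceptance order
    key = np.lexsort((sites[:, 1], sites[:, 0], -sites[:, 2]))
    sites = sites[key]
    triads = [local_triad(s, head.sphere_center) for s in sites]
    return sites, triads


def opm_configuration_label(components: tuple[str, ...]) -> str:
    comps = tuple(components)
    if comps == OPM_COMPONENTS:
        return "OPM-ALL"
    if comps == ("TAN-LAT", "TAN-LON"):
        return "OPM-TAN,LAT-LON"
    return "OPM-" + ",".join(comps)


def build_opm_array(
    sites: np.ndarray,
    triads: list[Triad],
    components: tuple[str, ...] = OPM_COMPONENTS,
    cell_edge: float = DEFAULT_CELL_EDGE,
    cell_center_standoff: float = DEFAULT_CELL_STANDOFF,
    subject_id: str = "",
) -> SensorArray:
    """One channel per site per requested component.

    Each channel integrates over the 8 corners of a cube of edge
    ``cell_edge`` (the vapor cell) whose center sits ``cell_center_standoff``
    outward from the site along the local normal, axes aligned with the site
    triad; all weights 1/8.  Channel ordering is site-major,
    component-minor, so component subsets share site positions and ordering.
    """
    components = tuple(components)
    if not components:
        raise ValueError("components must be non-empty")
    for comp in components:
        if comp not in OPM_COMPONENTS:
            raise ValueError(f"unknown component {comp!r}")
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
    ) * (cell_edge / 2.0)
    weights = np.full(8, 1.0 / 8.0)
    channels: list[Channel] = []
    for s_idx, (site, tri) in enumerate(zip(sites, triads)):
        center = site + cell_center_standoff * tri.e_nor
        frame = np.stack([tri.e_nor, tri.e_lat, tri.e_lon])  # rows are axes
        pts = center + corners @ frame
        for comp in components:
            channels.append(
                Channel(
                    kind="opm_magnetometer",
                    points=pts,
                    weights=weights,
                    orientation=tri.axis(comp),
                    label=f"OPM{s_idx:03d}-{comp}",
                    site=s_idx,
                )
            )
    return SensorArray(
        channels=channels,
        configuration=opm_configuration_label(components),
        subject_id=subject_id,
        site_positions=np.asarray(sites, dtype=float),
        site_triads=list(triads),
    )


def _farthest_point_order(points: np.ndarray, start: int, limit: int | None = None) -> np.ndarray:
    """Indices in farthest-point-sampling order starting from ``start``
    (optionally truncated to the first ``limit`` picks)."""
    n = len(points)
    n_pick = n if limit is None else min(limit, n)
    chosen = [start]
    dist = np.linalg.norm(points - points[start], axis=1)
    for _ in range(n_pick - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(chosen)


def build_squid_arrays(
    head: HeadModel,
    n_channels: int = 125,
    helmet_gap: float = DEFAULT_HELMET_GAP,
    baseline: float = DEFAULT_BASELINE,
    coil_radius: float = DEFAULT_COIL_RADIUS,
    seed: int = 0,
    coverage_cap_angle: float = DEFAULT_SQUID_CAP_ANGLE,
) -> dict[str, SensorArray]:
    """Helmet SQUID system: first-order axial gradiometers plus the three
    single-coil magnetometer layouts derived from the proximal coils.

    ``n_channels`` sites are chosen quasi-uniformly (farthest-point
    sampling) on the helmet surface — the scalp cap offset outward by
    ``helmet_gap``.  AXI-GRAD channels integrate 4 points per coil at 90
    degree spacing on the pickup circle, proximal coil sign +1, distal coil
    (displaced ``baseline`` along the site normal) sign -1, sensing along
    the site normal.  The magnetometer layouts reuse the proximal coil
    points with the orientation switched to the respective triad axis.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if helmet_gap <= 0 or baseline <= 0:
        raise ValueError("helmet_gap and baseline must be positive")

    # dense quasi-uniform candidate set on the helmet cap (Fibonacci spiral
    # over the spherical cap, radius = local scalp radius + helmet gap)
    n_cand = max(4000, 20 * n_channels)
    k = np.arange(n_cand) + 0.5
    cos_lo = np.cos(np.deg2rad(coverage_cap_angle))
    cosang = 1.0 - (1.0 - cos_lo) * k / n_cand
    sinang = np.sqrt(1.0 - cosang**2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    dirs = np.column_stack(
        [sinang * np.cos(golden * k), sinang * np.sin(golden * k), cosang]
    )
    r_helmet = head.layer_radius(dirs, "scalp") + helmet_gap
    cand = head.sphere_center + dirs * r_helmet[:, None]
    if len(cand) < n_channels:
        raise ValueError("not enough helmet surface for the requested channel count")

    rng = np.random.default_rng(seed)
    order = _farthest_point_order(
        cand, start=int(rng.integers(len(cand))), limit=4 * n_channels + 64
    )
    # take sites in farthest-point order, re-packing past any candidate
    # closer than one coil diameter to an already accepted site
    accepted: list[np.ndarray] = []
    for i in order:
        p = cand[i]
        if all(np.linalg.norm(p - q) >= 2 * coil_radius for q in accepted):
            accepted.append(p)
        if len(accepted) == n_channels:
            break
    if len(accepted) < n_channels:
        raise ValueError(
            "helmet too crowded: cannot place the requested channel count with "
            "one coil diameter of clearance"
        )
    sites = np.array(accepted)
    key = np.lexsort((sites[:, 1], sites[:, 0], -sites[:, 2]))
    sites = sites[key]
    triads = [local_triad(s, head.sphere_center) for s in sites]

    quarter = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float)
    w4 = np.full(4, 1.0 / 4.0)

    def coil_points(center: np.ndarray, tri: Triad) -> np.ndarray:
        return center + coil_radius * (
            quarter[:, :1] * tri.e_lat[None, :] + quarter[:, 1:] * tri.e_lon[None, :]
        )

    grad_channels: list[Channel] = []
    mag_channels: dict[str, list[Channel]] = {c: [] for c in OPM_COMPONENTS}
    for s_idx, (site, tri) in enumerate(zip(sites, triads)):
        prox = coil_points(site, tri)
        dist = coil_points(site + baseline * tri.e_nor, tri)
        grad_channels.append(
            Channel(
                kind="squid_axial_gradiometer",
                points=np.vstack([prox, dist]),
                weights=np.concatenate([w4, w4]),
                orientation=tri.e_nor,
                coil_signs=np.concatenate([np.ones(4), -np.ones(4)]),
                label=f"SQ{s_idx:03d}-GRAD",
                site=s_idx,
            )
        )
        for comp in OPM_COMPONENTS:
            mag_channels[comp].append(
                Channel(
                    kind="squid_magnetometer",
                    points=prox,
                    weights=w4,
                    orientation=tri.axis(comp),
                    label=f"SQ{s_idx:03d}-{comp}",
                    site=s_idx,
                )
            )

    def mk(channels: list[Channel], config: str) -> SensorArray:
        return SensorArray(
            channels=channels,
            configuration=config,
            subject_id=head.subject_id,
            site_positions=sites,
            site_triads=list(triads),
        )

    return {
        "SQUID-AXI-GRAD": mk(grad_channels, "SQUID-AXI-GRAD"),
        "SQUID-NOR": mk(mag_channels["NOR"], "SQUID-NOR"),
        "SQUID-TAN-LAT": mk(mag_channels["TAN-LAT"], "SQUID-TAN-LAT"),
        "SQUID-TAN-LON": mk(mag_channels["TAN-LON"], "SQUID-TAN-LON"),
    }


def remove_sensors(array: SensorArray, fraction_removed: float, seed: int = 0) -> SensorArray:
    """Thin an array by removing whole SITES, keeping the survivors
    quasi-equidistant via farthest-point subsampling.

    All component channels at a removed site are removed together.  The
    retained count is round((1 - fraction_removed) * n_sites), at least 4.
    """
    if not 0 <= fraction_removed < 1:
        raise ValueError("fraction_removed must be in [0, 1)")
    if fraction_removed == 0:
        return array
    n_sites = array.n_sites
    n_keep = int(round((1.0 - fraction_removed) * n_sites))
    if n_keep < 4:
        raise ValueError(f"fraction_removed={fraction_removed} would leave {n_keep} < 4 sites")
    rng = np.random.default_rng(seed)
    order = _farthest_point_order(array.site_positions, start=int(rng.integers(n_sites)))
    keep = np.sort(order[:n_keep])
    site_map = {int(old): new for new, old in enumerate(keep)}
    channels = [
        replace(c, site=site_map[c.site]) for c in array.channels if c.site in site_map
    ]
    return SensorArray(
        channels=channels,
        configuration=array.configuration,
        subject_id=array.subject_id,
        site_positions=array.site_positions[keep],
        site_triads=[array.site_triads[i] for i in keep] if array.site_triads else [],
    )


def array_to_frame(array: SensorArray):
    """Lossless tabular export: one row per integration point."""
    import pandas as pd

    rows = []
    for ci, c in enumerate(array.channels):
        signs = c.coil_signs if c.coil_signs is not None else np.ones(len(c.points))
        for p, w, s in zip(c.points, c.weights, signs):
            rows.append(
                {
                    "channel": ci,
                    "label": c.label,
                    "kind": c.kind,
                    "site": c.site,
                    "ox": c.orientation[0],
                    "oy": c.orientation[1],
                    "oz": c.orientation[2],
                    "weight": w,
                    "sign": s,
                    "x": p[0],
                    "y": p[1],
                    "z": p[2],
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs["configuration"] = array.configuration
    frame.attrs["subject_id"] = array.subject_id
    return frame


def array_from_frame(frame, configuration: str | None = None, subject_id: str | None = None) -> SensorArray:
    """Inverse of :func:`array_to_frame` (site triads are not restored)."""
    channels = []
    sites = {}
    for ci, grp in frame.groupby("channel", sort=True):
        kind = grp["kind"].iloc[0]
        signs = grp["sign"].to_numpy(dtype=float)
        channels.append(
            Channel(
                kind=kind,
                points=grp[["x", "y", "z"]].to_numpy(dtype=float),
                weights=grp["weight"].to_numpy(dtype=float),
                orientation=grp[["ox", "oy", "oz"]].iloc[0].to_numpy(dtype=float),
                label=grp["label"].iloc[0],
                coil_signs=signs if kind == "squid_axial_gradiometer" else None,
                site=int(grp["site"].iloc[0]),
            )
        )
        sites.setdefault(int(grp["site"].iloc[0]), grp[["x", "y", "z"]].to_numpy(dtype=float).mean(axis=0))
    site_positions = np.array([sites[k] for k in sorted(sites)])
    return SensorArray(
        channels=channels,
        configuration=configuration or frame.attrs.get("configuration", ""),
        subject_id=subject_id or frame.attrs.get("subject_id", ""),
        site_positions=site_positions,
    )
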