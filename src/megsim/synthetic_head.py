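"""Synthetic layered head geometry: nested scalp/skull/brain surfaces, a
cortical source space, and the fitted conductor sphere.

Surfaces are icospheres (optionally with a smooth seeded radial modulation
that mimics head asphericity), so each layer is an exact radial graph over
the unit sphere.  All coordinates are SI meters in a head frame whose +z
axis is the inferior-superior axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import trimesh
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

__all__ = [
    "TriMesh",
    "HeadModel",
    "SourceSpace",
    "make_head",
    "make_cohort",
    "make_source_space",
    "fit_sphere",
    "DEFAULT_CONDUCTIVITIES",
]

#: scalp / skull / brain conductivities in S/m.  Carried as provenance
#: metadata only: the external magnetic field of a spherically symmetric
#: conductor does not depend on the radial conductivity profile, so no
#: computation in this package ever reads these numbers.
DEFAULT_CONDUCTIVITIES = (0.3, 0.006, 0.3)


@dataclass(frozen=True)
class TriMesh:
    """Closed oriented triangle mesh (vertices in meters)."""

    vertices: np.ndarray  # (V, 3) float
    triangles: np.ndarray  # (T, 3) int

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "triangles", np.asarray(self.triangles, dtype=np.int64))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @cached_property
    def _trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    def contains(self, points: np.ndarray, chunk: int = 512) -> np.ndarray:
        """Point-in-mesh test for an (N, 3) array via the generalized
        winding number (sum of signed solid angles subtended by the
        triangles; 4 pi inside a closed oriented surface, 0 outside)."""
        points = np.atleast_2d(points)
        tri = self.vertices[self.triangles]  # (T, 3, 3)
        out = np.empty(len(points), dtype=bool)
        for lo in range(0, len(points), chunk):
            p = points[lo : lo + chunk]
            a = tri[None, :, 0, :] - p[:, None, :]
            b = tri[None, :, 1, :] - p[:, None, :]
            c = tri[None, :, 2, :] - p[:, None, :]
            la = np.linalg.norm(a, axis=2)
            lb = np.linalg.norm(b, axis=2)
            lc = np.linalg.norm(c, axis=2)
            # van Oosterom-Strackee signed solid angle of each triangle
            num = np.einsum("ptk,ptk->pt", a, np.cross(b, c))
            den = (
                la * lb * lc
                + np.einsum("ptk,ptk->pt", a, b) * lc
                + np.einsum("ptk,ptk->pt", b, c) * la
                + np.einsum("ptk,ptk->pt", a, c) * lb
            )
            winding = np.arctan2(num, den).sum(axis=1) / (2.0 * np.pi)
            out[lo : lo + chunk] = winding > 0.5
        return out

    def is_closed(self) -> bool:
        return bool(self._trimesh.is_watertight)

    def signed_volume(self) -> float:
        return float(self._trimesh.volume)

    def export(self, path: str) -> None:
        """Write the surface in a standard mesh format inferred from suffix
        (.off, .ply, .stl)."""
        self._trimesh.export(path)

    @classmethod
    def load(cls, path: str) -> "TriMesh":
        m = trimesh.load_mesh(path, process=False)
        return cls(np.asarray(m.vertices, dtype=float), np.asarray(m.faces))


def _unit_icosphere(subdivision: int) -> trimesh.Trimesh:
    return trimesh.creation.icosphere(subdivisions=subdivision, radius=1.0)


def _radial_modulation(directions: np.ndarray, seed: int) -> np.ndarray:
    """Smooth band-limited function on the unit sphere, normalized to
    max |f| = 1.  Built from a seeded random linear + quadratic form, so it
    contains only low spherical-harmonic degrees (l <= 2) and the perturbed
    surfaces stay star-shaped and smooth."""
    rng = np.random.default_rng(seed)
    lin = rng.standard_normal(3)
    quad = rng.standard_normal((3, 3))
    quad = 0.5 * (quad + quad.T)
    f = directions @ lin + np.einsum("ni,ij,nj->n", directions, quad, directions)
    f = f - f.mean()
    peak = np.max(np.abs(f))
    if peak > 0:
        f = f / peak
    return f


def fit_sphere(mesh: TriMesh | np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit: minimizes sum_i (|v_i - c| - r)^2.

    Uses the algebraic (Coope) solution as the starting point for a
    geometric Gauss-Newton refinement.  Raises ``ValueError`` for
    degenerate (coplanar) vertex sets.
    """
    pts = mesh.vertices if isinstance(mesh, TriMesh) else np.asarray(mesh, dtype=float)
    if len(pts) < 4:
        raise ValueError("sphere fit needs at least 4 vertices")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-12) < 3:
        raise ValueError("degenerate (coplanar) vertices: sphere fit undefined")
    # algebraic: |v|^2 = 2 v.c + (r^2 - |c|^2)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 0.0)))

    def resid(x: np.ndarray) -> np.ndarray:
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    out = least_squares(resid, np.append(c0, r0), method="lm")
    return out.x[:3].copy(), float(out.x[3])


@dataclass(frozen=True)
class HeadModel:
    """Three nested closed surfaces plus the conductor sphere fitted to the
    scalp.  ``conductivities`` are provenance metadata only (see module
    docstring)."""

    scalp: TriMesh
    skull: TriMesh
    brain: TriMesh
    conductivities: tuple[float, float, float]
    sphere_center: np.ndarray
    sphere_radius: float
    subject_id: str
    seed: int

    @cached_property
    def _dir_tree(self) -> cKDTree:
        dirs = self.scalp.vertices / np.linalg.norm(self.scalp.vertices, axis=1, keepdims=True)
        return cKDTree(dirs)

    @cached_property
    def _scalp_tree(self) -> cKDTree:
        return cKDTree(self.scalp.vertices)

    def layer_radius(self, directions: np.ndarray, layer: str = "brain") -> np.ndarray:
        """Surface radius along unit ``directions`` (origin-centred radial
        lookup via the nearest mesh vertex direction).  Valid because every
        layer is a radial graph built over the same unit icosphere."""
        directions = np.atleast_2d(directions)
        _, idx = self._dir_tree.query(directions)
        mesh = getattr(self, layer)
        return np.linalg.norm(mesh.vertices[idx], axis=1)

    def scalp_distance(self, points: np.ndarray) -> np.ndarray:
        """Minimum Euclidean distance from each point to the scalp vertices
        (the depth convention used throughout)."""
        d, _ = self._scalp_tree.query(np.atleast_2d(points))
        return d

    def inside_brain(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Fast radial interior test against the brain surface."""
        points = np.atleast_2d(points)
        r = np.linalg.norm(points, axis=1)
        out = np.zeros(len(points), dtype=bool)
        nz = r > 0
        out[~nz] = True
        if nz.any():
            dirs = points[nz] / r[nz, None]
            out[nz] = r[nz] <= self.layer_radius(dirs, "brain") - margin
        return out


@dataclass(frozen=True)
class SourceSpace:
    """Candidate dipole positions on a cortical shell, with their depths
    (distance to the nearest scalp vertex)."""

    positions: np.ndarray  # (N, 3) m
    depths: np.ndarray  # (N,) m
    seed: int

    def __len__(self) -> int:
        return len(self.positions)

    def depth_subset(self, lo: float, hi: float) -> np.ndarray:
        """Indices of candidates whose depth lies in [lo, hi]."""
        return np.nonzero((self.depths >= lo) & (self.depths <= hi))[0]


def make_head(
    scalp_radius: float = 0.092,
    skull_offset: float = 0.006,
    brain_offset: float = 0.006,
    subdivision: int = 4,
    perturbation: float = 0.02,
    seed: int = 0,
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES,
    subject_id: str | None = None,
) -> HeadModel:
    """Build a three-layer head as nested icospheres.

    Parameters
    ----------
    scalp_radius
        Nominal outer radius in meters.
    skull_offset, brain_offset
        Radial gaps scalp->skull and skull->brain (m); with the defaults the
        brain surface sits 12 mm under the scalp, a typical combined
        scalp + skull thickness.
    subdivision
        Icosphere subdivision order; 4 gives 2562 vertices / 5120 triangles
        per layer.
    perturbation
        Relative amplitude of a smooth seeded radial modulation applied to
        all three layers (same angular pattern, so the layer gaps scale and
        the surfaces can never intersect).  Must be < 0.1.
    """
    if not scalp_radius > skull_offset + brain_offset > 0:
        raise ValueError("need scalp_radius > skull_offset + brain_offset > 0")
    if subdivision < 0:
        raise ValueError("subdivision must be >= 0")
    if not 0 <= perturbation < 0.1:
        raise ValueError("perturbation must be in [0, 0.1)")

    base = _unit_icosphere(subdivision)
    dirs = np.asarray(base.vertices, dtype=float)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    factor = np.ones(len(dirs))
    if perturbation > 0:
        factor = 1.0 + perturbation * _radial_modulation(dirs, seed)

    radii = (
        scalp_radius,
        scalp_radius - skull_offset,
        scalp_radius - skull_offset - brain_offset,
    )
    if min(radii) * (1.0 - perturbation) <= 0:
        raise ValueError("perturbation would collapse the innermost layer")
    faces = np.asarray(base.faces)
    layers = [TriMesh(dirs * (r * factor)[:, None], faces) for r in radii]

    center, fitted_r = fit_sphere(layers[0])
    return HeadModel(
        scalp=layers[0],
        skull=layers[1],
        brain=layers[2],
        conductivities=tuple(conductivities),
        sphere_center=center,
        sphere_radius=fitted_r,
        subject_id=subject_id or f"synthetic-{seed}",
        seed=seed,
    )


def make_cohort(
    n_subjects: int = 8,
    radius_range: tuple[float, float] = (0.087, 0.096),
    subdivision: int = 4,
    perturbation: float = 0.02,
    seed: int = 0,
    **kwargs,
) -> list[HeadModel]:
    """A cohort of synthetic subjects with scalp radii spanning
    ``radius_range`` (evenly spaced) and per-subject perturbation seeds.
    The default range emulates realistic adult head-size variability."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    lo, hi = radius_range
    radii = np.linspace(lo, hi, n_subjects) if n_subjects > 1 else np.array([lo])
    child_seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    heads = []
    for i, (r, cs) in enumerate(zip(radii, child_seeds)):
        sub_seed = int(cs.generate_state(1, dtype=np.uint32)[0] % (2**31))
        heads.append(
            make_head(
                scalp_radius=float(r),
                subdivision=subdivision,
                perturbation=perturbation,
                seed=sub_seed,
                subject_id=f"S{i + 1:02d}",
                **kwargs,
            )
        )
    return heads


def make_source_space(
    head: HeadModel,
    n_candidates: int = 2000,
    depth_range: tuple[float, float] = (0.013, 0.035),
    seed: int = 0,
    margin: float = 1e-3,
    max_attempt_factor: int = 200,
) -> SourceSpace:
    """Sample candidate source positions quasi-uniformly on a cortical shell.

    Directions are uniform on the sphere and target depths uniform over
    ``depth_range``; each candidate is placed along its direction at the
    local scalp radius minus the target depth, then kept only if it lies
    strictly inside the brain surface (radial margin ``margin``) and its
    realized depth (distance to the nearest scalp vertex) falls inside
    ``depth_range``.  The default depth window 1.3-3.5 cm emulates the
    depth span of the cortical mantle under scalp and skull.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    lo, hi = depth_range
    if not (0 < lo <= hi < head.sphere_radius):
        raise ValueError("depth_range must lie within (0, sphere_radius)")

    rng = np.random.default_rng(seed)
    positions: list[np.ndarray] = []
    depths: list[float] = []
    attempts = 0
    max_attempts = max_attempt_factor * n_candidates
    batch = max(256, n_candidates)
    while len(positions) < n_candidates:
        if attempts >= max_attempts:
            achievable = (
                float(head.scalp_distance(np.zeros((1, 3)))[0]) if positions == [] else float("nan")
            )
            raise RuntimeError(
                f"source-space sampling failed after {attempts} attempts; "
                f"depth_range {depth_range} may be unreachable "
                f"(deepest achievable depth ~{achievable:.3f} m)"
            )
        dirs = rng.standard_normal((batch, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        target_depth = rng.uniform(lo, hi, size=batch)
        r_scalp = head.layer_radius(dirs, "scalp")
        pos = dirs * (r_scalp - target_depth)[:, None]
        ok = head.inside_brain(pos, margin=margin)
        realized = head.scalp_distance(pos)
        ok &= (realized >= lo) & (realized <= hi)
        attempts += batch
        for p, d in zip(pos[ok], realized[ok]):
            if len(positions) < n_candidates:
                positions.append(p)
                depths.append(float(d))
    return SourceSpace(np.array(positions), np.array(depths), seed=seed)


def source_space_to_table(space: SourceSpace):
    """Source space as a pandas DataFrame (x, y, z, depth in meters)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "x": space.positions[:, 0],
            "y": space.positions[:, 1],
            "z": space.positions[:, 2],
            "depth": space.depths,
        }
    )
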