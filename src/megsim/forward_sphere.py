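"""Closed-form magnetic field of a current dipole in a spherically
symmetric conductor (Sarvas expression), channel responses through sensor
integration points, and leadfield assembly.

For MEG the external field of a spherically symmetric conductor depends
only on the dipole and the sphere center — not on the radial conductivity
profile — so the layered head's conductivities never enter.  A consequence
used widely in the tests: radially oriented dipoles are magnetically
silent, and the field is exactly linear in the dipole moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensor_arrays import Channel, SensorArray

__all__ = [
    "MU0",
    "Dipole",
    "FieldMap",
    "dipole_field_point",
    "dipole_fields",
    "channel_response",
    "array_response",
    "leadfield",
]

MU0 = 4.0e-7 * np.pi  # T*m/A, exact

#: observation points closer than this to the source radius are rejected
#: rather than extrapolated (the closed form is singular at the source).
MIN_RADIAL_CLEARANCE = 1e-3


@dataclass(frozen=True)
class Dipole:
    """Current dipole: position (m) and moment vector (A*m)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "moment", np.asarray(self.moment, dtype=float))

    @property
    def q(self) -> float:
        """Moment magnitude (A*m)."""
        return float(np.linalg.norm(self.moment))

    @property
    def orientation(self) -> np.ndarray:
        q = self.q
        return self.moment / q if q > 0 else self.moment


@dataclass(frozen=True)
class FieldMap:
    """Per-channel field values (tesla) for one time sample."""

    values: np.ndarray
    configuration: str = ""
    subject_id: str = ""
    sample_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field map contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


def dipole_fields(
    dip_pos: np.ndarray,
    dip_mom: np.ndarray,
    obs: np.ndarray,
    sphere_center: np.ndarray = np.zeros(3),
) -> np.ndarray:
    """Sarvas field for D dipoles at P observation points -> (P, D, 3) tesla.

    B(r) = mu0 / (4 pi F^2) * [ F (Q x r0) - ((Q x r0) . r) grad F ],
    with r, r0 relative to the sphere center, a = r - r0, a = |a|, R = |r|,
    F = a (R a + R^2 - r0 . r) and
    grad F = (a^2/R + (a.r)/a + 2a + 2R) r - (a + 2R + (a.r)/a) r0.

    Raises for observation points whose radius does not exceed the source
    radius by at least ``MIN_RADIAL_CLEARANCE``.
    """
    dip_pos = np.atleast_2d(np.asarray(dip_pos, dtype=float))
    dip_mom = np.atleast_2d(np.asarray(dip_mom, dtype=float))
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    center = np.asarray(sphere_center, dtype=float)

    r0 = dip_pos - center  # (D, 3)
    r = obs - center  # (P, 3)
    Rn = np.sqrt(np.einsum("pk,pk->p", r, r))  # (P,)
    r0n = np.sqrt(np.einsum("dk,dk->d", r0, r0))  # (D,)
    if np.any(Rn[:, None] - r0n[None, :] < MIN_RADIAL_CLEARANCE):
        raise ValueError(
            "observation point within the minimum radial clearance of a source"
        )

    a_vec = r[:, None, :] - r0[None, :, :]  # (P, D, 3)
    a = np.sqrt(np.einsum("pdk,pdk->pd", a_vec, a_vec))  # (P, D)
    adotr = np.einsum("pdk,pk->pd", a_vec, r)  # (P, D)
    r0dotr = np.einsum("dk,pk->pd", r0, r)  # (P, D)
    F = a * (Rn[:, None] * a + Rn[:, None] ** 2 - r0dotr)  # (P, D)
    if np.any(np.abs(F) < 1e-30):
        raise ValueError("degenerate geometry: F = 0 in the closed-form field")

    c_r = a**2 / Rn[:, None] + adotr / a + 2.0 * a + 2.0 * Rn[:, None]
    c_r0 = a + 2.0 * Rn[:, None] + adotr / a
    gradF = c_r[:, :, None] * r[:, None, :] - c_r0[:, :, None] * r0[None, :, :]

    Qxr0 = np.cross(dip_mom, r0)  # (D, 3)
    Qxr0_dot_r = np.einsum("dk,pk->pd", Qxr0, r)  # (P, D)
    B = (
        F[:, :, None] * Qxr0[None, :, :] - Qxr0_dot_r[:, :, None] * gradF
    ) * (MU0 / (4.0 * np.pi * F**2))[:, :, None]
    return B


def dipole_field_point(
    dipole: Dipole, r_obs: np.ndarray, sphere_center: np.ndarray = np.zeros(3)
) -> np.ndarray:
    """Field 3-vector (tesla) of one dipole at one observation point."""
    return dipole_fields(dipole.position, dipole.moment, r_obs, sphere_center)[0, 0]


def channel_response(
    channel: Channel, dipole: Dipole, sphere_center: np.ndarray = np.zeros(3)
) -> float:
    """Integrated channel reading: sum over integration points of
    weight * coil_sign * (B(point) . orientation)."""
    B = dipole_fields(dipole.position, dipole.moment, channel.points, sphere_center)[:, 0, :]
    return float(channel.signed_weights @ (B @ channel.orientation))


def array_response(
    array: SensorArray,
    dip_pos: np.ndarray,
    dip_mom: np.ndarray,
    sphere_center: np.ndarray = np.zeros(3),
) -> np.ndarray:
    """Responses of every channel to D dipoles -> (n_channels, D) tesla.

    Vectorized over all integration points of the array at once.
    """
    pts, proj, offsets = array._flat
    B = dipole_fields(dip_pos, dip_mom, pts, sphere_center)  # (P, D, 3)
    contrib = np.einsum("pdk,pk->pd", B, proj)
    return np.add.reduceat(contrib, offsets, axis=0)


def leadfield(
    array: SensorArray,
    positions: np.ndarray,
    sphere_center: np.ndarray = np.zeros(3),
) -> np.ndarray:
    """Leadfield matrix (n_channels, 3 K): column 3k + j is the response to
    a unit dipole at positions[k] along Cartesian axis j.

    Assembled in a single vectorized field evaluation over all positions
    and the three unit moments."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    K = len(positions)
    pos_rep = np.repeat(positions, 3, axis=0)  # (3K, 3)
    mom = np.tile(np.eye(3), (K, 1))  # (3K, 3)
    return array_response(array, pos_rep, mom, sphere_center)
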