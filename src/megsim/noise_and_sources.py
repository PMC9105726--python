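"""Target-dipole sampling and the two noise models: random ambient sensor
noise and spontaneous brain noise from many random cortical dipoles.

Randomness is organised as named streams derived from one seed so that a
dataset is reproducible from a single integer and so that sweeps over noise
strength reuse identical dipole draws (variance reduction across grid
points): ambient noise at sigma and at 2*sigma differ only by the scale
factor, never by the realization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_sphere import Dipole, FieldMap, array_response
from .sensor_arrays import SensorArray
from .synthetic_head import HeadModel, SourceSpace

__all__ = [
    "NoiseSpec",
    "SimulationSample",
    "sample_target_dipoles",
    "ambient_noise",
    "spontaneous_noise",
    "simulate_dataset",
]

# stream tags (mixed into the RNG seed material)
_TARGET, _AMBIENT, _SPONT = 0, 1, 2


@dataclass(frozen=True)
class NoiseSpec:
    """Noise condition: ambient SD ``sigma`` (tesla), spontaneous dipole
    strength ``q_spont`` (A*m), number of spontaneous dipoles per sample,
    and the seed of the noise streams."""

    sigma: float = 0.0
    q_spont: float = 0.0
    n_noise_dipoles: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.q_spont < 0 or self.n_noise_dipoles < 0:
            raise ValueError("sigma, q_spont and n_noise_dipoles must be >= 0")


@dataclass(frozen=True)
class SimulationSample:
    """One time sample: the target dipole, its noise-free signal map, the
    combined noise map, and observed = signal + noise."""

    t: int
    target: Dipole
    signal: FieldMap
    noise: FieldMap
    observed: FieldMap


def _uniform_orientations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform directions on the unit sphere via normalized Gaussians."""
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1)
    while np.any(norms < 1e-12):  # pragma: no cover - astronomically rare
        bad = norms < 1e-12
        v[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1)
    return v / norms[:, None]


def sample_target_dipoles(
    source_space: SourceSpace,
    n_samples: int,
    q: float = 100e-9,
    depth_bin: tuple[float, float] | None = None,
    seed: int = 0,
) -> list[Dipole]:
    """Draw target dipoles: positions uniformly (with replacement) from the
    source-space candidates — optionally restricted to the depth bin
    [h - dh, h + dh] — and orientations uniform on the sphere; every moment
    has magnitude ``q`` (A*m)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if q < 0:
        raise ValueError("q must be >= 0")
    if depth_bin is not None:
        h, dh = depth_bin
        idx = source_space.depth_subset(h - dh, h + dh)
        if len(idx) == 0:
            raise ValueError(
                f"no source-space candidates in depth bin {h - dh:.4f}..{h + dh:.4f} m; "
                f"achievable depths span {source_space.depths.min():.4f}.."
                f"{source_space.depths.max():.4f} m"
            )
    else:
        idx = np.arange(len(source_space))
    rng = np.random.default_rng([seed, _TARGET])
    chosen = rng.choice(idx, size=n_samples, replace=True)
    orient = _uniform_orientations(rng, n_samples)
    return [
        Dipole(source_space.positions[i], q * o) for i, o in zip(chosen, orient)
    ]


def ambient_noise(spec: NoiseSpec, n_channels: int, t: int = 0) -> FieldMap:
    """Random ambient noise for one time sample: independent zero-mean
    Gaussians of SD ``sigma`` per channel, identical in amplitude for every
    array and component.  The realization is determined by (seed, t), so
    only the scale changes across a sigma sweep."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng([spec.seed, _AMBIENT, t])
    xi = rng.standard_normal(n_channels)
    return FieldMap(spec.sigma * xi, sample_index=t)


def spontaneous_noise(
    spec: NoiseSpec,
    source_space: SourceSpace,
    array: SensorArray,
    sphere_center: np.ndarray,
    t: int = 0,
) -> FieldMap:
    """Spontaneous brain noise for one time sample: the superposed forward
    field of ``n_noise_dipoles`` dipoles drawn fresh for this sample
    (uniform positions from the source space, uniform orientations, all
    with moment magnitude ``q_spont``).

    The dipole draw depends only on (seed, t) — not on the array — so every
    array observes the same interfering sources; being closer to the scalp,
    on-scalp sensors therefore see stronger noise.
    """
    rng = np.random.default_rng([spec.seed, _SPONT, t])
    idx = rng.integers(0, len(source_space), size=spec.n_noise_dipoles)
    orient = _uniform_orientations(rng, spec.n_noise_dipoles)
    if spec.q_spont == 0 or spec.n_noise_dipoles == 0:
        return FieldMap(
            np.zeros(array.n_channels),
            configuration=array.configuration,
            subject_id=array.subject_id,
            sample_index=t,
        )
    resp = array_response(
        array, source_space.positions[idx], spec.q_spont * orient, sphere_center
    )
    return FieldMap(
        resp.sum(axis=1),
        configuration=array.configuration,
        subject_id=array.subject_id,
        sample_index=t,
    )


def simulate_dataset(
    head: HeadModel,
    array: SensorArray,
    source_space: SourceSpace,
    n_samples: int = 100,
    q: float = 100e-9,
    spec: NoiseSpec = NoiseSpec(),
) -> list[SimulationSample]:
    """Full simulation protocol: per time sample one target dipole's
    noise-free signal map, one combined noise map (ambient + spontaneous),
    and observed = signal + noise."""
    targets = sample_target_dipoles(source_space, n_samples, q=q, seed=spec.seed)
    pos = np.array([d.position for d in targets])
    mom = np.array([d.moment for d in targets])
    signals = array_response(array, pos, mom, head.sphere_center)  # (C, T)
    samples = []
    for t in range(n_samples):
        sig = FieldMap(
            signals[:, t],
            configuration=array.configuration,
            subject_id=array.subject_id,
            sample_index=t,
        )
        amb = ambient_noise(spec, array.n_channels, t)
        spont = spontaneous_noise(spec, source_space, array, head.sphere_center, t)
        noise = FieldMap(
            amb.values + spont.values,
            configuration=array.configuration,
            subject_id=array.subject_id,
            sample_index=t,
        )
        obs = FieldMap(
            sig.values + noise.values,
            configuration=array.configuration,
            subject_id=array.subject_id,
            sample_index=t,
        )
        samples.append(SimulationSample(t=t, target=targets[t], signal=sig, noise=noise, observed=obs))
    return samples
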