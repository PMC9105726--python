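"""Sweep drivers comparing the measurement components of OPM- and
SQUID-MEG arrays across a cohort of synthetic subjects.

Every driver follows the same protocol: per subject, simulate dipolar
sources at q = 100 nAm for a number of time samples, add noise, fit an
equivalent current dipole per sample, compute the per-sample metrics
(SNR, RE, CC, d_s,f, RMS_signal), average over samples within each
subject, and report mean +/- SD across subjects per grid point.

The seed hierarchy (master seed -> subject -> named streams) guarantees
that grid points of a sweep share identical dipole and noise draws up to
the swept scale factor, and that grid points shared between sweeps (for
example sigma = 0 and q_spont = 0) agree exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecd_fit import FitOptions, fit_ecd
from .forward_sphere import array_response
from .metrics import localization_error, rms, snr_db
from .noise_and_sources import (
    NoiseSpec,
    ambient_noise,
    sample_target_dipoles,
    spontaneous_noise,
)
from .sensor_arrays import (
    OPM_COMPONENTS,
    SensorArray,
    build_opm_array,
    build_squid_arrays,
    place_opm_sites,
    remove_sensors,
)
from .synthetic_head import HeadModel, SourceSpace, make_head, make_source_space

__all__ = [
    "OPM_CONFIGURATIONS",
    "SQUID_CONFIGURATIONS",
    "SubjectContext",
    "SweepResult",
    "build_subjects",
    "run_baseline_rms",
    "run_ambient_sweep",
    "run_spontaneous_sweep",
    "run_noise_grid",
    "run_sensor_count_sweep",
    "run_depth_sweep",
    "aggregate_subjects",
    "component_matched_rms_ratios",
    "normal_tangential_rms_ratio",
    "deep_source_rms_ratio",
]

#: component subsets behind each OPM configuration label
OPM_CONFIGURATIONS: dict[str, tuple[str, ...]] = {
    "OPM-NOR": ("NOR",),
    "OPM-TAN-LAT": ("TAN-LAT",),
    "OPM-TAN-LON": ("TAN-LON",),
    "OPM-ALL": OPM_COMPONENTS,
    "OPM-NOR,TAN-LAT": ("NOR", "TAN-LAT"),
    "OPM-NOR,TAN-LON": ("NOR", "TAN-LON"),
    "OPM-TAN,LAT-LON": ("TAN-LAT", "TAN-LON"),
}

SQUID_CONFIGURATIONS = ("SQUID-AXI-GRAD", "SQUID-NOR", "SQUID-TAN-LAT", "SQUID-TAN-LON")

SINGLE_OPM = ("OPM-NOR", "OPM-TAN-LAT", "OPM-TAN-LON")
DUAL_OPM = ("OPM-NOR,TAN-LAT", "OPM-NOR,TAN-LON", "OPM-TAN,LAT-LON")

#: component-matched OPM / SQUID-magnetometer configuration pairs
MATCHED_PAIRS = (
    ("OPM-NOR", "SQUID-NOR"),
    ("OPM-TAN-LAT", "SQUID-TAN-LAT"),
    ("OPM-TAN-LON", "SQUID-TAN-LON"),
)


@dataclass
class SubjectContext:
    """One synthetic subject: head, cortical source space, shared OPM site
    set, and lazily built sensor arrays."""

    index: int
    head: HeadModel
    source_space: SourceSpace
    opm_sites: np.ndarray
    opm_triads: list
    squid_seed: int
    sim_seed: int
    fit_seed: int
    cfg: dict
    _arrays: dict = field(default_factory=dict)

    def array(self, configuration: str) -> SensorArray:
        if configuration in self._arrays:
            return self._arrays[configuration]
        opm_cfg = self.cfg["opm"]
        if configuration in OPM_CONFIGURATIONS:
            arr = build_opm_array(
                self.opm_sites,
                self.opm_triads,
                components=OPM_CONFIGURATIONS[configuration],
                cell_edge=opm_cfg["cell_edge"],
                cell_center_standoff=opm_cfg["cell_center_standoff"],
                subject_id=self.head.subject_id,
            )
        elif configuration in SQUID_CONFIGURATIONS:
            sq = self.cfg["squid"]
            arrays = build_squid_arrays(
                self.head,
                n_channels=sq["n_channels"],
                helmet_gap=sq["helmet_gap"],
                baseline=sq["baseline"],
                coil_radius=sq["coil_radius"],
                seed=self.squid_seed,
                coverage_cap_angle=sq["cap_angle"],
            )
            self._arrays.update(arrays)
            return self._arrays[configuration]
        else:
            raise KeyError(f"unknown configuration {configuration!r}")
        self._arrays[configuration] = arr
        return arr

    def fit_options(self) -> FitOptions:
        fit_cfg = self.cfg["fit"]
        return FitOptions(
            n_coarse=fit_cfg["n_coarse"],
            max_evaluations=fit_cfg["max_evaluations"],
            seed=self.fit_seed,
            source_space=self.source_space,
        )


@dataclass
class SweepResult:
    """Per-subject metric means and across-subject aggregates on a grid of
    sweep conditions."""

    axes: dict[str, list]
    per_subject: pd.DataFrame
    aggregate: pd.DataFrame
    configurations: list[str]
    provenance: dict
    per_sample: pd.DataFrame | None = None  # populated when keep_samples=True


def _subject_streams(master_seed: int, index: int, n: int = 6) -> list[int]:
    words = np.random.SeedSequence([master_seed, index]).generate_state(n, dtype=np.uint32)
    return [int(w % (2**31)) for w in words]


def default_config() -> dict:
    """All geometric and simulation defaults, in SI units."""
    return {
        "head": {
            "n_subjects": 8,
            "radius_range": (0.087, 0.096),
            "subdivision": 4,
            "perturbation": 0.02,
            "skull_offset": 0.006,
            "brain_offset": 0.006,
        },
        "source_space": {"n_candidates": 2000, "depth_range": (0.013, 0.035)},
        "opm": {
            "footprint": (0.010, 0.015),
            "standoff": 0.0,
            "cap_angle": 66.0,
            "cell_edge": 0.003,
            "cell_center_standoff": 0.0065,
        },
        "squid": {
            "n_channels": 125,
            "helmet_gap": 0.025,
            "baseline": 0.050,
            "coil_radius": 0.00775,
            "cap_angle": 90.0,
        },
        "simulation": {"n_samples": 100, "q": 100e-9, "n_noise_dipoles": 100},
        "fit": {"n_coarse": 200, "max_evaluations": 2000},
        "sweeps": {
            "sigma_grid_fT": (0.0, 25.0, 75.0, 150.0, 225.0, 300.0, 375.0),
            "q_spont_grid_nAm": (0.0, 1.0, 2.0, 3.0, 5.0, 7.0),
            "fractions_removed": (0.0, 0.25, 0.5, 0.75, 0.85, 0.9),
            "depth_grid_cm": (1.5, 2.5, 3.5, 4.5, 5.5),
            "depth_halfwidth_cm": 0.5,
        },
    }


def _merge(base: dict, override: dict | None) -> dict:
    if not override:
        return base
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=list).encode()).hexdigest()[:12]


def build_subjects(
    master_seed: int = 0,
    config: dict | None = None,
    n_subjects: int | None = None,
) -> list[SubjectContext]:
    """Build the synthetic cohort with per-subject seed streams."""
    cfg = _merge(default_config(), config)
    head_cfg = cfg["head"]
    n = n_subjects if n_subjects is not None else head_cfg["n_subjects"]
    lo, hi = head_cfg["radius_range"]
    radii = np.linspace(lo, hi, n) if n > 1 else np.array([lo])
    subjects = []
    for i in range(n):
        head_seed, sites_seed, space_seed, squid_seed, sim_seed, fit_seed = _subject_streams(
            master_seed, i
        )
        head = make_head(
            scalp_radius=float(radii[i]),
            skull_offset=head_cfg["skull_offset"],
            brain_offset=head_cfg["brain_offset"],
            subdivision=head_cfg["subdivision"],
            perturbation=head_cfg["perturbation"],
            seed=head_seed,
            subject_id=f"S{i + 1:02d}",
        )
        space = make_source_space(
            head,
            n_candidates=cfg["source_space"]["n_candidates"],
            depth_range=tuple(cfg["source_space"]["depth_range"]),
            seed=space_seed,
        )
        sites, triads = place_opm_sites(
            head,
            footprint=tuple(cfg["opm"]["footprint"]),
            standoff=cfg["opm"]["standoff"],
            coverage_cap_angle=cfg["opm"]["cap_angle"],
            seed=sites_seed,
        )
        subjects.append(
            SubjectContext(
                index=i,
                head=head,
                source_space=space,
                opm_sites=sites,
                opm_triads=triads,
                squid_seed=squid_seed,
                sim_seed=sim_seed,
                fit_seed=fit_seed,
                cfg=cfg,
            )
        )
    return subjects


def _signal_bundle(subject: SubjectContext, array: SensorArray, n_samples: int, q: float):
    """Targets and their noise-free signal maps (C, T) for one subject."""
    targets = sample_target_dipoles(
        subject.source_space, n_samples, q=q, seed=subject.sim_seed
    )
    pos = np.array([d.position for d in targets])
    mom = np.array([d.moment for d in targets])
    signals = array_response(array, pos, mom, subject.head.sphere_center)
    return targets, signals


def _sample_metrics(
    subject: SubjectContext,
    array: SensorArray,
    targets,
    signals: np.ndarray,
    noises: np.ndarray,
    do_fit: bool,
    fit_options: FitOptions | None = None,
) -> pd.DataFrame:
    """Per-sample metric table for observed = signal + noise."""
    n_samples = signals.shape[1]
    opts = fit_options or subject.fit_options()
    rows = []
    for t in range(n_samples):
        sig = signals[:, t]
        noi = noises[:, t]
        obs = sig + noi
        rms_sig = rms(sig)
        rms_noi = rms(noi)
        snr = snr_db(rms_sig, rms_noi) if rms_noi > 0 else np.nan
        row = {
            "t": t,
            "rms_signal": rms_sig,
            "rms_noise": rms_noi,
            "snr_db": snr,
            "re": np.nan,
            "cc": np.nan,
            "d_sf": np.nan,
        }
        if do_fit:
            fr = fit_ecd(obs, array, subject.head, opts)
            row["re"] = fr.metrics.re
            row["cc"] = fr.metrics.cc
            row["d_sf"] = localization_error(targets[t], fr.dipole)
        rows.append(row)
    return pd.DataFrame(rows)


_METRIC_COLS = ["rms_signal", "rms_noise", "snr_db", "re", "cc", "d_sf"]


def aggregate_subjects(per_subject: pd.DataFrame, axes: list[str]) -> pd.DataFrame:
    """Across-subject mean and SD of the per-subject metric means for every
    (configuration, grid point).  Requires at least one subject; SD is the
    sample SD over subjects (ddof=1, 0 for a single subject)."""
    if per_subject.empty:
        raise ValueError("nothing to aggregate")
    keys = ["configuration", *axes]
    subject_sets = per_subject.groupby(keys)["subject"].agg(frozenset)
    if subject_sets.nunique() > 1:
        raise ValueError("mismatched grids: subjects do not share all grid points")
    agg = per_subject.groupby(keys)[_METRIC_COLS].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    std_cols = [c for c in agg.columns if c.endswith("_std")]
    if len(subject_sets.iloc[0]) == 1:
        agg[std_cols] = 0.0
    return agg.reset_index()


def _provenance(cfg: dict, master_seed: int) -> dict:
    return {"config_hash": config_hash(cfg), "master_seed": master_seed}


def _ambient_draws(spec_seed: int, n_channels: int, n_samples: int) -> np.ndarray:
    """Unit-variance ambient draws (C, T); scaled by sigma at use sites."""
    unit = NoiseSpec(sigma=1.0, seed=spec_seed)
    return np.column_stack(
        [ambient_noise(unit, n_channels, t).values for t in range(n_samples)]
    )


def _spont_draws(
    subject: SubjectContext, array: SensorArray, n_samples: int, n_noise_dipoles: int
) -> np.ndarray:
    """Spontaneous-noise maps (C, T) at unit dipole strength (1 A*m);
    scaled by q_spont at use sites."""
    unit = NoiseSpec(q_spont=1.0, n_noise_dipoles=n_noise_dipoles, seed=subject.sim_seed)
    return np.column_stack(
        [
            spontaneous_noise(
                unit, subject.source_space, array, subject.head.sphere_center, t
            ).values
            for t in range(n_samples)
        ]
    )


def run_baseline_rms(
    subjects: list[SubjectContext],
    configurations: tuple[str, ...] = tuple(OPM_CONFIGURATIONS)[:4] + SQUID_CONFIGURATIONS,
    n_samples: int | None = None,
    q: float | None = None,
) -> SweepResult:
    """Noise-free RMS_signal per configuration: per-sample RMS -> subject
    mean -> across-subject mean +/- SD."""
    cfg = subjects[0].cfg
    n_samples = n_samples or cfg["simulation"]["n_samples"]
    q = q if q is not None else cfg["simulation"]["q"]
    rows = []
    for s in subjects:
        for conf in configurations:
            arr = s.array(conf)
            _, signals = _signal_bundle(s, arr, n_samples, q)
            per = _sample_metrics(s, arr, None, signals, np.zeros_like(signals), do_fit=False)
            rows.append(
                {"configuration": conf, "subject": s.head.subject_id, "condition": "baseline"}
                | per[_METRIC_COLS].mean().to_dict()
            )
    per_subject = pd.DataFrame(rows)
    return SweepResult(
        axes={"condition": ["baseline"]},
        per_subject=per_subject,
        aggregate=aggregate_subjects(per_subject, ["condition"]),
        configurations=list(configurations),
        provenance=_provenance(cfg, subjects[0].sim_seed),
    )


def _noise_sweep(
    subjects: list[SubjectContext],
    configurations: tuple[str, ...],
    sigma_grid_fT: tuple[float, ...],
    q_spont_grid_nAm: tuple[float, ...],
    axes_mode: str,
    n_samples: int | None,
    q: float | None,
    do_fit: bool = True,
    keep_samples: bool = False,
) -> SweepResult:
    cfg = subjects[0].cfg
    n_samples = n_samples or cfg["simulation"]["n_samples"]
    q = q if q is not None else cfg["simulation"]["q"]
    n_noise = cfg["simulation"]["n_noise_dipoles"]
    rows = []
    sample_frames = []
    for s in subjects:
        for conf in configurations:
            arr = s.array(conf)
            targets, signals = _signal_bundle(s, arr, n_samples, q)
            xi = _ambient_draws(s.sim_seed, arr.n_channels, n_samples)
            spont1 = (
                _spont_draws(s, arr, n_samples, n_noise)
                if any(qs > 0 for qs in q_spont_grid_nAm)
                else np.zeros_like(signals)
            )
            for sigma_fT in sigma_grid_fT:
                for qs_nAm in q_spont_grid_nAm:
                    noises = sigma_fT * 1e-15 * xi + qs_nAm * 1e-9 * spont1
                    per = _sample_metrics(s, arr, targets, signals, noises, do_fit)
                    base = {"configuration": conf, "subject": s.head.subject_id}
                    if axes_mode in ("sigma", "grid"):
                        base["sigma_fT"] = sigma_fT
                    if axes_mode in ("q_spont", "grid"):
                        base["q_spont_nAm"] = qs_nAm
                    rows.append(base | per[_METRIC_COLS].mean().to_dict())
                    if keep_samples:
                        sample_frames.append(per.assign(**base))
    per_subject = pd.DataFrame(rows)
    axes_cols = {
        "sigma": ["sigma_fT"],
        "q_spont": ["q_spont_nAm"],
        "grid": ["sigma_fT", "q_spont_nAm"],
    }[axes_mode]
    axes = {}
    if "sigma_fT" in axes_cols:
        axes["sigma_fT"] = list(sigma_grid_fT)
    if "q_spont_nAm" in axes_cols:
        axes["q_spont_nAm"] = list(q_spont_grid_nAm)
    return SweepResult(
        axes=axes,
        per_subject=per_subject,
        aggregate=aggregate_subjects(per_subject, axes_cols),
        configurations=list(configurations),
        provenance=_provenance(cfg, subjects[0].sim_seed),
        per_sample=pd.concat(sample_frames, ignore_index=True) if keep_samples else None,
    )


def run_ambient_sweep(
    subjects: list[SubjectContext],
    sigma_grid_fT: tuple[float, ...] | None = None,
    configurations: tuple[str, ...] = tuple(OPM_CONFIGURATIONS)[:4],
    n_samples: int | None = None,
    q: float | None = None,
    keep_samples: bool = False,
) -> SweepResult:
    """Ambient-noise sweep (q_spont = 0): RE, CC, SNR, d_s,f vs sigma."""
    cfg = subjects[0].cfg
    grid_fT = sigma_grid_fT or cfg["sweeps"]["sigma_grid_fT"]
    return _noise_sweep(
        subjects,
        configurations,
        tuple(grid_fT),
        (0.0,),
        "sigma",
        n_samples,
        q,
        keep_samples=keep_samples,
    )


def run_spontaneous_sweep(
    subjects: list[SubjectContext],
    q_spont_grid_nAm: tuple[float, ...] | None = None,
    configurations: tuple[str, ...] = tuple(OPM_CONFIGURATIONS)[:4],
    n_samples: int | None = None,
    q: float | None = None,
    keep_samples: bool = False,
) -> SweepResult:
    """Spontaneous-brain-noise sweep (sigma = 0)."""
    cfg = subjects[0].cfg
    grid_nAm = q_spont_grid_nAm or cfg["sweeps"]["q_spont_grid_nAm"]
    return _noise_sweep(
        subjects,
        configurations,
        (0.0,),
        tuple(grid_nAm),
        "q_spont",
        n_samples,
        q,
        keep_samples=keep_samples,
    )


def run_noise_grid(
    subjects: list[SubjectContext],
    sigma_grid_fT: tuple[float, ...] | None = None,
    q_spont_grid_nAm: tuple[float, ...] | None = None,
    configurations: tuple[str, ...] = ("OPM-ALL", "OPM-NOR", "OPM-TAN-LAT", "OPM-TAN-LON"),
    n_samples: int | None = None,
    q: float | None = None,
) -> SweepResult:
    """d_s,f surface over the (sigma, q_spont) grid per configuration."""
    cfg = subjects[0].cfg
    s_grid = sigma_grid_fT or cfg["sweeps"]["sigma_grid_fT"]
    q_grid = q_spont_grid_nAm or cfg["sweeps"]["q_spont_grid_nAm"]
    return _noise_sweep(
        subjects,
        configurations,
        tuple(s_grid),
        tuple(q_grid),
        "grid",
        n_samples,
        q,
    )


def run_sensor_count_sweep(
    subjects: list[SubjectContext],
    fractions_removed: tuple[float, ...] | None = None,
    configurations: tuple[str, ...] = SINGLE_OPM + DUAL_OPM + ("OPM-ALL",),
    cases: tuple[tuple[float, float], ...] = ((75e-15, 0.0), (0.0, 3e-9)),
    n_samples: int | None = None,
    q: float | None = None,
) -> SweepResult:
    """d_s,f vs fraction of OPM sites removed, for the seven OPM variants
    under the two fixed noise cases (sigma, q_spont) in SI units.

    Sites are removed equidistantly (farthest-point retention) and
    identically across configurations of the same subject.
    """
    cfg = subjects[0].cfg
    fractions = fractions_removed or cfg["sweeps"]["fractions_removed"]
    n_samples = n_samples or cfg["simulation"]["n_samples"]
    q = q if q is not None else cfg["simulation"]["q"]
    n_noise = cfg["simulation"]["n_noise_dipoles"]
    rows = []
    for s in subjects:
        for conf in configurations:
            full = s.array(conf)
            for frac in fractions:
                arr = remove_sensors(full, frac, seed=s.sim_seed)
                targets, signals = _signal_bundle(s, arr, n_samples, q)
                xi = _ambient_draws(s.sim_seed, arr.n_channels, n_samples)
                need_spont = any(qs > 0 for _, qs in cases)
                spont1 = (
                    _spont_draws(s, arr, n_samples, n_noise)
                    if need_spont
                    else np.zeros_like(signals)
                )
                for sigma, qs in cases:
                    noises = sigma * xi + qs * spont1
                    per = _sample_metrics(s, arr, targets, signals, noises, do_fit=True)
                    rows.append(
                        {
                            "configuration": conf,
                            "subject": s.head.subject_id,
                            "fraction_removed": frac,
                            "percent_removed": 100.0 * frac,
                            "sigma_fT": round(sigma * 1e15, 9),
                            "q_spont_nAm": round(qs * 1e9, 9),
                            "n_sites": arr.n_sites,
                            "n_channels": arr.n_channels,
                        }
                        | per[_METRIC_COLS].mean().to_dict()
                    )
    per_subject = pd.DataFrame(rows)
    axes_cols = ["fraction_removed", "sigma_fT", "q_spont_nAm"]
    return SweepResult(
        axes={
            "fraction_removed": list(fractions),
            "cases": [(sig * 1e15, qs * 1e9) for sig, qs in cases],
        },
        per_subject=per_subject,
        aggregate=aggregate_subjects(per_subject, axes_cols),
        configurations=list(configurations),
        provenance=_provenance(cfg, subjects[0].sim_seed),
    )


def run_depth_sweep(
    subjects: list[SubjectContext],
    depth_grid_cm: tuple[float, ...] | None = None,
    dh_cm: float | None = None,
    configurations: tuple[str, ...] = tuple(OPM_CONFIGURATIONS)[:4] + SQUID_CONFIGURATIONS,
    cases: tuple[tuple[float, float], ...] = ((75e-15, 0.0), (0.0, 3e-9)),
    n_samples: int | None = None,
    q: float | None = None,
    deep_space_candidates: int = 2000,
    do_fit: bool = True,
) -> SweepResult:
    """RMS_signal, SNR, and d_s,f vs source depth h (bins h +/- dh).

    Target dipoles are drawn from a dedicated deep source space whose depth
    range spans all requested bins; bins with no candidates are reported
    and skipped.
    """
    cfg = subjects[0].cfg
    grid_cm = depth_grid_cm or cfg["sweeps"]["depth_grid_cm"]
    dh = (dh_cm if dh_cm is not None else cfg["sweeps"]["depth_halfwidth_cm"]) * 1e-2
    n_samples = n_samples or cfg["simulation"]["n_samples"]
    q = q if q is not None else cfg["simulation"]["q"]
    n_noise = cfg["simulation"]["n_noise_dipoles"]
    rows = []
    skipped = []
    for s in subjects:
        lo = min(grid_cm) * 1e-2 - dh
        hi = max(grid_cm) * 1e-2 + dh
        hi = min(hi, s.head.sphere_radius - 0.02)
        deep_space = make_source_space(
            s.head,
            n_candidates=deep_space_candidates,
            depth_range=(max(lo, 0.013), hi),
            seed=s.sim_seed,
        )
        for conf in configurations:
            arr = s.array(conf)
            opts = FitOptions(
                n_coarse=s.cfg["fit"]["n_coarse"],
                max_evaluations=s.cfg["fit"]["max_evaluations"],
                seed=s.fit_seed,
                source_space=deep_space,
            )
            for h_cm in grid_cm:
                h = h_cm * 1e-2
                try:
                    targets = sample_target_dipoles(
                        deep_space,
                        n_samples,
                        q=q,
                        depth_bin=(h, dh),
                        seed=np.random.SeedSequence(
                            [s.sim_seed, int(round(h_cm * 10))]
                        ).generate_state(1, dtype=np.uint32)[0] % 2**31,
                    )
                except ValueError:
                    skipped.append((s.head.subject_id, conf, h_cm))
                    continue
                pos = np.array([d.position for d in targets])
                mom = np.array([d.moment for d in targets])
                signals = array_response(arr, pos, mom, s.head.sphere_center)
                xi = _ambient_draws(s.sim_seed, arr.n_channels, n_samples)
                need_spont = any(qs > 0 for _, qs in cases)
                spont1 = (
                    _spont_draws(s, arr, n_samples, n_noise)
                    if need_spont
                    else np.zeros_like(signals)
                )
                for sigma, qs in cases:
                    noises = sigma * xi + qs * spont1
                    per = _sample_metrics(
                        s, arr, targets, signals, noises, do_fit=do_fit, fit_options=opts
                    )
                    rows.append(
                        {
                            "configuration": conf,
                            "subject": s.head.subject_id,
                            "h_cm": h_cm,
                            "sigma_fT": round(sigma * 1e15, 9),
                            "q_spont_nAm": round(qs * 1e9, 9),
                        }
                        | per[_METRIC_COLS].mean().to_dict()
                    )
    per_subject = pd.DataFrame(rows)
    axes_cols = ["h_cm", "sigma_fT", "q_spont_nAm"]
    # drop grid points not reachable for every subject (deep bins on small
    # heads); they are reported in provenance["skipped_bins"]
    all_subjects = {s.head.subject_id for s in subjects}
    complete = per_subject.groupby(["configuration", *axes_cols])["subject"].transform(
        lambda col: set(col) == all_subjects
    )
    incomplete = per_subject[~complete]
    for _, row in incomplete.iterrows():
        skipped.append((row["subject"], row["configuration"], row["h_cm"]))
    per_subject = per_subject[complete].reset_index(drop=True)
    if per_subject.empty:
        raise ValueError("no depth bin is reachable for all subjects")
    return SweepResult(
        axes={
            "h_cm": list(grid_cm),
            "cases": [(sig * 1e15, qs * 1e9) for sig, qs in cases],
        },
        per_subject=per_subject,
        aggregate=aggregate_subjects(per_subject, axes_cols),
        configurations=list(configurations),
        provenance=_provenance(cfg, subjects[0].sim_seed) | {"skipped_bins": skipped},
    )


# ---------------------------------------------------------------------------
# derived summary quantities


def component_matched_rms_ratios(baseline: SweepResult) -> dict[str, float]:
    """OPM / SQUID ratio of across-subject mean RMS_signal for each
    component-matched magnetometer pair, plus their mean."""
    agg = baseline.aggregate.set_index("configuration")["rms_signal_mean"]
    ratios = {opm: float(agg[opm] / agg[sq]) for opm, sq in MATCHED_PAIRS}
    ratios["mean"] = float(np.mean(list(ratios.values())))
    return ratios


def normal_tangential_rms_ratio(baseline: SweepResult) -> float:
    """RMS(OPM-NOR) over the mean RMS of the two tangential OPM
    configurations (across-subject means)."""
    agg = baseline.aggregate.set_index("configuration")["rms_signal_mean"]
    return float(agg["OPM-NOR"] / ((agg["OPM-TAN-LAT"] + agg["OPM-TAN-LON"]) / 2.0))


def deep_source_rms_ratio(
    subjects: list[SubjectContext],
    h_cm: float = 5.5,
    dh_cm: float = 0.5,
    n_samples: int = 100,
    q: float = 100e-9,
    deep_space_candidates: int = 1500,
) -> float:
    """Across-subject mean of the per-subject OPM-NOR / SQUID-NOR noise-free
    RMS ratio for sources in the depth bin h +/- dh."""
    ratios = []
    for s in subjects:
        hi = min((h_cm + dh_cm) * 1e-2, s.head.sphere_radius - 0.02)
        deep_space = make_source_space(
            s.head,
            n_candidates=deep_space_candidates,
            depth_range=((h_cm - dh_cm) * 1e-2, hi),
            seed=s.sim_seed,
        )
        targets = sample_target_dipoles(deep_space, n_samples, q=q, seed=s.sim_seed)
        pos = np.array([d.position for d in targets])
        mom = np.array([d.moment for d in targets])
        vals = {}
        for conf in ("OPM-NOR", "SQUID-NOR"):
            arr = s.array(conf)
            resp = array_response(arr, pos, mom, s.head.sphere_center)
            vals[conf] = np.mean([rms(resp[:, t]) for t in range(n_samples)])
        ratios.append(vals["OPM-NOR"] / vals["SQUID-NOR"])
    return float(np.mean(ratios))
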