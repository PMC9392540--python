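"""Synthetic desk-scale cohort: phantom tractograms, lesions and behavior.

The generator emulates the shape of a ~100-subject stroke cohort analyzed
against normative tractography:

* a small template grid (32^3 voxels at 2 mm isotropic);
* two phantom fiber bundles (tubes around smooth polylines), one of which
  is the *target* whose disconnection drives cognition;
* N normative "controls", each a jittered copy of the bundles;
* spherical lesions of widely varying size, a fraction of them centered
  on the target bundle;
* a 0-30 integer cognitive score (MoCA-like) generated as
  ``clip(round(baseline - beta * d_i + noise), 0, 30)`` where ``d_i`` is
  the subject's mean disconnection over the target footprint;
* age / sex / stroke-phase covariates moment-matched to a typical elderly
  stroke sample, and a computerized battery available in an 80% subsample
  whose subtests load negatively on target disconnection.

Everything is deterministic from a single master seed via hierarchical
sub-seeds, and the generator returns its own ground truth (target
footprint, per-subject true disconnection) for recovery tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .disconnectome import DisconnectomeMap, disconnectome_batch
from .tractography import (
    Tractogram,
    default_step,
    resample_streamline,
    visitation_map,
    write_tractogram,
)
from .volumes import ImageVolume, LesionMask, lesion_summary, write_volume

log = logging.getLogger(__name__)

__all__ = [
    "BundleSpec",
    "PhantomSpec",
    "EffectSpec",
    "GroundTruth",
    "SyntheticCohort",
    "make_grid",
    "make_controls",
    "make_lesions",
    "make_behavior",
    "generate_cohort",
    "write_cohort",
    "verify_manifest",
]


@dataclasses.dataclass
class BundleSpec:
    """One phantom bundle: a tube of streamlines around a polyline."""

    name: str
    control_points: np.ndarray      # (K, 3) world mm
    radius_mm: float = 3.0
    n_streamlines: int = 60


def _default_bundles() -> list[BundleSpec]:
    # both bundles sit well inside the default 64 mm world box, with margin
    # for the tube radius plus 3 SD of jitter
    return [
        BundleSpec(
            "target",
            np.array(
                [
                    [12.0, 16.0, 30.0],
                    [22.0, 26.0, 36.0],
                    [32.0, 36.0, 38.0],
                    [44.0, 44.0, 34.0],
                    [52.0, 48.0, 30.0],
                ]
            ),
        ),
        BundleSpec(
            "off_target",
            np.array(
                [
                    [14.0, 50.0, 16.0],
                    [26.0, 44.0, 20.0],
                    [38.0, 32.0, 22.0],
                    [50.0, 18.0, 18.0],
                ]
            ),
        ),
    ]


@dataclasses.dataclass
class PhantomSpec:
    """Grid geometry and normative-tractogram phantom parameters."""

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 2.0
    bundles: list[BundleSpec] = dataclasses.field(default_factory=_default_bundles)
    n_controls: int = 20
    control_jitter_mm: float = 0.5     # whole-bundle offset SD per control
    streamline_jitter_mm: float = 0.25  # per-streamline offset SD

    def __post_init__(self) -> None:
        for b in self.bundles:
            if b.radius_mm <= self.voxel_size_mm / 2:
                raise ValueError(
                    f"bundle {b.name!r}: tube radius must exceed half a voxel"
                )


@dataclasses.dataclass
class EffectSpec:
    """Planted disconnection -> cognition effect.

    ``beta`` is points of cognitive score lost per unit mean disconnection
    of the target footprint (disconnection is a proportion in [0, 1], so
    beta=10 means a fully disconnected target costs 10 of 30 points).
    """

    target_bundle: str = "target"
    beta: float = 10.0
    noise_sd: float = 2.0
    baseline: float = 28.5
    battery_loadings: dict = dataclasses.field(
        default_factory=lambda: {
            "fluency_phonetic": 2.5,
            "fluency_semantic": 2.5,
            "attention_span": 2.0,
            "working_memory": 2.0,
            "psychomotor_speed": 1.8,
            "spatial_memory": 1.8,
            "motor_speed_dominant": 1.2,
            "motor_speed_nondominant": 1.2,
        }
    )
    battery_noise_sd: float = 1.0
    subsample_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline <= 30.0:
            raise ValueError("baseline score must be within the 0-30 scale")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """Generator-side truth used by recovery tests."""

    footprints: dict                  # bundle name -> binary ImageVolume
    target_bundle: str
    d: np.ndarray                     # per-subject true mean target disconnection
    on_target: np.ndarray             # bool, lesion centered on target bundle
    seed: int


@dataclasses.dataclass
class SyntheticCohort:
    grid: ImageVolume
    controls: list[Tractogram]
    lesions: list[LesionMask]
    maps: list[DisconnectomeMap]
    behavior: pd.DataFrame
    truth: GroundTruth
    spec: PhantomSpec
    effect: EffectSpec
    seed: int


def make_grid(spec: PhantomSpec) -> ImageVolume:
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    return ImageVolume(np.zeros(spec.shape, dtype=np.float32), affine)


def _world_bounds(grid: ImageVolume) -> tuple[np.ndarray, np.ndarray]:
    half = grid.voxel_sizes / 2
    lo = grid.affine[:3, 3] - half
    hi = grid.affine[:3, :3] @ (np.asarray(grid.shape) - 1) + grid.affine[:3, 3] + half
    return lo, hi


def _unit_ball(rng: np.random.Generator, n: int) -> np.ndarray:
    """n points uniform in the unit ball."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(size=(n, 1)) ** (1 / 3)
    return v * r


def make_controls(
    spec: PhantomSpec, seed: int
) -> tuple[list[Tractogram], dict]:
    """Phantom normative tractograms plus per-bundle noise-free footprints.

    Each bundle is a fixed fan of ``n_streamlines`` parallel offsets of
    its polyline within the tube radius; controls add a bundle-level and a
    streamline-level random translation. The footprint is the visitation
    map of the noise-free fan.
    """
    grid = make_grid(spec)
    lo, hi = _world_bounds(grid)
    jitter3 = 3 * (spec.control_jitter_mm + spec.streamline_jitter_mm)
    ss = np.random.SeedSequence(seed)
    base_ss, controls_ss = ss.spawn(2)
    base_rng = np.random.default_rng(base_ss)
    step = default_step(grid)

    base_fans: dict[str, list[np.ndarray]] = {}
    for b in spec.bundles:
        margin = b.radius_mm + jitter3
        if np.any(b.control_points.min(0) - margin < lo) or np.any(
            b.control_points.max(0) + margin > hi
        ):
            raise ValueError(
                f"bundle {b.name!r} escapes the grid after jitter at 3 SD"
            )
        poly = resample_streamline(b.control_points, 2.0)
        offsets = _unit_ball(base_rng, b.n_streamlines) * b.radius_mm
        base_fans[b.name] = [poly + off for off in offsets]

    footprints = {
        name: visitation_map(fan, grid, step) for name, fan in base_fans.items()
    }

    controls: list[Tractogram] = []
    for c, c_ss in enumerate(controls_ss.spawn(spec.n_controls)):
        rng = np.random.default_rng(c_ss)
        streamlines = []
        for b in spec.bundles:
            bundle_off = rng.normal(0, spec.control_jitter_mm, size=3)
            for base_sl in base_fans[b.name]:
                sl_off = rng.normal(0, spec.streamline_jitter_mm, size=3)
                streamlines.append(base_sl + bundle_off + sl_off)
        controls.append(Tractogram(streamlines, control_id=f"control-{c:03d}"))
    return controls, footprints


def make_lesions(
    spec: PhantomSpec,
    n_subjects: int,
    on_target_fraction: float = 0.3,
    radius_range_mm: tuple[float, float] = (2.0, 8.0),
    seed: int = 0,
) -> tuple[list[LesionMask], np.ndarray]:
    """Spherical lesions (1-3 spheres each), log-uniform radii.

    A fraction of subjects get their primary sphere centered on a random
    point of the target bundle's polyline; the rest land uniformly in the
    grid interior. Returns the masks and the on-target indicator.
    """
    if not 0.0 <= on_target_fraction <= 1.0:
        raise ValueError("on_target_fraction must be in [0, 1]")
    if n_subjects == 0:
        return [], np.zeros(0, dtype=bool)
    grid = make_grid(spec)
    lo, hi = _world_bounds(grid)
    if radius_range_mm[1] >= min(hi - lo) / 2:
        raise ValueError("lesion radius exceeds half the grid extent")
    by_name = {b.name: b for b in spec.bundles}
    target = by_name.get("target", spec.bundles[0])
    target_poly = resample_streamline(target.control_points, 1.0)

    idx = np.indices(grid.shape).reshape(3, -1).T.astype(float)
    centers_world = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]

    ss = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(ss.spawn(1)[0])
    n_on = int(round(on_target_fraction * n_subjects))
    on_target = np.zeros(n_subjects, dtype=bool)
    on_target[assign_rng.permutation(n_subjects)[:n_on]] = True

    lesions: list[LesionMask] = []
    for i, s_ss in enumerate(np.random.SeedSequence(seed).spawn(n_subjects + 1)[1:]):
        rng = np.random.default_rng(s_ss)
        n_spheres = int(rng.integers(1, 4))
        mask = np.zeros(int(np.prod(grid.shape)), dtype=np.uint8)
        for sph in range(n_spheres):
            radius = float(
                np.exp(rng.uniform(np.log(radius_range_mm[0]),
                                   np.log(radius_range_mm[1])))
            )
            if sph == 0 and on_target[i]:
                center = target_poly[rng.integers(len(target_poly))] + rng.normal(
                    0, 1.0, size=3
                )
            else:
                center = rng.uniform(lo + radius, hi - radius)
            inside = np.linalg.norm(centers_world - center, axis=1) <= radius
            mask[inside] = 1
        if not mask.any():  # can only happen for a sphere straddling the edge
            nearest = np.argmin(np.linalg.norm(centers_world - center, axis=1))
            mask[nearest] = 1
        lesions.append(
            LesionMask(grid.like(mask.reshape(grid.shape)), f"sub-{i + 1:03d}")
        )
    return lesions, on_target


# Table-1-like marginals of the emulated cohort
_AGE_MEAN, _AGE_SD = 66.3, 12.3
_P_FEMALE = 0.255
_GROUP_P = {"acute": 20 / 102, "subacute": 25 / 102, "chronic": 57 / 102}
_GROUP_DAYS = {"acute": (1, 6), "subacute": (7, 180), "chronic": (181, 1399)}


def make_behavior(
    maps: list[DisconnectomeMap],
    truth: GroundTruth,
    eff: EffectSpec,
    seed: int,
    lesions: list[LesionMask] | None = None,
) -> pd.DataFrame:
    """Cohort behavior table with the planted cognition effect.

    MoCA is ``clip(round(baseline - beta * d_i + eps), 0, 30)``; battery
    subtests are ``loading * (-d_i) + noise`` and present only in the
    subsample; phase groups are drawn from onset-day intervals using the
    7/180-day thresholds.
    """
    n = len(maps)
    footprint = truth.footprints[truth.target_bundle].data > 0
    d = np.array([float(m.data[footprint].mean()) for m in maps])
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    moca = np.clip(
        np.round(eff.baseline - eff.beta * d + rng.normal(0, eff.noise_sd, n)),
        0, 30,
    ).astype(int)
    age = np.clip(np.round(rng.normal(_AGE_MEAN, _AGE_SD, n)), 24, 95).astype(int)
    female = (rng.uniform(size=n) < _P_FEMALE).astype(int)
    groups = rng.choice(list(_GROUP_P), p=list(_GROUP_P.values()), size=n)
    days = np.array(
        [int(rng.integers(_GROUP_DAYS[g][0], _GROUP_DAYS[g][1] + 1)) for g in groups]
    )

    tab = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in maps],
            "age": age,
            "female": female,
            "moca": moca,
            "group": groups,
            "days_since_stroke": days,
        }
    )
    if lesions is not None:
        summaries = [lesion_summary(l) for l in lesions]
        tab["lesion_volume"] = [s["volume_mm3"] for s in summaries]
        tab["n_lesions"] = [s["n_components"] for s in summaries]

    n_battery = int(round(eff.subsample_fraction * n))
    has_battery = np.zeros(n, dtype=bool)
    has_battery[rng.permutation(n)[:n_battery]] = True
    for name, loading in eff.battery_loadings.items():
        score = loading * (-d) + rng.normal(0, eff.battery_noise_sd, n)
        tab[name] = np.where(has_battery, score, np.nan)
    truth.d = d
    return tab


def generate_cohort(
    spec: PhantomSpec | None = None,
    effect: EffectSpec | None = None,
    n_subjects: int = 102,
    on_target_fraction: float = 0.3,
    seed: int = 0,
) -> SyntheticCohort:
    """End-to-end synthetic cohort from one master seed.

    The defaults mirror the emulated study: 102 subjects, identity
    contrasts over (female, age, MoCA), an 80% battery subsample — but at
    desk scale (32^3 grid, 20 normative controls).
    """
    spec = spec or PhantomSpec()
    effect = effect or EffectSpec()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    controls, footprints = make_controls(spec, seeds[0])
    lesions, on_target = make_lesions(
        spec, n_subjects, on_target_fraction=on_target_fraction, seed=seeds[1]
    )
    grid = make_grid(spec)
    maps, errors = disconnectome_batch(lesions, controls, grid=grid)
    if errors:
        raise RuntimeError(f"synthetic disconnectome failures: {errors}")
    truth = GroundTruth(
        footprints=footprints,
        target_bundle=effect.target_bundle,
        d=np.zeros(n_subjects),
        on_target=on_target,
        seed=seed,
    )
    behavior = make_behavior(maps, truth, effect, seeds[2], lesions=lesions)
    return SyntheticCohort(
        grid=grid,
        controls=controls,
        lesions=lesions,
        maps=maps,
        behavior=behavior,
        truth=truth,
        spec=spec,
        effect=effect,
        seed=seed,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(outdir: str | Path, cohort: SyntheticCohort) -> Path:
    """Write lesions (NIfTI), controls (TCK), behavior (TSV) and ground
    truth, plus a manifest with SHA-256 of every file.

    Uncompressed NIfTI is used so regeneration from the same seed is
    byte-identical (gzip embeds metadata that breaks bit reproducibility).
    """
    out = Path(outdir)
    (out / "lesions").mkdir(parents=True, exist_ok=True)
    (out / "controls").mkdir(exist_ok=True)
    (out / "footprints").mkdir(exist_ok=True)
    files: list[Path] = []
    for lesion in cohort.lesions:
        p = out / "lesions" / f"{lesion.subject_id}_lesion.nii"
        write_volume(lesion.volume, p)
        files.append(p)
    for tg in cohort.controls:
        p = out / "controls" / f"{tg.control_id}.tck"
        write_tractogram(tg, p)
        files.append(p)
    for name, vol in cohort.truth.footprints.items():
        p = out / "footprints" / f"{name}_footprint.nii"
        write_volume(vol, p)
        files.append(p)
    p = out / "behavior.tsv"
    cohort.behavior.to_csv(p, sep="\t", index=False)
    files.append(p)
    p = out / "ground_truth.json"
    p.write_text(
        json.dumps(
            {
                "target_bundle": cohort.truth.target_bundle,
                "d": [float(x) for x in cohort.truth.d],
                "on_target": [bool(x) for x in cohort.truth.on_target],
                "seed": cohort.seed,
                "n_controls": cohort.spec.n_controls,
                "n_subjects": len(cohort.lesions),
            },
            indent=2,
            sort_keys=True,
        )
    )
    files.append(p)
    manifest = {
        "seed": cohort.seed,
        "files": {str(f.relative_to(out)): _sha256(f) for f in sorted(files)},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def verify_manifest(outdir: str | Path) -> None:
    """Raise if any file listed in the manifest is missing or altered."""
    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    for rel, digest in manifest["files"].items():
        p = out / rel
        if not p.exists():
            raise FileNotFoundError(f"manifest file missing: {rel}")
        if _sha256(p) != digest:
            raise ValueError(f"manifest hash mismatch (file altered): {rel}")
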