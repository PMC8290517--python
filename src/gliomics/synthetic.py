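"""Seeded phantom cohorts emulating a WHO grade II glioma MRI study.

Real multi-sequence MR images of the modeled cohort are not publicly
deposited, so this module generates phantoms that preserve the study's
structure: two classes (1p/19q codeletion n=65, non-codeletion n=92 by
default), three aligned MRI-like channels (T1WI, T2WI, CE-T1WI) per subject,
an ellipsoidal tumor mask whose volume follows a truncated normal law
(59.87 ± 52.74 cm³), and clinical covariates (age 41.6 ± 10.4 years drawn
identically for both classes, sex, IDH status).

The class contrast is textural: tumor interiors are filled with Gaussian
random fields, and codeletion tumors are sampled from a spatially rougher
field (shorter correlation length, heavier-tailed gray levels) than
non-codeletion tumors. Oligodendrogliomas (codeleted) show lower intratumoral
homogeneity than astrocytomas on MRI, and correlation length directly
controls the homogeneity-type texture features downstream. The single knob
``homogeneity_gap`` scales this contrast; at 0 the two classes are drawn from
the identical distribution.

The three channels share one spatial field with channel-specific gain,
offset and noise, so multi-sequence features are correlated but not
identical — mimicking real multi-sequence redundancy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import InfeasibleGeometryError, InvalidSpecError
from .grids import MaskGrid, VolumeGrid

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "sample_tumor_mask",
    "generate_cohort",
    "clinical_table",
    "planted_feature_table",
]

#: channel-specific (gain, offset) applied to the shared tumor texture field,
#: loosely following typical LGG appearance (T2 bright, T1 dark, mild enhancement)
_CHANNEL_MIX = {"T1WI": (-0.8, -0.3), "T2WI": (1.2, 0.8), "CE-T1WI": (0.6, 0.2)}
_CHANNEL_NOISE_SD = 0.15
_BASE_CORRELATION_MM = 2.0  # texture correlation length shared by both classes at gap 0


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for one phantom cohort.

    Defaults reproduce the modeled study's composition: 65 codeleted and 92
    non-codeleted subjects (16 of the latter IDH-wildtype), tumor volumes
    59.87 ± 52.74 cm³ truncated to the feasible range of the image grid,
    ages 41.6 ± 10.4 years with no class difference.
    """

    n_codel: int = 65
    n_noncodel: int = 92
    image_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    volume_mean_cm3: float = 59.87
    volume_sd_cm3: float = 52.74
    age_mean_y: float = 41.6
    age_sd_y: float = 10.4
    homogeneity_gap: float = 1.0
    idh_wildtype_fraction_noncodel: float = 16 / 92
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codel <= 0 or self.n_noncodel <= 0:
            raise InvalidSpecError("class counts must be positive")
        if len(self.image_shape) != 3 or any(s <= 0 for s in self.image_shape):
            raise InvalidSpecError(f"invalid image shape {self.image_shape}")
        if self.voxel_size_mm <= 0:
            raise InvalidSpecError("voxel size must be positive")
        if self.homogeneity_gap < 0:
            raise InvalidSpecError("homogeneity_gap must be >= 0")
        if not 0 <= self.idh_wildtype_fraction_noncodel <= 1:
            raise InvalidSpecError("idh_wildtype_fraction_noncodel must be in [0, 1]")


@dataclass
class SubjectRecord:
    """One phantom subject: clinical covariates plus image references.

    ``channels``/``mask`` hold in-memory grids; when the cohort is written to
    disk the ``*_path`` fields point at the NIfTI files instead.
    """

    subject_id: str
    age_y: float
    sex: str  # "male" | "female"
    idh: str  # "mutant" | "wildtype"
    label_1p19q: int  # codeletion=1, non-codeletion=0
    channels: dict[str, VolumeGrid] | None = None
    mask: MaskGrid | None = None
    channel_paths: dict[str, str] | None = None
    mask_path: str | None = None

    def __post_init__(self) -> None:
        # WHO 2016: codeletion defines oligodendroglioma, which is IDH-mutant
        if self.label_1p19q == 1 and self.idh != "mutant":
            raise InvalidSpecError("codeleted subjects must be IDH-mutant")


def sample_tumor_mask(
    shape: tuple[int, int, int],
    voxel_size_mm: float,
    target_volume_cm3: float,
    rng: np.random.Generator,
    axis_ratios: tuple[float, float, float] | None = None,
) -> MaskGrid:
    """Draw a connected ellipsoidal tumor mask of approximately the target volume.

    Axis ratios are drawn uniformly in [0.7, 1.3] unless given; the ellipsoid
    is scaled so its analytic volume matches the target and placed uniformly
    at random wherever it fits with a one-voxel margin. The realized
    (voxelized) volume is within 10% of the target for tumors >= ~0.5 cm³.
    """
    if target_volume_cm3 <= 0:
        raise InfeasibleGeometryError("target volume must be positive")
    shape = tuple(int(s) for s in shape)
    if axis_ratios is None:
        axis_ratios = tuple(rng.uniform(0.7, 1.3, size=3))
    u = np.asarray(axis_ratios, dtype=float)
    target_vox = target_volume_cm3 * 1000.0 / voxel_size_mm**3
    r = (3.0 * target_vox / (4.0 * np.pi * np.prod(u))) ** (1.0 / 3.0)
    radii = r * u  # in voxels
    limits = np.asarray(shape) / 2.0 - 1.0
    if np.any(radii > limits):
        raise InfeasibleGeometryError(
            f"ellipsoid radii {np.round(radii, 1)} vox exceed grid {shape}"
        )
    lo = np.ceil(radii + 0.5)
    hi = np.asarray(shape) - 1 - np.ceil(radii + 0.5)
    center = np.array([rng.uniform(l, h) if h > l else (l + h) / 2 for l, h in zip(lo, hi)])
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    q = sum(((g - c) / rad) ** 2 for g, c, rad in zip(grids, center, radii))
    mask = (q <= 1.0).astype(np.uint8)
    if mask.sum() == 0:
        raise InfeasibleGeometryError("target volume below one voxel")
    return MaskGrid(mask, (voxel_size_mm,) * 3, (0.0, 0.0, 0.0))


def _texture_field(
    shape: tuple[int, int, int],
    correlation_mm: float,
    voxel_mm: float,
    tail_weight: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Standardized Gaussian random field; tail_weight > 0 heavies the gray-level tail."""
    g = ndimage.gaussian_filter(rng.standard_normal(shape), correlation_mm / voxel_mm)
    g = (g - g.mean()) / g.std()
    if tail_weight > 0:
        g = g + tail_weight * g**3
        g = (g - g.mean()) / g.std()
    return g


def _class_texture_params(homogeneity_gap: float, codeleted: bool) -> tuple[float, float]:
    """(correlation length mm, tail weight) for one class at the given gap."""
    scale = 1.0 + 0.5 * homogeneity_gap
    if codeleted:  # rougher: shorter correlation, heavier tail
        return _BASE_CORRELATION_MM / scale, 0.15 * homogeneity_gap
    return _BASE_CORRELATION_MM * scale, 0.0


def _brain_background(shape, voxel_mm, rng) -> tuple[np.ndarray, np.ndarray]:
    """Smooth nonzero 'brain' ellipsoid on a zero exterior."""
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    center = [(s - 1) / 2 for s in shape]
    radii = [0.48 * s for s in shape]
    brain = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)) <= 1.0
    slow = ndimage.gaussian_filter(rng.standard_normal(shape), 6.0 / voxel_mm)
    slow = (slow - slow.mean()) / slow.std()
    bg = np.where(brain, 1.0 + 0.1 * slow, 0.0)
    return bg, brain


def _render_subject(
    spec: CohortSpec, codeleted: bool, rng: np.random.Generator
) -> tuple[dict[str, VolumeGrid], MaskGrid]:
    vx = spec.voxel_size_mm
    # tumor volume: one truncated-normal law for both classes, capped by geometry
    ratios = tuple(rng.uniform(0.7, 1.3, size=3))
    u = np.asarray(ratios)
    limits = np.asarray(spec.image_shape) / 2.0 - 1.5
    r_cap = float(np.min(limits / u))
    v_cap = 4.0 / 3.0 * np.pi * r_cap**3 * float(np.prod(u)) * vx**3 / 1000.0
    v_lo = min(2.0, 0.5 * v_cap)
    if v_cap <= v_lo:
        raise InfeasibleGeometryError("image too small for any feasible tumor volume")
    a = (v_lo - spec.volume_mean_cm3) / spec.volume_sd_cm3
    b = (v_cap - spec.volume_mean_cm3) / spec.volume_sd_cm3
    vol = float(
        stats.truncnorm.ppf(
            rng.uniform(), a, b, loc=spec.volume_mean_cm3, scale=spec.volume_sd_cm3
        )
    )
    mask = sample_tumor_mask(spec.image_shape, vx, vol, rng, axis_ratios=ratios)

    corr_mm, tail = _class_texture_params(spec.homogeneity_gap, codeleted)
    field = _texture_field(spec.image_shape, corr_mm, vx, tail, rng)
    bg, brain = _brain_background(spec.image_shape, vx, rng)
    inside = mask.values.astype(bool)

    channels: dict[str, VolumeGrid] = {}
    for name, (gain, offset) in _CHANNEL_MIX.items():
        img = bg.copy()
        img[inside] = 1.0 + offset + gain * 0.35 * field[inside]
        img[brain] += _CHANNEL_NOISE_SD * rng.standard_normal(int(brain.sum()))
        img[~brain] = 0.0
        channels[name] = VolumeGrid(img, (vx,) * 3, (0.0, 0.0, 0.0))
    return channels, mask


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> list[SubjectRecord]:
    """Generate the full phantom cohort, deterministically for a given seed.

    With ``out_dir`` set, volumes and masks are written as NIfTI-1 (.nii.gz),
    a ``clinical.csv`` table is written alongside, and each record carries
    file paths; otherwise grids stay in memory on the records.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_codel + spec.n_noncodel
    labels = np.array([1] * spec.n_codel + [0] * spec.n_noncodel)
    n_wt = int(round(spec.idh_wildtype_fraction_noncodel * spec.n_noncodel))
    idh_flags = ["mutant"] * spec.n_codel + ["wildtype"] * n_wt + ["mutant"] * (
        spec.n_noncodel - n_wt
    )
    records: list[SubjectRecord] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i in range(n_total):
        label = int(labels[i])
        channels, mask = _render_subject(spec, codeleted=bool(label), rng=rng)
        rec = SubjectRecord(
            subject_id=f"S{i + 1:03d}",
            age_y=float(rng.normal(spec.age_mean_y, spec.age_sd_y)),
            sex="female" if rng.uniform() < 73 / 157 else "male",
            idh=idh_flags[i],
            label_1p19q=label,
            channels=channels,
            mask=mask,
        )
        if out_path is not None:
            paths = {}
            for name, vol in rec.channels.items():
                p = out_path / f"{rec.subject_id}_{name.replace('-', '')}.nii.gz"
                vol.save(p)
                paths[name] = str(p)
            mp = out_path / f"{rec.subject_id}_mask.nii.gz"
            rec.mask.save(mp)
            rec.channel_paths, rec.mask_path = paths, str(mp)
        records.append(rec)
    if out_path is not None:
        clinical_table(records).to_csv(out_path / "clinical.csv", index=False)
    return records


def clinical_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Clinical covariates of a cohort as one row per subject."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "age": [r.age_y for r in records],
            "sex": [r.sex for r in records],
            "idh": [r.idh for r in records],
            "label_1p19q": [r.label_1p19q for r in records],
        }
    )


def planted_feature_table(
    n_codel: int = 65,
    n_noncodel: int = 92,
    n_signal: int = 6,
    n_noise: int = 194,
    effect_size: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Tabular analogue of the phantom cohort with known ground truth.

    Exactly ``n_signal`` feature columns carry a class mean shift of
    ``effect_size`` standard deviations; the rest are pure noise. Age is drawn
    from one law for both classes and sex is a Bernoulli indicator, mirroring
    the image cohort's covariates. Used for selection/recovery calibration
    where the discriminative columns must be known exactly.

    Returns (features, labels, idh flags) indexed by subject id.
    """
    rng = np.random.default_rng(seed)
    n = n_codel + n_noncodel
    y = np.array([1] * n_codel + [0] * n_noncodel)
    X = rng.standard_normal((n, n_signal + n_noise))
    X[:, :n_signal] += effect_size * y[:, None]
    cols = [f"signal_{i + 1}" for i in range(n_signal)] + [
        f"noise_{j + 1}" for j in range(n_noise)
    ]
    idx = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="subject_id")
    df = pd.DataFrame(X, columns=cols, index=idx)
    df["age"] = rng.normal(41.6, 10.4, size=n)
    df["sex_female"] = (rng.uniform(size=n) < 73 / 157).astype(float)
    n_wt = int(round(16 / 92 * n_noncodel))
    idh = np.array(["mutant"] * n_codel + ["wildtype"] * n_wt + ["mutant"] * (n_noncodel - n_wt))
    return df, pd.Series(y, index=idx, name="label_1p19q"), pd.Series(idh, index=idx, name="idh")


def cohort_spec_with(spec: CohortSpec, **updates) -> CohortSpec:
    """Return a copy of a spec with the given fields replaced."""
    return dataclasses.replace(spec, **updates)
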