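"""Per-subject feature assembly: 431 features x 3 sequences + age + sex.

Feature naming follows ``<SEQ>_Group <k>_<Feature Name>[_<band>]`` with
SEQ in {T1WI, T2WI, CE-T1WI}; the band suffix (1..8, see
:data:`~gliomics.features.wavelet.BAND_ORDER`) applies to Group 4 only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import MissingInputError
from ..preprocess import preprocess_subject
from .discretize import DiscretizationConfig
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import GLCM_NAMES, GLRLM_NAMES, RoiTextureContext, glcm_features, glrlm_features
from .wavelet import wavelet_features

__all__ = [
    "SEQUENCES",
    "GROUP_SIZES",
    "FEATURES_PER_SEQUENCE",
    "sequence_features",
    "extract_all",
    "extract_cohort",
]

SEQUENCES = ("T1WI", "T2WI", "CE-T1WI")
GROUP_SIZES = {1: 14, 2: 8, 3: 33, 4: 376}
FEATURES_PER_SEQUENCE = sum(GROUP_SIZES.values())  # 431


def sequence_features(
    volume,
    mask,
    cfg: DiscretizationConfig | None = None,
    ctx: RoiTextureContext | None = None,
    wavelet_family: str = "coif1",
) -> dict[str, float]:
    """The 431 radiomic features of one sequence, names without the SEQ prefix."""
    cfg = cfg or DiscretizationConfig()
    ctx = ctx or RoiTextureContext(mask.values)
    out: dict[str, float] = {}
    for name, val in first_order_features(volume, mask, cfg).items():
        out[f"Group 1_{name}"] = val
    for name, val in shape_features(mask).items():
        out[f"Group 2_{name}"] = val
    for name, val in glcm_features(volume, mask, cfg, ctx).items():
        out[f"Group 3_{name}"] = val
    for name, val in glrlm_features(volume, mask, cfg, ctx).items():
        out[f"Group 3_{name}"] = val
    for name, val in wavelet_features(volume, mask, cfg, ctx, wavelet_family).items():
        out[f"Group 4_{name}"] = val
    assert len(out) == FEATURES_PER_SEQUENCE
    return out


def extract_all(
    subject,
    cfg: DiscretizationConfig | None = None,
    wavelet_family: str = "coif1",
    preprocess: bool = True,
    target_mm: float = 1.0,
) -> dict[str, float]:
    """All 1,293 radiomic features of a subject plus age and sex indicator.

    Channels must be voxel-aligned to the mask. With ``preprocess=True`` the
    volumes are resliced to isotropic spacing and z-score normalized first.
    """
    from ..grids import load_mask, load_volume  # lazy: only needed for path records

    channels = subject.channels
    mask = subject.mask
    if channels is None:
        if subject.channel_paths is None:
            raise MissingInputError("subject has neither in-memory channels nor paths")
        channels = {k: load_volume(p) for k, p in subject.channel_paths.items()}
        mask = load_mask(subject.mask_path)
    for seq in SEQUENCES:
        if seq not in channels:
            raise MissingInputError(f"missing channel {seq}")
    if preprocess:
        channels, mask = preprocess_subject(channels, mask, target_mm)
    cfg = cfg or DiscretizationConfig()
    ctx = RoiTextureContext(mask.values)
    out: dict[str, float] = {}
    for seq in SEQUENCES:
        for name, val in sequence_features(channels[seq], mask, cfg, ctx, wavelet_family).items():
            out[f"{seq}_{name}"] = val
    out["age"] = float(subject.age_y)
    out["sex_female"] = 1.0 if subject.sex == "female" else 0.0
    return out


def extract_cohort(
    records,
    cfg: DiscretizationConfig | None = None,
    wavelet_family: str = "coif1",
    preprocess: bool = True,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Feature table for a cohort: (features, 1p/19q labels, IDH flags).

    The returned frame has one row per subject and 1,295 columns
    (1,293 radiomic + age + sex_female), with no missing values.
    """
    rows = [extract_all(r, cfg, wavelet_family, preprocess) for r in records]
    idx = pd.Index([r.subject_id for r in records], name="subject_id")
    df = pd.DataFrame(rows, index=idx)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise MissingInputError(f"non-finite features: {bad[:5]}...")
    labels = pd.Series([r.label_1p19q for r in records], index=idx, name="label_1p19q")
    idh = pd.Series([r.idh for r in records], index=idx, name="idh")
    return df, labels, idh
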