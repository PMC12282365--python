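"""Assembly of the per-point feature table from a study.

Runs preprocessing (channel band-pass), functional and time-frequency feature
extraction per point, then per-map spatial gradients of the extracted
activation/repolarization annotations, and attaches the one-hot map-type
indicator covariates.  Output columns follow the feature registry exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core_model import MAP_TYPE_COLUMNS, Rhythm, Study, build_registry
from .features_functional import functional_features
from .features_spatial import spatial_gradient
from .features_timefreq import DEFAULT_TF_SPEC, TFSpec, tf_features
from .labeling import label_points
from .preprocessing import bandpass_for

__all__ = ["extract_features", "build_feature_table"]

logger = logging.getLogger(__name__)


def extract_features(study: Study, tf_spec: TFSpec = DEFAULT_TF_SPEC) -> pd.DataFrame:
    """Per-point values for all 46 registry features plus map-type indicators.

    Spatial gradients are computed per map from the pipeline's own extracted
    LAT/RT/ARI annotations (not any generator ground truth).  Missing
    annotations propagate as NaN.
    """
    registry = build_registry()
    frames = []
    for m in study.maps:
        rows = []
        for p in m.points:
            uni = bandpass_for(p.uni)
            bip = bandpass_for(p.bip)
            vals: dict[str, float] = {}
            f = functional_features(uni, bip)
            vals.update({k: (np.nan if v is None else v) for k, v in f.items()})
            vals.update(tf_features(uni, bip))
            rows.append(vals)
        df = pd.DataFrame(rows)
        df.insert(0, "map_id", m.map_id)
        df.insert(1, "point_id", [p.point_id for p in m.points])
        df.insert(2, "rhythm", m.rhythm.value)

        xyz = np.vstack([p.xyz for p in m.points])
        df["Grad_AT"] = spatial_gradient(xyz, df["LAT_B"].to_numpy())
        df["Grad_RT"] = spatial_gradient(xyz, df["RT"].to_numpy())
        df["Grad_ARI"] = spatial_gradient(xyz, df["ARI_B"].to_numpy())
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)

    for col, rhythm in zip(MAP_TYPE_COLUMNS, (Rhythm.SR, Rhythm.LV, Rhythm.RV, Rhythm.BIV)):
        out[col] = (out["rhythm"] == rhythm.value).astype(int)

    missing = [n for n in registry.names if n not in out.columns]
    extra = [c for c in out.columns
             if c not in registry.names
             and c not in ("map_id", "point_id", "rhythm", *MAP_TYPE_COLUMNS)]
    if missing or extra:  # registry and pipeline must agree exactly
        raise RuntimeError(f"feature/registry mismatch: missing={missing} extra={extra}")
    # canonical column order: ids, registry features, indicators
    return out[["map_id", "point_id", "rhythm", *registry.names, *MAP_TYPE_COLUMNS]]


def build_feature_table(study: Study, radius_mm: float = 6.0,
                        tf_spec: TFSpec = DEFAULT_TF_SPEC) -> pd.DataFrame:
    """Feature table with labels and leakage group ids merged in."""
    feats = extract_features(study, tf_spec)
    labels = label_points(study, radius_mm)
    out = feats.merge(labels, on=["map_id", "point_id"], validate="one_to_one")
    n_pos = int(out["label"].sum())
    logger.info("feature table: %d points, %d positive (%.2f%%)",
                len(out), n_pos, 100.0 * n_pos / max(1, len(out)))
    return out
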