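"""Distance-based labeling of potential ablation targets and leakage groups.

A mapping point is a potential ablation target (positive class) when its 3D
Euclidean distance to the nearest VT critical site is at most ``radius_mm``
(default 6 mm; the ball is closed, so a point at exactly the radius is
positive).  Each positive point is grouped by its nearest critical site —
these groups are the unit that must never be split across training and test
data — while negatives are grouped by their map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_model import Study, SubstrateMap

__all__ = ["LabelConfig", "deduplicate", "label_points", "radius_sweep",
           "label_prevalence", "DEFAULT_RADIUS_MM", "DEFAULT_SWEEP_MM"]

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_MM = 6.0
DEFAULT_SWEEP_MM = tuple(float(r) for r in range(3, 11))
DEDUP_TOLERANCE_MM = 0.01


@dataclass(frozen=True)
class LabelConfig:
    radius_mm: float = DEFAULT_RADIUS_MM
    sweep: tuple[float, ...] = DEFAULT_SWEEP_MM
    dedup_tolerance_mm: float = DEDUP_TOLERANCE_MM

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or any(r <= 0 for r in self.sweep):
            raise ValueError("labeling radii must be positive")


def deduplicate(study: Study, tolerance_mm: float = DEDUP_TOLERANCE_MM) -> Study:
    """Collapse duplicated points (same coordinates and identical traces) per map.

    Points whose coordinates agree within ``tolerance_mm`` and whose unipolar
    and bipolar samples are byte-identical collapse to the first occurrence.
    The number of removed points is logged.
    """
    new_maps = []
    removed = 0
    for m in study.maps:
        kept = []
        seen: list = []
        for p in m.points:
            dup = False
            for q in seen:
                if (np.all(np.abs(p.xyz - q.xyz) <= tolerance_mm)
                        and p.uni.samples.tobytes() == q.uni.samples.tobytes()
                        and p.bip.samples.tobytes() == q.bip.samples.tobytes()):
                    dup = True
                    break
            if dup:
                removed += 1
            else:
                kept.append(p)
                seen.append(p)
        new_maps.append(SubstrateMap(m.map_id, m.subject_id, m.rhythm,
                                     m.protocol, kept))
    if removed:
        logger.info("deduplicate: removed %d duplicated points", removed)
    return Study(subject_ids=list(study.subject_ids), maps=new_maps,
                 sites=list(study.sites))


def label_points(study: Study, radius_mm: float = DEFAULT_RADIUS_MM) -> pd.DataFrame:
    """Per-point labels and leakage group ids.

    Returns a DataFrame with columns map_id, point_id, label (0/1), group_id,
    site_distance_mm.  Positives take the id of the nearest critical site
    (ties broken by lowest site_id); negatives take ``neg:<map_id>``.
    Without sites, all labels are 0 (a warning is logged).
    """
    sites = study.site_coords()
    site_ids = [s.site_id for s in study.sites]
    if sites.shape[0] == 0:
        logger.warning("label_points: no VT critical sites; all labels 0")
    rows = []
    order = np.argsort(np.array(site_ids, dtype=object)) if site_ids else None
    for m in study.maps:
        for p in m.points:
            if sites.shape[0]:
                d = np.linalg.norm(sites - p.xyz, axis=1)
                # lowest site_id wins ties: scan in sorted-id order
                best = min(order, key=lambda k: (d[k], site_ids[k]))
                dist = float(d[best])
            else:
                best, dist = None, float("inf")
            pos = dist <= radius_mm
            rows.append({
                "map_id": m.map_id,
                "point_id": p.point_id,
                "label": int(pos),
                "group_id": site_ids[best] if pos else f"neg:{m.map_id}",
                "nearest_site_id": site_ids[best] if best is not None else "",
                "site_distance_mm": dist,
            })
    return pd.DataFrame(rows)


def radius_sweep(study: Study,
                 radii: tuple[float, ...] = DEFAULT_SWEEP_MM) -> pd.DataFrame:
    """Labels for each radius of the sweep plus per-radius prevalence.

    Radii must be ascending; the positive sets are then nested and prevalence
    is non-decreasing.  Returns a frame with one label column per radius
    (``label_<r>mm``) and attrs['prevalence'] mapping radius -> prevalence.
    """
    radii = tuple(float(r) for r in radii)
    if list(radii) != sorted(radii):
        raise ValueError("radii must be sorted ascending")
    base = label_points(study, radius_mm=radii[0])
    out = base[["map_id", "point_id", "site_distance_mm"]].copy()
    prevalence = {}
    for r in radii:
        lab = (out["site_distance_mm"] <= r).astype(int)
        out[f"label_{r:g}mm"] = lab
        prevalence[r] = float(lab.mean()) if len(lab) else 0.0
    out.attrs["prevalence"] = prevalence
    return out


def label_prevalence(study: Study, radius_mm: float = DEFAULT_RADIUS_MM) -> float:
    lab = label_points(study, radius_mm)
    return float(lab["label"].mean()) if len(lab) else 0.0
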