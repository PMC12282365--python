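"""Domain types, the 46-feature registry, and the map-bundle exchange format.

An electroanatomical "study" is a set of substrate maps (3D point clouds with
one unipolar and one bipolar electrogram per point) plus the ventricular
tachycardia (VT) critical sites localized from separate VT activation maps.
Because no open standard exists for electroanatomical exports, the bundle
format is bespoke: a ``study.json`` manifest, per-map CSV tables for point
geometry/annotations and for the raw signal matrices, and a ``sites.csv``
table for VT critical sites.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "Rhythm",
    "Protocol",
    "Phase",
    "EGMTrace",
    "MapPoint",
    "VTCriticalSite",
    "SubstrateMap",
    "Study",
    "FeatureSpec",
    "FeatureRegistry",
    "build_registry",
    "read_map_bundle",
    "write_map_bundle",
    "BundleFormatError",
    "ValidationError",
    "DEFAULT_FS",
]

#: Nominal sampling rate of the mapping system export (Hz).
DEFAULT_FS = 2034.5


class BundleFormatError(RuntimeError):
    """A map bundle is missing files or has a malformed layout."""


class ValidationError(ValueError):
    """A domain-type invariant is violated; message carries the offending id."""


class Channel(str, enum.Enum):
    UNIPOLAR = "unipolar"
    BIPOLAR = "bipolar"
    GENERAL = "general"


class Rhythm(str, enum.Enum):
    SR = "SR"
    LV = "LV"
    RV = "RV"
    BIV = "BIV"


class Protocol(str, enum.Enum):
    NONE = "none"
    SE = "SE"
    S1S2 = "S1S2"


class Phase(str, enum.Enum):
    """Diastolic phase of a VT critical site: entry, isthmus, exit."""

    EARLY = "early"
    MID = "mid"
    LATE = "late"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class EGMTrace:
    """One channel's sampled electrogram with its analysis windows.

    Windows are stored as sample indices; conversion to milliseconds always
    goes through ``fs``.  ``t_end`` bounds the T-wave window for unipolar
    traces; for bipolar traces it is conventionally the trace length (the
    post-QRS window runs to the end of the recording).
    """

    samples: np.ndarray
    fs: float
    kind: Channel
    qrs_on: int
    qrs_end: int
    t_end: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("trace must be a 1-D signal of length >= 2")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        n = self.samples.size
        if not (0 <= self.qrs_on < self.qrs_end <= self.t_end <= n):
            raise ValidationError(
                f"window indices violate 0 <= qrs_on < qrs_end <= t_end <= {n}: "
                f"({self.qrs_on}, {self.qrs_end}, {self.t_end})"
            )
        if self.kind is Channel.GENERAL:
            raise ValidationError("a trace is unipolar or bipolar, never general")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def ms_of(self, index: float) -> float:
        """Sample index -> milliseconds from trace start."""
        return 1000.0 * index / self.fs

    def index_of(self, ms: float) -> int:
        """Milliseconds from trace start -> nearest sample index."""
        return int(round(ms * self.fs / 1000.0))

    def __eq__(self, other: object) -> bool:  # structural equality for round-trips
        if not isinstance(other, EGMTrace):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.qrs_on == other.qrs_on
            and self.qrs_end == other.qrs_end
            and self.t_end == other.t_end
            and np.isclose(self.fs, other.fs)
            and self.samples.shape == other.samples.shape
            and np.allclose(self.samples, other.samples, rtol=0, atol=1e-12)
        )


@dataclass
class MapPoint:
    """A mapping site: 3D position, the two traces, functional annotations.

    ``lat_ms`` (local activation time, from the bipolar EGM) and ``rt_ms``
    (repolarization time, from the unipolar T-wave) may be absent (None).
    ``ari_ms`` is derived: ARI = RT - LAT whenever both are present.
    """

    point_id: str
    xyz: np.ndarray
    uni: EGMTrace
    bip: EGMTrace
    lat_ms: float | None = None
    rt_ms: float | None = None
    ari_ms: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValidationError(f"point {self.point_id}: xyz must be 3 finite floats")
        if self.uni.kind is not Channel.UNIPOLAR or self.bip.kind is not Channel.BIPOLAR:
            raise ValidationError(f"point {self.point_id}: trace kinds mismatched")
        if self.lat_ms is not None and self.rt_ms is not None:
            self.ari_ms = self.rt_ms - self.lat_ms
        else:
            self.ari_ms = None


@dataclass
class VTCriticalSite:
    site_id: str
    vt_id: str
    xyz: np.ndarray
    phase: Phase

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValidationError(f"site {self.site_id}: xyz must be 3 finite floats")
        self.phase = Phase(self.phase)


@dataclass
class SubstrateMap:
    map_id: str
    subject_id: str
    rhythm: Rhythm
    protocol: Protocol
    points: list[MapPoint]

    def __post_init__(self) -> None:
        self.rhythm = Rhythm(self.rhythm)
        self.protocol = Protocol(self.protocol)
        ids = [p.point_id for p in self.points]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"map {self.map_id}: duplicate point_ids")
        if self.rhythm is Rhythm.SR and self.protocol is not Protocol.NONE:
            raise ValidationError(f"map {self.map_id}: SR maps carry no pacing protocol")
        if self.rhythm is not Rhythm.SR and self.protocol is Protocol.NONE:
            raise ValidationError(f"map {self.map_id}: paced maps need a protocol")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class Study:
    """A multi-map electroanatomical study with its VT critical sites."""

    subject_ids: list[str]
    maps: list[SubstrateMap]
    sites: list[VTCriticalSite]

    def __post_init__(self) -> None:
        known = set(self.subject_ids)
        for m in self.maps:
            if m.subject_id not in known:
                raise ValidationError(f"map {m.map_id}: unknown subject {m.subject_id}")
        mids = [m.map_id for m in self.maps]
        if len(set(mids)) != len(mids):
            raise ValidationError("duplicate map_ids in study")
        sids = [s.site_id for s in self.sites]
        if len(set(sids)) != len(sids):
            raise ValidationError("duplicate site_ids in study")

    @property
    def n_points(self) -> int:
        return sum(m.n_points for m in self.maps)

    def site_coords(self) -> np.ndarray:
        if not self.sites:
            return np.empty((0, 3))
        return np.vstack([s.xyz for s in self.sites])


# ---------------------------------------------------------------------------
# Feature registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureSpec:
    """One registered feature: canonical column name, printed symbol, and tags."""

    name: str
    symbol: str
    channel: Channel
    window: str  # "QRS" | "post" | "whole" | "n/a"
    domain: str  # "functional" | "spatial" | "spectral" | "timefreq"


class FeatureRegistry:
    """Ordered inventory of the 46 per-point signal features.

    The bipolar model uses features tagged bipolar or general; the unipolar
    model uses features tagged unipolar or general.  Two features are tagged
    ``general`` (the activation annotation and the activation-gradient map),
    which is the accounting under which 22 bipolar-model + 26 unipolar-model
    features share 2 and total 46.
    """

    def __init__(self, specs: Sequence[FeatureSpec]):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValidationError("registry feature names must be unique")
        self._specs = list(specs)
        self._by_name = {s.name: s for s in specs}

    def __len__(self) -> int:
        return len(self._specs)

    def __iter__(self):
        return iter(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> FeatureSpec:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._specs]

    def names_for_model(self, channel: Channel | str) -> list[str]:
        """Feature names available to the given signal-type model.

        ``bipolar`` -> bipolar + general; ``unipolar`` -> unipolar + general;
        ``general`` (meaning "both signal types") -> all features.
        """
        channel = Channel(channel)
        if channel is Channel.GENERAL:
            return self.names
        keep = {channel, Channel.GENERAL}
        return [s.name for s in self._specs if s.channel in keep]


def _tf_specs(chan: Channel, prefix: str, windows: tuple[str, str],
              band_edges: Sequence[int], win_tags: tuple[str, str]) -> list[FeatureSpec]:
    """Total energy + 4 fractional band energies per window, one channel."""
    out = []
    lo, hi = band_edges[0], band_edges[-1]
    for wname, wtag in zip(windows, win_tags):
        out.append(FeatureSpec(
            f"E_{prefix}_{wname}", f"E{prefix},{wname}{lo}-{hi}", chan, wtag, "timefreq"))
        for a, b in zip(band_edges[:-1], band_edges[1:]):
            out.append(FeatureSpec(
                f"R_{prefix}_{wname}_{a}_{b}", f"R{prefix},{wname}{a}-{b}",
                chan, wtag, "timefreq"))
    return out


def build_registry() -> FeatureRegistry:
    """The canonical 46-feature inventory.

    Functional (19) + spatial gradients (3) + spectral (4) + time-frequency
    (20, tiling 2 windows x 4 bands per channel plus per-window totals).
    """
    U, B, G = Channel.UNIPOLAR, Channel.BIPOLAR, Channel.GENERAL
    specs: list[FeatureSpec] = [
        # functional — annotations and intervals
        FeatureSpec("LAT_B", "LATB", G, "QRS", "functional"),
        FeatureSpec("RT", "RT", U, "post", "functional"),
        FeatureSpec("ARI_B", "ARIB", U, "n/a", "functional"),
        # durations
        FeatureSpec("D_B", "DB", B, "whole", "functional"),
        FeatureSpec("D_U", "DU", U, "QRS", "functional"),
        # amplitudes
        FeatureSpec("A_B", "AB", B, "QRS", "functional"),
        FeatureSpec("A_Bp", "ABp", B, "post", "functional"),
        FeatureSpec("A_U", "AU", U, "QRS", "functional"),
        FeatureSpec("A_UT", "AUT", U, "post", "functional"),
        # deflection counts
        FeatureSpec("Def_B", "DefB", B, "QRS", "functional"),
        FeatureSpec("Def_U", "DefU", U, "QRS", "functional"),
        # change rates
        FeatureSpec("max_dBQRSdt", "max|dBQRSdt|", B, "QRS", "functional"),
        FeatureSpec("mean_dBQRSdt", "mean|dBQRSdt|", B, "QRS", "functional"),
        FeatureSpec("max_dBpdt", "max|dBpdt|", B, "post", "functional"),
        FeatureSpec("mean_dBpdt", "mean|dBpdt|", B, "post", "functional"),
        FeatureSpec("max_dUQRSdt", "max|dUQRSdt|", U, "QRS", "functional"),
        FeatureSpec("mean_dUQRSdt", "mean|dUQRSdt|", U, "QRS", "functional"),
        FeatureSpec("max_dUTdt", "max|dUTdt|", U, "post", "functional"),
        FeatureSpec("mean_dUTdt", "mean|dUTdt|", U, "post", "functional"),
        # spatial gradients
        FeatureSpec("Grad_AT", "GradAT", G, "n/a", "spatial"),
        FeatureSpec("Grad_RT", "GradRT", U, "n/a", "spatial"),
        FeatureSpec("Grad_ARI", "GradARI", U, "n/a", "spatial"),
        # spectral
        FeatureSpec("f_B", "fB", B, "whole", "spectral"),
        FeatureSpec("f_U", "fU", U, "whole", "spectral"),
        FeatureSpec("P_B", "PB", B, "whole", "spectral"),
        FeatureSpec("P_U", "PU", U, "whole", "spectral"),
    ]
    specs += _tf_specs(B, "B", ("QRS", "P"), (0, 40, 80, 120, 160), ("QRS", "post"))
    specs += _tf_specs(U, "U", ("QRS", "T"), (0, 20, 40, 60, 80), ("QRS", "post"))
    reg = FeatureRegistry(specs)
    assert len(reg) == 46
    return reg


#: Indicator columns for map type, one-hot over the four rhythms.
MAP_TYPE_COLUMNS = ["map_SR", "map_LV", "map_RV", "map_BIV"]


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # shortest exact round-trip for float64


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return _FLOAT_FMT % x


def write_map_bundle(study: Study, path: str | Path) -> None:
    """Write a study as a bundle directory. Deterministic byte layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_ids": list(study.subject_ids),
        "maps": [
            {
                "map_id": m.map_id,
                "subject_id": m.subject_id,
                "rhythm": m.rhythm.value,
                "protocol": m.protocol.value,
                "n_points": m.n_points,
            }
            for m in study.maps
        ],
    }
    (path / "study.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    with open(path / "sites.csv", "w") as fh:
        fh.write("site_id,vt_id,phase,x_mm,y_mm,z_mm\n")
        for s in study.sites:
            fh.write(
                f"{s.site_id},{s.vt_id},{s.phase.value},"
                f"{_fmt(s.xyz[0])},{_fmt(s.xyz[1])},{_fmt(s.xyz[2])}\n"
            )

    for m in study.maps:
        with open(path / f"points_{m.map_id}.csv", "w") as fh:
            fh.write("point_id,x_mm,y_mm,z_mm,lat_ms,rt_ms\n")
            for p in m.points:
                fh.write(
                    f"{p.point_id},{_fmt(p.xyz[0])},{_fmt(p.xyz[1])},{_fmt(p.xyz[2])},"
                    f"{_fmt(p.lat_ms)},{_fmt(p.rt_ms)}\n"
                )
        for chan, attr in (("uni", "uni"), ("bip", "bip")):
            with open(path / f"{chan}_{m.map_id}.csv", "w") as fh:
                for p in m.points:
                    tr: EGMTrace = getattr(p, attr)
                    head = f"{_fmt(tr.fs)},{tr.qrs_on},{tr.qrs_end},{tr.t_end}"
                    body = ",".join(_FLOAT_FMT % v for v in tr.samples)
                    fh.write(head + "," + body + "\n")


def _parse_signal_rows(path: Path, kind: Channel) -> list[EGMTrace]:
    traces = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            fs = float(parts[0])
            qrs_on, qrs_end, t_end = (int(parts[i]) for i in (1, 2, 3))
            samples = np.array([float(v) for v in parts[4:]])
            traces.append(EGMTrace(samples, fs, kind, qrs_on, qrs_end, t_end))
    return traces


def read_map_bundle(path: str | Path) -> Study:
    """Read and validate a bundle directory written by :func:`write_map_bundle`."""
    path = Path(path)
    meta_path = path / "study.json"
    if not meta_path.exists():
        raise BundleFormatError(f"missing study.json in {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise BundleFormatError(f"corrupt study.json in {path}: {exc}") from exc

    sites_path = path / "sites.csv"
    if not sites_path.exists():
        raise BundleFormatError(f"missing sites.csv in {path}")
    sites_df = pd.read_csv(sites_path, dtype={"site_id": str, "vt_id": str})
    sites = [
        VTCriticalSite(
            site_id=str(r.site_id), vt_id=str(r.vt_id),
            xyz=np.array([r.x_mm, r.y_mm, r.z_mm]), phase=Phase(r.phase),
        )
        for r in sites_df.itertuples()
    ]

    maps = []
    for mm in meta["maps"]:
        mid = mm["map_id"]
        pts_path = path / f"points_{mid}.csv"
        if not pts_path.exists():
            raise BundleFormatError(f"missing points table for map {mid}")
        pts_df = pd.read_csv(pts_path, dtype={"point_id": str})
        unis = _parse_signal_rows(path / f"uni_{mid}.csv", Channel.UNIPOLAR)
        bips = _parse_signal_rows(path / f"bip_{mid}.csv", Channel.BIPOLAR)
        if len(unis) != len(pts_df) or len(bips) != len(pts_df):
            raise ValidationError(
                f"map {mid}: {len(pts_df)} points but {len(unis)} unipolar / "
                f"{len(bips)} bipolar signal rows"
            )
        points = []
        for i, r in enumerate(pts_df.itertuples()):
            lat = None if pd.isna(r.lat_ms) else float(r.lat_ms)
            rt = None if pd.isna(r.rt_ms) else float(r.rt_ms)
            points.append(MapPoint(
                point_id=str(r.point_id),
                xyz=np.array([r.x_mm, r.y_mm, r.z_mm]),
                uni=unis[i], bip=bips[i], lat_ms=lat, rt_ms=rt,
            ))
        maps.append(SubstrateMap(
            map_id=mid, subject_id=mm["subject_id"],
            rhythm=Rhythm(mm["rhythm"]), protocol=Protocol(mm["protocol"]),
            points=points,
        ))
    return Study(subject_ids=list(meta["subject_ids"]), maps=maps, sites=sites)
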