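"""Seeded synthetic electroanatomical studies.

The generator emulates the statistical structure a substrate-mapping analysis
relies on, not the biophysics: multi-map studies per subject on an
ellipsoidal ventricular shell; a contiguous low-voltage scar patch; VT
critical sites placed along a channel through the scar; activation from a
pacing-site-dependent origin slowed inside scar; a smooth repolarization
(ARI) field with a boosted spatial gradient near critical sites; and
template-based unipolar/bipolar electrograms whose site-proximal distortions
follow the known substrate signatures — reduced amplitude, fractionated
high-frequency components within and after the QRS (bipolar), flattened
T-waves and reduced change rate (unipolar).  A per-map random intercept on
the late-potential log-odds gives the mixed-effects analysis a ground-truth
random effect to recover.

All randomness flows from one ``numpy`` generator seeded by ``SimConfig.seed``;
a fixed seed reproduces the study exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    DEFAULT_FS,
    Channel,
    EGMTrace,
    MapPoint,
    Phase,
    Protocol,
    Rhythm,
    Study,
    SubstrateMap,
    VTCriticalSite,
)

__all__ = ["SimConfig", "ConfigError", "Geometry", "Fields",
           "generate_geometry", "simulate_fields", "synthesize_egms",
           "generate_study", "simulate_logistic_clusters"]


class ConfigError(ValueError):
    """Simulation configuration is infeasible; message carries a diagnosis."""


#: Ellipsoid semi-axes (mm) of the ventricular shell. Sized so that the
#: default number of critical sites yields a 6-mm-labelled prevalence near
#: the target 7.3%.
SHELL_AXES = (18.0, 18.0, 25.0)

#: Pacing/activation origin direction per map type (projected onto the shell).
_ORIGINS = {
    Rhythm.SR: np.array([0.0, 0.3, -1.0]),
    Rhythm.RV: np.array([0.8, -0.6, -0.5]),
    Rhythm.LV: np.array([-0.9, 0.4, -0.3]),
    Rhythm.BIV: np.array([0.0, -1.0, -0.2]),
}

#: Direction of the scar patch centre (anterior wall).
_SCAR_DIR = np.array([1.0, 0.0, 0.35])


@dataclass
class SimConfig:
    """Study-generator configuration. Defaults define the simulated conditions."""

    seed: int = 0
    n_subjects: int = 6
    #: (rhythm, protocol) of each map created per subject.
    maps_per_subject: tuple[tuple[str, str], ...] = (
        ("SR", "none"), ("RV", "SE"), ("LV", "S1S2"), ("BIV", "SE"),
    )
    #: Points per map; sinus-rhythm maps get double density (as in practice).
    points_per_map: int = 120
    sr_density_factor: float = 2.0
    scar_fraction: float = 0.25
    n_vts: int = 3
    sites_per_vt: int = 2  # phases assigned early, mid, late in order
    # --- effect profile (site-proximal distortions) ---
    amplitude_reduction: float = 0.5   # QRS amplitude scale at a critical site
    late_potential_base: float = 0.03  # late-potential probability far from scar
    late_potential_boost: float = 3.0  # added log-odds at a critical site
    late_band_hz: tuple[float, float] = (45.0, 100.0)
    t_flattening: float = 0.55         # T-wave amplitude reduction at a site
    ari_gradient_boost: float = 40.0   # ms bump of ARI near sites
    ari_boost_scale_mm: float = 3.5    # spatial scale of the ARI bump
    effect_scale_mm: float = 5.0       # spatial scale of site-proximal effects
    # --- noise / random effects ---
    noise_sd: float = 0.02             # additive white noise (mV)
    map_random_effect_sd: float = 0.5  # per-map intercept on LP log-odds
    target_prevalence: float = 0.0731
    # --- signal template ---
    fs: float = DEFAULT_FS
    duration_ms: float = 560.0
    conduction_speed: float = 0.7      # mm/ms outside scar
    scar_slowing: float = 1.2          # extra delay per mm of scar depth (ms/mm)
    electrode_spacing_mm: float = 3.0  # bipolar source separation

    def __post_init__(self) -> None:
        for name in ("scar_fraction", "amplitude_reduction", "late_potential_base",
                     "t_flattening", "target_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.points_per_map < 20:
            raise ConfigError("points_per_map must be >= 20")
        if self.sites_per_vt > 3:
            raise ConfigError("at most 3 sites (early/mid/late) per VT")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass
class Geometry:
    xyz: np.ndarray          # (n, 3) mm
    scar_mask: np.ndarray    # (n,) bool
    sites: np.ndarray        # (m, 3) mm
    site_meta: list[tuple[str, str, Phase]]  # (site_id, vt_id, phase)


def _project_shell(v: np.ndarray) -> np.ndarray:
    """Project direction(s) onto the ellipsoidal shell."""
    axes = np.asarray(SHELL_AXES)
    u = v / np.linalg.norm(v, axis=-1, keepdims=True)
    return u * axes


def _angle_to_scar(xyz: np.ndarray) -> np.ndarray:
    axes = np.asarray(SHELL_AXES)
    u = xyz / axes
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    d = _SCAR_DIR / np.linalg.norm(_SCAR_DIR)
    return np.arccos(np.clip(u @ d, -1.0, 1.0))


def _scar_angle(scar_fraction: float) -> float:
    """Cap half-angle such that uniformly random directions land in the cap
    with probability ``scar_fraction`` (spherical-cap area rule)."""
    if scar_fraction <= 0:
        return -1.0
    return float(np.arccos(1.0 - 2.0 * scar_fraction))


def _place_sites(cfg: SimConfig, rng: np.random.Generator,
                 subject_id: str) -> tuple[np.ndarray, list[tuple[str, str, Phase]]]:
    """VT critical sites along short channels through the scar patch."""
    theta = max(_scar_angle(cfg.scar_fraction), 0.25)  # sites cluster even if no scar
    d = _SCAR_DIR / np.linalg.norm(_SCAR_DIR)
    # orthonormal tangent frame at the scar centre
    t1 = np.cross(d, [0.0, 0.0, 1.0])
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(d, t1)
    phases = [Phase.EARLY, Phase.MID, Phase.LATE]
    coords, meta = [], []
    r_mean = float(np.mean(SHELL_AXES))
    for v in range(cfg.n_vts):
        # channel entry: random direction within ~60% of the scar cap
        ang = theta * 0.6 * np.sqrt(rng.uniform())
        azi = rng.uniform(0, 2 * np.pi)
        base = d * np.cos(ang) + (t1 * np.cos(azi) + t2 * np.sin(azi)) * np.sin(ang)
        # channel direction: tangent, random azimuth
        cazi = rng.uniform(0, 2 * np.pi)
        step = (t1 * np.cos(cazi) + t2 * np.sin(cazi)) * (4.0 / r_mean)
        for s in range(cfg.sites_per_vt):
            pos = _project_shell(base + s * step)
            coords.append(pos)
            meta.append((f"{subject_id}_vt{v}_s{s}", f"{subject_id}_vt{v}", phases[s]))
    if not coords:
        return np.empty((0, 3)), []
    return np.vstack(coords), meta


def generate_geometry(cfg: SimConfig, rng: np.random.Generator,
                      n_points: int | None = None,
                      sites: np.ndarray | None = None,
                      site_meta: list | None = None,
                      subject_id: str = "subj") -> Geometry:
    """Sample one map's point cloud on the shell; place sites unless given."""
    n = n_points if n_points is not None else cfg.points_per_map
    if n < 20:
        raise ConfigError("need at least 20 points per map")
    u = rng.normal(size=(n, 3))
    xyz = _project_shell(u)
    scar_mask = _angle_to_scar(xyz) <= _scar_angle(cfg.scar_fraction)
    if sites is None:
        sites, site_meta = _place_sites(cfg, rng, subject_id)
    return Geometry(xyz=xyz, scar_mask=scar_mask, sites=sites,
                    site_meta=list(site_meta or []))


# ---------------------------------------------------------------------------
# Ground-truth fields
# ---------------------------------------------------------------------------


@dataclass
class Fields:
    lat: np.ndarray      # ms
    ari: np.ndarray      # ms
    rt: np.ndarray       # ms; rt == lat + ari exactly
    site_w: np.ndarray   # site-proximity weight in [0, 1]
    scar_depth: np.ndarray  # mm inside the scar patch (0 outside)


def _site_distance(xyz: np.ndarray, sites: np.ndarray) -> np.ndarray:
    if sites.size == 0:
        return np.full(xyz.shape[0], np.inf)
    d = np.linalg.norm(xyz[:, None, :] - sites[None, :, :], axis=2)
    return d.min(axis=1)


def simulate_fields(geometry: Geometry, cfg: SimConfig,
                    rhythm: Rhythm = Rhythm.SR) -> Fields:
    """Per-point LAT / ARI / RT ground truth (deterministic given geometry)."""
    xyz = geometry.xyz
    origin = _project_shell(_ORIGINS[Rhythm(rhythm)])
    dist = np.linalg.norm(xyz - origin, axis=1)
    theta = _scar_angle(cfg.scar_fraction)
    r_mean = float(np.mean(SHELL_AXES))
    depth = np.maximum(0.0, (theta - _angle_to_scar(xyz)) * r_mean)
    lat = dist / cfg.conduction_speed + cfg.scar_slowing * depth

    d_site = _site_distance(xyz, geometry.sites)
    w = np.exp(-0.5 * (d_site / cfg.effect_scale_mm) ** 2)
    # smooth large-scale repolarization heterogeneity + scar prolongation
    base = 220.0 + 20.0 * np.sin(xyz[:, 2] / 18.0) + 12.0 * np.cos(xyz[:, 0] / 15.0)
    bump = cfg.ari_gradient_boost * np.exp(-0.5 * (d_site / cfg.ari_boost_scale_mm) ** 2)
    ari = base + 15.0 * (depth > 0) + bump
    rt = lat + ari
    return Fields(lat=lat, ari=ari, rt=rt, site_w=w, scar_depth=depth)


# ---------------------------------------------------------------------------
# Electrogram synthesis
# ---------------------------------------------------------------------------


def _unipolar_template(t_ms: np.ndarray, lat: float, rt: float,
                       a_qrs: float, a_t: float,
                       sigma_q: float = 8.0, sigma_t: float = 35.0) -> np.ndarray:
    """R/S deflection (derivative of Gaussian) at LAT + T-wave whose maximum
    upslope falls exactly at RT (Gaussian peak at RT + sigma_t)."""
    dq = (t_ms - lat) / sigma_q
    qrs = -a_qrs * dq * np.exp(0.5 - 0.5 * dq ** 2)  # peak amplitude a_qrs
    dt_ = (t_ms - (rt + sigma_t)) / sigma_t
    tw = a_t * np.exp(-0.5 * dt_ ** 2)
    return qrs + tw


def synthesize_egms(geometry: Geometry, fields: Fields, cfg: SimConfig,
                    rng: np.random.Generator, map_effect: float = 0.0,
                    id_prefix: str = "p") -> list[MapPoint]:
    """Build MapPoints with unipolar and bipolar traces from the fields.

    The bipolar trace is the difference of two spatially offset unipolar
    sources (the T-wave, being far-field, cancels); late fractionated bursts
    and QRS fractionation spikes are injected with probability elevated near
    critical sites; ``map_effect`` is this map's random intercept on the
    late-potential log-odds.
    """
    fs = cfg.fs
    n_samp = int(round(cfg.duration_ms * fs / 1000.0))
    t_ms = np.arange(n_samp) * 1000.0 / fs
    qrs_on = int(round(10.0 * fs / 1000.0))
    lat_max = float(np.max(fields.lat)) if fields.lat.size else 50.0
    qrs_end = int(round((lat_max + 30.0) * fs / 1000.0))
    qrs_end = min(qrs_end, n_samp - 200)
    dt_pair = cfg.electrode_spacing_mm / cfg.conduction_speed  # ms between poles

    if cfg.late_potential_base > 0:
        base_logit = np.log(cfg.late_potential_base
                            / (1 - cfg.late_potential_base))
    else:
        base_logit = -np.inf  # late potentials disabled
    points: list[MapPoint] = []
    for i in range(geometry.xyz.shape[0]):
        lat, rt, w = fields.lat[i], fields.rt[i], fields.site_w[i]
        in_scar = fields.scar_depth[i] > 0
        amp_scale = (0.75 if in_scar else 1.0) * (
            1.0 - (1.0 - cfg.amplitude_reduction) * w)
        a_qrs = 2.0 * amp_scale
        a_t = 0.6 * (1.0 - cfg.t_flattening * w)

        uni = _unipolar_template(t_ms, lat, rt, a_qrs, a_t)
        uni2 = _unipolar_template(t_ms, lat + dt_pair, rt, a_qrs, a_t)
        bip = uni - uni2  # T-wave (far field) cancels exactly

        # QRS fractionation: extra narrow deflections near critical sites
        n_frac = rng.binomial(3, 0.7 * w + (0.1 if in_scar else 0.0))
        for _ in range(n_frac):
            off = rng.uniform(-18.0, 18.0)
            df = (t_ms - (lat + off)) / 2.0
            bip = bip + 0.35 * a_qrs * rng.choice([-1.0, 1.0]) * df * np.exp(
                0.5 - 0.5 * df ** 2)

        # late potential: low-amplitude high-frequency burst after the QRS
        p_lp = 1.0 / (1.0 + np.exp(-(base_logit
                                     + 1.2 * float(in_scar)
                                     + cfg.late_potential_boost * w
                                     + map_effect)))
        if rng.uniform() < p_lp:
            centre = t_ms[qrs_end] + rng.uniform(15.0, 70.0)
            f_hz = rng.uniform(*cfg.late_band_hz)
            env = np.exp(-0.5 * ((t_ms - centre) / 9.0) ** 2)
            bip = bip + 0.22 * env * np.cos(2 * np.pi * f_hz * (t_ms - centre) / 1000.0)

        if cfg.noise_sd > 0:
            uni = uni + rng.normal(0.0, cfg.noise_sd, n_samp)
            bip = bip + rng.normal(0.0, cfg.noise_sd, n_samp)

        t_end_u = min(n_samp, int(round((rt + 70.0) * fs / 1000.0)))
        t_end_u = max(t_end_u, qrs_end + 64)
        uni_tr = EGMTrace(uni, fs, Channel.UNIPOLAR, qrs_on, qrs_end, t_end_u)
        bip_tr = EGMTrace(bip, fs, Channel.BIPOLAR, qrs_on, qrs_end, n_samp)
        points.append(MapPoint(
            point_id=f"{id_prefix}{i:04d}", xyz=geometry.xyz[i],
            uni=uni_tr, bip=bip_tr,
            lat_ms=float(lat), rt_ms=float(rt),
        ))
    return points


# ---------------------------------------------------------------------------
# Whole-study assembly
# ---------------------------------------------------------------------------


def generate_study(cfg: SimConfig, check_prevalence: bool = True) -> Study:
    """A seeded multi-subject, multi-map study with VT critical sites.

    Raises :class:`ConfigError` when the labelled prevalence at 6 mm falls
    outside +/-30% (relative) of ``cfg.target_prevalence`` — the geometry or
    site count then needs adjusting, and the error message says in which
    direction.
    """
    rng = np.random.default_rng(cfg.seed)
    subject_ids = [f"s{k:02d}" for k in range(cfg.n_subjects)]
    maps: list[SubstrateMap] = []
    all_sites: list[VTCriticalSite] = []
    for k, sid in enumerate(subject_ids):
        # each subject lives in its own anatomical frame: translate well beyond
        # any labeling radius so cross-subject distances never label points
        offset = np.array([500.0 * k, 0.0, 0.0])
        sites, meta = _place_sites(cfg, rng, sid)
        for (site_id, vt_id, phase), pos in zip(meta, sites):
            all_sites.append(VTCriticalSite(site_id, vt_id, pos + offset, phase))
        for j, (rhythm, protocol) in enumerate(cfg.maps_per_subject):
            rhythm = Rhythm(rhythm)
            n_pts = cfg.points_per_map
            if rhythm is Rhythm.SR:
                n_pts = int(round(n_pts * cfg.sr_density_factor))
            geom = generate_geometry(cfg, rng, n_points=n_pts,
                                     sites=sites, site_meta=meta, subject_id=sid)
            flds = simulate_fields(geom, cfg, rhythm)
            b_m = rng.normal(0.0, cfg.map_random_effect_sd)
            mid = f"{sid}_m{j}_{rhythm.value}"
            pts = synthesize_egms(geom, flds, cfg, rng, map_effect=b_m,
                                  id_prefix=f"{mid}_")
            for p in pts:
                p.xyz = p.xyz + offset
            maps.append(SubstrateMap(map_id=mid, subject_id=sid,
                                     rhythm=rhythm, protocol=Protocol(protocol),
                                     points=pts))
    study = Study(subject_ids=subject_ids, maps=maps, sites=all_sites)

    if check_prevalence and cfg.n_vts > 0 and cfg.sites_per_vt > 0:
        from .labeling import label_prevalence
        prev = label_prevalence(study, radius_mm=6.0)
        lo, hi = 0.7 * cfg.target_prevalence, 1.3 * cfg.target_prevalence
        if not lo <= prev <= hi:
            direction = "small" if prev < lo else "large"
            raise ConfigError(
                f"labelled prevalence {prev:.4f} outside [{lo:.4f}, {hi:.4f}]: "
                f"site coverage too {direction} for the shell; adjust n_vts, "
                f"sites_per_vt or the shell size"
            )
    return study


def simulate_logistic_clusters(n_clusters: int, n_per_cluster: int,
                               beta: np.ndarray | list[float],
                               sigma: float, seed: int,
                               intercept: float = -1.0) -> "pd.DataFrame":
    """Random-intercept logistic data for estimator-recovery checks.

    y ~ Bernoulli(sigmoid(intercept + X beta + u_cluster)), u ~ N(0, sigma^2),
    X standard normal.  Returns a DataFrame with columns x0.., y, map_id.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    p = beta.size
    n = n_clusters * n_per_cluster
    X = rng.normal(size=(n, p))
    u = rng.normal(0.0, sigma, n_clusters)
    cluster = np.repeat(np.arange(n_clusters), n_per_cluster)
    eta = intercept + X @ beta + u[cluster]
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df["y"] = y
    df["map_id"] = [f"m{c:03d}" for c in cluster]
    return df
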