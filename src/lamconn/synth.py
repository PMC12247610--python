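"""Synthetic acquisition generator with known laminar ground truth.

Generates everything the analysis pipeline consumes, at desk scale and with
planted parameters, so every downstream stage can be tested for parameter
recovery without external data:

* spherical cortical geometry (icosphere white surface, pial offset by a
  smoothly varying thickness) with GM/WM/CSF voxel masks,
* an interleaved blood-nulled/control volume series.  The control voxel value
  is ``S0 (1 + b)(1 + drift + noise)`` and the nulled value
  ``S0 (1 - v)(1 + b)(1 + drift + noise)``, where ``v`` is the planted
  intravascular (blood-volume/perfusion) signal and ``b`` a multiplicative
  BOLD factor whose gain grows linearly toward the pial surface (draining
  vein bias).  BOLD and drift are evaluated on the pair grid (the slow-BOLD
  assumption under which dynamic division removes them exactly); a
  ``fast_bold`` switch re-evaluates them per volume to exercise residual
  contamination,
* planted laminar coupling: each network carries a shared latent signal whose
  coupling to the cortex follows a depth profile (middle-peak,
  superficial-peak, or double-bump); every vertex additionally carries an
  idiosyncratic latent so that inter-vertex correlations are informative,
* motion traces (random walk plus spikes), signal glitches at spike times,
  polynomial drift, a CSF nuisance source, and an MT-prepared/control
  anatomical pair with stronger saturation in white than gray matter,
* multi-session groups related to a template by a known rotation +
  vertex-permutation deformation whose exact inverse is returned as the
  registration map.

The geometry is deliberately sphere-based: cortical curvature enters the
equi-volume construction only through inner/outer area ratios, which a
sphere provides in closed form.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from .contrast import CONTROL, NULLED, VolumeSeries
from .lamsurf import (
    LaminarMesh,
    RegistrationMap,
    SurfaceMesh,
    build_depth_surfaces,
    icosphere,
)
from .preprocess import MotionTrace

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkSpec",
    "MotionSpec",
    "SyntheticConfig",
    "CorticalModel",
    "GroundTruth",
    "coupling_profile",
    "make_cortical_model",
    "network_vertex_masks",
    "simulate_session",
    "simulate_mt_pair",
    "make_group",
]

PROFILE_TYPES = ("middle-peak", "superficial-peak", "double-bump", "uniform")

# profile peak positions as depth fractions (0 = white, 1 = pial);
# 0.47 is the centre of bin 9 of 18, 0.92 the centre of bin 17
MIDDLE_PEAK_FRAC = 0.472
SUPERFICIAL_PEAK_FRAC = 0.917


@dataclass
class NetworkSpec:
    """A planted functional network: a geodesic patch with a laminar coupling
    profile tying it to one shared latent signal."""

    name: str
    center: tuple  # unit direction of the patch centre
    radius_deg: float  # angular patch radius
    profile: str  # one of PROFILE_TYPES
    latent: int = 0  # index of the shared latent signal
    amplitude: float = 0.05  # peak coupling, fraction of baseline

    def __post_init__(self) -> None:
        if self.profile not in PROFILE_TYPES:
            raise ValueError(f"unknown profile type {self.profile!r}")
        if self.amplitude < 0:
            raise ValueError("coupling amplitude must be nonnegative")


@dataclass
class MotionSpec:
    """Head-motion model: random walk plus discrete spikes."""

    rw_scale: float = 0.01  # mm (or deg) random-walk step sd per volume
    spike_volumes: tuple = ()  # original volume indices
    spike_amplitude: float = 1.0  # mm added to x-translation at a spike
    glitch_fraction: float = 0.15  # fraction of brain voxels offset at a spike
    glitch_amplitude: float = 0.05  # offset, fraction of baseline


def _default_networks() -> list:
    return [
        NetworkSpec("ffwd", (1.0, 0.0, 0.0), 35.0, "middle-peak", latent=0),
        NetworkSpec("fback", (-1.0, 0.0, 0.0), 35.0, "superficial-peak", latent=1),
    ]


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the seed fully determines every output."""

    grid_shape: tuple = (40, 40, 40)
    voxel_size: float = 0.7  # mm, isotropic
    n_vertices: int = 162  # icosphere size is rounded up to 10 * 4^s + 2
    n_depths: int = 18
    thickness_range: tuple = (2.0, 3.0)  # mm
    white_radius: float = 8.0  # mm
    volume_tr: float = 6.082  # s
    te: float = 0.020  # s, metadata
    n_pairs: int = 60
    networks: list = field(default_factory=_default_networks)
    vein_bias_slope: float = 1.0  # BOLD gain increase from white to pial
    bold_gain: float = 0.01  # BOLD amplitude at the white surface
    noise_sd: float = 0.02  # thermal noise, fraction of baseline
    drift_amp: float = 0.005  # slow drift, fraction of baseline
    vertex_signal_sd: float = 0.02  # idiosyncratic vertex latent amplitude
    blood_fraction: float = 0.05  # baseline intravascular signal fraction in GM
    csf_coupling: float = 0.01  # CSF nuisance leakage into gray matter
    fast_bold: bool = False  # evaluate BOLD factor per volume, not per pair
    motion: MotionSpec = field(default_factory=MotionSpec)
    n_dummies: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_depths < 2:
            raise ValueError("n_depths must be >= 2")
        if self.volume_tr <= 0:
            raise ValueError("volume_tr must be positive")
        if self.thickness_range[0] > self.thickness_range[1] or self.thickness_range[0] <= 0:
            raise ValueError("invalid thickness_range")
        if self.noise_sd < 0 or self.drift_amp < 0:
            raise ValueError("noise/drift amplitudes must be nonnegative")


@dataclass
class CorticalModel:
    """Geometry plus voxel bookkeeping for one session."""

    lmesh: LaminarMesh
    white: SurfaceMesh
    pial: SurfaceMesh
    thickness: np.ndarray  # (V,) mm
    affine: np.ndarray  # (4, 4)
    gm_mask: np.ndarray  # (X, Y, Z) bool
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    vox_vertex: np.ndarray  # (X, Y, Z) nearest column index, -1 outside GM
    vox_depth_frac: np.ndarray  # (X, Y, Z) float, NaN outside GM
    vox_depth_bin: np.ndarray  # (X, Y, Z) int, -1 outside GM

    @property
    def n_vertices(self) -> int:
        return self.lmesh.n_vertices


@dataclass
class GroundTruth:
    """Planted structure of one simulated session."""

    labels: np.ndarray  # (V,) 1 = middle-peak, 2 = superficial-peak, 0 = none
    peak_depth: np.ndarray  # (V,) 1-based planted peak depth bin, 0 = none
    network_masks: dict  # name -> (V,) bool
    latent_signals: np.ndarray  # (L, P)
    registration_map: RegistrationMap | None = None
    node_labels: np.ndarray | None = None


def coupling_profile(kind: str, depth_frac: np.ndarray) -> np.ndarray:
    """Nonnegative laminar coupling profile evaluated at depth fractions.

    A small baseline keeps every depth weakly coupled to the network, as
    cortico-cortical connections are not confined to a single lamina.
    """
    x = np.asarray(depth_frac, dtype=float)
    if kind == "middle-peak":
        return 0.15 + np.exp(-0.5 * ((x - MIDDLE_PEAK_FRAC) / 0.16) ** 2)
    if kind == "superficial-peak":
        return 0.15 + np.exp(-0.5 * ((x - SUPERFICIAL_PEAK_FRAC) / 0.16) ** 2)
    if kind == "double-bump":
        return (
            0.15
            + np.exp(-0.5 * ((x - 0.15) / 0.10) ** 2)
            + np.exp(-0.5 * ((x - 0.85) / 0.10) ** 2)
        )
    if kind == "uniform":
        return np.ones_like(x)
    raise ValueError(f"unknown profile type {kind!r}")


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _subdivisions_for(n_vertices: int) -> int:
    s = 0
    while 10 * 4**s + 2 < n_vertices:
        s += 1
    return s


def _grid_affine(grid_shape, voxel_size: float) -> np.ndarray:
    """Isotropic affine with the grid centred on the origin."""
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size
    aff[:3, 3] = -voxel_size * (np.asarray(grid_shape) - 1) / 2.0
    return aff


def model_from_surfaces(config: SyntheticConfig, white: SurfaceMesh, pial: SurfaceMesh) -> CorticalModel:
    """Voxelize a white/pial surface pair on the config grid.

    Each voxel is referred to its nearest vertex column (by direction from
    the sphere centre) and to the depth fraction along that column; GM voxels
    are those with depth fraction in [0, 1].
    """
    affine = _grid_affine(config.grid_shape, config.voxel_size)
    shape = tuple(config.grid_shape)
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    xyz = ijk @ affine[:3, :3].T + affine[:3, 3]
    r = np.linalg.norm(xyz, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = xyz / np.where(r[:, None] > 0, r[:, None], 1.0)

    wdir = white.vertices / np.linalg.norm(white.vertices, axis=1, keepdims=True)
    tree = cKDTree(wdir)
    _, nearest = tree.query(dirs)
    r_w = np.linalg.norm(white.vertices, axis=1)[nearest]
    r_p = np.linalg.norm(pial.vertices, axis=1)[nearest]
    thick = r_p - r_w
    depth_frac = (r - r_w) / thick

    pial_max = np.linalg.norm(pial.vertices, axis=1).max()
    half_extent = config.voxel_size * (min(shape) - 1) / 2.0
    if pial_max + config.voxel_size > half_extent:
        raise ValueError("grid too small: pial surface needs >= 1 voxel margin")

    gm = (depth_frac >= 0.0) & (depth_frac <= 1.0)
    wm = depth_frac < 0.0
    csf = depth_frac > 1.0
    vox_vertex = np.where(gm, nearest, -1).reshape(shape)
    D = config.n_depths
    dbin = np.clip(np.floor(depth_frac * D), 0, D - 1).astype(int)
    vox_depth_bin = np.where(gm, dbin, -1).reshape(shape)
    vox_depth_frac = np.where(gm, depth_frac, np.nan).reshape(shape)

    lmesh = build_depth_surfaces(white, pial, D)
    return CorticalModel(
        lmesh=lmesh,
        white=white,
        pial=pial,
        thickness=np.linalg.norm(pial.vertices - white.vertices, axis=1),
        affine=affine,
        gm_mask=gm.reshape(shape),
        wm_mask=wm.reshape(shape),
        csf_mask=csf.reshape(shape),
        vox_vertex=vox_vertex,
        vox_depth_frac=vox_depth_frac,
        vox_depth_bin=vox_depth_bin,
    )


def make_cortical_model(config: SyntheticConfig) -> CorticalModel:
    """Spherical white/pial surface pair with smoothly varying thickness,
    voxelized on the config grid."""
    rng = np.random.default_rng(config.seed)
    sub = _subdivisions_for(config.n_vertices)
    white = icosphere(sub, config.white_radius)
    V = white.n_vertices
    t_lo, t_hi = config.thickness_range
    if t_hi > t_lo:
        thick = rng.uniform(t_lo, t_hi, size=V)
        adj = white.adjacency()
        deg = np.asarray(adj.sum(axis=1)).ravel()
        for _ in range(20):  # low-pass the thickness field
            thick = (thick + (adj @ thick) / deg) / 2.0
        rngspan = thick.max() - thick.min()
        if rngspan > 0:  # restore the requested range after smoothing
            thick = t_lo + (thick - thick.min()) / rngspan * (t_hi - t_lo)
    else:
        thick = np.full(V, t_lo)
    normals = white.vertices / np.linalg.norm(white.vertices, axis=1, keepdims=True)
    pial = SurfaceMesh(white.vertices + thick[:, None] * normals, white.triangles)
    if np.any(pial.triangle_areas() <= 0):
        raise ValueError("pial offset produced a self-intersecting mesh; reject config")
    return model_from_surfaces(config, white, pial)


def network_vertex_masks(config: SyntheticConfig, model: CorticalModel) -> dict:
    """Geodesic-cap vertex masks for every configured network."""
    wdir = model.white.vertices / np.linalg.norm(model.white.vertices, axis=1, keepdims=True)
    masks = {}
    for spec in config.networks:
        c = np.asarray(spec.center, dtype=float)
        c = c / np.linalg.norm(c)
        ang = np.degrees(np.arccos(np.clip(wdir @ c, -1.0, 1.0)))
        masks[spec.name] = ang <= spec.radius_deg
    return masks


# --------------------------------------------------------------------------
# signals
# --------------------------------------------------------------------------

def _band_limited(rng: np.random.Generator, n_series: int, n_time: int, sigma: float = 1.5) -> np.ndarray:
    """Temporally smooth unit-variance Gaussian processes (rows)."""
    x = rng.standard_normal((n_series, n_time))
    x = gaussian_filter1d(x, sigma, axis=1, mode="wrap")
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _ground_truth_labels(config: SyntheticConfig, model: CorticalModel, masks: dict):
    """Planted per-vertex laminar-type labels and 1-based peak depth bins."""
    V = model.n_vertices
    D = config.n_depths
    labels = np.zeros(V, dtype=int)
    peak = np.zeros(V, dtype=int)
    bin_frac = (np.arange(D) + 0.5) / D
    for spec in config.networks:
        m = masks[spec.name]
        prof = coupling_profile(spec.profile, bin_frac)
        pk = int(np.argmax(prof)) + 1
        if spec.profile == "middle-peak":
            labels[m] = 1
        elif spec.profile == "superficial-peak":
            labels[m] = 2
        peak[m] = pk
    return labels, peak


def simulate_session(
    config: SyntheticConfig,
    model: CorticalModel,
    masks: dict | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[VolumeSeries, MotionTrace, GroundTruth]:
    """Simulate one interleaved nulled/control run on a cortical model.

    Returns the raw volume series (with leading dummy volumes flagged), the
    motion trace, and the planted ground truth.
    """
    if masks is None:
        masks = network_vertex_masks(config, model)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    P = config.n_pairs
    n_dum = config.n_dummies
    n_vol = n_dum + 2 * P
    shape = model.gm_mask.shape

    n_latents = max((s.latent for s in config.networks), default=-1) + 1
    g = _band_limited(rng, max(n_latents, 1), P)
    eta = _band_limited(rng, model.n_vertices, P)
    csf_sig = _band_limited(rng, 1, P)[0]

    gm = model.gm_mask
    gm_flat = gm.ravel()
    vvert = model.vox_vertex.ravel()[gm_flat]
    dfrac = model.vox_depth_frac.ravel()[gm_flat]
    n_gm = int(gm_flat.sum())

    # planted intravascular signal v (n_gm, P): baseline blood fraction plus
    # network-coupled and idiosyncratic fluctuations
    v = config.blood_fraction + config.vertex_signal_sd * eta[vvert]
    v += config.csf_coupling * csf_sig[None, :]
    drive = np.zeros((n_gm, P))  # neural drive for the BOLD factor
    for spec in config.networks:
        in_net = masks[spec.name][vvert]
        beta = spec.amplitude * coupling_profile(spec.profile, dfrac[in_net])
        v[in_net] += beta[:, None] * g[spec.latent][None, :]
        drive[in_net] += g[spec.latent][None, :]
    if np.any(v >= 1.0):
        warnings.warn("nulling overshoot (v >= 1); clipping")
        v = np.clip(v, None, 0.99)

    # multiplicative BOLD factor with linear vein-bias gain over depth
    gain = config.bold_gain * (1.0 + config.vein_bias_slope * dfrac)
    b_pair = gain[:, None] * drive  # (n_gm, P), pair-level

    # global slow drift on the pair grid
    x = np.linspace(-1.0, 1.0, P)
    c1, c2 = rng.standard_normal(2)
    drift = config.drift_amp * (c1 * x + c2 * x**2)

    # baseline signal map
    S0 = np.zeros(shape)
    S0[model.wm_mask] = 800.0
    S0[model.csf_mask] = 1600.0
    S0[gm] = 1000.0
    brain = gm | model.wm_mask | model.csf_mask
    s0_gm = S0.ravel()[gm_flat]

    data = np.zeros(shape + (n_vol,))
    schedule = []
    dummy = np.zeros(n_vol, dtype=bool)
    flat_brain = brain.ravel()

    def volume(pair_idx: int, nulled: bool, fast_rng_draws: bool) -> np.ndarray:
        vol = S0.copy().ravel()
        bfac = b_pair[:, pair_idx]
        if config.fast_bold:
            bfac = bfac * (1.0 + 0.3 * rng.standard_normal())
        signal = s0_gm * (1.0 + bfac)
        if nulled:
            signal = signal * (1.0 - v[:, pair_idx])
        vol[gm_flat] = signal
        vol[flat_brain] *= 1.0 + drift[pair_idx]
        if config.noise_sd > 0:
            vol[flat_brain] *= 1.0 + config.noise_sd * rng.standard_normal(int(flat_brain.sum()))
        return vol.reshape(shape)

    for d in range(n_dum):
        cond = NULLED if d % 2 == 0 else CONTROL
        data[..., d] = volume(0, cond == NULLED, False) * 1.05  # pre-steady-state
        schedule.append(cond)
        dummy[d] = True
    for p in range(P):
        data[..., n_dum + 2 * p] = volume(p, True, True)
        schedule.append(NULLED)
        data[..., n_dum + 2 * p + 1] = volume(p, False, True)
        schedule.append(CONTROL)

    # motion: random walk + spikes; spikes also glitch the data
    params = np.cumsum(config.motion.rw_scale * rng.standard_normal((n_vol, 6)), axis=0)
    n_brain = int(flat_brain.sum())
    for sv in config.motion.spike_volumes:
        if sv >= n_vol:
            continue
        params[sv, 0] += config.motion.spike_amplitude
        n_glitch = int(config.motion.glitch_fraction * n_brain)
        sel = rng.choice(n_brain, size=n_glitch, replace=False)
        flat_vol = data[..., sv].ravel()
        idx = np.where(flat_brain)[0][sel]
        flat_vol[idx] += config.motion.glitch_amplitude * S0.ravel()[idx]
        data[..., sv] = flat_vol.reshape(shape)

    series = VolumeSeries(
        data=data,
        affine=model.affine,
        volume_tr=config.volume_tr,
        schedule=schedule,
        te=config.te,
        dummy_flags=dummy,
    )
    labels, peak = _ground_truth_labels(config, model, masks)
    truth = GroundTruth(
        labels=labels,
        peak_depth=peak,
        network_masks=masks,
        latent_signals=g,
    )
    return series, MotionTrace(params), truth


def simulate_mt_pair(
    config: SyntheticConfig,
    model: CorticalModel,
    rng: np.random.Generator | None = None,
    wm_saturation: float = 0.3,
    gm_saturation: float = 0.1,
    csf_saturation: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean control and MT-prepared anatomical volumes.

    Saturation follows the macromolecular proton fraction: strongest in white
    matter, weaker in gray, negligible in CSF.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    shape = model.gm_mask.shape
    S0 = np.full(shape, 50.0)  # background
    S0[model.wm_mask] = 800.0
    S0[model.csf_mask] = 1600.0
    S0[model.gm_mask] = 1000.0
    sat = np.zeros(shape)
    sat[model.wm_mask] = wm_saturation
    sat[model.gm_mask] = gm_saturation
    sat[model.csf_mask] = csf_saturation
    noise = config.noise_sd / np.sqrt(max(config.n_pairs, 1))  # mean over volumes
    ctrl = S0 * (1.0 + noise * rng.standard_normal(shape))
    mt = S0 * (1.0 - sat) * (1.0 + noise * rng.standard_normal(shape))
    return ctrl, mt


# --------------------------------------------------------------------------
# groups
# --------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(0, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)


def make_group(
    config: SyntheticConfig,
    n_sessions: int,
    deformation: str = "rotate-permute",
    max_angle_deg: float = 8.0,
):
    """Simulate a group of sessions tied to one template.

    Each session's mesh is a known deformation of the template (rotation plus
    a random relabeling of vertex indices; ``deformation='none'`` gives
    identical meshes).  The returned registration maps are the exact inverse
    correspondences, and the planted labels agree vertex-wise on the template
    after registration.

    Returns (sessions, template_model, template_truth) where each session is
    a dict with keys ``series``, ``motion``, ``truth``, ``model``, ``regmap``.
    """
    if n_sessions < 2:
        raise ValueError("n_sessions must be >= 2")
    template = make_cortical_model(config)
    template_masks = network_vertex_masks(config, template)
    labels, peak = _ground_truth_labels(config, template, template_masks)
    template_truth = GroundTruth(
        labels=labels,
        peak_depth=peak,
        network_masks=template_masks,
        latent_signals=np.zeros((0, config.n_pairs)),
    )
    V = template.n_vertices
    sessions = []
    for s in range(n_sessions):
        rng = np.random.default_rng([config.seed, s])
        if deformation == "none":
            perm = np.arange(V)
            R = np.eye(3)
        elif deformation == "rotate-permute":
            perm = rng.permutation(V)
            R = _random_rotation(rng, max_angle_deg)
        else:
            raise ValueError(f"unknown deformation {deformation!r}")
        # session vertex j corresponds to template vertex tau[j]; perm maps
        # template index -> session index, i.e. tau[perm[t]] = t
        tau = np.empty(V, dtype=int)
        tau[perm] = np.arange(V)
        white_v = (template.white.vertices @ R.T)[tau]
        pial_v = (template.pial.vertices @ R.T)[tau]
        tri = perm[template.white.triangles]
        white = SurfaceMesh(white_v, tri)
        pial = SurfaceMesh(pial_v, tri)
        model = model_from_surfaces(config, white, pial)
        masks = {name: m[tau] for name, m in template_masks.items()}
        series, motion, truth = simulate_session(config, model, masks=masks, rng=rng)
        truth.registration_map = RegistrationMap.from_permutation(perm)
        sessions.append(
            {
                "series": series,
                "motion": motion,
                "truth": truth,
                "model": model,
                "regmap": truth.registration_map,
            }
        )
    return sessions, template, template_truth
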