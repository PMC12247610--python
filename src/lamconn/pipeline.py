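"""Session- and group-level orchestration.

Session stage order: trim dummies -> split/pair the interleaved conditions ->
dynamic-division contrast -> censor -> nuisance regression -> optional
evoked-response regression -> volume-to-surface sampling at every depth ->
within-depth smoothing -> connectivity statistics (network FCS, seed FCS,
global hubness).  Group level: register each session's maps depth-wise to the
template, average, cluster laminar profiles, and run the split-half /
random-null reliability analysis.  Every stage logs its counts; any
precondition failure aborts with a stage-tagged error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import cluster as cl
from . import connstat, contrast, io, lamsurf, preprocess

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineParams",
    "PipelineConfig",
    "PipelineError",
    "SessionResult",
    "run_session",
    "run_session_files",
    "run_group",
    "grid_bookkeeping",
    "laminar_size",
]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineParams:
    """Numeric pipeline defaults.

    The defaults are the acquisition/analysis constants of the target
    protocol: enorm 0.4 mm, outlier fraction 0.10, drift polynomials up to
    order 5, 15 mm local-WM radius, 18 depths, FWHM 3 mm within-depth
    smoothing, 1000 columnar nodes, k = 2 laminar types, 50 reliability
    repetitions.
    """

    enorm_thresh: float = 0.4
    outlier_frac: float = 0.10
    poly_order: int = 5
    wm_radius: float = 15.0
    n_depths: int = 18
    fwhm: float = 3.0
    sampling_mode: str = "trilinear"
    n_nodes: int = 1000
    k: int = 2
    n_restarts: int = 10
    n_rep: int = 50
    mask_threshold: float = 0.5
    do_smooth: bool = True
    do_hubness: bool = False
    seed: int = 0


@dataclass
class PipelineConfig:
    """File-based configuration for a session run; round-trips through YAML."""

    volumes: str = ""
    motion: str = ""
    surface_prefix: str = ""
    gm_mask: str = ""
    wm_mask: str = ""
    csf_mask: str = ""
    networks: str = ""  # JSON {name: [0/1 per vertex]}
    out_dir: str = "lamconn_out"
    params: PipelineParams = field(default_factory=PipelineParams)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        params = PipelineParams(**d.pop("params", {}))
        return cls(params=params, **d)


@dataclass
class SessionResult:
    paired: contrast.PairedSeries
    censor: preprocess.CensorMask
    residual: np.ndarray  # 4D, NaN at censored pairs
    laminar: lamsurf.LaminarDataset
    fcs_maps: dict  # network name -> FCSProfileMap
    hubness: connstat.FCSProfileMap | None = None
    n_missing_vertices: int = 0


def _stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
        raise PipelineError(stage, str(exc)) from exc


def run_session(
    series: contrast.VolumeSeries,
    motion: preprocess.MotionTrace,
    lmesh: lamsurf.LaminarMesh,
    gm_mask: np.ndarray,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    networks: dict,
    params: PipelineParams | None = None,
    evoked: np.ndarray | None = None,
    evoked_region: np.ndarray | None = None,
    session_id: str = "",
) -> SessionResult:
    """Run the full session-level pipeline on in-memory objects."""
    p = params or PipelineParams()
    brain = gm_mask | wm_mask | csf_mask

    paired = _stage("contrast", contrast.pair_series, series, mask=brain)
    logger.info("contrast: %d pairs, effective TR %.3f s", paired.n_pairs, paired.effective_tr)

    ofrac = _stage(
        "censor",
        preprocess.outlier_fraction,
        series.data,
        brain,
        p.poly_order,
        exclude=series.dummy_flags,
    )
    cens = _stage(
        "censor",
        preprocess.censor,
        motion,
        paired,
        p.enorm_thresh,
        p.outlier_frac,
        volume_outlier_frac=ofrac,
        dummy_volumes=series.dummy_flags,
    )
    logger.info("censor: kept %d of %d pairs", cens.n_kept, paired.n_pairs)

    resid = _stage(
        "nuisance",
        preprocess.regress_nuisance,
        paired,
        motion,
        csf_mask,
        wm_mask,
        cens,
        gm_mask=gm_mask,
        poly_order=p.poly_order,
        wm_radius=p.wm_radius,
    )

    laminar = _stage(
        "sampling",
        lamsurf.sample_volume_to_surface,
        resid,
        series.affine,
        lmesh,
        p.sampling_mode,
        session_id,
    )
    logger.info("sampling: %d missing vertex samples", laminar.n_missing)

    if evoked is not None and evoked_region is not None:
        laminar.values = _stage(
            "evoked", preprocess.regress_evoked, laminar.values, evoked, evoked_region
        )

    if p.do_smooth and p.fwhm > 0:
        laminar = _stage("smoothing", lamsurf.smooth_within_depth, laminar, p.fwhm)

    fcs_maps = {}
    for name, mask in networks.items():
        fcs_maps[name] = _stage(
            "fcs", connstat.network_fcs, laminar, mask, keep=cens.keep, network_id=name
        )
        logger.info("fcs[%s]: %d vertices", name, int(np.asarray(mask).sum()))

    hub = None
    if p.do_hubness:
        n_nodes = min(p.n_nodes, lmesh.n_vertices)
        nodes = _stage("hubness", connstat.columnar_parcellation, lmesh, n_nodes, p.seed)
        hub = _stage("hubness", connstat.global_hubness, laminar, nodes, keep=cens.keep)

    return SessionResult(
        paired=paired,
        censor=cens,
        residual=resid,
        laminar=laminar,
        fcs_maps=fcs_maps,
        hubness=hub,
        n_missing_vertices=laminar.n_missing,
    )


def run_session_files(config: PipelineConfig) -> SessionResult:
    """Load a session from files per the config, run it, write outputs."""
    def load(stage, fn, path, *a):
        if not path or not Path(path).exists():
            raise PipelineError(stage, f"missing input file: {path!r}")
        return fn(path, *a)

    series = load("input", io.load_volume_series, config.volumes)
    motion = load("input", io.load_motion_tsv, config.motion)
    if not config.surface_prefix or not Path(f"{config.surface_prefix}.laminar.json").exists():
        raise PipelineError("input", f"missing surfaces: {config.surface_prefix!r}")
    lmesh = io.load_laminar_mesh(config.surface_prefix)
    gm = load("input", io.load_volume, config.gm_mask)[0] > 0.5
    wm = load("input", io.load_volume, config.wm_mask)[0] > 0.5
    csf = load("input", io.load_volume, config.csf_mask)[0] > 0.5
    networks = {
        name: np.asarray(v, dtype=bool)
        for name, v in load("input", io.load_json, config.networks).items()
    }
    result = run_session(series, motion, lmesh, gm, wm, csf, networks, config.params)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.save_volume(out / "vaper.nii.gz", result.paired.vaper, series.affine)
    io.save_volume(out / "bold.nii.gz", result.paired.bold, series.affine)
    io.save_censor_mask(out / "censor.txt", result.censor.keep)
    for name, fmap in result.fcs_maps.items():
        io.save_fcs_tsv(out / f"fcs_{name}.tsv", fmap.values)
    return result


def run_group(
    session_maps: list,
    regmaps: list,
    template_lmesh: lamsurf.LaminarMesh,
    regions: dict,
    params: PipelineParams | None = None,
):
    """Group analysis: register session FCS maps depth-wise, average, cluster,
    and assess reliability against the random-pattern null.

    ``session_maps`` is a list (one per session) of dicts mapping network name
    to an FCSProfileMap on the individual mesh; ``regmaps`` the matching
    registration maps; ``regions`` maps network name to a template vertex
    mask.  Returns a dict per network with the group map, the Parcellation,
    and (with >= 4 sessions) a ReliabilityResult.
    """
    p = params or PipelineParams()
    if len(session_maps) < 2:
        raise PipelineError("group", "need at least 2 sessions")
    if len(session_maps) != len(regmaps):
        raise PipelineError("group", "session/registration count mismatch")

    registered: dict[str, list[np.ndarray]] = {name: [] for name in regions}
    for maps, rm in zip(session_maps, regmaps):
        for name in regions:
            if name not in maps:
                raise PipelineError("group", f"session missing network {name!r}")
            fmap = maps[name]
            if rm.n_individual != fmap.values.shape[0]:
                raise PipelineError("group", "session on mismatched template")
            ds = lamsurf.LaminarDataset(
                fmap.values[:, :, None], _mesh_for(rm, template_lmesh, fmap)
            )
            reg = lamsurf.apply_registration(rm, ds, template_lmesh)
            registered[name].append(reg.values[:, :, 0])

    results = {}
    rng = np.random.default_rng(p.seed)
    for name, region in regions.items():
        region = np.asarray(region, dtype=bool)
        group_map = np.mean(registered[name], axis=0)
        parc = _stage(
            "cluster",
            cl.kmeans_profiles,
            group_map,
            region,
            k=p.k,
            n_restarts=p.n_restarts,
            seed=int(rng.integers(2**31)),
        )
        rel = None
        if len(session_maps) >= 4:
            dice = _stage(
                "reliability",
                cl.split_half_reliability,
                registered[name],
                region,
                n_rep=p.n_rep,
                seed=int(rng.integers(2**31)),
                k=p.k,
                n_restarts=p.n_restarts,
            )
            null = cl.random_pattern_null(region, n_pairs=p.n_rep, seed=int(rng.integers(2**31)))
            t, pv = cl.compare_dice(dice, null)
            rel = cl.ReliabilityResult(dice_values=dice, null_dice=null, t_stat=t, p_value=pv)
        results[name] = {"group_map": group_map, "parcellation": parc, "reliability": rel}
        logger.info("group[%s]: %d region vertices", name, int(region.sum()))
    return results


def _mesh_for(rm, template_lmesh, fmap):
    """A lightweight mesh stand-in for registration when only maps are given."""
    V = fmap.values.shape[0]
    if V == template_lmesh.n_vertices:
        return template_lmesh
    raise PipelineError("group", "map size does not match any known mesh")


def grid_bookkeeping(dims, upsample: int) -> int:
    """Voxel count of a grid after per-axis upsampling (exact integers)."""
    d = [int(x) for x in dims]
    u = int(upsample)
    if any(x <= 0 for x in d) or u <= 0:
        raise ValueError("dimensions and upsample factor must be positive")
    n = d[0] * d[1] * d[2] * u**3
    logger.info("grid bookkeeping: %s x %d^3 = %d voxels", d, u, n)
    return n


def laminar_size(n_vertices: int, n_depths: int) -> int:
    """Total vertex-sample count of a laminar surface dataset."""
    v, d = int(n_vertices), int(n_depths)
    if v <= 0 or d <= 0:
        raise ValueError("counts must be positive")
    n = v * d
    logger.info("laminar bookkeeping: %d vertices x %d depths = %d", v, d, n)
    return n
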