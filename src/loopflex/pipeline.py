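"""End-to-end protocol orchestration on paired toy systems.

The full protocol, mirroring the enhanced-sampling study design at desk
scale: per system, well-tempered metadynamics exploration from several
starting conformations; pooling; Ca-trace embedding; average-linkage
RMSD clustering at a fixed cutoff; medoid representatives used to seed
balanced unbiased runs; then a *combined* PCA space over both systems
with per-system free-energy surfaces, tICA at a fixed lag, k-means
microstates, MSM estimation with implied-timescale and
Chapman-Kolmogorov diagnostics, PCCA+ macrostates with stationary
probabilities, representatives and directed transition timescales; and
finally a flexibility comparison verdict between the two systems.

Every stochastic stage derives its seed from the master seed through
numpy ``SeedSequence(master, spawn_key=(stage, index))``, so a rerun with
the same config and seed reproduces every number exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .clustering import (ClusterModel, average_linkage_cluster,
                         kabsch_rmsd, kmeans_cluster, pairwise_rmsd_matrix,
                         write_cluster_table, write_matrix)
from .collective_variables import default_loop_cvs
from .errors import ValidationError
from .metadynamics import MetadParams, run_wt_metad
from .msm import (MSMModel, MacrostateModel, ck_test, estimate_msm,
                  its_scan, macrostate_mfpt, macrostate_representatives,
                  pcca_plus)
from .projections import (count_fes_basins, fit_pca, fit_tica,
                          free_energy_surface, project)
from .structure_io import embed_ca_trace
from .toy_dynamics import (TorsionTrajectory, ToySystemSpec, Well,
                           langevin_trajectory)

__all__ = ["SystemConfig", "PipelineConfig", "RunManifest", "SystemResult",
           "PipelineResult", "balance_seeded_runs", "run_pipeline",
           "comparison_report", "default_config", "load_config"]

CONFIG_SCHEMA_VERSION = 1

# stage indices of the seed-derivation counter scheme (documented contract)
_STAGE_METAD = 0
_STAGE_SEEDED = 1
_STAGE_KMEANS = 2


@dataclass
class SystemConfig:
    """One 'antibody' analogue: a toy landscape plus starting points."""

    name: str
    spec: ToySystemSpec
    starts: Tuple[Tuple[float, ...], ...]
    n_macrostates: int = 2

    def __post_init__(self):
        if len(self.starts) == 0:
            raise ValidationError(f"system {self.name}: no starting points")
        if self.n_macrostates < 2:
            raise ValidationError(
                f"system {self.name}: PCCA+ needs n_macrostates >= 2")


@dataclass
class PipelineConfig:
    """Full protocol configuration (see docs/methods.md for rationale)."""

    systems: Tuple[SystemConfig, ...]
    metad: MetadParams = field(default_factory=lambda: MetadParams(
        height=1.2, stride=500, biasfactor=10.0))
    metad_steps: int = 40_000
    metad_save_stride: int = 20
    cluster_cutoff: float = 1.0          # Angstrom
    cluster_stride: int = 10             # frame stride before the RMSD matrix
    seed_run_steps: int = 20_000         # length of each seeded unbiased run
    seed_save_stride: int = 20
    total_sampling_target: int = 480_000  # steps per system, all seeded runs
    pca_dims: int = 2
    tica_lag: int = 25                   # frames
    tica_dims: int = 2
    n_microstates: int = 150
    msm_lag: int = 25                    # frames
    its_lags: Tuple[int, ...] = (5, 10, 25, 50)
    fes_bins: int = 60
    basin_depth: float = 2.0             # kT, threshold for basin counting
    basin_smooth: float = 2.5            # bins, Gaussian smoothing width
    seed: int = 2026
    outdir: Optional[str] = None

    def __post_init__(self):
        if len(self.systems) == 0:
            raise ValidationError("at least one system required")
        if self.seed is None:
            raise ValidationError("a master seed is required")
        if self.msm_lag < 1 or self.tica_lag < 1:
            raise ValidationError("lags must be >= 1")


@dataclass
class RunManifest:
    """Per-stage provenance: parameters, seeds, outputs, wall time."""

    master_seed: int
    stages: List[dict] = field(default_factory=list)

    def record(self, stage: str, params: dict, seed: Optional[int] = None,
               outputs: Optional[Dict[str, str]] = None,
               wall_time: float = 0.0) -> None:
        self.stages.append({"stage": stage, "params": params, "seed": seed,
                            "outputs": outputs or {},
                            "wall_time_s": round(wall_time, 3)})

    def to_json(self) -> str:
        return json.dumps({"master_seed": self.master_seed,
                           "stages": self.stages}, indent=2, default=str)


@dataclass
class SystemResult:
    name: str
    n_metad_frames: int
    cluster: ClusterModel
    runs_per_cluster: int
    n_seeded_runs: int
    msm: MSMModel
    macro: MacrostateModel
    its_table: pd.DataFrame
    ck_table: pd.DataFrame
    fes: "object"
    n_basins: int
    slowest_timescale: float
    representative_rmsd_max: float
    pca_projection: np.ndarray
    tica_eigenvalues: np.ndarray


@dataclass
class PipelineResult:
    manifest: RunManifest
    systems: Dict[str, SystemResult]
    comparison: Optional[pd.DataFrame]
    verdict: Optional[str]


def derived_seed(master: int, *key: int) -> int:
    """Documented counter scheme mapping the master seed to stage seeds."""
    ss = np.random.SeedSequence(int(master), spawn_key=tuple(int(k)
                                                             for k in key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def balance_seeded_runs(n_clusters: int, run_length: float,
                        total_target: float) -> int:
    """Runs per cluster so total sampling approaches a shared target.

    runs_per_cluster = max(1, round(total_target / (n_clusters *
    run_length))) — few clusters get many independent runs, many clusters
    get one each, mirroring the 12-runs-of-100-ns balancing of sparse
    cluster sets against 100+-cluster sets with single runs.
    """
    if n_clusters < 1 or run_length <= 0 or total_target <= 0:
        raise ValidationError("all inputs must be positive")
    return max(1, int(round(total_target / (n_clusters * run_length))))


def _explore_and_seed(cfg: PipelineConfig, sysc: SystemConfig,
                      sys_index: int, manifest: RunManifest):
    """Metadynamics exploration, clustering, and seeded unbiased runs."""
    spec = sysc.spec
    n = spec.n_torsions
    # one CV per torsion-block half: first half 'H3', second half 'L3'
    n_h3 = (n + 1) // 2
    cv_h3, cv_l3 = default_loop_cvs(n_h3, n - n_h3)
    cvs = [cv_h3] if cv_l3 is None else [cv_h3, cv_l3]

    t0 = time.perf_counter()
    metad_frames = []
    for i, start in enumerate(sysc.starts):
        seed = derived_seed(cfg.seed, _STAGE_METAD, sys_index, i)
        traj, hills = run_wt_metad(spec, cvs, cfg.metad, np.asarray(start),
                                   cfg.metad_steps, cfg.metad_save_stride,
                                   seed=seed)
        metad_frames.append(traj.angles)
    pooled = np.vstack(metad_frames)
    manifest.record(f"{sysc.name}:metadynamics",
                    {"n_starts": len(sysc.starts),
                     "n_steps": cfg.metad_steps,
                     "height_kT": cfg.metad.height,
                     "stride": cfg.metad.stride,
                     "biasfactor": cfg.metad.biasfactor},
                    seed=derived_seed(cfg.seed, _STAGE_METAD, sys_index, 0),
                    wall_time=time.perf_counter() - t0)

    # embed pooled biased ensemble and cluster at the shared cutoff
    t0 = time.perf_counter()
    pooled_traj = TorsionTrajectory(pooled,
                                    spec.dt * cfg.metad_save_stride,
                                    origin_label=f"{sysc.name}-metad-pool")
    coords = embed_ca_trace(pooled_traj)
    D = pairwise_rmsd_matrix(coords, stride=cfg.cluster_stride)
    cluster = average_linkage_cluster(D, cfg.cluster_cutoff)
    strided_index = np.arange(pooled.shape[0])[::cfg.cluster_stride]
    rep_frames = strided_index[cluster.representatives]
    rep_coords = coords.coords[rep_frames]
    rep_rmsd_max = 0.0
    for i in range(len(rep_frames)):
        for j in range(i + 1, len(rep_frames)):
            rep_rmsd_max = max(rep_rmsd_max,
                               kabsch_rmsd(rep_coords[i], rep_coords[j]))
    manifest.record(f"{sysc.name}:clustering",
                    {"cutoff_A": cfg.cluster_cutoff,
                     "n_frames": int(strided_index.size),
                     "n_clusters": cluster.n_clusters},
                    wall_time=time.perf_counter() - t0)

    # balanced seeded unbiased runs from the medoid representatives
    t0 = time.perf_counter()
    runs_per = balance_seeded_runs(cluster.n_clusters, cfg.seed_run_steps,
                                   cfg.total_sampling_target)
    seeded: List[TorsionTrajectory] = []
    run_idx = 0
    for rep in rep_frames:
        for _ in range(runs_per):
            seed = derived_seed(cfg.seed, _STAGE_SEEDED, sys_index, run_idx)
            seeded.append(langevin_trajectory(
                spec, pooled[rep], cfg.seed_run_steps,
                cfg.seed_save_stride, seed=seed))
            run_idx += 1
    manifest.record(f"{sysc.name}:seeded-runs",
                    {"runs_per_cluster": runs_per,
                     "n_runs": run_idx,
                     "run_steps": cfg.seed_run_steps},
                    seed=derived_seed(cfg.seed, _STAGE_SEEDED, sys_index, 0),
                    wall_time=time.perf_counter() - t0)
    return cluster, runs_per, seeded, rep_rmsd_max, pooled.shape[0]


def _features(seeded: Sequence[TorsionTrajectory]) -> List[np.ndarray]:
    """Flattened Ca-trace coordinates per seeded run."""
    feats = []
    for traj in seeded:
        coords = embed_ca_trace(traj)
        feats.append(coords.coords.reshape(coords.n_frames, -1))
    return feats


def run_pipeline(config: PipelineConfig, outdir=None,
                 make_figures: bool = False) -> PipelineResult:
    """Execute the full protocol for every configured system.

    Returns a :class:`PipelineResult`; if ``outdir`` (or
    ``config.outdir``) is set, report tables and the manifest are written
    there as delimited text / JSON.
    """
    manifest = RunManifest(master_seed=config.seed)
    per_system = {}
    for si, sysc in enumerate(config.systems):
        per_system[sysc.name] = _explore_and_seed(config, sysc, si, manifest)

    # combined PCA space: pooled fit over every system's seeded ensembles
    t0 = time.perf_counter()
    feats = {name: _features(res[2]) for name, res in per_system.items()}
    pooled_feats = np.vstack([f for fl in feats.values() for f in fl])
    pca = fit_pca(pooled_feats, config.pca_dims)
    pooled_Y = project(pca, pooled_feats)
    ranges = [(pooled_Y[:, d].min(), pooled_Y[:, d].max())
              for d in range(config.pca_dims)]
    manifest.record("combined-pca",
                    {"n_frames": int(pooled_feats.shape[0]),
                     "dims": config.pca_dims,
                     "explained_variance":
                         [round(float(v), 4)
                          for v in pca.explained_variance]},
                    wall_time=time.perf_counter() - t0)

    results: Dict[str, SystemResult] = {}
    for si, sysc in enumerate(config.systems):
        cluster, runs_per, seeded, rep_rmsd_max, n_metad = \
            per_system[sysc.name]
        sys_feats = feats[sysc.name]
        frame_interval = sysc.spec.dt * config.seed_save_stride

        t0 = time.perf_counter()
        Y = project(pca, np.vstack(sys_feats))
        fes = free_energy_surface(Y[:, :2], bins=config.fes_bins,
                                  kT=sysc.spec.kT,
                                  ranges=ranges[:2])
        n_basins = count_fes_basins(fes, config.basin_depth,
                                    config.basin_smooth)

        tica = fit_tica(sys_feats, lag=config.tica_lag, m=config.tica_dims)
        tica_Y = [project(tica, f) for f in sys_feats]
        km_seed = derived_seed(config.seed, _STAGE_KMEANS, si)
        km = kmeans_cluster(np.vstack(tica_Y), config.n_microstates,
                            seed=km_seed)
        # split microstate labels back into per-run discrete trajectories
        lengths = [y.shape[0] for y in tica_Y]
        splits = np.cumsum(lengths)[:-1]
        dtrajs = np.split(km.labels, splits)

        its = its_scan(dtrajs, config.its_lags, n_timescales=2,
                       frame_interval=frame_interval)
        msm = estimate_msm(dtrajs, config.msm_lag, frame_interval)
        ck = ck_test(dtrajs, config.msm_lag, factors=(2, 3))
        macro = pcca_plus(msm.T, msm.pi, sysc.n_macrostates)
        macro.mfpt = macrostate_mfpt(msm.T, msm.pi, macro.assignment,
                                     frame_interval)
        # representatives in tICA space: microstate centers on active set
        active_centers = km.centers[msm.active_set]
        all_tica = np.vstack(tica_Y)
        frame_micro = km.labels
        # map frame microstates into active-set local indices (-1 if pruned)
        local = -np.ones(config.n_microstates, dtype=np.int64)
        local[msm.active_set] = np.arange(msm.active_set.size)
        macrostate_representatives(macro, active_centers, all_tica,
                                   pi=msm.pi,
                                   frame_microstates=local[frame_micro])
        ts = msm.timescales(3)
        slowest = float(ts[0]) if ts.size else np.nan
        manifest.record(f"{sysc.name}:msm",
                        {"lag": config.msm_lag,
                         "n_microstates": config.n_microstates,
                         "connected_fraction":
                             round(float(msm.connected_fraction), 4),
                         "n_macrostates": sysc.n_macrostates},
                        seed=km_seed,
                        wall_time=time.perf_counter() - t0)

        results[sysc.name] = SystemResult(
            name=sysc.name, n_metad_frames=n_metad, cluster=cluster,
            runs_per_cluster=runs_per, n_seeded_runs=len(seeded),
            msm=msm, macro=macro, its_table=its, ck_table=ck, fes=fes,
            n_basins=n_basins, slowest_timescale=slowest,
            representative_rmsd_max=rep_rmsd_max,
            pca_projection=Y, tica_eigenvalues=tica.eigenvalues)

    comparison = None
    verdict = None
    if len(results) == 2:
        a, b = list(results.values())
        comparison, verdict = comparison_report(a, b)

    out = outdir or config.outdir
    if out is not None:
        _write_outputs(Path(out), config, manifest, results, comparison,
                       verdict, make_figures)
    return PipelineResult(manifest=manifest, systems=results,
                          comparison=comparison, verdict=verdict)


def comparison_report(a: SystemResult, b: SystemResult
                      ) -> Tuple[pd.DataFrame, str]:
    """Pairwise flexibility comparison of two completed systems.

    Reports cluster counts at the shared cutoff, occupied free-energy
    basins in the combined PCA space, slowest implied timescales,
    macrostate counts/probabilities and the representative RMSD spread,
    plus a verdict naming the more rigid system (longer slowest
    timescale). Ratios within 1% of unity on all axes give the verdict
    "indistinguishable".
    """
    if a.pca_projection.shape[1] != b.pca_projection.shape[1]:
        raise ValidationError("systems were not projected into a shared "
                              "PCA space")
    rows = []
    for r in (a, b):
        rows.append({
            "system": r.name,
            "n_clusters": r.cluster.n_clusters,
            "n_fes_basins": r.n_basins,
            "slowest_timescale": r.slowest_timescale,
            "n_macrostates": r.macro.n_macrostates,
            "macrostate_probabilities": np.round(r.macro.probabilities,
                                                 4).tolist(),
            "max_representative_rmsd_A": round(r.representative_rmsd_max, 3),
            "connected_fraction": round(float(r.msm.connected_fraction), 4),
        })
    table = pd.DataFrame(rows)

    def _ratio(x, y):
        return np.inf if y == 0 else x / y

    ratios = [_ratio(a.cluster.n_clusters, b.cluster.n_clusters),
              _ratio(a.n_basins, b.n_basins),
              _ratio(a.slowest_timescale, b.slowest_timescale)]
    if all(abs(r - 1.0) < 0.01 for r in ratios):
        verdict = "indistinguishable"
    elif a.slowest_timescale > b.slowest_timescale:
        verdict = f"{a.name} is more rigid"
    else:
        verdict = f"{b.name} is more rigid"
    return table, verdict


def _write_outputs(out: Path, config: PipelineConfig, manifest: RunManifest,
                   results: Dict[str, SystemResult],
                   comparison: Optional[pd.DataFrame],
                   verdict: Optional[str], make_figures: bool) -> None:
    out.mkdir(parents=True, exist_ok=True)

    def _register(stage: str, path: Path):
        digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        manifest.stages.append({"stage": f"write:{stage}", "params": {},
                                "seed": None,
                                "outputs": {str(path.name): digest},
                                "wall_time_s": 0.0})

    for name, r in results.items():
        p = out / f"{name}_clusters.tsv"
        write_cluster_table(r.cluster, p)
        _register(f"{name}:clusters", p)
        p = out / f"{name}_its.csv"
        r.its_table.to_csv(p, index=False)
        _register(f"{name}:its", p)
        p = out / f"{name}_ck.csv"
        r.ck_table.to_csv(p, index=False)
        _register(f"{name}:ck", p)
        p = out / f"{name}_transition_matrix.txt"
        write_matrix(r.msm.T, p)
        _register(f"{name}:T", p)
        p = out / f"{name}_macrostate_mfpt.txt"
        write_matrix(r.macro.mfpt, p)
        _register(f"{name}:mfpt", p)
        if make_figures:
            p = out / f"{name}_fes.png"
            _fes_figure(r, p)
            _register(f"{name}:fes-figure", p)
    if comparison is not None:
        p = out / "comparison.csv"
        comparison.to_csv(p, index=False)
        _register("comparison", p)
        (out / "verdict.txt").write_text(verdict + "\n")
        _register("verdict", out / "verdict.txt")
    (out / "manifest.json").write_text(manifest.to_json())


def _fes_figure(r: SystemResult, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fes = r.fes
    fig, ax = plt.subplots(figsize=(5, 4))
    F = np.where(np.isfinite(fes.free_energy), fes.free_energy, np.nan)
    xc, yc = fes.bin_centers
    im = ax.pcolormesh(xc, yc, F.T, shading="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="free energy (kT)")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(f"{r.name}: combined-PCA free-energy surface")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# packaged default study conditions and config file handling


def default_config(seed: int = 2026) -> PipelineConfig:
    """The packaged flexible/rigid toy pair.

    The flexible system has four comparably deep wells (2.5 kT, width
    0.55 rad) spread over the two-torsion torus; the rigid system has one
    dominant deep well (6.5 kT) and one minor well (5.0 kT), width
    0.45 rad. Barrier heights then differ by roughly a factor two in kT,
    which is the construction behind every directional comparison.
    """
    flexible = SystemConfig(
        name="flexible",
        spec=ToySystemSpec(
            n_torsions=2,
            wells=[Well((-1.8, 0.0), 2.5, 0.55),
                   Well((0.0, 1.8), 2.5, 0.55),
                   Well((1.8, 0.0), 2.5, 0.55),
                   Well((0.0, -1.8), 2.5, 0.55)],
            kT=1.0, friction=1.0, dt=0.01, seed=seed),
        starts=((-1.8, 0.0), (1.8, 0.0)),
        n_macrostates=4)
    rigid = SystemConfig(
        name="rigid",
        spec=ToySystemSpec(
            n_torsions=2,
            wells=[Well((-1.35, 0.0), 6.5, 0.45),
                   Well((1.35, 0.0), 5.0, 0.45)],
            kT=1.0, friction=1.0, dt=0.01, seed=seed),
        starts=((-1.35, 0.0), (1.35, 0.0)),
        n_macrostates=2)
    return PipelineConfig(systems=(flexible, rigid), seed=seed)


def load_config(path) -> PipelineConfig:
    """Read a pipeline configuration from a versioned YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw.get("schema") != CONFIG_SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported config schema {raw.get('schema')!r}; "
            f"expected {CONFIG_SCHEMA_VERSION}")
    systems = []
    for s in raw["systems"]:
        wells = [Well(tuple(w["center"]), w["depth"], w["width"])
                 for w in s["wells"]]
        spec = ToySystemSpec(n_torsions=s["n_torsions"], wells=wells,
                             kT=s.get("kT", 1.0),
                             friction=s.get("friction", 1.0),
                             dt=s.get("dt", 0.01),
                             seed=s.get("seed", raw.get("seed", 0)))
        systems.append(SystemConfig(name=s["name"], spec=spec,
                                    starts=tuple(tuple(x)
                                                 for x in s["starts"]),
                                    n_macrostates=s.get("n_macrostates", 2)))
    metad_raw = raw.get("metadynamics", {})
    metad = MetadParams(
        height=metad_raw.get("height", 1.2),
        sigmas=tuple(metad_raw["sigmas"]) if "sigmas" in metad_raw else None,
        stride=metad_raw.get("stride", 500),
        biasfactor=metad_raw.get("biasfactor", 10.0),
        kT=metad_raw.get("kT", 1.0))
    kwargs = {k: raw[k] for k in
              ("metad_steps", "metad_save_stride", "cluster_cutoff",
               "cluster_stride", "seed_run_steps", "seed_save_stride",
               "total_sampling_target", "pca_dims", "tica_lag", "tica_dims",
               "n_microstates", "msm_lag", "fes_bins", "basin_depth",
               "basin_smooth", "outdir") if k in raw}
    if "its_lags" in raw:
        kwargs["its_lags"] = tuple(raw["its_lags"])
    return PipelineConfig(systems=tuple(systems), metad=metad,
                          seed=raw["seed"], **kwargs)
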