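"""Simulation-study driver: abnormal-activation sweeps and summaries.

Runs the forward pipeline for a grid of abnormal patch activations
(delayed velocity sweeps, dyssynchronous jitter sweeps, three connection
types, strength scaling) against one normal-activation reference, and
aggregates per-simulation summary QRS-CC values into a table of
median/IQR/min/max per simulation type plus a per-lead mean +/- SD CC map.

The exact membership of the original 153-sequence design is not published;
the default grid documented in :class:`StudyConfig` is a reconstruction
(4 patch locations x [3 connection types x 6 delayed velocities + 3 x 6
dyssynchronous jitter draws] + 9 strength-scaled simulations = 153).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activation import (
    Velocities,
    default_foci,
    delayed_patch_activation,
    dyssynchronous_patch_activation,
    ventricular_activation,
)
from .anatomy import PATCH_LOCATIONS, AnatomyModel, make_synthetic_anatomy
from .bem import VolumeConductor
from .patch import PatchSpec, embed_patch
from .sources import SourceConfig, nominal_strength, qrs_window, simulate_potentials
from .stats import compare_groups, qrs_cc

__all__ = ["StudyConfig", "SimulationRow", "StudyResult", "run_simulation_study"]

CONNECTION_SUFFIX = {
    "full_inner": "",
    "outer_ring_full": "_type1",
    "outer_ring_latest_25pct": "_type2",
}


@dataclass
class SimulationRow:
    """One abnormal simulation of the sweep."""

    sim_id: int
    location: str
    kind: str  # 'delayed' | 'dyssynchronous'
    connection_type: str
    patch_velocity: float
    jitter_max: float = 0.0
    jitter_seed: int = 0
    strength_scale: float = 1.0

    @property
    def sim_type(self) -> str:
        return self.kind + CONNECTION_SUFFIX[self.connection_type]


@dataclass
class StudyConfig:
    """Study design: anatomy, patch geometry and the simulation grid."""

    seed: int = 1
    locations: tuple = ("rv_free_wall", "lv_free_wall", "rv_tricuspid", "rvot")
    patch_radius: float = 15.0
    patch_depth: float = 3.0
    patch_host: str = "epicardial"
    delayed_velocities: tuple = (0.25, 0.33, 0.41, 0.49, 0.57, 0.65)
    dyssynchronous_velocity: float = 0.45
    jitter_levels: tuple = (30.0, 42.0, 54.0, 66.0, 78.0, 90.0)
    connection_types: tuple = (
        "full_inner",
        "outer_ring_full",
        "outer_ring_latest_25pct",
    )
    strength_scales: tuple = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    strength_scale_location: str = "rv_free_wall"
    velocities: Velocities = field(default_factory=Velocities)
    source: SourceConfig = field(default_factory=SourceConfig)
    summary: str = "min_lead"
    anatomy_params: object = None

    def rows(self) -> list[SimulationRow]:
        """Expand the grid into one row per abnormal simulation."""
        rows: list[SimulationRow] = []
        sid = 0
        for loc in self.locations:
            for conn in self.connection_types:
                for v in self.delayed_velocities:
                    rows.append(
                        SimulationRow(sid, loc, "delayed", conn, patch_velocity=v)
                    )
                    sid += 1
                for i, jit in enumerate(self.jitter_levels):
                    rows.append(
                        SimulationRow(
                            sid,
                            loc,
                            "dyssynchronous",
                            conn,
                            patch_velocity=self.dyssynchronous_velocity,
                            jitter_max=jit,
                            jitter_seed=self.seed * 10_000 + sid,
                        )
                    )
                    sid += 1
        for f in self.strength_scales:
            rows.append(
                SimulationRow(
                    sid,
                    self.strength_scale_location,
                    "dyssynchronous",
                    "full_inner",
                    patch_velocity=self.dyssynchronous_velocity,
                    jitter_max=60.0,
                    jitter_seed=self.seed * 10_000 + sid,
                    strength_scale=f,
                )
            )
            sid += 1
        return rows

    def validate(self) -> None:
        unknown = set(self.locations) - set(PATCH_LOCATIONS)
        if unknown:
            raise ValueError(f"unknown patch locations {sorted(unknown)}")
        if self.strength_scales and self.strength_scale_location not in self.locations:
            raise ValueError("strength-scale location must be one of the study locations")
        for v in self.delayed_velocities:
            if not 0 < v <= self.velocities.surface:
                raise ValueError(f"delayed velocity {v} outside (0, normal]")
        for j in self.jitter_levels:
            if j < 0:
                raise ValueError("jitter level must be >= 0")


@dataclass
class StudyResult:
    """Per-simulation table, Table-2-style summary and per-lead CC map."""

    simulations: pd.DataFrame
    summary_table: pd.DataFrame
    lead_cc_map: pd.DataFrame  # mean/sd of per-lead CC by location
    group_tests: dict
    normal_qrs_duration_ms: float
    metadata: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.simulations.to_csv(outdir / "simulations.csv", index=False)
        self.summary_table.to_csv(outdir / "summary.csv")
        self.lead_cc_map.to_csv(outdir / "lead_cc_map.csv", index=False)
        (outdir / "manifest.json").write_text(
            json.dumps(
                {
                    "metadata": self.metadata,
                    "group_tests": {
                        k: {kk: float(vv) for kk, vv in v.items()}
                        for k, v in self.group_tests.items()
                    },
                    "normal_qrs_duration_ms": self.normal_qrs_duration_ms,
                },
                indent=2,
            )
        )


def summarize_cc(per_sim_cc: pd.DataFrame) -> pd.DataFrame:
    """Median/IQR/min/max of summary CC per simulation type.

    A pure function of the per-simulation table, so the summary can be
    recomputed from the saved CSV.
    """
    rows = {}
    for sim_type, grp in per_sim_cc.groupby("sim_type"):
        cc = grp["summary_cc"].to_numpy()
        rows[sim_type] = {
            "Median": np.median(cc),
            "IQR1": np.percentile(cc, 25),
            "IQR3": np.percentile(cc, 75),
            "Min": cc.min(),
            "Max": cc.max(),
        }
    return pd.DataFrame(rows).T.sort_index()


def run_simulation_study(
    config: StudyConfig | None = None,
    anatomy: AnatomyModel | None = None,
    progress: bool = False,
) -> StudyResult:
    """Run the abnormal-activation sweep and aggregate the statistics.

    Fully deterministic for a fixed config (all randomness is derived from
    ``config.seed``).  The volume conductor is assembled once; per patch
    location only the dented-ventricle and patch transfer matrices are
    recomputed, and per simulation only the patch activation and its
    potential contribution.
    """
    config = config or StudyConfig()
    config.validate()
    rows = config.rows()

    anatomy = anatomy or make_synthetic_anatomy(config.anatomy_params, seed=config.seed)
    foci = default_foci(anatomy)
    vmap = ventricular_activation(anatomy.ventricles, foci)
    finite = vmap.times[np.isfinite(vmap.times)]
    normal_qrs = float(finite.max() - finite.min())

    vc = VolumeConductor(anatomy)
    A_normal = vc.transfer_matrix(anatomy.source_surface)
    src = config.source
    normal_bsp = simulate_potentials(
        {"ventricles": A_normal}, {"ventricles": vmap}, src, labels=anatomy.electrode_labels
    )

    heart_center = anatomy.source_surface.vertices.mean(axis=0)
    patched, transfers = {}, {}
    for loc in config.locations:
        spec = PatchSpec(
            center=heart_center + 60.0 * PATCH_LOCATIONS[loc] / np.linalg.norm(PATCH_LOCATIONS[loc]),
            radius=config.patch_radius,
            depth=config.patch_depth,
            host=config.patch_host,
        )
        pm = embed_patch(anatomy.ventricles, spec)
        patched[loc] = pm
        transfers[loc] = {
            "ventricles": vc.transfer_matrix(pm.ventricles.surface),
            "patch_0": vc.transfer_matrix(pm.patches[0].mesh),
        }

    # the dented-ventricle BSP contribution is per-location constant
    records, lead_records = [], []
    strength = nominal_strength(src)
    for loc in config.locations:
        pm = patched[loc]
        base = simulate_potentials(
            {"ventricles": transfers[loc]["ventricles"]},
            {"ventricles": vmap},
            src,
            labels=anatomy.electrode_labels,
        )
        for row in (r for r in rows if r.location == loc):
            pm.patches[0].spec.connection_type = row.connection_type
            if row.kind == "delayed":
                pmap = delayed_patch_activation(pm, vmap, row.patch_velocity)
            else:
                pmap = dyssynchronous_patch_activation(
                    pm, vmap, row.jitter_max, seed=row.jitter_seed,
                    patch_velocity=row.patch_velocity,
                )
            patch_bsp = simulate_potentials(
                {"patch_0": transfers[loc]["patch_0"]},
                {"patch_0": pmap},
                src,
                strength_scales={"patch_0": row.strength_scale},
                labels=anatomy.electrode_labels,
            )
            abnormal = _superpose(base, patch_bsp, normal_bsp.times)
            normal_ref = _extend(normal_bsp, abnormal.times)
            window = qrs_window([vmap, pmap])
            window = (max(window[0], abnormal.times[0]), min(window[1], abnormal.times[-1]))
            qrs_dur = float(
                max(np.max(pmap.times[np.isfinite(pmap.times)]), finite.max())
                - min(np.min(pmap.times[np.isfinite(pmap.times)]), finite.min())
            )
            res = qrs_cc(
                normal_ref,
                abnormal,
                window,
                qrs_duration_ms=qrs_dur,
                summary=config.summary,
            )
            records.append(
                {
                    "sim_id": row.sim_id,
                    "location": row.location,
                    "kind": row.kind,
                    "sim_type": row.sim_type,
                    "connection_type": row.connection_type,
                    "patch_velocity": row.patch_velocity,
                    "jitter_max": row.jitter_max,
                    "jitter_seed": row.jitter_seed,
                    "strength_scale": row.strength_scale,
                    "summary_cc": res.summary_cc,
                    "most_affected_lead": res.most_affected_lead,
                    "most_affected_cc": res.most_affected_cc,
                    "qrs_duration_ms": res.qrs_duration_ms,
                }
            )
            lead_records.append(
                pd.DataFrame(
                    {
                        "sim_id": row.sim_id,
                        "location": row.location,
                        "lead": res.lead_labels,
                        "cc": res.lead_cc,
                    }
                )
            )
            if progress:
                print(f"[{row.sim_id + 1}/{len(rows)}] {row.location} {row.sim_type}")

    sims = pd.DataFrame.from_records(records)
    lead_cc = pd.concat(lead_records, ignore_index=True)
    lead_map = (
        lead_cc.groupby(["location", "lead"])["cc"]
        .agg(["mean", "std"])
        .reset_index()
    )

    tests = {}
    for a, b in [("delayed", "dyssynchronous")] + [
        (f"delayed{s}", f"dyssynchronous{s}") for s in ("_type1", "_type2")
    ]:
        ga = sims.loc[sims.sim_type == a, "summary_cc"]
        gb = sims.loc[sims.sim_type == b, "summary_cc"]
        if len(ga) >= 2 and len(gb) >= 2:
            g = compare_groups(ga, gb)
            tests[f"{a}_vs_{b}"] = {
                "median_a": g.medians[0],
                "median_b": g.medians[1],
                "mannwhitney_u": g.mannwhitney_u,
                "mannwhitney_p": g.mannwhitney_p,
            }

    return StudyResult(
        simulations=sims,
        summary_table=summarize_cc(sims),
        lead_cc_map=lead_map,
        group_tests=tests,
        normal_qrs_duration_ms=normal_qrs,
        metadata={
            "n_simulations": len(rows),
            "seed": config.seed,
            "strength_mA_per_m": strength,
            "summary": config.summary,
        },
    )


def _extend(tr, grid):
    """Re-sample traces onto a longer grid, holding the final value.

    Valid because after complete activation the potentials are constant
    (a fully depolarized closed layer contributes nothing external).
    """
    from .sources import PotentialTraces

    if len(grid) == len(tr.times) and grid[0] == tr.times[0]:
        return tr
    v = np.zeros((tr.values.shape[0], len(grid)))
    n = min(len(tr.times), len(grid))
    v[:, :n] = tr.values[:, :n]
    v[:, n:] = tr.values[:, -1:]
    return PotentialTraces(np.asarray(grid), v, labels=tr.labels)


def _superpose(a, b, times):
    """Sum two trace sets on the union grid (zero-padded)."""
    from .sources import PotentialTraces

    t0 = min(a.times[0], b.times[0])
    t1 = max(a.times[-1], b.times[-1])
    dt = a.dt_ms
    grid = np.arange(t0, t1 + 0.5 * dt, dt)

    def expand(tr):
        v = np.zeros((tr.values.shape[0], len(grid)))
        i0 = int(round((tr.times[0] - t0) / dt))
        v[:, i0 : i0 + tr.values.shape[1]] = tr.values
        # potentials hold their end value after complete activation
        v[:, i0 + tr.values.shape[1] :] = tr.values[:, -1:]
        return v

    return PotentialTraces(grid, expand(a) + expand(b), labels=a.labels)


def nearest_electrodes(anatomy: AnatomyModel, point: np.ndarray, k: int = 5) -> np.ndarray:
    """Indices of the k electrodes closest to a point (patch centre)."""
    d = np.linalg.norm(anatomy.electrode_positions - np.asarray(point), axis=1)
    return np.argsort(d)[:k]
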