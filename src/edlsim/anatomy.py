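"""Anatomical models: conductor compartments, ventricular wall, electrodes.

The synthetic anatomy stands in for an imaging-derived patient model so the
whole pipeline runs without external data.  It nests ellipsoid surfaces —
torso, two lungs, two ventricular blood cavities — around a biventricular
source surface built from an epicardial shell and two endocardial shells
merged into one closed surface bounding the myocardial wall (endocardial
shells are flipped so the merged surface is oriented out of the wall).

Units: mm; conductivities S/m.  Coordinate convention: right-handed, x to
the patient's left, y posterior, z cranial; the anterior chest is at y < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import TriSurface, ellipsoid, merge_surfaces, validate_surface

__all__ = [
    "ConfigurationError",
    "Compartment",
    "VentricularModel",
    "AnatomyModel",
    "SyntheticAnatomyParams",
    "make_synthetic_anatomy",
    "PATCH_LOCATIONS",
]

SIGMA_THORAX = 0.2
SIGMA_LUNG = 0.04
SIGMA_BLOOD = 0.6


class ConfigurationError(ValueError):
    """Inconsistent anatomy configuration (nesting, electrodes, labels)."""


def _ellipsoid_inside(center, semi_axes):
    c = np.asarray(center, dtype=float)
    a = np.asarray(semi_axes, dtype=float)

    def inside(points: np.ndarray) -> np.ndarray:
        q = (np.atleast_2d(points) - c) / a
        return np.einsum("ij,ij->i", q, q) < 1.0

    return inside


@dataclass
class Compartment:
    """A homogeneous conductor region bounded by a closed surface."""

    surface: TriSurface
    sigma_in: float
    sigma_out: float
    inside_fn: object = None  # optional fast analytic containment test

    def contains(self, points: np.ndarray) -> np.ndarray:
        if self.inside_fn is not None:
            return self.inside_fn(points)
        return self.surface.to_trimesh().contains(np.atleast_2d(points))


@dataclass
class VentricularModel:
    """Closed biventricular source surface plus wall metadata.

    ``surface`` bounds the myocardial wall (epicardium outward, endocardial
    shells flipped).  ``endo_epi_pairs`` give, for every endocardial vertex,
    the nearest epicardial vertex: these carry the transmural activation
    edges.  ``wall_thickness`` (per epicardial vertex, mm) bounds admissible
    patch dent depths.
    """

    surface: TriSurface
    epi_vertex_ids: np.ndarray
    endo_vertex_ids: np.ndarray
    endo_epi_pairs: np.ndarray  # (n_endo, 2): [endo vid, epi vid]
    wall_thickness: np.ndarray  # per epi vertex, mm
    endo_component: np.ndarray  # per endo vid: 0 = LV, 1 = RV


@dataclass
class AnatomyModel:
    """Compartments + ventricular source model + electrode layout."""

    compartments: list  # torso first
    ventricles: VentricularModel
    electrode_labels: list
    electrode_positions: np.ndarray  # (64, 3), on the torso surface
    electrode_vertex_ids: np.ndarray  # torso-mesh vertex index per electrode
    lead_map: dict  # 'RA','LA','LL','V1'..'V6' -> electrode index (0-63)
    torso_index: int = 0
    sigma_myocardium: float = SIGMA_THORAX
    metadata: dict = field(default_factory=dict)

    @property
    def torso(self) -> TriSurface:
        return self.compartments[self.torso_index].surface

    @property
    def source_surface(self) -> TriSurface:
        return self.ventricles.surface

    def electrode_node_indices(self) -> np.ndarray:
        return self.electrode_vertex_ids

    def conductivity_at(self, points: np.ndarray) -> np.ndarray:
        """sigma (S/m) at interior points; 0 outside the torso (air)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        sigma = np.zeros(len(pts))
        for comp in self.compartments:  # torso first, inner compartments override
            sigma[comp.contains(pts)] = comp.sigma_in
        return sigma

    def validate(self) -> None:
        for comp in self.compartments:
            diag = validate_surface(comp.surface)
            if not diag.ok:
                raise ConfigurationError(f"invalid compartment {comp.surface.name!r}")
        torso = self.compartments[self.torso_index]
        if torso.sigma_out != 0.0:
            raise ConfigurationError("conductivity outside the torso must be 0 (air)")
        for comp in self.compartments:
            if comp is torso:
                continue
            if not np.all(torso.contains(comp.surface.vertices)):
                raise ConfigurationError(
                    f"compartment {comp.surface.name!r} is not nested inside the torso"
                )
        if not np.all(torso.contains(self.source_surface.vertices)):
            raise ConfigurationError("source surface is not inside the torso")
        # electrodes coincide with torso mesh vertices by construction
        d = np.linalg.norm(
            self.electrode_positions - torso.surface.vertices[self.electrode_vertex_ids], axis=1
        )
        if np.any(d > 1e-9):
            raise ConfigurationError("electrodes do not lie on the torso surface")
        missing = REQUIRED_LEADS - set(self.lead_map)
        if missing:
            raise ConfigurationError(f"lead map missing {sorted(missing)}")

    def save(self, outdir) -> None:
        """Write surfaces (PLY), electrodes (CSV) and a manifest (JSON)."""
        import json
        from pathlib import Path

        from .mesh import save_surface

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}
        for comp in self.compartments:
            fn = f"{comp.surface.name}.ply"
            save_surface(comp.surface, str(outdir / fn))
            files[comp.surface.name] = {
                "file": fn,
                "sigma_in": comp.sigma_in,
                "sigma_out": comp.sigma_out,
            }
        save_surface(self.source_surface, str(outdir / "ventricles.ply"))
        files["ventricles"] = {"file": "ventricles.ply", "role": "source"}
        pd.DataFrame(
            {
                "label": self.electrode_labels,
                "x": self.electrode_positions[:, 0],
                "y": self.electrode_positions[:, 1],
                "z": self.electrode_positions[:, 2],
            }
        ).to_csv(outdir / "electrodes.csv", index=False)
        manifest = {
            "surfaces": files,
            "electrodes": "electrodes.csv",
            "lead_map": {k: int(v) for k, v in self.lead_map.items()},
            "metadata": self.metadata,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


REQUIRED_LEADS = {"RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6"}


@dataclass
class SyntheticAnatomyParams:
    """Size/resolution settings of the synthetic anatomy (mm).

    Defaults approximate an adult thorax.  ``*_subdiv`` are icosphere
    subdivision levels (2 -> 320 triangles, 3 -> 1280).
    """

    torso_axes: tuple = (160.0, 110.0, 300.0)
    lung_axes: tuple = (40.0, 60.0, 130.0)
    lung_centers: tuple = ((-95.0, 10.0, 50.0), (95.0, 10.0, 50.0))
    heart_center: tuple = (0.0, -40.0, -10.0)
    epi_axes: tuple = (45.0, 40.0, 60.0)
    lv_cavity_axes: tuple = (17.0, 15.0, 38.0)
    lv_cavity_offset: tuple = (17.0, 0.0, 0.0)
    rv_cavity_axes: tuple = (13.0, 12.0, 33.0)
    rv_cavity_offset: tuple = (-18.0, -2.0, 2.0)
    blood_shrink: float = 1.5  # gap between blood interface and endocardium
    torso_subdiv: int = 3
    lung_subdiv: int = 2
    epi_subdiv: int = 3
    endo_subdiv: int = 2
    jitter_mm: float = 0.05  # seed-dependent symmetry-breaking perturbation


#: Patch-centre landmarks (unit directions from the heart centre), resolved to
#: the nearest epicardial vertex at generation time.
PATCH_LOCATIONS = {
    "rv_free_wall": np.array([-0.8, -0.55, 0.0]),
    "lv_free_wall": np.array([0.85, -0.35, -0.2]),
    "rv_tricuspid": np.array([-0.75, 0.3, 0.55]),
    "rvot": np.array([-0.35, -0.5, 0.85]),
}


def make_synthetic_anatomy(
    params: SyntheticAnatomyParams | None = None, seed: int = 1
) -> AnatomyModel:
    """Generate the default nested-ellipsoid anatomy with 64 electrodes.

    Deterministic for a fixed ``(params, seed)`` pair: the seed drives only a
    small symmetry-breaking vertex perturbation.  Conductivities follow the
    standard piecewise-homogeneous torso: 0.2 S/m thorax and myocardium,
    0.04 S/m lungs, 0.6 S/m blood.
    """
    p = params or SyntheticAnatomyParams()
    rng = np.random.default_rng(seed)
    hc = np.asarray(p.heart_center)

    if np.any(np.asarray(p.epi_axes) >= np.asarray(p.torso_axes)):
        raise ConfigurationError("ventricles do not fit inside the torso")
    for sub, label in [(p.torso_subdiv, "torso"), (p.lung_subdiv, "lung"),
                       (p.epi_subdiv, "epi"), (p.endo_subdiv, "endo")]:
        if sub < 2:  # subdivision 2 = 320 triangles per surface
            raise ConfigurationError(f"{label}_subdiv must be >= 2 (>=100 triangles)")

    def jitter(surface: TriSurface) -> TriSurface:
        if p.jitter_mm > 0.0:
            # radial-ish perturbation, deterministic in rng draw order
            surface.vertices = surface.vertices + p.jitter_mm * rng.standard_normal(
                surface.vertices.shape
            )
        return surface

    torso = jitter(ellipsoid(p.torso_axes, subdivisions=p.torso_subdiv, name="torso"))
    lungs = [
        jitter(ellipsoid(p.lung_axes, c, subdivisions=p.lung_subdiv, name=n))
        for c, n in zip(p.lung_centers, ("lung_right", "lung_left"))
    ]

    lv_c = hc + np.asarray(p.lv_cavity_offset)
    rv_c = hc + np.asarray(p.rv_cavity_offset)
    epi = ellipsoid(p.epi_axes, hc, subdivisions=p.epi_subdiv, name="epicardium")
    lv_endo = ellipsoid(p.lv_cavity_axes, lv_c, subdivisions=p.endo_subdiv, name="lv_endo")
    rv_endo = ellipsoid(p.rv_cavity_axes, rv_c, subdivisions=p.endo_subdiv, name="rv_endo")
    source = merge_surfaces(
        [epi, lv_endo.flipped(), rv_endo.flipped()], name="ventricles"
    )

    n_epi, n_lv, n_rv = epi.n_vertices, lv_endo.n_vertices, rv_endo.n_vertices
    epi_ids = np.arange(n_epi)
    endo_ids = np.arange(n_epi, n_epi + n_lv + n_rv)
    endo_component = np.concatenate([np.zeros(n_lv, int), np.ones(n_rv, int)])

    endo_pos = source.vertices[endo_ids]
    epi_pos = source.vertices[epi_ids]
    d = np.linalg.norm(endo_pos[:, None, :] - epi_pos[None, :, :], axis=2)
    nearest_epi = d.argmin(axis=1)
    endo_epi_pairs = np.column_stack([endo_ids, epi_ids[nearest_epi]])
    wall_thickness = np.linalg.norm(
        epi_pos[:, None, :] - endo_pos[None, :, :], axis=2
    ).min(axis=1)

    ventricles = VentricularModel(
        surface=source,
        epi_vertex_ids=epi_ids,
        endo_vertex_ids=endo_ids,
        endo_epi_pairs=endo_epi_pairs,
        wall_thickness=wall_thickness,
        endo_component=endo_component,
    )

    blood = [
        ellipsoid(
            tuple(np.asarray(ax) - p.blood_shrink), c, subdivisions=p.endo_subdiv, name=n
        )
        for ax, c, n in (
            (p.lv_cavity_axes, lv_c, "blood_lv"),
            (p.rv_cavity_axes, rv_c, "blood_rv"),
        )
    ]

    compartments = [
        Compartment(torso, SIGMA_THORAX, 0.0),
        Compartment(
            lungs[0], SIGMA_LUNG, SIGMA_THORAX,
            _ellipsoid_inside(p.lung_centers[0], p.lung_axes),
        ),
        Compartment(
            lungs[1], SIGMA_LUNG, SIGMA_THORAX,
            _ellipsoid_inside(p.lung_centers[1], p.lung_axes),
        ),
        Compartment(
            blood[0], SIGMA_BLOOD, SIGMA_THORAX,
            _ellipsoid_inside(lv_c, np.asarray(p.lv_cavity_axes) - p.blood_shrink),
        ),
        Compartment(
            blood[1], SIGMA_BLOOD, SIGMA_THORAX,
            _ellipsoid_inside(rv_c, np.asarray(p.rv_cavity_axes) - p.blood_shrink),
        ),
    ]
    # the torso compartment keeps a mesh-free analytic test too (pre-jitter
    # ellipsoid): adequate because the jitter is far smaller than any margin
    compartments[0].inside_fn = _ellipsoid_inside((0, 0, 0), p.torso_axes)

    labels, positions, vids, lead_map = _electrode_grid(torso, p)

    model = AnatomyModel(
        compartments=compartments,
        ventricles=ventricles,
        electrode_labels=labels,
        electrode_positions=positions,
        electrode_vertex_ids=vids,
        lead_map=lead_map,
        metadata={"generator": "make_synthetic_anatomy", "seed": seed},
    )
    model.validate()
    return model


def _electrode_grid(torso: TriSurface, p: SyntheticAnatomyParams):
    """64-lead layout: 8x6 anterior + 8x2 posterior grid, snapped to vertices.

    Columns run from the patient's right (col 1) to left (col 8).  The
    12-lead subset: V1..V6 are columns 3..8 of the third anterior row
    (z = -15 mm); RA/LA sit at the outer columns of the top anterior row and
    LL at the left end of the lowest anterior row.
    """
    ax, ay, az = p.torso_axes
    angles = np.deg2rad(np.linspace(-70, 70, 8))
    rows_ant = np.array([-75.0, -45.0, -15.0, 15.0, 45.0, 75.0])
    rows_post = np.array([-30.0, 30.0])

    targets, labels = [], []
    for r, z in enumerate(rows_ant):
        s = np.sqrt(max(1e-9, 1.0 - (z / az) ** 2))
        for c, th in enumerate(angles):
            targets.append([ax * s * np.sin(th), -ay * s * np.cos(th), z])
            labels.append(f"A{r + 1}{c + 1}")
    post_angles = np.deg2rad(np.linspace(-60, 60, 8))
    for r, z in enumerate(rows_post):
        s = np.sqrt(max(1e-9, 1.0 - (z / az) ** 2))
        for c, th in enumerate(post_angles):
            targets.append([ax * s * np.sin(th), ay * s * np.cos(th), z])
            labels.append(f"P{r + 1}{c + 1}")
    targets = np.asarray(targets)

    d = np.linalg.norm(targets[:, None, :] - torso.vertices[None, :, :], axis=2)
    vids = np.full(len(targets), -1, dtype=int)
    for i in np.argsort(d.min(axis=1)):  # greedy, best-matched first
        for v in np.argsort(d[i]):
            if v not in vids:
                vids[i] = v
                break
    if np.any(vids < 0):
        raise ConfigurationError("could not place 64 distinct electrodes")
    positions = torso.vertices[vids].copy()

    def idx(label):
        return labels.index(label)

    lead_map = {
        "RA": idx("A61"),
        "LA": idx("A68"),
        "LL": idx("A18"),
        "V1": idx("A33"),
        "V2": idx("A34"),
        "V3": idx("A35"),
        "V4": idx("A36"),
        "V5": idx("A37"),
        "V6": idx("A38"),
    }
    return labels, positions, vids, lead_map
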