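"""Cardiac electrograms: unipolar/bipolar traces, LAT and voltage maps.

Unipolar electrograms are potentials simulated at cardiac observation
points placed a small distance along the inward normal from the source
surface nodes (the potential is discontinuous across the dipole layer
itself).  Bipolar electrograms subtract the unipolar traces of direct
mesh neighbours; the per-node bipolar voltage is the maximum absolute
potential difference to any neighbour over time.  Local activation time
(LAT) is annotated either from the simulation (delta itself) or from the
electrogram as the instant of maximal absolute bipolar amplitude, which
corresponds to the maximum downslope -dV/dt of the unipolar signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import TriSurface
from .sources import PotentialTraces

__all__ = [
    "ElectrogramSet",
    "cardiac_observation_points",
    "bipolar_from_unipolar",
    "annotate_lat",
    "fractionation_index",
]


def cardiac_observation_points(
    surface: TriSurface, offset_mm: float = 0.5, side: str = "inside"
) -> np.ndarray:
    """Observation points offset from each surface node.

    ``side="inside"`` (default) offsets along the inward normal, into the
    tissue; ``side="outside"`` offsets away from the surface, where a
    mapping catheter in contact with the wall records.
    """
    sign = -1.0 if side == "inside" else 1.0
    return surface.vertices + sign * offset_mm * surface.vertex_normals()


def _neighbor_lists(surface: TriSurface) -> list[np.ndarray]:
    edges = surface.edge_array()
    nbrs: list[list[int]] = [[] for _ in range(surface.n_vertices)]
    for i, j in edges:
        nbrs[i].append(j)
        nbrs[j].append(i)
    return [np.array(sorted(n), dtype=int) for n in nbrs]


@dataclass
class ElectrogramSet:
    """Unipolar traces per cardiac node with derived bipolar quantities."""

    unipolar: PotentialTraces  # channels = surface nodes
    surface: TriSurface
    bipolar_voltage: np.ndarray = None  # (n,) mV
    best_neighbor: np.ndarray = None  # neighbour attaining the voltage
    isolated: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def times(self) -> np.ndarray:
        return self.unipolar.times

    def bipolar_trace(self, i: int, j: int) -> np.ndarray:
        """bipolar(i, j)(t) = uni_i(t) - uni_j(t)."""
        return self.unipolar.values[i] - self.unipolar.values[j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": np.arange(self.surface.n_vertices),
                "x": self.surface.vertices[:, 0],
                "y": self.surface.vertices[:, 1],
                "z": self.surface.vertices[:, 2],
                "bipolar_voltage_mv": self.bipolar_voltage,
            }
        )


def bipolar_from_unipolar(unipolar: PotentialTraces, surface: TriSurface) -> ElectrogramSet:
    """Derive bipolar voltages from unipolar traces over the mesh adjacency.

    Per node, the bipolar voltage is the maximum over direct neighbours of
    the maximum absolute instantaneous potential difference.  Nodes without
    neighbours are flagged isolated (voltage NaN).
    """
    if unipolar.values.shape[0] != surface.n_vertices:
        raise ValueError("need one unipolar trace per surface node")
    nbrs = _neighbor_lists(surface)
    n = surface.n_vertices
    voltage = np.full(n, np.nan)
    best = np.full(n, -1, dtype=int)
    isolated = []
    for i in range(n):
        if len(nbrs[i]) == 0:
            isolated.append(i)
            continue
        diffs = np.abs(unipolar.values[i][None, :] - unipolar.values[nbrs[i]])
        per_nbr = diffs.max(axis=1)
        k = int(per_nbr.argmax())
        voltage[i] = per_nbr[k]
        best[i] = nbrs[i][k]
    return ElectrogramSet(
        unipolar=unipolar,
        surface=surface,
        bipolar_voltage=voltage,
        best_neighbor=best,
        isolated=np.array(isolated, dtype=int),
    )


def annotate_lat(
    egms: ElectrogramSet,
    mode: str = "electrogram",
    activation_times: np.ndarray | None = None,
    flat_tol: float = 1e-9,
) -> np.ndarray:
    """Local activation times (ms) per node.

    ``mode="simulated"`` returns the prescribed activation times delta.
    ``mode="electrogram"`` annotates the instant of maximal absolute
    bipolar amplitude against the node's best neighbour.
    ``mode="unipolar_downslope"`` annotates the maximal negative dV/dt of
    the unipolar trace (equivalent criterion, exposed as a variant).
    Flat traces yield NaN (no-LAT flag).
    """
    if mode == "simulated":
        if activation_times is None:
            raise ValueError("simulated mode needs the activation map times")
        return np.asarray(activation_times, dtype=float).copy()
    t = egms.times
    n = egms.surface.n_vertices
    lat = np.full(n, np.nan)
    for i in range(n):
        if mode == "electrogram":
            j = egms.best_neighbor[i]
            if j < 0:
                continue
            sig = np.abs(egms.bipolar_trace(i, j))
            if sig.max() <= flat_tol:
                continue
            lat[i] = t[int(sig.argmax())]
        elif mode == "unipolar_downslope":
            dv = np.gradient(egms.unipolar.values[i], t)
            if np.ptp(egms.unipolar.values[i]) <= flat_tol:
                continue
            lat[i] = t[int(dv.argmin())]
        else:
            raise ValueError(f"unknown LAT mode {mode!r}")
    return lat


def fractionation_index(
    egms: ElectrogramSet, noise_floor_mv_per_ms: float = 0.05
) -> np.ndarray:
    """Qualitative fractionation metric: deflection count per node.

    Counts sign changes of the unipolar dV/dt whose flanking slopes exceed
    the noise floor.  A descriptive index of waveform complexity, not a
    clinical fractionation definition.
    """
    t = egms.times
    counts = np.zeros(egms.surface.n_vertices, dtype=int)
    for i in range(egms.surface.n_vertices):
        dv = np.gradient(egms.unipolar.values[i], t)
        sig = np.where(np.abs(dv) > noise_floor_mv_per_ms, np.sign(dv), 0.0)
        sig = sig[sig != 0.0]
        counts[i] = int(np.sum(np.diff(sig) != 0.0)) if len(sig) else 0
    return counts
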