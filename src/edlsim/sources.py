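"""Time-varying dipole-layer source strengths and potential simulation.

During depolarization the local transmembrane potential is modelled as a
step: 0 in the resting state, 1 once depolarized at the local activation
time delta.  The dipole-layer strength is calibrated so a completely
activated element produces the physiological potential step across the
wavefront: with a step of 40 mV and a myocardial conductivity of 0.2 S/m
the nominal strength is 40 * 0.2 = 8 mA/m (identically 8 uA/mm).

A triangle whose vertices activate at different times is weighted by the
fraction of its area already depolarized, assuming the activation time
varies linearly over the triangle; the fraction has a closed form in the
sorted vertex times.  Potentials follow by superposition over source
components (ventricles and patches), each patch scaled by its fraction of
electrically active tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activation import ActivationMap
from .bem import TransferMatrix

__all__ = [
    "SourceConfig",
    "PotentialTraces",
    "nominal_strength",
    "activated_fraction",
    "simulate_potentials",
    "qrs_window",
]


@dataclass
class SourceConfig:
    """Source calibration and time grid.

    ``potential_step_mv``: transmembrane step across the wavefront (mV).
    ``sigma``: myocardial conductivity (S/m); strength = step * sigma.
    ``dt_ms``: sample interval; ``t_start/t_end`` default to the activation
    range padded by ``margin_ms``.
    """

    potential_step_mv: float = 40.0
    sigma: float = 0.2
    dt_ms: float = 1.0
    t_start: float | None = None
    t_end: float | None = None
    margin_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.potential_step_mv <= 0 or self.sigma <= 0 or self.dt_ms <= 0:
            raise ValueError("potential step, conductivity and time step must be positive")


def nominal_strength(config: SourceConfig | None = None, health_fraction: float = 1.0) -> float:
    """Dipole-layer strength (mA/m = uA/mm): potential step x conductivity.

    ``health_fraction`` scales the strength for partially active tissue
    (0.5 -> 4 mA/m with the defaults; 0 -> electrically silent).
    """
    config = config or SourceConfig()
    if not 0.0 <= health_fraction <= 1.0:
        raise ValueError("health_fraction must lie in [0, 1]")
    return health_fraction * config.potential_step_mv * config.sigma


def activated_fraction(deltas: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Fraction of triangle area activated at time(s) ``t``.

    ``deltas``: (..., 3) vertex activation times; ``t``: scalar or (T,).
    With sorted vertex times d1 <= d2 <= d3 and linear interpolation of the
    activation time over the triangle, the activated sub-area is a quadratic
    in t on each interval:

        0                                   t < d1
        (t-d1)^2 / ((d2-d1)(d3-d1))         d1 <= t < d2
        1 - (d3-t)^2 / ((d3-d2)(d3-d1))     d2 <= t < d3
        1                                   t >= d3

    Equal-time degeneracies are the continuous limits (a fully synchronous
    triangle is a step at its activation time).  Returns shape (..., T) for
    vector ``t``.
    """
    d = np.sort(np.asarray(deltas, dtype=float), axis=-1)
    scalar_t = np.ndim(t) == 0
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    d1, d2, d3 = (d[..., k, None] for k in range(3))
    with np.errstate(divide="ignore", invalid="ignore"):
        rising = (tt - d1) ** 2 / ((d2 - d1) * (d3 - d1))
        falling = 1.0 - (d3 - tt) ** 2 / ((d3 - d2) * (d3 - d1))
    f = np.where(tt < d2, rising, falling)
    f = np.where(tt < d1, 0.0, f)
    f = np.where(tt >= d3, 1.0, f)
    f = np.nan_to_num(f, nan=0.0)
    # degenerate spans: step behaviour
    f = np.where((d1 == d3) & (tt >= d1), 1.0, f)
    f = np.clip(f, 0.0, 1.0)
    return f[..., 0] if scalar_t else f


@dataclass
class PotentialTraces:
    """Time-sampled potentials (mV) on a shared uniform grid."""

    times: np.ndarray  # (T,) ms
    values: np.ndarray  # (channels, T) mV
    labels: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.times):
            raise ValueError("values and time grid mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite potentials")

    @property
    def dt_ms(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def channel(self, label: str) -> np.ndarray:
        return self.values[self.labels.index(label)]

    def window(self, t0: float, t1: float) -> "PotentialTraces":
        m = (self.times >= t0) & (self.times <= t1)
        return PotentialTraces(self.times[m], self.values[:, m], self.labels, self.metadata)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=self.labels)
        df.insert(0, "time_ms", self.times)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PotentialTraces":
        times = df["time_ms"].to_numpy()
        labels = [c for c in df.columns if c != "time_ms"]
        return cls(times, df[labels].to_numpy().T, labels)


def qrs_window(maps, margin_ms: float = 5.0) -> tuple[float, float]:
    """[first activation - margin, last activation + margin] over components."""
    finite = np.concatenate(
        [m.times[np.isfinite(m.times)] for m in np.atleast_1d(maps)]
    )
    return float(finite.min() - margin_ms), float(finite.max() + margin_ms)


def simulate_potentials(
    transfers: dict[str, TransferMatrix],
    maps: dict[str, ActivationMap],
    config: SourceConfig | None = None,
    strength_scales: dict[str, float] | None = None,
    labels: list | None = None,
) -> PotentialTraces:
    """Potentials by superposition over source components.

    ``transfers`` and ``maps`` are keyed by component name ('ventricles',
    'patch_0', ...); each transfer matrix and map must share a mesh.  Per
    sample, each triangle's strength is its component's scaled nominal
    strength times the activated fraction; potentials are the transfer
    matrices applied to those strengths, summed over components.
    """
    config = config or SourceConfig()
    strength_scales = strength_scales or {}
    if set(transfers) != set(maps):
        raise ValueError("transfers and maps must cover the same components")

    t_lo, t_hi = [], []
    for name, amap in maps.items():
        if len(amap.times) != transfers[name].source.n_vertices:
            raise ValueError(f"component {name!r}: activation map does not match source mesh")
        finite = amap.times[np.isfinite(amap.times)]
        t_lo.append(finite.min())
        t_hi.append(finite.max())
    t0 = config.t_start if config.t_start is not None else min(0.0, min(t_lo))
    t1 = config.t_end if config.t_end is not None else max(t_hi) + config.margin_ms
    times = np.arange(t0, t1 + 0.5 * config.dt_ms, config.dt_ms)

    n_obs = next(iter(transfers.values())).n_observations
    phi = np.zeros((n_obs, len(times)))
    for name, A in transfers.items():
        if A.n_observations != n_obs:
            raise ValueError("all transfer matrices must share the observation set")
        scale = strength_scales.get(name, 1.0)
        if scale == 0.0:
            continue
        strength = nominal_strength(config, 1.0) * scale
        tri_deltas = maps[name].times[A.source.triangles]
        frac = activated_fraction(tri_deltas, times)  # (m, T)
        phi += A.triangle_gains @ (strength * frac)
    return PotentialTraces(
        times,
        phi,
        labels=list(labels) if labels is not None else [f"ch{i}" for i in range(n_obs)],
        metadata={
            "dt_ms": config.dt_ms,
            "components": sorted(transfers),
            "strength_scales": {k: float(v) for k, v in strength_scales.items()},
        },
    )
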