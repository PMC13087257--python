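"""Post-processing of MD interaction-energy series and lipid distributions.

The protein-environment association free energy is estimated from an
interaction-energy time series U(t) by exponential averaging against the
ideal-gas reference state,

    dG = -kT ln < exp(-U / kT) >,

evaluated with a log-sum-exp shift so arbitrarily large |U| cannot
overflow. Because interaction energies drift on long time scales, errors
are estimated by block averaging: the estimator is applied per contiguous
block of the last half of the trajectory and the block-to-block dispersion
is reported as the error. A small radial-distribution utility supports
lipid-around-protein analyses on point sets (2D leaflets or 3D boxes).

Energies are kcal/mol internally; kJ/mol inputs can be converted with
``KJ_PER_KCAL``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.special import logsumexp

from .synthetic_data import EnergySeries

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "KJ_PER_KCAL",
    "FreeEnergyEstimate",
    "RdfProfile",
    "exp_avg_free_energy",
    "block_free_energy",
    "delta_delta_g",
    "pv_term",
    "radial_distribution",
    "read_energy_series",
]

KB_KCAL_PER_MOL_K = 0.0019872041
KJ_PER_KCAL = 4.184
#: 1 bar * 1 nm^3 * Avogadro, in kJ/mol
BAR_NM3_TO_KJ_PER_MOL = 0.0602214076


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """Block-averaged exponential-average free energy, kcal/mol."""

    delta_g: float
    error: float
    n_blocks: int
    temperature: float
    n_frames_used: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("error must be non-negative")
        if self.n_blocks < 2:
            raise ValueError("need at least 2 blocks")


@dataclass
class RdfProfile:
    """Radial distribution g(r) around a reference point set."""

    bin_centers_nm: NDArray[np.float64]
    g: NDArray[np.float64]
    bulk_density: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_centers_nm) <= 0):
            raise ValueError("bins must be strictly increasing")
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")


def exp_avg_free_energy(series: EnergySeries) -> float:
    """dG = -kT ln<exp(-U/kT)> in kcal/mol, overflow-safe via log-sum-exp.

    By Jensen's inequality the result never exceeds the arithmetic mean of
    U, and adding a constant to U shifts dG by exactly that constant.
    """
    u = series.values
    if u.size == 0:
        raise ValueError("empty energy series")
    kt = KB_KCAL_PER_MOL_K * series.temperature
    return float(-kt * (logsumexp(-u / kt) - np.log(u.size)))


def block_free_energy(
    series: EnergySeries,
    n_blocks: int = 5,
    use_last_half: bool = True,
    label: str = "",
) -> FreeEnergyEstimate:
    """Exponential-average free energy with block-averaged error.

    The estimator is applied to each of ``n_blocks`` equal contiguous
    blocks (of the last half of the series by default); the estimate is
    the mean of the block values and the error their standard deviation.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    values = series.values
    if use_last_half:
        values = values[values.size // 2 :]
    if values.size < 2 * n_blocks:
        raise ValueError(
            f"series too short: {values.size} frames for {n_blocks} blocks "
            f"(need >= {2 * n_blocks})"
        )
    blocks = np.array_split(values, n_blocks)
    dgs = [
        exp_avg_free_energy(
            EnergySeries(b, series.dt_ps, series.temperature, series.label)
        )
        for b in blocks
    ]
    return FreeEnergyEstimate(
        delta_g=float(np.mean(dgs)),
        error=float(np.std(dgs)),
        n_blocks=n_blocks,
        temperature=series.temperature,
        n_frames_used=int(values.size),
        label=label or series.label,
    )


def delta_delta_g(
    est_1: FreeEnergyEstimate, est_2: FreeEnergyEstimate
) -> tuple[float, float]:
    """Free-energy difference dG(T1) - dG(T2) with errors added in quadrature.

    Both estimates must carry the same state/composition label; comparing
    different systems this way is meaningless.
    """
    if est_1.label != est_2.label:
        raise ValueError(
            f"state labels differ ({est_1.label!r} vs {est_2.label!r}); "
            f"temperature differences require identical system composition"
        )
    return (
        est_1.delta_g - est_2.delta_g,
        float(np.hypot(est_1.error, est_2.error)),
    )


def pv_term(pressure_bar: float, volume_nm3: float) -> float:
    """Pressure-volume work p*V*N_A in kJ/mol (1 bar nm^3 = 0.0602 kJ/mol)."""
    if pressure_bar <= 0 or volume_nm3 <= 0:
        raise ValueError("pressure and volume must be positive")
    return pressure_bar * volume_nm3 * BAR_NM3_TO_KJ_PER_MOL


def radial_distribution(
    points: ArrayLike,
    reference_points: ArrayLike,
    r_max: float,
    n_bins: int,
    box_measure: float,
    dimensionality: int = 2,
) -> RdfProfile:
    """g(r) of minimum distances from ``points`` to a reference point set.

    Shell counts are normalised by the bulk density ``n_points /
    box_measure`` times the annular area (2D) or shell volume (3D). With a
    point reference and uniform points this converges to 1 away from the
    origin. A warning is attached if ``r_max`` exceeds half the box extent
    implied by the box measure.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ref = np.atleast_2d(np.asarray(reference_points, dtype=float))
    if pts.size == 0 or ref.size == 0:
        raise ValueError("point sets must be non-empty")
    if dimensionality not in (2, 3):
        raise ValueError("dimensionality must be 2 or 3")
    if box_measure <= 0:
        raise ValueError("box measure must be positive")
    import warnings as _warnings

    half_extent = 0.5 * box_measure ** (1.0 / dimensionality)
    if r_max > half_extent:
        _warnings.warn(
            f"r_max={r_max} exceeds half the box extent ({half_extent:.3g}); "
            f"outer shells are undersampled",
            stacklevel=2,
        )
    dmin = np.min(
        np.linalg.norm(pts[:, None, :] - ref[None, :, :], axis=2), axis=1
    )
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts, _ = np.histogram(dmin, bins=edges)
    if dimensionality == 2:
        shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    else:
        shell = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    bulk = pts.shape[0] / box_measure
    g = counts / (shell * bulk)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RdfProfile(centers, g, bulk)


def read_energy_series(
    path: str | Path, temperature: float = 298.15, dt_ps: float = 100.0
) -> EnergySeries:
    """Read a delimited (frame, U) text file into an :class:`EnergySeries`."""
    data = np.loadtxt(path, comments=("#", "@"))
    values = data[:, 1] if data.ndim == 2 else data
    return EnergySeries(values, dt_ps=dt_ps, temperature=temperature,
                        label=Path(path).stem)
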