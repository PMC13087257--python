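"""Synthetic inputs with known ground truth for every pipeline stage.

Provides bimodal-Gaussian distance distributions, simulated multi-window
DEER trace sets, idealised helix-dimer coordinates for spin-labelling tests,
and autocorrelated (AR(1)) energy series for the free-energy estimator.
Every generator is a pure function of its parameters and seed.

Two packaged fixtures, ``exp19C`` and ``exp40C``, encode a two-state
conformational ensemble (components near 3.3 nm / SD 0.5 nm and 5.0 nm /
SD 0.3 nm) with temperature-dependent state weights; they are the ground
truth for round-trip validation of the invert-and-quantify pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from numpy.typing import NDArray

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .dipolar_model import (
    BackgroundModel,
    DistanceAxis,
    DistanceDistribution,
    ModulationParams,
    dipolar_signal,
)
from .traces import DipolarTrace, TraceSet, write_trace

__all__ = [
    "GroundTruthSpec",
    "TraceSpec",
    "EnergySeries",
    "make_ground_truth",
    "simulate_trace",
    "simulate_trace_set",
    "helix_dimer_fixture",
    "simulate_energy_series",
    "load_fixture_registry",
    "fixture_ground_truth",
    "fixture_trace_specs",
    "write_trace_set",
    "read_trace_set",
]


@dataclass(frozen=True)
class GroundTruthSpec:
    """Mixture-of-Gaussians ground truth: (mean nm, SD nm, weight) triples."""

    components: tuple[tuple[float, float, float], ...]
    axis: DistanceAxis = DistanceAxis()

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("need at least one component")
        weights = np.array([c[2] for c in self.components])
        if np.any(weights < 0):
            raise ValueError("component weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        for mean, sd, _ in self.components:
            if not self.axis.r_min <= mean <= self.axis.r_max:
                raise ValueError(f"component mean {mean} nm outside axis")
            if sd <= 0:
                raise ValueError("component SD must be positive")


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of one simulated dipolar trace."""

    t_max: float = 4.0
    dt: float = 0.016
    lam: float = 0.3
    bg_k: float = 0.05
    bg_d: float = 3.0
    noise_sd: float = 0.005
    v0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dt < self.t_max:
            raise ValueError("need 0 < dt < t_max")
        if self.t_max > 10.0:
            raise ValueError("t_max capped at 10 us")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def time_axis(self) -> NDArray[np.float64]:
        n = int(np.floor(self.t_max / self.dt + 1e-9)) + 1
        return self.dt * np.arange(n)


@dataclass
class EnergySeries:
    """Scalar interaction-energy time series from MD post-processing."""

    values: NDArray[np.float64]
    dt_ps: float = 100.0
    temperature: float = 298.15
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("energy series needs at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("energy series contains non-finite values")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def __len__(self) -> int:
        return self.values.size


def make_ground_truth(spec: GroundTruthSpec) -> DistanceDistribution:
    """Evaluate the Gaussian mixture on the axis and renormalise."""
    r = spec.axis.values
    dens = np.zeros_like(r)
    for mean, sd, w in spec.components:
        dens += w * np.exp(-0.5 * ((r - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    return DistanceDistribution(spec.axis, dens).normalized()


def simulate_trace(dist: DistanceDistribution, spec: TraceSpec) -> DipolarTrace:
    """Forward-simulate one noisy trace; deterministic given ``spec.seed``."""
    t = spec.time_axis()
    clean = dipolar_signal(
        dist.normalized(),
        ModulationParams(lam=spec.lam, v0=spec.v0),
        BackgroundModel(k=spec.bg_k, d=spec.bg_d),
        t,
    )
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd * spec.v0, size=t.size) if spec.noise_sd > 0 else 0.0
    return DipolarTrace(
        t,
        clean + noise,
        noise_sd=spec.noise_sd * spec.v0 if spec.noise_sd > 0 else None,
        label=f"tmax{spec.t_max:g}us",
        meta={"truth": spec.__dict__.copy()},
    )


def simulate_trace_set(
    dist: DistanceDistribution, specs: list[TraceSpec], sample_id: str = "synthetic"
) -> TraceSet:
    """Simulate several evolution windows of the same sample (shared P(r))."""
    if not specs:
        raise ValueError("need at least one trace spec")
    if len(specs) > 6:
        raise ValueError("at most 6 traces per sample")
    return TraceSet(
        [simulate_trace(dist, s) for s in specs],
        sample_id=sample_id,
        meta={"n_traces": len(specs)},
    )


# --------------------------------------------------------------------------
# packaged fixtures

def load_fixture_registry() -> dict:
    """Parse the packaged fixture configuration."""
    text = resources.files("deerquant").joinpath("data/fixtures.yaml").read_text()
    return yaml.safe_load(text)


def fixture_ground_truth(name: str, axis: DistanceAxis | None = None) -> DistanceDistribution:
    """Ground-truth distribution of a named fixture (``exp19C`` / ``exp40C``)."""
    registry = load_fixture_registry()
    try:
        fx = registry["fixtures"][name]
    except KeyError:
        known = ", ".join(registry["fixtures"])
        raise KeyError(f"unknown fixture {name!r}; available: {known}") from None
    comps = tuple((c["mean"], c["sd"], c["weight"]) for c in fx["components"])
    return make_ground_truth(GroundTruthSpec(comps, axis or DistanceAxis()))


def fixture_state_weights(name: str) -> dict[str, float]:
    """Ground-truth state populations of a named fixture, keyed NS/S."""
    registry = load_fixture_registry()
    return {c["state"]: c["weight"] for c in registry["fixtures"][name]["components"]}


def fixture_trace_specs(seed: int, noise_sd: float | None = None) -> list[TraceSpec]:
    """Default four-window trace specs (t_max 2/4/6/7.5 us), seeded per trace."""
    d = load_fixture_registry()["trace_defaults"]
    specs = []
    for i, t_max in enumerate(d["t_max_set"]):
        specs.append(
            TraceSpec(
                t_max=t_max,
                dt=d["dt"],
                lam=d["lambda"],
                bg_k=d["background_k"],
                bg_d=d["background_d"],
                noise_sd=d["noise_sd"] if noise_sd is None else noise_sd,
                seed=int(seed) * 100 + i,
            )
        )
    return specs


# --------------------------------------------------------------------------
# trace-set file round trip

def write_trace_set(ts: TraceSet, directory: str | Path) -> list[Path]:
    """Write each trace as two-column text plus a YAML sidecar with metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    sidecar: dict = {"sample_id": ts.sample_id, "traces": []}
    for i, tr in enumerate(ts.traces):
        p = directory / f"trace_{i}.dat"
        write_trace(tr, p)
        paths.append(p)
        sidecar["traces"].append(
            {"file": p.name, "label": tr.label, "noise_sd": tr.noise_sd, "meta": tr.meta}
        )
    with open(directory / "traceset.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return paths


def read_trace_set(directory: str | Path) -> TraceSet:
    directory = Path(directory)
    with open(directory / "traceset.yaml") as fh:
        sidecar = yaml.safe_load(fh)
    traces = []
    for entry in sidecar["traces"]:
        data = np.loadtxt(directory / entry["file"])
        traces.append(
            DipolarTrace(
                data[:, 0],
                data[:, 1],
                noise_sd=entry.get("noise_sd"),
                label=entry.get("label", ""),
                meta=entry.get("meta", {}),
            )
        )
    return TraceSet(traces, sample_id=sidecar.get("sample_id", ""))


# --------------------------------------------------------------------------
# idealised coordinates for labelling tests

# ideal backbone geometry (A / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_CA_CB, _B_C_O = 1.458, 1.525, 1.329, 1.530, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def place_atom(a: NDArray, b: NDArray, c: NDArray, bond: float, angle_deg: float,
               torsion_deg: float) -> NDArray[np.float64]:
    """Place atom d from three predecessors by internal coordinates (NeRF)."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _ideal_helix_backbone(n_res: int) -> dict[str, NDArray]:
    """N/CA/C/O/CB coordinates of an ideal poly-Ala alpha-helix (phi -57, psi -47)."""
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # seed triad
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    C[0] = place_atom(np.array([-1.0, 1.0, 0.0]), N[0], CA[0], _B_CA_C, _A_N_CA_C, _PHI)
    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, _PSI)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, _OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, _PHI)
    O = np.zeros((n_res, 3))
    CB = np.zeros((n_res, 3))
    for i in range(n_res):
        if i + 1 < n_res:
            O[i] = place_atom(N[i], CA[i], C[i], _B_C_O, 120.8, _PSI + 180.0)
        else:
            O[i] = place_atom(N[i], CA[i], C[i], _B_C_O, 120.8, 0.0)
        # tetrahedral branch off CA, opposite side from the backbone plane
        u1 = N[i] - CA[i]
        u1 /= np.linalg.norm(u1)
        u2 = C[i] - CA[i]
        u2 /= np.linalg.norm(u2)
        bis = u1 + u2
        bis /= np.linalg.norm(bis)
        perp = np.cross(u2, u1)
        perp /= np.linalg.norm(perp)
        CB[i] = CA[i] + _B_CA_CB * (-0.620 * bis + 0.785 * perp)
    # orient the helix axis along z and centre laterally
    axis = CA[-1] - CA[0]
    axis /= np.linalg.norm(axis)
    zhat = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, zhat)
    s, cth = np.linalg.norm(v), float(axis @ zhat)
    if s > 1e-12:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - cth) / s**2)
    else:
        rot = np.eye(3)
    out = {}
    centroid = None
    for name, arr in [("N", N), ("CA", CA), ("C", C), ("O", O), ("CB", CB)]:
        arr = arr @ rot.T
        if centroid is None:
            centroid = arr.mean(axis=0) * np.array([1.0, 1.0, 0.0])
        out[name] = arr - centroid
    return out


def helix_dimer_fixture(
    n_res: int = 30, separation_nm: float = 3.0, sites: list[int] | None = None
) -> struc.AtomArray:
    """Two parallel idealised poly-alanine helices offset by ``separation_nm``.

    Chains A and B carry backbone + CB atoms; residue numbering starts at 1.
    ``sites`` (residue indices) are validated to lie inside the chains. The
    construction is deterministic, so geometric oracles (rise per residue,
    inter-chain distances equal to the separation) hold exactly.
    """
    if n_res < 10:
        raise ValueError("need at least 10 residues per helix")
    if separation_nm < 1.0:
        raise ValueError("chain separation must be >= 1 nm")
    if sites:
        for s in sites:
            if not 1 <= s <= n_res:
                raise ValueError(f"site {s} outside chain (1..{n_res})")
    bb = _ideal_helix_backbone(n_res)
    atom_names = ["N", "CA", "C", "O", "CB"]
    elements = ["N", "C", "C", "O", "C"]
    n_atoms = 2 * n_res * len(atom_names)
    arr = struc.AtomArray(n_atoms)
    idx = 0
    for chain, xoff in (("A", -separation_nm * 5.0), ("B", separation_nm * 5.0)):
        for res in range(n_res):
            for name, elem in zip(atom_names, elements):
                arr.coord[idx] = bb[name][res] + np.array([xoff, 0.0, 0.0])
                arr.chain_id[idx] = chain
                arr.res_id[idx] = res + 1
                arr.res_name[idx] = "ALA"
                arr.atom_name[idx] = name
                arr.element[idx] = elem
                arr.hetero[idx] = False
                idx += 1
    return arr


def write_structure_pdb(structure: struc.AtomArray, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(structure)
    pdb.write(str(path))


# --------------------------------------------------------------------------
# autocorrelated energy series

def simulate_energy_series(
    mean: float,
    sd: float,
    autocorr_time: float,
    n: int,
    temperature: float = 298.15,
    seed: int = 0,
    dt_ps: float = 100.0,
) -> EnergySeries:
    """AR(1) energy series with given marginal mean/SD and lag-1
    autocorrelation ``exp(-1/autocorr_time)`` (autocorr_time in frames)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return EnergySeries(np.full(n, mean), dt_ps, temperature)
    phi = np.exp(-1.0 / autocorr_time)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return EnergySeries(mean + x, dt_ps, temperature)
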