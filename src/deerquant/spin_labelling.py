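"""In-silico nitroxide spin labelling by accessible-volume rotamer search.

A methanethiosulfonate spin label (R1 side chain) is grafted onto a chosen
residue by sampling its five rotatable dihedrals (chi1-chi5) uniformly and
keeping sterically allowed conformers, up to an ensemble cap of 200
rotamers. The unpaired electron sits on the nitroxide N-O bond; the
midpoint of that bond is the label position used for distance prediction.
Inter-label distance distributions are histograms over all pairs of
rotamer positions of two ensembles.

Structures are handled as ``biotite`` atom arrays; PDB reading keeps the
first model, 'A'/blank altlocs, and drops waters. Clash detection uses
heavy atoms only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.typing import NDArray

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .dipolar_model import DistanceAxis, DistanceDistribution
from .synthetic_data import place_atom

__all__ = [
    "LabelSite",
    "RotamerEnsemble",
    "SearchSettings",
    "read_pdb",
    "attach_rotamers",
    "pair_distance_distribution",
    "predict_pair",
]

MAX_ROTAMERS = 200

# R1 side-chain internal coordinates: (name, parent triple, bond A, angle deg)
# chain CB-SG-SD-CE-C3 with the 2,2,5,5-tetramethyl-pyrroline-1-oxyl ring
# rigid beyond C3; chi1..chi5 are the torsions about the five single bonds.
_R1_CHAIN = [
    # name, (a, b, c), bond, angle  -- torsion supplied by the sampler
    ("SG", ("N", "CA", "CB"), 1.81, 114.0),   # chi1
    ("SD", ("CA", "CB", "SG"), 2.04, 104.0),  # chi2 (disulfide bond)
    ("CE", ("CB", "SG", "SD"), 1.81, 104.0),  # chi3
    ("C3", ("SG", "SD", "CE"), 1.50, 114.0),  # chi4
]
# rigid nitroxide ring atoms, placed from (SD, CE, C3) after chi5; torsions
# relative to chi5 keep the ring planar-ish with gem-dimethyl carbons implicit
_R1_RING = [
    # name, bond to C3-frame predecessor chain, angle, torsion offset from chi5
    ("C4", 1.34, 126.0, 0.0),      # sp2 ring double bond C3=C4
    ("C5", 1.51, 112.0, 180.0),    # ring carbon bearing methyls
    ("N1", 1.47, 106.0, 0.0),      # ring nitrogen (from C4-C5)
    ("O1", 1.28, 122.0, 180.0),    # nitroxide oxygen on N1
]


@dataclass(frozen=True)
class LabelSite:
    """A labelling position: chain id and residue number."""

    chain_id: str
    res_id: int

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.res_id}"


@dataclass(frozen=True)
class SearchSettings:
    """Rotamer-search mode: try budget and van-der-Waals strictness.

    'thorough' searches 30000 candidates ('quick' 3000); 'loose' van der
    Waals restraints allow up to 5 protein contacts closer than 2.5 A,
    'tight' allows none closer than 3.4 A.
    """

    mode: str = "thorough"
    vdw: str = "loose"

    def __post_init__(self) -> None:
        if self.mode not in ("quick", "thorough"):
            raise ValueError("mode must be 'quick' or 'thorough'")
        if self.vdw not in ("tight", "loose"):
            raise ValueError("vdw must be 'tight' or 'loose'")

    @property
    def try_budget(self) -> int:
        return 30000 if self.mode == "thorough" else 3000

    @property
    def clash_cutoff(self) -> float:
        return 2.5 if self.vdw == "loose" else 3.4

    @property
    def max_clashes(self) -> int:
        return 5 if self.vdw == "loose" else 0


@dataclass
class RotamerEnsemble:
    """Accepted spin-label conformers at one site."""

    site: LabelSite
    positions: NDArray[np.float64]        # (n, 3) N-O midpoints, Angstrom
    sidechain_coords: list[NDArray]       # per rotamer, full side-chain atoms
    clash_counts: NDArray[np.int64]
    tries: int
    settings: SearchSettings

    def __post_init__(self) -> None:
        if len(self.positions) > MAX_ROTAMERS:
            raise ValueError(f"ensemble exceeds {MAX_ROTAMERS} rotamers")
        if np.any(self.clash_counts > self.settings.max_clashes):
            raise ValueError("ensemble contains rotamers above the clash limit")

    def __len__(self) -> int:
        return len(self.positions)


def read_pdb(source: str | Path | io.StringIO) -> struc.AtomArray:
    """Read a PDB file: first model only, altloc 'A'/blank, waters dropped."""
    if isinstance(source, io.StringIO):
        pdb = PDBFile.read(source)
    else:
        path = Path(source)
        try:
            pdb = PDBFile.read(str(path))
        except Exception as exc:
            raise ValueError(f"{path}: cannot parse PDB file: {exc}") from exc
    try:
        atoms = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise ValueError(f"cannot extract model 1: {exc}") from exc
    if atoms.array_length() == 0:
        raise ValueError("no ATOM records in model 1")
    atoms = atoms[atoms.res_name != "HOH"]
    if not np.all(np.isfinite(atoms.coord)):
        raise ValueError("non-finite coordinates in PDB file")
    return atoms


def _backbone_frame(structure: struc.AtomArray, site: LabelSite):
    """N/CA/CB (CB synthesised for glycine) of the site + validation."""
    res_mask = (structure.chain_id == site.chain_id) & (structure.res_id == site.res_id)
    if not np.any(res_mask):
        raise ValueError(f"site {site} not found in structure")
    res = structure[res_mask]

    def coord_of(name):
        m = res.atom_name == name
        return res.coord[m][0] if np.any(m) else None

    n, ca, c = coord_of("N"), coord_of("CA"), coord_of("C")
    if n is None or ca is None or c is None:
        raise ValueError(f"site {site} lacks backbone N/CA/C atoms")
    cb = coord_of("CB")
    if cb is None:
        # synthesise a tetrahedral CB (glycine)
        u1 = (n - ca) / np.linalg.norm(n - ca)
        u2 = (c - ca) / np.linalg.norm(c - ca)
        bis = (u1 + u2) / np.linalg.norm(u1 + u2)
        perp = np.cross(u2, u1)
        perp /= np.linalg.norm(perp)
        cb = ca + 1.53 * (-0.620 * bis + 0.785 * perp)
    _check_disulfide(structure, site, res)
    return n, ca, cb


def _check_disulfide(structure: struc.AtomArray, site: LabelSite, res: struc.AtomArray):
    """Reject cysteines whose SG is within disulfide range of another SG."""
    if res.res_name[0] != "CYS":
        return
    sg_mask = res.atom_name == "SG"
    if not np.any(sg_mask):
        return
    sg = res.coord[sg_mask][0]
    others = structure[
        (structure.atom_name == "SG")
        & ~((structure.chain_id == site.chain_id) & (structure.res_id == site.res_id))
    ]
    if others.array_length() and np.min(np.linalg.norm(others.coord - sg, axis=1)) < 2.5:
        raise ValueError(f"site {site} is a disulfide-bonded cysteine; not labellable")


def attach_rotamers(
    structure: struc.AtomArray,
    site: LabelSite,
    settings: SearchSettings | None = None,
    max_rotamers: int = MAX_ROTAMERS,
    seed: int = 0,
) -> RotamerEnsemble:
    """Accessible-volume rotamer search of the R1 label at ``site``.

    Candidates are built from the internal-coordinate template by uniform
    sampling of chi1-chi5 and accepted if at most ``max_clashes`` protein
    heavy atoms (excluding the labelled residue's own side chain and
    hydrogens) lie closer than the clash cutoff to any label heavy atom.
    The search is seeded and stops at ``max_rotamers`` accepted conformers
    or when the try budget is exhausted.
    """
    settings = settings or SearchSettings()
    n, ca, cb = _backbone_frame(structure, site)

    # clash environment: protein heavy atoms, excluding the labelled residue
    # itself (the grafted side chain is covalently bonded to its backbone,
    # so own-residue contacts are bonded geometry, not clashes)
    heavy = np.isin(structure.element, ["C", "N", "O", "S", "P"])
    own = (structure.chain_id == site.chain_id) & (structure.res_id == site.res_id)
    env = structure.coord[heavy & ~own]
    # pre-restrict to the reachable sphere around CB (max extension ~12 A)
    near = np.linalg.norm(env - cb, axis=1) < 12.0 + settings.clash_cutoff + 1.0
    env = env[near]

    rng = np.random.default_rng(seed)
    positions, sidechains, clashes = [], [], []
    tries = 0
    cutoff = settings.clash_cutoff
    while tries < settings.try_budget and len(positions) < max_rotamers:
        tries += 1
        chi = rng.uniform(0.0, 360.0, size=5)
        frame = {"N": n, "CA": ca, "CB": cb}
        coords = []
        for (name, (a, b, c), bond, angle), torsion in zip(_R1_CHAIN, chi[:4]):
            frame[name] = place_atom(frame[a], frame[b], frame[c], bond, angle, torsion)
            coords.append(frame[name])
        # rigid ring: C4 via chi5, then ring closure atoms
        c4 = place_atom(frame["SD"], frame["CE"], frame["C3"], *_ring_args(0, chi[4]))
        c5 = place_atom(frame["CE"], frame["C3"], c4, *_ring_args(1, chi[4]))
        n1 = place_atom(frame["C3"], c4, c5, *_ring_args(2, chi[4]))
        o1 = place_atom(c4, c5, n1, *_ring_args(3, chi[4]))
        coords += [c4, c5, n1, o1]
        label_atoms = np.array(coords)
        d = np.linalg.norm(label_atoms[:, None, :] - env[None, :, :], axis=2)
        n_clash = int(np.sum(np.min(d, axis=0) < cutoff))
        if n_clash <= settings.max_clashes:
            positions.append(0.5 * (n1 + o1))
            sidechains.append(label_atoms)
            clashes.append(n_clash)
    if not positions:
        raise RuntimeError(
            f"rotamer starvation at site {site}: no conformer of {tries} tries "
            f"satisfied the clash limit"
        )
    return RotamerEnsemble(
        site=site,
        positions=np.array(positions),
        sidechain_coords=sidechains,
        clash_counts=np.array(clashes, dtype=np.int64),
        tries=tries,
        settings=settings,
    )


def _ring_args(i: int, chi5: float) -> tuple[float, float, float]:
    name, bond, angle, offset = _R1_RING[i]
    torsion = chi5 + offset if i == 0 else offset
    return bond, angle, torsion


def pair_distance_distribution(
    ens_a: RotamerEnsemble,
    ens_b: RotamerEnsemble,
    bin_width_nm: float = 0.05,
) -> tuple[DistanceDistribution, float, float]:
    """Histogram of all inter-ensemble label-label distances.

    Returns the normalised distance density together with the mean and SD
    of the raw pair distances (in nm). Symmetric in its ensemble arguments.
    """
    if len(ens_a) == 0 or len(ens_b) == 0:
        raise ValueError("both rotamer ensembles must be non-empty")
    d_nm = (
        np.linalg.norm(
            ens_a.positions[:, None, :] - ens_b.positions[None, :, :], axis=2
        ).ravel()
        / 10.0
    )
    mean, sd = float(np.mean(d_nm)), float(np.std(d_nm))
    lo = max(1.0, np.floor(d_nm.min() / bin_width_nm) * bin_width_nm - 10 * bin_width_nm)
    hi = np.ceil(d_nm.max() / bin_width_nm) * bin_width_nm + 10 * bin_width_nm
    axis = DistanceAxis(lo, hi, bin_width_nm)
    edges = np.concatenate([axis.values - bin_width_nm / 2, [axis.values[-1] + bin_width_nm / 2]])
    counts, _ = np.histogram(d_nm, bins=edges)
    dens = counts.astype(float)
    if dens.sum() == 0:
        raise ValueError("no distances fell on the axis")
    dist = DistanceDistribution(axis, dens).normalized()
    return dist, mean, sd


@dataclass
class PairPrediction:
    """In-silico distance prediction for one site pair."""

    site_a: LabelSite
    site_b: LabelSite
    distribution: DistanceDistribution
    mean_nm: float
    sd_nm: float
    most_probable_nm: float
    ensemble_sizes: tuple[int, int]
    warnings: list[str] = field(default_factory=list)


def predict_pair(
    structure: struc.AtomArray,
    site_a: LabelSite,
    site_b: LabelSite,
    settings: SearchSettings | None = None,
    bin_width_nm: float = 0.05,
    seed: int = 0,
) -> PairPrediction:
    """Label two sites and predict their inter-spin distance distribution."""
    ens_a = attach_rotamers(structure, site_a, settings, seed=seed)
    ens_b = attach_rotamers(structure, site_b, settings, seed=seed + 1)
    dist, mean, sd = pair_distance_distribution(ens_a, ens_b, bin_width_nm)
    warnings = []
    if mean < 0.5 or mean > 9.0:
        warnings.append(
            f"predicted mean {mean:.2f} nm outside the physically sensible "
            f"[0.5, 9] nm window"
        )
    return PairPrediction(
        site_a=site_a,
        site_b=site_b,
        distribution=dist,
        mean_nm=mean,
        sd_nm=sd,
        most_probable_nm=dist.mode(),
        ensemble_sizes=(len(ens_a), len(ens_b)),
        warnings=warnings,
    )
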