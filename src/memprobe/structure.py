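"""Structural and ordering analyses of bilayer trajectories.

Area per lipid, P-plane thickness, deuterium order parameters, chain tilt
distributions (optionally conditioned on the distance to the nearest probe
molecule), transverse group positions and mass-density profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import AMU_PER_NM3_TO_KG_PER_M3
from .exceptions import (
    AnalysisError,
    GeometryError,
    ParameterError,
    SelectionError,
)
from .trajectory import Trajectory, minimum_image

__all__ = [
    "FrameSeriesSummary",
    "BilayerFrameSummary",
    "ChainSpec",
    "TiltDistribution",
    "DensityProfile",
    "OrderParameterProfile",
    "TransverseLocation",
    "compute_area_per_lipid",
    "compute_thickness_dpp",
    "compute_scd_profile",
    "scd_from_vectors",
    "compute_tilt_distribution",
    "compute_proximity_binned_tilts",
    "sd_increase_percent",
    "compute_transverse_positions",
    "compute_density_profile",
]


# ======================================================================
# result types
# ======================================================================

@dataclass
class FrameSeriesSummary:
    """A per-frame scalar series with its mean and a 95% CI half-width."""

    series: np.ndarray
    mean: float
    ci95: float


@dataclass
class BilayerFrameSummary:
    """Per-frame area per lipid (nm^2) and/or P-plane thickness (nm)."""

    area_per_lipid: FrameSeriesSummary | None = None
    d_pp: FrameSeriesSummary | None = None


@dataclass(frozen=True)
class ChainSpec:
    """Defines a chain long axis per molecule: species plus first (head-
    side) and last (terminal) carbon atom names. The tilt vector is
    terminal -> first, i.e. it points outward."""

    species: str
    first_atom: str
    last_atom: str


@dataclass
class TiltDistribution:
    """Normalized tilt-angle histogram on [0, 90] degrees with sample mean
    (deg), variance (deg^2) and a condition label."""

    edges: np.ndarray
    density: np.ndarray
    mean: float
    variance: float
    n_samples: int
    label: str = "all"

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.n_samples > 0:
            total = float(np.sum(self.density * np.diff(self.edges)))
            if abs(total - 1.0) > 1e-6:
                raise AnalysisError("tilt density must integrate to 1")


@dataclass
class DensityProfile:
    """Mass density (kg/m^3) along the normal, per species, in the
    bilayer-COM frame."""

    z_centers: np.ndarray
    density: dict[str, np.ndarray]
    bin_width: float


@dataclass
class OrderParameterProfile:
    """Deuterium order parameter per carbon index along the chain."""

    carbon_index: np.ndarray
    s_cd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.s_cd < -0.5 - 1e-9) or np.any(self.s_cd > 1.0 + 1e-9):
            raise AnalysisError("S_CD out of [-0.5, 1]")


@dataclass
class TransverseLocation:
    """Mean |z - z_COM| of a group (nm) with a 95% CI over molecules."""

    mean: float
    ci95: float
    per_molecule: np.ndarray


def _mean_ci_frames(series: np.ndarray) -> FrameSeriesSummary:
    series = np.asarray(series, dtype=float)
    n = len(series)
    ci = 1.96 * series.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
    return FrameSeriesSummary(series=series, mean=float(series.mean()), ci95=ci)


# ======================================================================
# thickness and area
# ======================================================================

def compute_area_per_lipid(
    traj: Trajectory, n_lipids_per_leaflet: int
) -> BilayerFrameSummary:
    """Per-frame instant box area divided by the number of phospholipids in
    each leaflet, averaged over the analysis range."""
    if n_lipids_per_leaflet < 1:
        raise ParameterError("n_lipids_per_leaflet must be >= 1")
    plane = [ax for ax in range(3) if ax != traj.normal_axis]
    a = traj.box[:, plane[0]] * traj.box[:, plane[1]] / n_lipids_per_leaflet
    return BilayerFrameSummary(area_per_lipid=_mean_ci_frames(a))


def compute_thickness_dpp(
    traj: Trajectory, species: str = "lipid", atom_name: str = "P"
) -> BilayerFrameSummary:
    """Distance between the average planes (mean normal coordinate) of the
    selected atoms in the two leaflets, per frame."""
    ax = traj.normal_axis
    upper = traj.select(species=species, name=atom_name, leaflet="upper")
    lower = traj.select(species=species, name=atom_name, leaflet="lower")
    if upper.size == 0 or lower.size == 0:
        raise SelectionError("selector matched no atoms in one of the leaflets")
    d = (
        traj.positions[:, upper, ax].mean(axis=1)
        - traj.positions[:, lower, ax].mean(axis=1)
    )
    return BilayerFrameSummary(d_pp=_mean_ci_frames(np.abs(d)))


# ======================================================================
# deuterium order parameters
# ======================================================================

def scd_from_vectors(ch_vectors: np.ndarray, normal=(0.0, 0.0, 1.0)) -> float:
    """S_CD = <3 cos^2(theta) - 1> / 2 for C-H vectors vs the normal."""
    v = np.asarray(ch_vectors, dtype=float)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    norms = np.linalg.norm(v, axis=-1)
    if np.any(norms < 1e-12):
        raise GeometryError("zero-length C-H vector")
    cos = (v @ n) / norms
    return float(np.mean(1.5 * cos**2 - 0.5))


_TETRA_HALF = math.radians(109.47 / 2.0)


def _reconstruct_ch_dirs(prev, cur, nxt):
    """Unit C-H directions for the two methylene hydrogens of ``cur``
    given its bonded neighbours, by standard tetrahedral geometry.

    Arrays have shape (..., 3); returns two arrays of the same shape.
    """
    p = prev - cur
    q = nxt - cur
    p = p / np.linalg.norm(p, axis=-1, keepdims=True)
    q = q / np.linalg.norm(q, axis=-1, keepdims=True)
    s = p + q
    sn = np.linalg.norm(s, axis=-1, keepdims=True)
    if np.any(sn < 1e-10):
        raise GeometryError("collinear chain segment: C-H geometry undefined")
    s = s / sn
    n = np.cross(p, q)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(nn < 1e-10):
        raise GeometryError("collinear chain segment: C-H geometry undefined")
    n = n / nn
    h1 = -s * math.cos(_TETRA_HALF) + n * math.sin(_TETRA_HALF)
    h2 = -s * math.cos(_TETRA_HALF) - n * math.sin(_TETRA_HALF)
    return h1, h2


def compute_scd_profile(traj: Trajectory, chain: ChainSpec) -> OrderParameterProfile:
    """S_CD per interior chain carbon, with H positions reconstructed from
    the carbon skeleton, averaged over frames and molecules."""
    first = int(chain.first_atom.lstrip("C") or 1)
    last = int(chain.last_atom.lstrip("C"))
    names = [f"C{k}" for k in range(first, last + 1)]
    if len(names) < 3:
        raise GeometryError("need at least 3 chain atoms for S_CD")
    cols = []
    for nm in names:
        idx = traj.require(species=chain.species, name=nm,
                           err=f"missing chain atom {nm}")
        mols = traj.molecule_atom_indices(idx)
        cols.append([mols[m][0] for m in sorted(mols)])
    cols = np.asarray(cols)  # (n_carbons, n_mol)

    ax = np.zeros(3)
    ax[traj.normal_axis] = 1.0
    carbons, values = [], []
    for j in range(1, len(names) - 1):
        prev = traj.positions[:, cols[j - 1], :]
        cur = traj.positions[:, cols[j], :]
        nxt = traj.positions[:, cols[j + 1], :]
        h1, h2 = _reconstruct_ch_dirs(prev, cur, nxt)
        cos = np.concatenate([(h1 @ ax).ravel(), (h2 @ ax).ravel()])
        carbons.append(first + j)
        values.append(float(np.mean(1.5 * cos**2 - 0.5)))
    return OrderParameterProfile(
        carbon_index=np.array(carbons), s_cd=np.array(values)
    )


# ======================================================================
# tilt distributions
# ======================================================================

def _tilt_angles(traj: Trajectory, chain: ChainSpec) -> np.ndarray:
    """Tilt of the terminal->first chain vector vs the outward leaflet
    normal, folded to [0, 90] degrees; shape (n_frames, n_mol)."""
    idx_f = traj.require(species=chain.species, name=chain.first_atom,
                         err=f"missing atom {chain.first_atom}")
    idx_l = traj.require(species=chain.species, name=chain.last_atom,
                         err=f"missing atom {chain.last_atom}")
    mols_f = traj.molecule_atom_indices(idx_f)
    mols_l = traj.molecule_atom_indices(idx_l)
    common = sorted(set(mols_f) & set(mols_l))
    if not common:
        raise SelectionError("chain first/terminal atoms never share a molecule")
    fa = np.array([mols_f[m][0] for m in common])
    la = np.array([mols_l[m][0] for m in common])
    sign = np.array(
        [1.0 if traj.topology.leaflet[i] == "upper" else -1.0 for i in fa]
    )
    vec = traj.positions[:, fa, :] - traj.positions[:, la, :]
    norms = np.linalg.norm(vec, axis=2)
    if np.any(norms < 1e-12):
        raise GeometryError("zero-length chain vector")
    cos = sign[None, :] * vec[:, :, traj.normal_axis] / norms
    ang = np.degrees(np.arccos(np.clip(np.abs(cos), 0.0, 1.0)))
    return ang


def _make_tilt_distribution(
    samples: np.ndarray, bin_width: float, label: str
) -> TiltDistribution:
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        return TiltDistribution(
            edges=edges, density=np.zeros(len(edges) - 1),
            mean=float("nan"), variance=float("nan"), n_samples=0, label=label,
        )
    hist, _ = np.histogram(samples, bins=edges, density=True)
    return TiltDistribution(
        edges=edges, density=hist,
        mean=float(samples.mean()),
        variance=float(samples.var(ddof=0)),
        n_samples=samples.size, label=label,
    )


def compute_tilt_distribution(
    traj: Trajectory, chain: ChainSpec, bin_width: float = 1.0
) -> TiltDistribution:
    """Pooled (frames x molecules) tilt-angle distribution of one chain."""
    ang = _tilt_angles(traj, chain)
    return _make_tilt_distribution(ang, bin_width, label=f"{chain.species}:all")


def compute_proximity_binned_tilts(
    traj: Trajectory,
    lipid_chain: ChainSpec,
    probe_species: str = "probe",
    r_edges: tuple[float, float] = (0.7, 1.2),
    bin_width: float = 1.0,
) -> dict[str, TiltDistribution]:
    """Tilt distributions of lipid chains binned by the 3-D minimum-image
    COM distance R to the nearest probe molecule in the same leaflet.

    Returns ``{"near": ..., "mid": ..., "far": ...}`` with R < r_edges[0],
    r_edges[0] <= R < r_edges[1] and R >= r_edges[1] respectively.
    """
    if r_edges[0] > r_edges[1]:
        raise ParameterError("r_edges must be non-decreasing")
    probe_idx = traj.select(species=probe_species)
    if probe_idx.size == 0:
        raise AnalysisError("proximity analysis undefined without probes")

    ang = _tilt_angles(traj, lipid_chain)

    lipid_idx = traj.require(species=lipid_chain.species)
    lipid_mols = traj.molecule_atom_indices(lipid_idx)
    probe_mols = traj.molecule_atom_indices(probe_idx)
    lipid_ids = sorted(lipid_mols)
    lipid_leaf = [
        traj.topology.leaflet[lipid_mols[m][0]] for m in lipid_ids
    ]
    probe_leaf = [
        traj.topology.leaflet[probe_mols[m][0]] for m in sorted(probe_mols)
    ]
    lipid_com = np.stack(
        [traj.molecule_com(lipid_mols[m]) for m in lipid_ids], axis=1
    )  # (n_frames, n_lipid, 3)
    probe_com = np.stack(
        [traj.molecule_com(probe_mols[m]) for m in sorted(probe_mols)], axis=1
    )

    plane = [a for a in range(3) if a != traj.normal_axis]
    n_frames, n_lipid = ang.shape
    rmin = np.full((n_frames, n_lipid), np.inf)
    for j, leaf in enumerate(probe_leaf):
        d = lipid_com - probe_com[:, j: j + 1, :]
        d[:, :, plane] = minimum_image(
            d[:, :, plane], traj.box[:, None, plane]
        )
        dist = np.sqrt((d**2).sum(axis=2))
        same = np.array([l == leaf for l in lipid_leaf])
        dist[:, ~same] = np.inf
        rmin = np.minimum(rmin, dist)

    near_lo, near_hi = r_edges
    out = {}
    masks = {
        "near": rmin < near_lo,
        "mid": (rmin >= near_lo) & (rmin < near_hi),
        "far": rmin >= near_hi,
    }
    for label, mask in masks.items():
        out[label] = _make_tilt_distribution(
            ang[mask], bin_width, label=f"{lipid_chain.species}:{label}"
        )
    return out


def sd_increase_percent(var_far: float, var_near: float) -> int:
    """Percent increase of the tilt SD from the far bin to the near bin:
    100 (sqrt(var_near / var_far) - 1), rounded to the nearest integer."""
    if var_far <= 0:
        raise ParameterError("var_far must be > 0")
    if var_near < 0:
        raise ParameterError("var_near must be >= 0")
    return int(round(100.0 * (math.sqrt(var_near / var_far) - 1.0)))


# ======================================================================
# transverse locations and density profiles
# ======================================================================

def compute_transverse_positions(
    traj: Trajectory, groups: dict[str, tuple[str, str]]
) -> dict[str, TransverseLocation]:
    """Mean |z_group-COM - z_bilayer-COM| per group.

    ``groups`` maps a label to (species, atom-name pattern). The CI is
    1.96 x the standard error over per-molecule means (molecules are the
    independent units; frames are autocorrelated).
    """
    ax = traj.normal_axis
    z_bil = traj.bilayer_com()[:, ax]
    out = {}
    for label, (species, pattern) in groups.items():
        idx = traj.require(species=species, name=pattern,
                           err=f"group {label!r} is empty")
        mols = traj.molecule_atom_indices(idx)
        per_mol = np.array(
            [
                np.abs(traj.molecule_com(ai)[:, ax] - z_bil).mean()
                for ai in mols.values()
            ]
        )
        n = len(per_mol)
        ci = 1.96 * per_mol.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
        out[label] = TransverseLocation(
            mean=float(per_mol.mean()), ci95=float(ci), per_molecule=per_mol
        )
    return out


def compute_density_profile(
    traj: Trajectory,
    species_list: list[str] | None = None,
    bin_width: float = 0.1,
) -> DensityProfile:
    """Mass density profile along the normal in the bilayer-COM frame,
    averaged over frames, in kg/m^3.

    The bin volume is box area x bin width; an "all" profile over every
    atom is always included.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    ax = traj.normal_axis
    plane = [a for a in range(3) if a != ax]
    z_bil = traj.bilayer_com()[:, ax]
    z = traj.positions[:, :, ax] - z_bil[:, None]
    zmax = max(abs(float(z.min())), abs(float(z.max()))) + bin_width
    n_half = math.ceil(zmax / bin_width)
    edges = np.arange(-n_half, n_half + 1) * bin_width
    area = float(np.mean(traj.box[:, plane[0]] * traj.box[:, plane[1]]))

    if species_list is None:
        species_list = sorted(set(traj.topology.species))
    density: dict[str, np.ndarray] = {}
    conv = AMU_PER_NM3_TO_KG_PER_M3 / (area * bin_width * traj.n_frames)
    for sp in list(species_list) + ["all"]:
        idx = (
            np.arange(traj.n_atoms)
            if sp == "all"
            else traj.select(species=sp)
        )
        hist, _ = np.histogram(
            z[:, idx].ravel(),
            bins=edges,
            weights=np.tile(traj.topology.mass[idx], traj.n_frames),
        )
        density[sp] = hist * conv
    centers = 0.5 * (edges[1:] + edges[:-1])
    return DensityProfile(z_centers=centers, density=density, bin_width=bin_width)
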