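"""Atom-atom radial distribution functions and cumulative coordination
numbers.

3-D spherical-shell normalization (bin volume x mean selection density),
minimum-image distances in an orthorhombic box, optional exclusion of
intramolecular pairs. N(r) is the average number of selection atoms within
r of one reference atom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, RangeError, SelectionError
from .trajectory import Trajectory, minimum_image

__all__ = ["RDFCurve", "compute_rdf"]


@dataclass
class RDFCurve:
    r: np.ndarray        # bin centers, nm
    g: np.ndarray        # dimensionless
    n_cum: np.ndarray    # cumulative count per reference atom
    ref_label: str = ""
    sel_label: str = ""

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise ParameterError("g(r) must be >= 0")
        if np.any(np.diff(self.n_cum) < -1e-12):
            raise ParameterError("N(r) must be non-decreasing")


def compute_rdf(
    traj: Trajectory,
    ref_indices: np.ndarray,
    sel_indices: np.ndarray,
    r_max: float,
    bin_width: float = 0.01,
    exclude_same_molecule: bool = True,
) -> RDFCurve:
    """RDF g(r) and cumulative N(r) between two atom selections.

    Parameters
    ----------
    ref_indices, sel_indices : atom index arrays (see Trajectory.select).
    r_max : maximum distance, must not exceed half the smallest box edge.
    exclude_same_molecule : drop pairs within one molecule (self pairs are
        always dropped).
    """
    ref = np.asarray(ref_indices, dtype=int)
    sel = np.asarray(sel_indices, dtype=int)
    if ref.size == 0 or sel.size == 0:
        raise SelectionError("reference and selection must be non-empty")
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    if r_max <= 0:
        raise ParameterError("r_max must be > 0")
    if r_max > 0.5 * float(traj.box.min()) + 1e-12:
        raise RangeError("r_max exceeds half the smallest box dimension")

    mids = traj.topology.molecule_id
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    n_bins = len(edges) - 1
    counts = np.zeros(n_bins)
    vol_sum = 0.0
    n_frames = traj.n_frames

    for f in range(n_frames):
        box = traj.box[f]
        vol_sum += float(np.prod(box))
        pos_ref = traj.positions[f, ref, :]
        pos_sel = traj.positions[f, sel, :]
        # chunk over reference atoms to bound memory
        chunk = max(1, int(2e6 // max(sel.size, 1)))
        for i0 in range(0, ref.size, chunk):
            r_blk = pos_ref[i0: i0 + chunk]
            d = r_blk[:, None, :] - pos_sel[None, :, :]
            d = minimum_image(d, box)
            dist = np.sqrt((d**2).sum(axis=2))
            mask = dist < r_max
            # self pairs
            same_atom = ref[i0: i0 + chunk, None] == sel[None, :]
            mask &= ~same_atom
            if exclude_same_molecule:
                same_mol = (
                    mids[ref[i0: i0 + chunk], None] == mids[sel[None, :]]
                )
                mask &= ~same_mol
            h, _ = np.histogram(dist[mask], bins=edges)
            counts += h

    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    mean_vol = vol_sum / n_frames
    rho_sel = sel.size / mean_vol
    norm = ref.size * n_frames
    g = counts / (norm * shell_vol * rho_sel)
    n_cum = np.cumsum(counts) / norm
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFCurve(r=centers, g=g, n_cum=n_cum)
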