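import numpy as np
import pytest

from memprobe import trajgen
from memprobe.trajectory import Topology, Trajectory


@pytest.fixture(scope="session")
def small_bilayer():
    """A small probe-carrying bilayer used by several structure tests."""
    spec = trajgen.SyntheticBilayerSpec(
        n_lipids_per_leaflet=64,
        lattice_spacing=1.0,
        chain_length=6,
        d_pp_true=4.0,
        tilt_mean=30.0,
        tilt_sd_near=9.2,
        tilt_sd_mid=7.0,
        tilt_sd_far=5.8,
        probe_spec=trajgen.ProbeSpec(1, 1.9),
    )
    return trajgen.gen_bilayer_config(spec, n_frames=30, seed=42)


def make_trajectory(positions, box=(10.0, 10.0, 10.0), species=None,
                    names=None, masses=None, leaflets=None, mol_id=None,
                    times=None):
    """Hand-rolled Trajectory helper for focused unit tests."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[None]
    n_frames, n_atoms, _ = positions.shape
    if species is None:
        species = ["lipid"] * n_atoms
    if names is None:
        names = [f"A{i}" for i in range(n_atoms)]
    if masses is None:
        masses = [1.0] * n_atoms
    if leaflets is None:
        leaflets = ["upper"] * n_atoms
    if mol_id is None:
        mol_id = list(range(n_atoms))
    top = Topology(
        species=np.array(species, dtype=object),
        molecule_id=np.array(mol_id),
        atom_name=np.array(names, dtype=object),
        mass=np.array(masses, dtype=float),
        leaflet=np.array(leaflets, dtype=object),
    )
    boxes = np.tile(np.asarray(box, dtype=float), (n_frames, 1))
    if times is None:
        times = np.arange(n_frames, dtype=float)
    return Trajectory(positions=positions, box=boxes,
                      time=np.asarray(times, dtype=float), topology=top)
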