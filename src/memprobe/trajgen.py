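"""Synthetic ground-truth generators.

Every analysis stage in this package can be exercised without MD data: the
generators below produce hindered-rotor orientation series with a known
order parameter, 2-D lateral random walks with a known diffusion
coefficient, idealized two-leaflet bilayer configurations with prescribed
thickness/tilt statistics/probe depth, umbrella-window samples drawn
exactly from an analytic free-energy landscape, and multiexponential ACF
curves with known parameters.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import rt
from .exceptions import ParameterError, RangeError
from .trajectory import Topology, Trajectory

__all__ = [
    "ConeModelParams",
    "LateralWalkParams",
    "LateralWalk",
    "ProbeSpec",
    "SyntheticBilayerSpec",
    "AnalyticPMF",
    "cone_order_parameter",
    "gen_hindered_rotor",
    "gen_lateral_walk",
    "gen_bilayer_config",
    "gen_umbrella_samples",
    "gen_acf_curve",
]

_MAX_SUBSTEP_RMS_RAD = math.radians(3.0)  # spherical-BD accuracy bound


# ======================================================================
# hindered rotor (wobbling in a cone)
# ======================================================================

@dataclass(frozen=True)
class ConeModelParams:
    """Cone-hindered rotational diffusion parameters.

    theta_c : cone half-angle in degrees, in (0, 180].
    d_w : wobbling diffusion coefficient, rad^2/ns.
    axis : cone axis (normalized on construction).
    """

    theta_c: float
    d_w: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_c <= 180.0):
            raise ParameterError("theta_c must lie in (0, 180] degrees")
        if self.d_w < 0:
            raise ParameterError("d_w must be >= 0")
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ParameterError("axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(a / n))


def cone_order_parameter(theta_c_deg: float) -> float:
    """Order parameter S of uniform wobbling in a cone of half-angle
    theta_c: S = cos(theta_c) (1 + cos(theta_c)) / 2."""
    c = math.cos(math.radians(theta_c_deg))
    return 0.5 * c * (1.0 + c)


def _fold_into_cone(theta: np.ndarray, theta_c: float) -> np.ndarray:
    """Mirror polar angles back inside [0, theta_c] (triangle-wave fold).

    A mirror step preserves the uniform equilibrium density inside the cone.
    """
    y = np.mod(theta, 2.0 * theta_c)
    return np.where(y > theta_c, 2.0 * theta_c - y, y)


def gen_hindered_rotor(
    params: ConeModelParams,
    n_steps: int,
    dt: float,
    n_molecules: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Simulate unit axis vectors undergoing cone-hindered rotational
    Brownian motion.

    Propagation uses small tangent-plane Gaussian steps followed by
    renormalization; internal sub-stepping keeps the RMS step angle below
    3 degrees. Steps leaving the cone are reflected at the cone surface.
    Initial orientations are drawn from the uniform density inside the
    cone, so the output series is stationary.

    Returns
    -------
    ndarray, shape (n_steps, n_molecules, 3)
        Unit vectors; the angle to ``params.axis`` never exceeds theta_c.
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if n_molecules < 1:
        raise ParameterError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    theta_c = math.radians(params.theta_c)
    d_w = params.d_w

    # Work in a frame where the cone axis is +z; rotate at the end.
    cos_tc = math.cos(theta_c)
    u0_cos = rng.uniform(cos_tc, 1.0, size=n_molecules)
    u0_phi = rng.uniform(0.0, 2.0 * math.pi, size=n_molecules)
    s0 = np.sqrt(np.clip(1.0 - u0_cos**2, 0.0, None))
    u = np.column_stack([s0 * np.cos(u0_phi), s0 * np.sin(u0_phi), u0_cos])

    out = np.empty((n_steps, n_molecules, 3))
    out[0] = u
    if n_steps > 1 and d_w > 0:
        n_sub = max(1, math.ceil(4.0 * d_w * dt / _MAX_SUBSTEP_RMS_RAD**2))
        sigma = math.sqrt(2.0 * d_w * dt / n_sub)
        kernel = _numba_kernel() or _propagate_block_numpy
        block = 20000  # bound the pre-generated random block size
        for i0 in range(1, n_steps, block):
            i1 = min(i0 + block, n_steps)
            rand = rng.standard_normal((i1 - i0, n_sub, n_molecules, 2)) * sigma
            kernel(u, rand, theta_c, out[i0:i1])
            u = out[i1 - 1].copy()
    elif n_steps > 1:
        out[1:] = u  # d_w = 0: frozen orientations

    axis = np.asarray(params.axis)
    if not np.allclose(axis, (0.0, 0.0, 1.0)):
        b3 = axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(b3[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        b1 = np.cross(helper, b3)
        b1 /= np.linalg.norm(b1)
        b2 = np.cross(b3, b1)
        out = out @ np.stack([b1, b2, b3])
    return out


def _bd_substep(u: np.ndarray, xi: np.ndarray, theta_c: float) -> np.ndarray:
    """One tangent-plane Gaussian step + renormalization + cone reflection
    (cone axis = +z); ``xi`` holds the pre-scaled Gaussian displacements."""
    # tangent basis at u, avoiding degeneracy when u is near an axis
    helper = np.where(
        (np.abs(u[:, 2]) < 0.9)[:, None],
        np.array([0.0, 0.0, 1.0]),
        np.array([1.0, 0.0, 0.0]),
    )
    t1 = np.cross(u, helper)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(u, t1)
    u = u + xi[:, :1] * t1 + xi[:, 1:] * t2
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    ct = np.clip(u[:, 2], -1.0, 1.0)
    theta = np.arccos(ct)
    over = theta > theta_c
    if np.any(over):
        theta_new = _fold_into_cone(theta[over], theta_c)
        rho = np.linalg.norm(u[over, :2], axis=1)
        # preserve azimuth; arbitrary azimuth for vectors exactly on a pole
        ex = np.where(rho > 1e-12, u[over, 0] / np.where(rho > 0, rho, 1.0), 1.0)
        ey = np.where(rho > 1e-12, u[over, 1] / np.where(rho > 0, rho, 1.0), 0.0)
        st = np.sin(theta_new)
        u[over, 0] = st * ex
        u[over, 1] = st * ey
        u[over, 2] = np.cos(theta_new)
    return u


def _propagate_block_numpy(u, rand, theta_c, out) -> None:
    """Numpy fallback for the blockwise propagation kernel."""
    for i in range(rand.shape[0]):
        for k in range(rand.shape[1]):
            u = _bd_substep(u, rand[i, k], theta_c)
        out[i] = u


_NUMBA_KERNEL = None


def _numba_kernel():
    """Compile (once) a scalar propagation kernel if numba is available."""
    global _NUMBA_KERNEL
    if _NUMBA_KERNEL is not None:
        return _NUMBA_KERNEL or None
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional speed-up
        _NUMBA_KERNEL = False
        return None

    @njit(cache=False)
    def kernel(u, rand, theta_c, out):  # pragma: no cover - compiled
        n_rec, n_sub, n_mol, _ = rand.shape
        for i in range(n_rec):
            for k in range(n_sub):
                for m in range(n_mol):
                    ux, uy, uz = u[m, 0], u[m, 1], u[m, 2]
                    if abs(uz) < 0.9:
                        hx, hy, hz = 0.0, 0.0, 1.0
                    else:
                        hx, hy, hz = 1.0, 0.0, 0.0
                    t1x = uy * hz - uz * hy
                    t1y = uz * hx - ux * hz
                    t1z = ux * hy - uy * hx
                    inv = 1.0 / math.sqrt(t1x * t1x + t1y * t1y + t1z * t1z)
                    t1x *= inv
                    t1y *= inv
                    t1z *= inv
                    t2x = uy * t1z - uz * t1y
                    t2y = uz * t1x - ux * t1z
                    t2z = ux * t1y - uy * t1x
                    a = rand[i, k, m, 0]
                    b = rand[i, k, m, 1]
                    ux += a * t1x + b * t2x
                    uy += a * t1y + b * t2y
                    uz += a * t1z + b * t2z
                    inv = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux *= inv
                    uy *= inv
                    uz *= inv
                    ct = uz
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                    theta = math.acos(ct)
                    if theta > theta_c:
                        y = theta % (2.0 * theta_c)
                        if y > theta_c:
                            y = 2.0 * theta_c - y
                        rho = math.sqrt(ux * ux + uy * uy)
                        if rho > 1e-12:
                            ex = ux / rho
                            ey = uy / rho
                        else:
                            ex, ey = 1.0, 0.0
                        st = math.sin(y)
                        ux = st * ex
                        uy = st * ey
                        uz = math.cos(y)
                    u[m, 0], u[m, 1], u[m, 2] = ux, uy, uz
            for m in range(n_mol):
                out[i, m, 0] = u[m, 0]
                out[i, m, 1] = u[m, 1]
                out[i, m, 2] = u[m, 2]

    _NUMBA_KERNEL = kernel
    return kernel


# ======================================================================
# lateral random walk
# ======================================================================

@dataclass(frozen=True)
class LateralWalkParams:
    """2-D Brownian walk parameters: D (nm^2/ns), molecule count, step dt
    (ns) and an optional common per-step leaflet drift (nm)."""

    d: float
    n_molecules: int
    dt: float
    drift: np.ndarray | None = None  # (n_steps-1, 2) per-step displacements

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ParameterError("D must be >= 0")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.n_molecules < 1:
            raise ParameterError("n_molecules must be >= 1")


@dataclass
class LateralWalk:
    """Generated walk: positions (n_steps, n_molecules, 2), times (ns) and
    the cumulative common drift actually applied (n_steps, 2)."""

    positions: np.ndarray
    time: np.ndarray
    drift: np.ndarray


def gen_lateral_walk(
    params: LateralWalkParams, n_steps: int, seed: int = 0
) -> LateralWalk:
    """Simulate independent 2-D Gaussian random walks plus a common drift.

    Increments per axis are N(0, 2 D dt); the same drift displacement is
    added to every molecule, mimicking leaflet center-of-mass motion.
    """
    if n_steps < 2:
        raise ParameterError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(2.0 * params.d * params.dt)
    steps = rng.standard_normal((n_steps - 1, params.n_molecules, 2)) * sigma
    pos = np.zeros((n_steps, params.n_molecules, 2))
    np.cumsum(steps, axis=0, out=pos[1:])

    drift_cum = np.zeros((n_steps, 2))
    if params.drift is not None:
        d = np.asarray(params.drift, dtype=float)
        if d.shape != (n_steps - 1, 2):
            raise ParameterError("drift must have shape (n_steps - 1, 2)")
        np.cumsum(d, axis=0, out=drift_cum[1:])
        pos = pos + drift_cum[:, None, :]

    time = np.arange(n_steps) * params.dt
    return LateralWalk(positions=pos, time=time, drift=drift_cum)


# ======================================================================
# synthetic bilayer configurations
# ======================================================================

@dataclass(frozen=True)
class ProbeSpec:
    """Probe content of each leaflet: count and carboxylate transverse
    depth |z| from the bilayer center (nm)."""

    n_per_leaflet: int
    carboxylate_depth: float

    def __post_init__(self) -> None:
        if self.n_per_leaflet < 0:
            raise ParameterError("probe count must be >= 0")
        if self.carboxylate_depth <= 0:
            raise ParameterError("carboxylate depth must be > 0")


@dataclass(frozen=True)
class SyntheticBilayerSpec:
    """Parameters of the idealized two-leaflet bilayer generator.

    Lipids sit on a square lattice, one head bead ("P") on the P plane at
    z = +/- d_pp_true/2 and a straight segmented chain tilted toward the
    midplane. The per-frame tilt of each chain is drawn from a normal law
    N(tilt_mean, sd) where sd depends on the lipid's lateral distance to
    the nearest probe site (near/mid/far, split at ``proximity_edges``).
    Probes carry a carboxylate head bead ("COO") fixed at
    |z| = carboxylate depth and a chain like the lipids'.
    """

    n_lipids_per_leaflet: int = 100
    lattice_spacing: float = 1.0
    chain_length: int = 8
    d_pp_true: float = 4.0
    tilt_mean: float = 0.0
    tilt_sd_near: float = 0.0
    tilt_sd_mid: float = 0.0
    tilt_sd_far: float = 0.0
    probe_spec: ProbeSpec = field(default_factory=lambda: ProbeSpec(0, 1.9))
    proximity_edges: tuple[float, float] = (0.7, 1.2)
    head_mass: float = 300.0
    chain_bead_mass: float = 12.0
    bond_length: float = 0.15
    zigzag: float = 0.05  # lateral offset of even interior beads, nm
    frame_dt: float = 1.0  # ns between frames

    def __post_init__(self) -> None:
        if self.n_lipids_per_leaflet < 1:
            raise ParameterError("need at least one lipid per leaflet")
        if min(self.lattice_spacing, self.d_pp_true, self.bond_length) <= 0:
            raise ParameterError("spacings and depths must be > 0")
        if self.chain_length < 1:
            raise ParameterError("chain_length must be >= 1")
        if min(self.tilt_sd_near, self.tilt_sd_mid, self.tilt_sd_far) < 0:
            raise ParameterError("tilt SDs must be >= 0")
        if self.probe_spec.n_per_leaflet > self.n_lipids_per_leaflet:
            raise ParameterError("probes per leaflet cannot exceed lipids per leaflet")


def _lattice_sites(n: int, a: float) -> tuple[np.ndarray, float]:
    m = math.ceil(math.sqrt(n))
    ij = np.arange(n)
    xy = np.column_stack([(ij % m) * a, (ij // m) * a]) + 0.5 * a
    return xy, m * a


def _probe_sites(n_probes: int, m_side: float, a: float) -> np.ndarray:
    """Probe xy positions: offset by (a/2, 0) from host lattice sites laid
    out on a coarse sub-grid so probes stay well separated."""
    if n_probes == 0:
        return np.zeros((0, 2))
    g = math.ceil(math.sqrt(n_probes))
    pitch = m_side / g
    if pitch < 3.0 * a:
        raise ParameterError(
            "probe count exceeds available lattice sites for separated placement"
        )
    ij = np.arange(n_probes)
    xy = np.column_stack(
        [(ij % g + 0.5) * pitch + 0.5 * a, (ij // g + 0.5) * pitch]
    )
    return xy


def gen_bilayer_config(
    spec: SyntheticBilayerSpec, n_frames: int, seed: int = 0
) -> Trajectory:
    """Generate an idealized bilayer trajectory (see SyntheticBilayerSpec).

    The two leaflets are mirror-symmetric about z = 0, the P planes sit at
    +/- d_pp_true / 2 and probe carboxylates at +/- carboxylate depth.
    Leaflet labels are stored explicitly in the topology.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    a = spec.lattice_spacing
    nlip = spec.n_lipids_per_leaflet
    nprobe = spec.probe_spec.n_per_leaflet
    chain = spec.chain_length
    lipid_xy, side = _lattice_sites(nlip, a)
    probe_xy = _probe_sites(nprobe, side, a)
    box = np.array([side, side, spec.d_pp_true + 2.0])

    # static proximity class of each lipid site (min-image lateral distance
    # to the nearest probe site in the same leaflet)
    if nprobe > 0:
        d = lipid_xy[:, None, :] - probe_xy[None, :, :]
        d -= box[:2] * np.round(d / box[:2])
        rmin = np.sqrt((d**2).sum(axis=2)).min(axis=1)
        near, mid = spec.proximity_edges
        sd_by_lipid = np.where(
            rmin < near,
            spec.tilt_sd_near,
            np.where(rmin < mid, spec.tilt_sd_mid, spec.tilt_sd_far),
        )
    else:
        sd_by_lipid = np.full(nlip, spec.tilt_sd_far)

    # topology: per leaflet, lipids (P + chain beads) then probes (COO + chain)
    species, mol_id, names, masses, leaflets = [], [], [], [], []
    mol = 0
    for leaflet in ("upper", "lower"):
        for _ in range(nlip):
            species += ["lipid"] * (1 + chain)
            names += ["P"] + [f"C{k + 1}" for k in range(chain)]
            masses += [spec.head_mass] + [spec.chain_bead_mass] * chain
            mol_id += [mol] * (1 + chain)
            leaflets += [leaflet] * (1 + chain)
            mol += 1
        for _ in range(nprobe):
            species += ["probe"] * (1 + chain)
            names += ["COO"] + [f"C{k + 1}" for k in range(chain)]
            masses += [spec.head_mass] + [spec.chain_bead_mass] * chain
            mol_id += [mol] * (1 + chain)
            leaflets += [leaflet] * (1 + chain)
            mol += 1
    top = Topology(
        species=np.array(species, dtype=object),
        molecule_id=np.array(mol_id),
        atom_name=np.array(names, dtype=object),
        mass=np.array(masses, dtype=float),
        leaflet=np.array(leaflets, dtype=object),
    )

    n_atoms = top.n_atoms
    positions = np.empty((n_frames, n_atoms, 3))
    kbead = np.arange(1, chain + 1) * spec.bond_length

    for f in range(n_frames):
        frame = np.empty((n_atoms, 3))
        at = 0
        for sign in (1.0, -1.0):
            for group, xy_all, z_head, sds in (
                ("lipid", lipid_xy, sign * spec.d_pp_true / 2.0, sd_by_lipid),
                (
                    "probe",
                    probe_xy,
                    sign * spec.probe_spec.carboxylate_depth,
                    np.full(nprobe, spec.tilt_sd_near),
                ),
            ):
                nm = len(xy_all)
                if nm == 0:
                    continue
                # sd = 0 gives exactly tilt_mean; negative draws fold at 0
                theta = np.abs(rng.normal(0.0, 1.0, nm) * sds + spec.tilt_mean)
                theta = np.clip(theta, 0.0, 90.0)
                phi = rng.uniform(0.0, 2.0 * math.pi, nm)
                th = np.radians(theta)
                dirs = np.column_stack(
                    [
                        np.sin(th) * np.cos(phi),
                        np.sin(th) * np.sin(phi),
                        -sign * np.cos(th),
                    ]
                )
                for i in range(nm):
                    head = np.array([xy_all[i, 0], xy_all[i, 1], z_head])
                    frame[at] = head
                    beads = head + kbead[:, None] * dirs[i]
                    if spec.zigzag > 0 and chain >= 3:
                        # offset even interior beads perpendicular to the
                        # chain so consecutive triples are never collinear;
                        # first/terminal beads stay on the axis, keeping
                        # the tilt vector exact
                        perp = np.cross(dirs[i], [0.0, 0.0, 1.0])
                        pn = np.linalg.norm(perp)
                        if pn < 1e-9:
                            perp = np.array([1.0, 0.0, 0.0])
                        else:
                            perp = perp / pn
                        kk = np.arange(1, chain + 1)
                        interior_even = (kk % 2 == 0) & (kk > 1) & (kk < chain)
                        beads[interior_even] += spec.zigzag * perp
                    frame[at + 1: at + 1 + chain] = beads
                    at += 1 + chain
        positions[f] = frame

    time = np.arange(n_frames) * spec.frame_dt
    boxes = np.tile(box, (n_frames, 1))
    return Trajectory(positions=positions, box=boxes, time=time, topology=top)


# ======================================================================
# analytic PMFs and umbrella sampling
# ======================================================================

@dataclass
class AnalyticPMF:
    """Analytic free-energy landscape G(z) on a grid (kJ/mol, nm)."""

    z: np.ndarray
    g: np.ndarray
    form: str = "custom"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.z.shape != self.g.shape or self.z.ndim != 1:
            raise ParameterError("z and G must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.g)):
            raise ParameterError("G must be finite on the grid")

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return np.interp(z, self.z, self.g)

    # ------------------------------------------------------------ factories
    @classmethod
    def flat(cls, z_min: float = 0.0, z_max: float = 4.0, n: int = 401) -> "AnalyticPMF":
        z = np.linspace(z_min, z_max, n)
        return cls(z=z, g=np.zeros_like(z), form="flat")

    @classmethod
    def harmonic(
        cls, kappa: float, z_min: float = -3.0, z_max: float = 3.0, n: int = 601
    ) -> "AnalyticPMF":
        z = np.linspace(z_min, z_max, n)
        return cls(z=z, g=0.5 * kappa * z**2, form="harmonic", params={"kappa": kappa})

    @classmethod
    def amphiphile(
        cls,
        well_depth: float = 25.0,
        center_barrier: float = 10.0,
        z_well: float = 1.6,
        sigma_well: float = 0.35,
        sigma_barrier: float = 0.6,
        z_max: float = 4.0,
        n: int = 801,
    ) -> "AnalyticPMF":
        """Amphiphile-shaped landscape: interfacial wells of depth
        ``well_depth`` at +/- z_well, a central barrier ``center_barrier``
        above the water plateau (G = 0 for large |z|)."""
        z = np.linspace(-z_max, z_max, n)
        g = (
            -well_depth * np.exp(-((z - z_well) ** 2) / (2 * sigma_well**2))
            - well_depth * np.exp(-((z + z_well) ** 2) / (2 * sigma_well**2))
            + center_barrier * np.exp(-(z**2) / (2 * sigma_barrier**2))
        )
        return cls(
            z=z,
            g=g,
            form="amphiphile",
            params={
                "well_depth": well_depth,
                "center_barrier": center_barrier,
                "z_well": z_well,
            },
        )


def gen_umbrella_samples(
    pmf: AnalyticPMF,
    window_centers,
    k: float,
    n_samples: int,
    temperature: float = 298.15,
    seed: int = 0,
    grid_step: float = 1e-3,
    stratified: bool = True,
):
    """Draw exact samples from each biased window density
    p(z) ~ exp(-[G(z) + k/2 (z - z0)^2] / RT) by grid inverse-CDF.

    With ``stratified`` (default) the uniform variates are drawn one per
    equal-probability stratum and shuffled: every sample still follows the
    exact biased density, but the empirical distribution converges as
    ~1/n instead of ~1/sqrt(n), which sharpens ground-truth comparisons.
    Set ``stratified=False`` for plain independent draws.

    Returns a list of :class:`memprobe.energetics.UmbrellaWindow`.
    """
    from .energetics import UmbrellaWindow  # local import avoids a cycle

    if k <= 0:
        raise ParameterError("force constant must be > 0")
    if temperature <= 0:
        raise ParameterError("temperature must be > 0")
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    centers = np.asarray(window_centers, dtype=float)
    zlo, zhi = float(pmf.z[0]), float(pmf.z[-1])
    eps = 1e-9 * max(1.0, abs(zlo), abs(zhi))
    if np.any(centers < zlo - eps) or np.any(centers > zhi + eps):
        raise RangeError("window centers must lie within the PMF grid")
    centers = np.clip(centers, zlo, zhi)

    rng = np.random.default_rng(seed)
    beta = 1.0 / rt(temperature)
    grid = np.arange(zlo, zhi + 0.5 * grid_step, grid_step)
    g_fine = pmf(grid)
    windows = []
    for z0 in centers:
        logw = -beta * (g_fine + 0.5 * k * (grid - z0) ** 2)
        w = np.exp(logw - logw.max())
        # cell probabilities on midpoints -> piecewise-linear inverse CDF
        p = 0.5 * (w[1:] + w[:-1])
        cdf = np.concatenate([[0.0], np.cumsum(p)])
        cdf /= cdf[-1]
        if stratified:
            u = (np.arange(n_samples) + rng.uniform(size=n_samples)) / n_samples
            rng.shuffle(u)
        else:
            u = rng.uniform(0.0, 1.0, n_samples)
        samples = np.interp(u, cdf, grid)
        windows.append(
            UmbrellaWindow(center=float(z0), k=k, samples=samples,
                           temperature=temperature)
        )
    return windows


# ======================================================================
# synthetic ACF curves
# ======================================================================

def gen_acf_curve(fit, t_grid, noise_sd: float = 0.0, seed: int = 0):
    """Evaluate a multiexponential-plus-constant ACF model on ``t_grid``
    and optionally add Gaussian noise.

    ``fit`` is a :class:`memprobe.dynamics.ACFFitParams` (or anything with
    ``amplitudes``, ``times`` and ``a_inf``).
    """
    from .dynamics import ACFCurve, acf_model

    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    t = np.asarray(t_grid, dtype=float)
    c = acf_model(t, np.asarray(fit.amplitudes), np.asarray(fit.times), fit.a_inf)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        c = c + rng.normal(0.0, noise_sd, size=t.shape)
    return ACFCurve(t=t, c=c)
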