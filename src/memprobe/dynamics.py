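"""Rotational and translational dynamics.

* P2 rotational autocorrelation of a molecular axis, averaged over time
  origins and molecules (FFT-accelerated for stride-1 origins).
* Bounded multiexponential-plus-constant fitting with deterministic
  multistart initialization and parsimony-based model-order selection.
* Limiting-anisotropy estimate r_inf = r0 * a_inf.
* Mean correlation time <Phi> = sum_i a_i Phi_i (analytic integral of the
  decaying part of the fitted model).
* 2-D mean squared displacement with optional leaflet-COM removal and the
  Einstein-relation lateral diffusion coefficient (slope / 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .constants import NM2_PER_NS_TO_CM2_PER_S
from .exceptions import (
    AnalysisError,
    FitError,
    GeometryError,
    ParameterError,
)
from .trajectory import Trajectory

__all__ = [
    "ACFCurve",
    "ACFFitParams",
    "AnisotropyEstimate",
    "MSDCurve",
    "DiffusionEstimate",
    "acf_model",
    "p2_acf",
    "compute_rotational_acf",
    "fit_acf",
    "anisotropy_estimate",
    "mean_correlation_time",
    "msd_from_positions",
    "compute_msd",
    "estimate_dlat",
]


# ======================================================================
# data types
# ======================================================================

@dataclass
class ACFCurve:
    """P2 orientational ACF: lag times (ns), averaged C(t), optional
    per-molecule curves (n_lags, n_molecules) and origin counts."""

    t: np.ndarray
    c: np.ndarray
    per_molecule: np.ndarray | None = None
    n_origins: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.c = np.asarray(self.c, dtype=float)


@dataclass
class ACFFitParams:
    """Fitted parameters of C(t) = sum_i a_i exp(-t/Phi_i) + a_inf.

    ``times`` are sorted ascending; ``mean_time`` is sum_i a_i Phi_i.
    """

    amplitudes: np.ndarray
    times: np.ndarray
    a_inf: float
    n_exp: int = 0
    mean_time: float = 0.0
    ssr: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if self.amplitudes.shape != self.times.shape:
            raise ParameterError("amplitudes and times must have equal length")
        if np.any(self.amplitudes < 0):
            raise ParameterError("amplitudes must be >= 0")
        if np.any(self.times[self.amplitudes > 0] <= 0):
            raise ParameterError("times must be > 0 where amplitude > 0")
        if not (0.0 <= self.a_inf <= 1.0 + 1e-9):
            raise ParameterError("a_inf must lie in [0, 1]")
        order = np.argsort(self.times)
        self.times = self.times[order]
        self.amplitudes = self.amplitudes[order]
        if self.n_exp == 0:
            self.n_exp = len(self.amplitudes)
        if self.mean_time == 0.0:
            self.mean_time = float(np.sum(self.amplitudes * self.times))


@dataclass
class AnisotropyEstimate:
    """Fundamental (r0) and limiting (r_inf) anisotropy estimates."""

    r0: float
    r_inf: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_inf <= self.r0 <= 0.4 + 1e-9):
            raise ParameterError("require 0 <= r_inf <= r0 <= 2/5")


@dataclass
class MSDCurve:
    """In-plane MSD: lag times (ns) and MSD (nm^2)."""

    t: np.ndarray
    msd: np.ndarray
    label: str = ""
    leaflet_com_removed: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)


@dataclass
class DiffusionEstimate:
    """Lateral diffusion coefficient (cm^2/s), fit window (ns) and R^2."""

    d_lat: float
    fit_window: tuple[float, float]
    r_squared: float


# ======================================================================
# rotational ACF
# ======================================================================

def acf_model(t, amplitudes, times, a_inf):
    """Evaluate sum_i a_i exp(-t/Phi_i) + a_inf."""
    t = np.asarray(t, dtype=float)
    c = np.full(t.shape, float(a_inf))
    for a, phi in zip(np.atleast_1d(amplitudes), np.atleast_1d(times)):
        if a != 0:
            c = c + a * np.exp(-t / phi)
    return c


def _raw_autocorr_fft(x: np.ndarray) -> np.ndarray:
    """Raw lag sums S(l) = sum_t x[t] x[t+l] along axis 0 via FFT.

    x has shape (n, ...); the result has the same shape.
    """
    n = x.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, n=nfft, axis=0)
    s = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:n]
    return s


def p2_acf(
    orientations: np.ndarray,
    times: np.ndarray | None = None,
    max_lag_fraction: float = 0.5,
    origin_stride: int = 1,
) -> ACFCurve:
    """P2 autocorrelation of unit-vector time series.

    C(l) = < P2( u(xi) . u(xi + l) ) >, averaged over all origins xi
    (subsampled by ``origin_stride``) and molecules.

    Parameters
    ----------
    orientations : ndarray, shape (n_frames, n_molecules, 3) or (n_frames, 3)
    times : optional frame times (ns); defaults to the frame index.
    """
    u = np.asarray(orientations, dtype=float)
    if u.ndim == 2:
        u = u[:, None, :]
    if u.ndim != 3 or u.shape[2] != 3:
        raise ParameterError("orientations must have shape (n_frames, n_mol, 3)")
    n, n_mol, _ = u.shape
    if n < 2:
        raise ParameterError("need at least 2 frames")
    norms = np.linalg.norm(u, axis=2)
    if np.any(norms < 1e-12):
        raise GeometryError("zero-length axis vector encountered")
    u = u / norms[:, :, None]

    n_lags = max(2, int(round(n * max_lag_fraction)) + 1)
    n_lags = min(n_lags, n)
    if times is None:
        t = np.arange(n_lags, dtype=float)
    else:
        times = np.asarray(times, dtype=float)
        t = times[:n_lags] - times[0]

    if origin_stride == 1:
        # (u.v)^2 = sum_ab (u_a u_b)(v_a v_b): correlate the 6 unique
        # quadratic products with multiplicities.
        pairs = [(0, 0, 1.0), (1, 1, 1.0), (2, 2, 1.0),
                 (0, 1, 2.0), (0, 2, 2.0), (1, 2, 2.0)]
        acc = np.zeros((n_lags, n_mol))
        for a, b, w in pairs:
            y = u[:, :, a] * u[:, :, b]
            acc += w * _raw_autocorr_fft(y)[:n_lags]
        counts = (n - np.arange(n_lags, dtype=float))[:, None]
        per_mol = 1.5 * acc / counts - 0.5
        n_origins = counts[:, 0].astype(int)
    else:
        per_mol = np.empty((n_lags, n_mol))
        n_origins = np.empty(n_lags, dtype=int)
        for lag in range(n_lags):
            orig = np.arange(0, n - lag, origin_stride)
            dots = np.einsum("omd,omd->om", u[orig], u[orig + lag])
            per_mol[lag] = np.mean(1.5 * dots**2 - 0.5, axis=0)
            n_origins[lag] = len(orig)

    return ACFCurve(
        t=t, c=per_mol.mean(axis=1), per_molecule=per_mol, n_origins=n_origins
    )


def compute_rotational_acf(
    traj: Trajectory,
    species: str,
    atom_a: str,
    atom_b: str,
    max_lag_fraction: float = 0.5,
    origin_stride: int = 1,
) -> ACFCurve:
    """P2 ACF of the axis defined per molecule by atoms ``atom_a -> atom_b``
    (e.g. the fluorophore long axis between two chain carbons)."""
    idx_a = traj.require(species=species, name=atom_a,
                         err=f"no atoms {species}/{atom_a}")
    idx_b = traj.require(species=species, name=atom_b,
                         err=f"no atoms {species}/{atom_b}")
    mols_a = traj.molecule_atom_indices(idx_a)
    mols_b = traj.molecule_atom_indices(idx_b)
    common = sorted(set(mols_a) & set(mols_b))
    if not common:
        raise AnalysisError("axis atoms never co-occur in a molecule")
    ia = np.array([mols_a[m][0] for m in common])
    ib = np.array([mols_b[m][0] for m in common])
    vec = traj.positions[:, ib, :] - traj.positions[:, ia, :]
    return p2_acf(vec, times=traj.time, max_lag_fraction=max_lag_fraction,
                  origin_stride=origin_stride)


# ======================================================================
# multiexponential fitting
# ======================================================================

def _fit_fixed_order(t, c, n_exp):
    """Best bounded least-squares fit with ``n_exp`` exponentials, over a
    deterministic multistart set of characteristic-time initializations."""
    span = float(t[-1] - t[0]) if t[-1] > t[0] else 1.0
    tiny = max(span * 1e-4, float(np.min(np.diff(np.unique(t)))) * 0.1)
    grid = np.geomspace(tiny, 2.0 * span, 8)
    start_idx = {
        1: [(i,) for i in range(8)],
        2: [(0, 3), (0, 5), (0, 7), (1, 4), (2, 5), (2, 7), (3, 6), (4, 7)],
        3: [(0, 3, 6), (0, 4, 7), (1, 4, 7), (0, 2, 5),
            (2, 4, 6), (1, 3, 5), (0, 5, 7), (3, 5, 7)],
    }[n_exp]

    a_tot = max(float(c[0] - c[-1]), 1e-3)
    a_inf0 = float(np.clip(c[-1], 0.0, 1.0))
    lb = np.concatenate([np.zeros(n_exp), np.full(n_exp, 1e-9), [0.0]])
    ub = np.concatenate([np.full(2 * n_exp, np.inf), [1.0]])

    def resid(x):
        return acf_model(t, x[:n_exp], x[n_exp:2 * n_exp], x[-1]) - c

    best = None
    for idx in start_idx:
        x0 = np.concatenate(
            [np.full(n_exp, a_tot / n_exp), grid[list(idx)], [a_inf0]]
        )
        try:
            res = least_squares(
                resid, x0, bounds=(lb, ub), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
            )
        except Exception:
            continue
        ssr = float(np.sum(res.fun**2))
        if best is None or ssr < best[0]:
            best = (ssr, res.x)
    if best is None:
        raise FitError(f"all multistart fits failed for n_exp={n_exp}")
    return best


def fit_acf(
    curve: ACFCurve, n_exp_max: int = 3, improvement_threshold: float = 0.01
) -> ACFFitParams:
    """Fit C(t) = sum a_i exp(-t/Phi_i) + a_inf by bounded nonlinear least
    squares (a_i >= 0, Phi_i > 0, 0 <= a_inf <= 1; no sum-to-one
    constraint).

    The model order is the smallest n for which adding one more
    exponential improves the SSR by less than ``improvement_threshold``
    (relative). Initialization is a fixed multistart set, so the result is
    deterministic.
    """
    t = np.asarray(curve.t, dtype=float)
    c = np.asarray(curve.c, dtype=float)
    if len(t) < 10:
        raise ParameterError("need at least 10 lag points to fit")

    fits = {}
    chosen = 1
    fits[1] = _fit_fixed_order(t, c, 1)
    for n in range(2, n_exp_max + 1):
        prev_ssr = fits[chosen][0]
        if prev_ssr <= 0:
            break
        fits[n] = _fit_fixed_order(t, c, n)
        if fits[n][0] < (1.0 - improvement_threshold) * prev_ssr:
            chosen = n
        else:
            break

    ssr, x = fits[chosen]
    n = chosen
    return ACFFitParams(
        amplitudes=x[:n], times=x[n:2 * n], a_inf=float(x[-1]),
        n_exp=n, ssr=ssr,
    )


def anisotropy_estimate(fit: ACFFitParams, r0: float = 0.4) -> AnisotropyEstimate:
    """Limiting anisotropy r_inf = r0 * a_inf (r0 defaults to the maximal
    theoretical value 2/5)."""
    return AnisotropyEstimate(r0=r0, r_inf=r0 * fit.a_inf)


def mean_correlation_time(fit: ACFFitParams) -> float:
    """<Phi> = sum_i a_i Phi_i — the analytic time integral of the decaying
    part of the fitted model."""
    return float(np.sum(fit.amplitudes * fit.times))


# ======================================================================
# MSD and lateral diffusion
# ======================================================================

def _msd_fft(r: np.ndarray) -> np.ndarray:
    """All-origin MSD for positions r of shape (n, n_mol, d), returned as
    (n, n_mol). Uses the FFT decomposition MSD(l) = S1(l) - 2 S2(l)."""
    n = r.shape[0]
    d_sq = np.sum(r**2, axis=2)  # (n, n_mol)
    s2 = np.zeros_like(d_sq)
    for k in range(r.shape[2]):
        s2 += _raw_autocorr_fft(r[:, :, k])
    counts = (n - np.arange(n, dtype=float))[:, None]
    s2 /= counts

    q = 2.0 * d_sq.sum(axis=0)
    s1 = np.empty_like(d_sq)
    for lag in range(n):
        if lag > 0:
            q = q - d_sq[lag - 1] - d_sq[n - lag]
        s1[lag] = q / (n - lag)
    return s1 - 2.0 * s2


def msd_from_positions(
    positions: np.ndarray,
    times: np.ndarray | None = None,
    remove_com: bool = False,
    max_lag_fraction: float = 0.5,
    label: str = "",
) -> MSDCurve:
    """Molecule- and origin-averaged 2-D MSD of ``positions`` of shape
    (n_frames, n_molecules, 2). With ``remove_com`` the per-frame mean
    position over molecules (the common/leaflet COM) is subtracted first.
    """
    r = np.asarray(positions, dtype=float)
    if r.ndim != 3 or r.shape[2] != 2:
        raise ParameterError("positions must have shape (n_frames, n_mol, 2)")
    n = r.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 frames")
    if remove_com:
        r = r - r.mean(axis=1, keepdims=True)
    msd = _msd_fft(r).mean(axis=1)
    n_lags = max(2, min(n, int(round(n * max_lag_fraction)) + 1))
    if times is None:
        t = np.arange(n_lags, dtype=float)
    else:
        times = np.asarray(times, dtype=float)
        t = times[:n_lags] - times[0]
    return MSDCurve(t=t, msd=msd[:n_lags], label=label,
                    leaflet_com_removed=remove_com)


def compute_msd(
    traj: Trajectory,
    species: str,
    leaflet_com_removal: bool = True,
    max_lag_fraction: float = 0.5,
) -> MSDCurve:
    """In-plane MSD of molecular COMs of one species; when enabled, each
    frame's leaflet COM (x, y) is subtracted from molecules of that
    leaflet before differencing."""
    idx = traj.require(species=species, err=f"no atoms of species {species!r}")
    mols = traj.molecule_atom_indices(idx)
    plane = [ax for ax in range(3) if ax != traj.normal_axis]

    leaflet_of = {}
    for m, ai in mols.items():
        labels = set(traj.topology.leaflet[ai])
        if len(labels) != 1:
            raise AnalysisError(f"molecule {m} spans both leaflets")
        leaflet_of[m] = labels.pop()

    com_xy = np.stack(
        [traj.molecule_com(ai)[:, plane] for ai in mols.values()], axis=1
    )  # (n_frames, n_mol, 2)

    if leaflet_com_removal:
        leaf_com = {}
        for leaf in set(leaflet_of.values()):
            li = np.flatnonzero(
                np.array([l == leaf for l in traj.topology.leaflet])
            )
            leaf_com[leaf] = traj.molecule_com(li)[:, plane]
        for j, m in enumerate(mols):
            com_xy[:, j, :] -= leaf_com[leaflet_of[m]]

    curve = msd_from_positions(
        com_xy, times=traj.time, remove_com=False,
        max_lag_fraction=max_lag_fraction, label=species,
    )
    curve.leaflet_com_removed = leaflet_com_removal
    return curve


def estimate_dlat(
    msd: MSDCurve, fit_window_fractions: tuple[float, float] = (0.1, 0.5)
) -> DiffusionEstimate:
    """Lateral diffusion coefficient from the Einstein relation: least-
    squares slope of MSD(t) over the fit window, divided by 4 and
    converted nm^2/ns -> cm^2/s."""
    f0, f1 = fit_window_fractions
    if not (0.0 <= f0 < f1 <= 1.0):
        raise ParameterError("fit window fractions must satisfy 0 <= f0 < f1 <= 1")
    t_max = msd.t[-1]
    sel = (msd.t >= f0 * t_max) & (msd.t <= f1 * t_max)
    if np.count_nonzero(sel) < 4:
        raise FitError("fewer than 4 points in the fit window")
    tt, yy = msd.t[sel], msd.msd[sel]
    slope, intercept = np.polyfit(tt, yy, 1)
    pred = slope * tt + intercept
    sst = float(np.sum((yy - yy.mean()) ** 2))
    ssr = float(np.sum((yy - pred) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    d_lat = max(slope / 4.0, 0.0) * NM2_PER_NS_TO_CM2_PER_S
    return DiffusionEstimate(
        d_lat=d_lat, fit_window=(float(tt[0]), float(tt[-1])), r_squared=r2
    )
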