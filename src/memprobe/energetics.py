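"""Umbrella-sampling free-energy post-processing.

1-D WHAM reconstruction of the potential of mean force from harmonic
umbrella windows, first-half/second-half convergence diagnostics, barrier
decomposition (insertion / desorption / translocation on the
center-to-water branch) and partition-coefficient estimation
Kp = exp(-dG(w->l) / RT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import rt
from .exceptions import (
    AnalysisError,
    ConvergenceError,
    CoverageError,
    ParameterError,
)

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "BarrierSet",
    "PartitionEstimate",
    "wham",
    "pmf_convergence",
    "extract_barriers",
    "partition_coefficient",
]

MIN_SAMPLES_PER_WINDOW = 100


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias center z0 (nm), force constant k
    (kJ mol^-1 nm^-2), reaction-coordinate samples (nm), temperature (K)."""

    center: float
    k: float
    samples: np.ndarray
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ParameterError("force constant must be > 0")
        if self.temperature <= 0:
            raise ParameterError("temperature must be > 0")
        self.samples = np.asarray(self.samples, dtype=float).ravel()


@dataclass
class PMFProfile:
    """Reconstructed G(z) (kJ/mol) on a grid of bin centers (nm),
    referenced so that the declared water plateau averages to zero."""

    z: np.ndarray
    g: np.ndarray
    water_region: tuple[float, float] | None = None
    uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.g = np.asarray(self.g, dtype=float)

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return np.interp(z, self.z, self.g)


@dataclass
class BarrierSet:
    """Free-energy barriers (kJ/mol) on the analysis branch and the
    location of the interfacial minimum (nm)."""

    insertion: float
    desorption: float
    translocation: float
    z_min: float

    def __post_init__(self) -> None:
        if self.insertion < 0:
            raise ParameterError("insertion barrier must be >= 0")


@dataclass
class PartitionEstimate:
    """Water->lipid transfer free energy and partition coefficient."""

    dg_transfer: float  # kJ/mol, negative when partition is favorable
    kp: float
    temperature: float
    rt: float

    def __post_init__(self) -> None:
        expected = math.exp(-self.dg_transfer / self.rt)
        if not math.isclose(self.kp, expected, rel_tol=1e-9):
            raise ParameterError("Kp inconsistent with exp(-dG/RT)")


# ======================================================================
# WHAM
# ======================================================================

def _check_overlap(windows, min_fraction: float = 0.05) -> None:
    """Adjacent windows (sorted by center) must share sample support."""
    order = np.argsort([w.center for w in windows])
    for i, j in zip(order[:-1], order[1:]):
        a, b = windows[i].samples, windows[j].samples
        lo = max(a.min(), b.min())
        hi = min(a.max(), b.max())
        if hi <= lo:
            raise CoverageError(
                f"windows at {windows[i].center} and {windows[j].center} nm "
                "do not overlap"
            )
        fa = np.mean((a >= lo) & (a <= hi))
        fb = np.mean((b >= lo) & (b <= hi))
        if min(fa, fb) < min_fraction:
            raise CoverageError(
                f"windows at {windows[i].center} and {windows[j].center} nm "
                f"share < {min_fraction:.0%} of their samples' support"
            )


def wham(
    windows: list[UmbrellaWindow],
    bin_width: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 100000,
    water_region: tuple[float, float] | None = None,
    _min_samples: int = MIN_SAMPLES_PER_WINDOW,
) -> PMFProfile:
    """Self-consistent 1-D WHAM over harmonic umbrella windows.

    The window free energies are obtained by minimizing the convex WHAM
    likelihood objective (L-BFGS with analytic gradient), then polished by
    direct iteration until the largest change is below ``tol`` (kJ/mol).
    G(z) is shifted so the mean over ``water_region`` (or, if none is
    declared, the profile minimum) is zero.
    """
    if not windows:
        raise ParameterError("need at least one window")
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ParameterError("all windows must share one temperature")
    for w in windows:
        if len(w.samples) < _min_samples:
            raise ParameterError(
                f"window at {w.center} nm has fewer than {_min_samples} samples"
            )
    if len(windows) > 1:
        _check_overlap(windows)

    temperature = windows[0].temperature
    beta = 1.0 / rt(temperature)
    zlo = min(w.samples.min() for w in windows)
    zhi = max(w.samples.max() for w in windows)
    n_bins = max(1, math.ceil((zhi - zlo) / bin_width))
    edges = zlo + np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[1:] + edges[:-1])

    n_win = len(windows)
    hist = np.zeros((n_win, n_bins))
    n_i = np.zeros(n_win)
    for i, w in enumerate(windows):
        h, _ = np.histogram(w.samples, bins=edges)
        hist[i] = h
        n_i[i] = h.sum()
    n_b = hist.sum(axis=0)

    # Bin-averaged Boltzmann factor of the harmonic bias. Using the point
    # value at the bin center is badly biased when the window width
    # sqrt(RT/k) is comparable to the bin width (stiff springs), so
    # integrate exp(-beta k/2 (z-z0)^2) analytically over each bin.
    from scipy.special import erf

    c_ib = np.empty((n_win, n_bins))
    for i, w in enumerate(windows):
        s = math.sqrt(0.5 * beta * w.k)
        lo = s * (edges[:-1] - w.center)
        hi = s * (edges[1:] - w.center)
        c_ib[i] = (math.sqrt(math.pi) / (2.0 * s)) * (erf(hi) - erf(lo)) / bin_width

    # Convex MLE objective over dimensionless window free energies g_i
    # (= -ln z_i); invariant under a common shift.
    from scipy.optimize import minimize
    from scipy.special import logsumexp

    with np.errstate(divide="ignore"):
        log_c = np.log(c_ib)
    log_n = np.log(n_i)
    sampled = n_b > 0

    def objective(x):
        # pin g_0 = 0 to remove the common-shift flat direction
        g = np.concatenate([[0.0], x])
        a = log_n[:, None] + g[:, None] + log_c  # (n_win, n_bins)
        lse = logsumexp(a, axis=0)
        val = -(n_i * g).sum() + (n_b[sampled] * lse[sampled]).sum()
        w = np.exp(a[:, sampled] - lse[sampled])
        grad = -n_i + (n_b[sampled][None, :] * w).sum(axis=1)
        return val, grad[1:]

    g_win = np.zeros(n_win)
    if n_win > 1:
        res = minimize(
            objective, np.zeros(n_win - 1), jac=True, method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-10},
        )
        g_win = np.concatenate([[0.0], res.x])

    # polish by direct iteration and enforce the stated tolerance
    f = -g_win / beta
    f -= f[0]
    delta = np.inf
    for _ in range(max_iter):
        weight = np.exp(beta * f)[:, None] * c_ib  # (n_win, n_bins)
        denom = (n_i[:, None] * weight).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_b = np.where(denom > 0, n_b / denom, 0.0)
        z_i = (c_ib * p_b[None, :]).sum(axis=1)
        f_new = -np.log(z_i) / beta
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {delta:.3e} kJ/mol)"
        )
    weight = np.exp(beta * f)[:, None] * c_ib
    denom = (n_i[:, None] * weight).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_b = np.where(denom > 0, n_b / denom, 0.0)

    mask = p_b > 0
    g = np.full(n_bins, np.nan)
    g[mask] = -np.log(p_b[mask]) / beta
    z, g = centers[mask], g[mask]
    if water_region is not None:
        sel = (z >= water_region[0]) & (z <= water_region[1])
        if not np.any(sel):
            raise ParameterError("water region contains no sampled bins")
        g = g - g[sel].mean()
    else:
        g = g - g.min()
    return PMFProfile(z=z, g=g, water_region=water_region)


def pmf_convergence(
    windows: list[UmbrellaWindow],
    split: float = 0.5,
    bin_width: float = 0.05,
    water_region: tuple[float, float] | None = None,
    **wham_kwargs,
):
    """Reconstruct PMFs from the first vs second part of every window's
    samples and report their discrepancy.

    Returns (pmf_first, pmf_second, max_discrepancy, rms_discrepancy); the
    discrepancy is evaluated on the overlap of the two grids.
    """
    if not (0.0 < split < 1.0):
        raise ParameterError("split must lie in (0, 1)")
    firsts, seconds = [], []
    for w in windows:
        cut = int(round(len(w.samples) * split))
        if cut < 2 or len(w.samples) - cut < 2:
            raise ParameterError("too few samples to split a window")
        firsts.append(
            UmbrellaWindow(w.center, w.k, w.samples[:cut], w.temperature)
        )
        seconds.append(
            UmbrellaWindow(w.center, w.k, w.samples[cut:], w.temperature)
        )
    min_samples = min(min(len(w.samples) for w in firsts),
                      min(len(w.samples) for w in seconds))
    kw = dict(wham_kwargs)
    kw.setdefault("_min_samples", min(MIN_SAMPLES_PER_WINDOW, min_samples))
    pmf1 = wham(firsts, bin_width=bin_width, water_region=water_region, **kw)
    pmf2 = wham(seconds, bin_width=bin_width, water_region=water_region, **kw)
    zlo = max(pmf1.z.min(), pmf2.z.min())
    zhi = min(pmf1.z.max(), pmf2.z.max())
    zz = np.linspace(zlo, zhi, 200)
    diff = pmf1(zz) - pmf2(zz)
    return pmf1, pmf2, float(np.max(np.abs(diff))), float(
        np.sqrt(np.mean(diff**2))
    )


# ======================================================================
# barriers and partition
# ======================================================================

def extract_barriers(
    pmf: PMFProfile,
    z_center: float = 0.0,
    water_region: tuple[float, float] | None = None,
) -> BarrierSet:
    """Decompose one branch of a PMF (center -> water) into insertion,
    desorption and translocation barriers.

    * z_min: location of the branch minimum.
    * desorption = G_water - G_min.
    * insertion = max(0, max G between the minimum and the water edge,
      minus G_water).
    * translocation = max G on [z_center, z_min] - G_min.
    """
    if water_region is None:
        water_region = pmf.water_region
    if water_region is None:
        raise ParameterError("a water region must be declared")
    branch = pmf.z >= z_center
    z = pmf.z[branch]
    g = pmf.g[branch]
    if z.size < 3:
        raise AnalysisError("PMF does not span the center-to-water branch")
    wsel = (z >= water_region[0]) & (z <= water_region[1])
    if not np.any(wsel):
        raise ParameterError("water region not covered by the PMF branch")
    g_water = float(g[wsel].mean())
    water_edge = float(z[wsel].min())

    interior = z <= water_edge
    i_min = int(np.argmin(g[interior]))
    z_min = float(z[interior][i_min])
    g_min = float(g[interior][i_min])
    if g_min >= g_water - 1e-6:
        raise AnalysisError("no interior free-energy minimum found")

    between = (z >= z_min) & (z <= water_edge)
    insertion = max(0.0, float(g[between].max()) - g_water)
    desorption = g_water - g_min
    core = (z >= z_center) & (z <= z_min)
    translocation = float(g[core].max()) - g_min
    return BarrierSet(
        insertion=insertion,
        desorption=desorption,
        translocation=translocation,
        z_min=z_min,
    )


def partition_coefficient(
    barriers: BarrierSet, temperature: float = 298.15
) -> PartitionEstimate:
    """Kp = exp(-dG(w->l)/RT) with dG(w->l) = -(desorption - insertion),
    so that favorable transfer into the membrane gives Kp > 1."""
    if temperature <= 0:
        raise ParameterError("temperature must be > 0")
    rtv = rt(temperature)
    dg = -(barriers.desorption - barriers.insertion)
    return PartitionEstimate(
        dg_transfer=dg, kp=math.exp(-dg / rtv), temperature=temperature, rt=rtv
    )
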