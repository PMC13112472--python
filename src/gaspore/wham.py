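"""Umbrella-sampling bookkeeping and WHAM solution of 1D PMFs.

Windows carry a harmonic bias ½k(z − z0)² on the pore-axis coordinate.
The weighted histogram analysis method combines the biased window
histograms into one unbiased probability profile P(z) and per-window shift
constants F_j by self-consistent iteration:

    P(z_b) = Σ_j n_j(z_b) / Σ_j N_j e^{(F_j − w_j(z_b))/RT}
    F_j    = −RT ln Σ_b P(z_b) e^{−w_j(z_b)/RT}

iterated until max_j |ΔF_j| < tol; the PMF is G(z) = −RT ln P(z), defined
up to a constant until referenced to bulk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import RT, T_DEFAULT
from .grids import Profile1D

logger = logging.getLogger(__name__)

__all__ = [
    "UmbrellaWindow",
    "WindowSet",
    "PMF",
    "plan_windows",
    "discard_equilibration",
    "wham",
    "reference_to_bulk",
]


@dataclass
class UmbrellaWindow:
    """One umbrella window: center ``z0`` (Å), force constant ``k``
    (kcal/mol/Å²), and optionally its sampled coordinate series."""

    z0: float
    k: float
    samples: np.ndarray | None = None
    times_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"window at z0={self.z0}: force constant must be positive")
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=float)
        if self.times_ns is not None:
            self.times_ns = np.asarray(self.times_ns, dtype=float)

    def bias(self, z: np.ndarray) -> np.ndarray:
        return 0.5 * self.k * (np.asarray(z, dtype=float) - self.z0) ** 2


@dataclass
class WindowSet:
    """An ordered ladder of umbrella windows covering [z_min, z_max]."""

    windows: list[UmbrellaWindow]
    z_min: float
    z_max: float
    spacing: float

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.z0 for w in self.windows])


def plan_windows(z_min: float, z_max: float, spacing: float, k: float) -> WindowSet:
    """Plan a ladder of windows at z_min + i·spacing, both endpoints included.

    The span must be an integral number of spacings (to 1e−9 relative);
    otherwise this raises rather than silently truncating.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if z_max <= z_min:
        raise ValueError("z_max must exceed z_min")
    span = z_max - z_min
    n_float = span / spacing
    n = round(n_float)
    if abs(n_float - n) > 1e-9 * max(1.0, abs(n_float)):
        raise ValueError(
            f"span {span} is not an integral number of spacings {spacing} "
            f"({n_float} intervals)"
        )
    windows = [UmbrellaWindow(z0=z_min + i * spacing, k=k) for i in range(int(n) + 1)]
    return WindowSet(windows=windows, z_min=z_min, z_max=z_max, spacing=spacing)


def discard_equilibration(
    window: UmbrellaWindow, fraction: float | None = None, keep_last_ns: float | None = None
) -> UmbrellaWindow:
    """Drop the leading equilibration part of a window's series.

    Either ``fraction`` of samples is discarded from the front, or (with
    ``keep_last_ns`` and per-sample times) only the stated trailing time
    span is retained.  The default discards the first 1/6 of the series —
    the convention of analyzing the last 2.5 ns of 3-ns windows.
    """
    if window.samples is None:
        raise ValueError("window has no samples")
    n = window.samples.shape[0]
    if keep_last_ns is not None:
        if window.times_ns is None:
            raise ValueError("keep_last_ns requires per-sample times")
        t_end = window.times_ns[-1]
        mask = window.times_ns > t_end - keep_last_ns
        if not mask.any():
            raise ValueError("discard removes every sample")
        return UmbrellaWindow(
            z0=window.z0,
            k=window.k,
            samples=window.samples[mask].copy(),
            times_ns=window.times_ns[mask].copy(),
        )
    frac = 1.0 - 2.5 / 3.0 if fraction is None else fraction
    if not 0.0 <= frac < 1.0:
        raise ValueError("discard fraction must be in [0, 1)")
    start = int(np.floor(frac * n + 1e-9))
    if start >= n:
        raise ValueError("discard removes every sample")
    return UmbrellaWindow(
        z0=window.z0,
        k=window.k,
        samples=window.samples[start:].copy(),
        times_ns=None if window.times_ns is None else window.times_ns[start:].copy(),
    )


@dataclass
class PMF:
    """WHAM result: bin centers, G(z) in kcal/mol, per-window shifts F_j,
    and convergence metadata."""

    z: np.ndarray
    G: np.ndarray
    F: np.ndarray
    bin_width: float
    n_iterations: int
    residual: float
    empty_bins: np.ndarray  # mask over z: bins with zero total counts
    counts: np.ndarray  # total counts per bin

    def profile(self) -> Profile1D:
        return Profile1D(z=self.z.copy(), values=self.G.copy(), flags=self.empty_bins.copy(), label="WHAM PMF")

    def shifted(self, offset: float) -> "PMF":
        return PMF(
            z=self.z.copy(),
            G=self.G + offset,
            F=self.F.copy(),
            bin_width=self.bin_width,
            n_iterations=self.n_iterations,
            residual=self.residual,
            empty_bins=self.empty_bins.copy(),
            counts=self.counts.copy(),
        )


class WHAMConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"WHAM did not converge within {max_iter} iterations (residual {residual:.3e})"
        )
        self.residual = residual
        self.max_iter = max_iter


def wham(
    windows: WindowSet,
    bin_width: float = 0.25,
    temperature: float = T_DEFAULT,
    tol: float = 1e-7,
    max_iter: int = 100000,
    z_range: tuple[float, float] | None = None,
) -> PMF:
    """Solve the WHAM equations for a sampled window set.

    Histogram bins are half-open [left, right) of ``bin_width`` (default
    0.25 Å) spanning the sampled range (or ``z_range``).  Empty bins inside
    the sampled range are flagged and excluded (G = +inf there).  The
    solution is deterministic given the inputs; non-convergence raises
    :class:`WHAMConvergenceError`.  Adjacent windows whose histograms share
    fewer than 5% of counts trigger an overlap warning.
    """
    ws = [w for w in windows.windows if w.samples is not None and w.samples.size > 0]
    if not ws:
        raise ValueError("no windows with samples")
    rt = RT(temperature)
    all_samples = np.concatenate([w.samples for w in ws])
    if z_range is None:
        lo = np.floor(all_samples.min() / bin_width) * bin_width
        hi = np.ceil(all_samples.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = z_range
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])

    n_w = len(ws)
    n_jb = np.zeros((n_w, n_bins))
    for j, w in enumerate(ws):
        n_jb[j], _ = np.histogram(w.samples, bins=edges)
    _warn_poor_overlap(ws, n_jb)

    N_j = n_jb.sum(axis=1)
    n_b = n_jb.sum(axis=0)
    w_jb = np.stack([w.bias(centers) for w in ws])  # (n_w, n_bins)

    # log-space iteration: biases far from a window's samples can exceed
    # hundreds of kcal/mol, so linear-space Boltzmann factors under/overflow
    from scipy.special import logsumexp as _lse

    log_N = np.log(N_j)
    neg_w = -w_jb / rt  # (n_w, n_bins)
    occupied = n_b > 0
    log_n_b = np.where(occupied, np.log(np.where(occupied, n_b, 1.0)), -np.inf)
    def sc_update(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # log denominator_b = lse_j [ ln N_j + (F_j/RT) + (-w_jb/RT) ]
        log_denom = _lse(log_N[:, None] + F[:, None] / rt + neg_w, axis=0)
        log_P = log_n_b - log_denom
        log_P -= _lse(log_P[occupied])  # normalize over occupied bins
        F_new = -rt * _lse(log_P[None, occupied] + neg_w[:, occupied], axis=1)
        return F_new - F_new[0], log_P

    # The self-consistent WHAM equations are the stationarity conditions of a
    # convex likelihood in g_j = F_j/RT; minimizing it directly converges in
    # orders of magnitude fewer sweeps than plain iteration.  The stopping
    # criterion below is still max_j |ΔF_j| < tol on the fixed-point update.
    nw_occ = neg_w[:, occupied]
    n_b_occ = n_b[occupied]
    log_n_occ = log_n_b[occupied]
    N_tot = N_j.sum()

    def objective(g: np.ndarray):
        log_D = _lse(log_N[:, None] + g[:, None] + nw_occ, axis=0)
        phi = -float(N_j @ g) + float(n_b_occ @ log_D)
        t_j = _lse(log_n_occ[None, :] + nw_occ - log_D[None, :], axis=1)
        grad = N_j * (np.exp(g + t_j) - 1.0)
        return phi / N_tot, grad / N_tot

    from scipy.optimize import minimize as _minimize

    res = _minimize(
        objective,
        np.zeros(n_w),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
    )
    F = rt * (res.x - res.x[0])

    residual = np.inf
    converged = False
    for it in range(1, max_iter + 1):
        F_new, log_P = sc_update(F)
        residual = float(np.max(np.abs(F_new - F)))
        F = F_new
        if residual < tol:
            converged = True
            break
    if not converged:
        raise WHAMConvergenceError(residual, max_iter)

    empty = ~occupied
    G = np.where(occupied, -rt * log_P, np.inf)
    # fix the gauge: minimum of G over sampled bins at 0
    finite = np.isfinite(G)
    if finite.any():
        G = G - G[finite].min()
    return PMF(
        z=centers,
        G=G,
        F=F - F[0],
        bin_width=bin_width,
        n_iterations=it,
        residual=residual,
        empty_bins=empty,
        counts=n_b,
    )


def _warn_poor_overlap(ws, n_jb: np.ndarray) -> None:
    order = np.argsort([w.z0 for w in ws])
    for a, b in zip(order[:-1], order[1:]):
        ha, hb = n_jb[a], n_jb[b]
        shared = np.minimum(ha, hb).sum()
        smaller = min(ha.sum(), hb.sum())
        if smaller > 0 and shared < 0.05 * smaller:
            logger.warning(
                "windows at z0=%.2f and z0=%.2f share <5%% of counts; WHAM may be ill-conditioned",
                ws[a].z0,
                ws[b].z0,
            )


def reference_to_bulk(
    pmf: PMF, bulk_zrange: tuple[float, float], temperature: float = T_DEFAULT
) -> PMF:
    """Shift the PMF so its Boltzmann average over the bulk z-range is zero,
    turning insertion free energies into bulk-referenced partitioning ones."""
    lo, hi = bulk_zrange
    mask = (pmf.z >= lo) & (pmf.z <= hi) & np.isfinite(pmf.G)
    if not mask.any():
        raise ValueError(f"no finite PMF bins inside bulk range {bulk_zrange}")
    rt = RT(temperature)
    g = pmf.G[mask]
    gmin = g.min()
    ref = gmin - rt * np.log(np.mean(np.exp(-(g - gmin) / rt)))
    return pmf.shifted(-ref)
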