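"""Global analysis of transient-absorption data.

A sequential kinetic scheme 1 -> 2 -> ... -> n with lifetimes tau_i feeds a
variable-projection global fit: for trial lifetimes (and optionally time
zero and IRF width) the compartment concentration profiles are computed
analytically -- each exponential convolved with a Gaussian instrument
response in closed form -- and the evolution-associated decay spectra
(EADS) follow as the linear least-squares solution; the nonlinear
parameters are then optimized on the projected residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erfc, erfcx

__all__ = [
    "TAMatrix",
    "KineticScheme",
    "GlobalFitResult",
    "concentration_profiles",
    "simulate_ta",
    "fit_global",
    "compute_eads",
]


@dataclass
class TAMatrix:
    """Delay (ps) x wavelength (nm) difference-absorbance matrix in mOD."""

    delays: np.ndarray
    wavelengths: np.ndarray
    da: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.da = np.asarray(self.da, dtype=float)
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.da.shape != (len(self.delays), len(self.wavelengths)):
            raise ValueError("dA must be (n_delays, n_wavelengths)")
        if not np.all(np.isfinite(self.da)):
            raise ValueError("dA contains non-finite values")


@dataclass
class KineticScheme:
    """Sequential compartments with lifetimes in ps; the last lifetime may
    be infinite (non-decaying within the measurement window)."""

    lifetimes: Sequence[float]
    irf_fwhm: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        taus = np.asarray(self.lifetimes, dtype=float)
        if len(taus) < 1:
            raise ValueError("need at least one compartment")
        if np.any(taus <= 0):
            raise ValueError("lifetimes must be positive (or infinite)")
        if np.any(np.isinf(taus[:-1])):
            raise ValueError("only the terminal compartment may be non-decaying")
        if self.irf_fwhm < 0:
            raise ValueError("IRF FWHM must be non-negative")
        self.lifetimes = taus

    @property
    def n(self) -> int:
        return len(self.lifetimes)

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(np.isinf(self.lifetimes), 0.0, 1.0 / self.lifetimes)

    @property
    def irf_sigma(self) -> float:
        return self.irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class GlobalFitResult:
    scheme: KineticScheme
    eads: np.ndarray
    residual_rms: float
    lifetime_stderr: np.ndarray
    wavelengths: np.ndarray
    converged: bool = True
    cost: float = 0.0


def _exp_conv_gauss(t: np.ndarray, k: float, sigma: float) -> np.ndarray:
    """exp(-k t) (for t >= 0) convolved with a unit-area Gaussian of width
    sigma, evaluated stably via the scaled complementary error function."""
    if sigma == 0.0:
        out = np.where(t >= 0, np.exp(-k * np.clip(t, 0, None)), 0.0)
        return out
    arg = (k * sigma - t / sigma) / np.sqrt(2.0)
    # two stable branches: erfcx form where arg >= 0, plain erfc form where
    # the decaying exponential already tames the prefactor
    with np.errstate(over="ignore", invalid="ignore"):
        pos = 0.5 * erfcx(arg) * np.exp(-(t * t) / (2.0 * sigma * sigma))
        neg = 0.5 * np.exp(k * k * sigma * sigma / 2.0 - k * t) * erfc(arg)
    return np.where(arg >= 0, pos, neg)


def concentration_profiles(scheme: KineticScheme, delays: Sequence[float]) -> np.ndarray:
    """Populations of the sequential chain at each delay, shape (n, n_delays).

    Bateman solution of 1 -> 2 -> ... -> n with each exponential term
    analytically convolved with the Gaussian IRF.  With a non-decaying
    terminal compartment the column sums approach 1 after the IRF has
    passed; they never exceed 1.
    """
    t = np.asarray(delays, dtype=float) - scheme.t0
    k = scheme.rates
    n = scheme.n
    # distinct rates are required by the partial-fraction (Bateman) form
    for i in range(n):
        for j in range(i + 1, n):
            if abs(k[i] - k[j]) <= 1e-12 * max(k[i], k[j], 1e-30):
                raise ValueError(
                    f"degenerate lifetimes (compartments {i + 1} and {j + 1}); "
                    "sequential populations require distinct lifetimes"
                )
    sigma = scheme.irf_sigma
    basis = np.array([_exp_conv_gauss(t, ki, sigma) for ki in k])  # (n, n_t)
    profiles = np.zeros((n, len(t)))
    for j in range(n):
        prefactor = np.prod(k[:j]) if j > 0 else 1.0
        for i in range(j + 1):
            denom = np.prod([k[l] - k[i] for l in range(j + 1) if l != i])
            coeff = prefactor / denom if j > 0 else 1.0
            profiles[j] += coeff * basis[i]
    return np.clip(profiles, a_min=None, a_max=None)


def simulate_ta(
    scheme: KineticScheme,
    species_spectra: np.ndarray,
    delays: Sequence[float],
    wavelengths: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TAMatrix:
    """Synthetic TA matrix: dA = profiles^T . spectra + Gaussian noise."""
    spectra = np.asarray(species_spectra, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if spectra.shape != (scheme.n, len(wavelengths)):
        raise ValueError(
            f"species_spectra must be ({scheme.n}, {len(wavelengths)}), got {spectra.shape}"
        )
    profiles = concentration_profiles(scheme, delays)
    da = profiles.T @ spectra
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        da = da + rng.normal(0.0, noise_sd, size=da.shape)
    return TAMatrix(delays=np.asarray(delays, dtype=float), wavelengths=wavelengths, da=da)


def _projected_residual(
    taus: np.ndarray, t0: float, irf_fwhm: float, data: TAMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Residual matrix and EADS for fixed nonlinear parameters."""
    scheme = KineticScheme(lifetimes=taus, irf_fwhm=irf_fwhm, t0=t0)
    profiles = concentration_profiles(scheme, data.delays)  # (n, n_t)
    eads, *_ = np.linalg.lstsq(profiles.T, data.da, rcond=None)  # (n, n_wl)
    resid = data.da - profiles.T @ eads
    return resid, eads


def fit_global(
    data: TAMatrix,
    n: int,
    init_lifetimes: Sequence[float],
    irf_fwhm: float = 0.0,
    t0: float = 0.0,
    fit_irf: bool = False,
    fit_t0: bool = True,
    n_starts: int = 3,
    seed: int = 0,
    max_nfev: int = 400,
) -> GlobalFitResult:
    """Variable-projection global fit of a sequential scheme to a TA matrix.

    Finite initial lifetimes are optimized in log space; an infinite entry
    marks a non-decaying terminal compartment and is held fixed.  Several
    jittered starts (seeded) guard against local minima; the best solution
    by cost is returned.
    """
    init = np.asarray(init_lifetimes, dtype=float)
    if len(init) != n:
        raise ValueError(f"expected {n} initial lifetimes, got {len(init)}")
    if len(np.unique(init[np.isfinite(init)])) != np.sum(np.isfinite(init)):
        raise ValueError("initial lifetimes must be distinct")
    free = np.isfinite(init)
    rng = np.random.default_rng(seed)

    def unpack(x: np.ndarray) -> tuple[np.ndarray, float, float]:
        taus = init.copy()
        taus[free] = np.exp(x[: free.sum()])
        pos = free.sum()
        t0_val = x[pos] if fit_t0 else t0
        pos += int(fit_t0)
        irf_val = np.exp(x[pos]) if fit_irf else irf_fwhm
        return taus, float(t0_val), float(irf_val)

    def residual(x: np.ndarray) -> np.ndarray:
        taus, t0_val, irf_val = unpack(x)
        # nudge apart lifetimes the optimizer drives degenerate
        ftaus = taus[np.isfinite(taus)]
        if len(np.unique(ftaus)) != len(ftaus):
            taus = taus * (1 + 1e-9 * np.arange(len(taus)))
        try:
            resid, _ = _projected_residual(taus, t0_val, irf_val, data)
        except ValueError:
            return np.full(data.da.size, 1e6)
        return resid.ravel()

    x0_base = list(np.log(init[free]))
    if fit_t0:
        x0_base.append(t0)
    if fit_irf:
        x0_base.append(np.log(max(irf_fwhm, 1e-3)))
    x0_base = np.asarray(x0_base)

    best = None
    for start in range(max(n_starts, 1)):
        x0 = x0_base.copy()
        if start > 0:
            x0[: free.sum()] += rng.normal(0.0, 0.2, size=free.sum())
        try:
            sol = least_squares(residual, x0, max_nfev=max_nfev, method="lm")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("global fit failed to produce any solution")

    taus, t0_val, irf_val = unpack(best.x)
    resid, eads = _projected_residual(taus, t0_val, irf_val, data)
    scheme = KineticScheme(lifetimes=taus, irf_fwhm=irf_val, t0=t0_val)
    dof = max(data.da.size - best.x.size - scheme.n * len(data.wavelengths), 1)
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * (2.0 * best.cost / dof)
        log_err = np.sqrt(np.clip(np.diag(cov)[: free.sum()], 0, None))
        stderr = np.full(n, np.nan)
        stderr[free] = taus[free] * log_err  # delta method from log space
    except Exception:
        stderr = np.full(n, np.nan)
    return GlobalFitResult(
        scheme=scheme,
        eads=eads,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        lifetime_stderr=stderr,
        wavelengths=data.wavelengths.copy(),
        converged=bool(best.success),
        cost=float(best.cost),
    )


def compute_eads(fit: GlobalFitResult) -> np.ndarray:
    """Evolution-associated decay spectra of a converged fit (n x n_wl, mOD)."""
    return fit.eads
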