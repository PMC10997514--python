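"""Scaling of observed amplitudes and weighted difference (DED) coefficients.

Light and dark observed amplitudes are put on a common scale with a linear
plus isotropic-B model, k * exp(-B s^2 / 4).  Per-reflection weights

    w = (1 + dF^2/<dF^2> + sigma_dF^2/<sigma_dF^2>)^-1

down-weight reflections with outlier amplitude differences or large
experimental uncertainty; the averages are plain arithmetic means over the
working reflection set.  The weighted difference amplitudes with dark-model
phases are synthesized into difference electron density (DED) maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DifferenceSet, RealSpaceMap, ReflectionSet
from .sf import default_grid, synthesize_map

__all__ = [
    "ScaleResult",
    "scale_to_reference",
    "weight_reflections",
    "difference_coefficients",
    "ded_map",
]


@dataclass
class ScaleResult:
    """Fitted scale k, isotropic scale-B (A^2) and post-scaling residual."""

    k: float
    b: float
    residual: float
    n_common: int


def scale_to_reference(
    target: ReflectionSet, reference: ReflectionSet, min_common: int = 20
) -> tuple[ReflectionSet, ScaleResult]:
    """Scale target amplitudes (and sigmas) onto the reference.

    Fits k, B in F_ref ~= k * exp(-B s^2/4) * F_target by amplitude-weighted
    linear least squares on log amplitudes, then applies the per-reflection
    factor to the target set.
    """
    it, ir = target.common_indices(reference)
    if len(it) < min_common:
        raise ValueError(
            f"only {len(it)} common reflections; need at least {min_common} for scaling"
        )
    ft = target.amplitude[it]
    fr = reference.amplitude[ir]
    ok = (ft > 0) & (fr > 0)
    if ok.sum() < min_common:
        raise ValueError("too few positive common amplitudes for log scaling")
    s2 = (1.0 / target.d_spacings()[it][ok]) ** 2
    y = np.log(fr[ok] / ft[ok])
    # design: y = log k - B s^2/4 ; weights ~ amplitude
    a_mat = np.column_stack([np.ones_like(s2), -s2 / 4.0])
    wts = np.sqrt(fr[ok])
    coef, *_ = np.linalg.lstsq(a_mat * wts[:, None], y * wts, rcond=None)
    k = float(np.exp(coef[0]))
    b = float(coef[1])
    s2_all = (1.0 / target.d_spacings()) ** 2
    factor = k * np.exp(-b * s2_all / 4.0)
    scaled = ReflectionSet(
        cell=target.cell,
        hkl=target.hkl,
        amplitude=target.amplitude * factor,
        sigma=target.sigma * factor,
        phase=target.phase,
        label=target.label + "(scaled)",
    )
    fs = scaled.amplitude[it][ok]
    residual = float(np.sqrt(np.mean(((fr[ok] - fs) / fr[ok]) ** 2)))
    return scaled, ScaleResult(k=k, b=b, residual=residual, n_common=int(len(it)))


def weight_reflections(deltas: Sequence[float], sigmas: Sequence[float]) -> np.ndarray:
    """Per-reflection weights w = (1 + dF^2/<dF^2> + s^2/<s^2>)^-1 in (0, 1].

    A ratio term whose denominator (the mean over the set) is zero is taken
    as zero, so an all-zero set yields weights of exactly 1.
    """
    df = np.asarray(deltas, dtype=float)
    sg = np.asarray(sigmas, dtype=float)
    if df.shape != sg.shape or df.ndim != 1 or len(df) == 0:
        raise ValueError("deltas and sigmas must be equal-length 1-D arrays")
    if np.any(sg < 0):
        raise ValueError("negative sigma")
    mean_df2 = float(np.mean(df**2))
    mean_sg2 = float(np.mean(sg**2))
    term_df = df**2 / mean_df2 if mean_df2 > 0 else np.zeros_like(df)
    term_sg = sg**2 / mean_sg2 if mean_sg2 > 0 else np.zeros_like(sg)
    return 1.0 / (1.0 + term_df + term_sg)


def difference_coefficients(
    light: ReflectionSet,
    dark: ReflectionSet,
    dark_phases: ReflectionSet,
    weighting: str = "q",
    normalize_weights: bool = True,
) -> DifferenceSet:
    """Difference coefficients dF = w (F_light - F_dark) with dark phases.

    ``light`` must already be scaled to ``dark``.  Sigmas propagate in
    quadrature.  Indices present in only some of the three inputs are
    dropped (the count is recorded on the returned object).

    ``weighting="q"`` applies the per-reflection weights of
    :func:`weight_reflections`; with ``normalize_weights`` the applied
    weights are divided by their mean so the weighting suppresses outliers
    without shrinking the overall difference-amplitude scale (the stored
    ``weight`` column keeps the raw w in (0, 1]).  ``weighting="none"``
    keeps the plain amplitude differences; this is the appropriate input
    for extrapolated structure factors, where any systematic shrinkage of
    the differences would bias the extrapolation-factor scale.
    """
    il, idk = light.common_indices(dark)
    if len(il) == 0:
        raise ValueError("light and dark reflection sets share no Miller indices")
    sub_hkl = light.hkl[il]
    phase_map = dark_phases.index_map()
    keep = np.array([tuple(h) in phase_map for h in sub_hkl.tolist()])
    if not keep.any():
        raise ValueError("dark-model phases cover none of the common reflections")
    il, idk = il[keep], idk[keep]
    sub_hkl = sub_hkl[keep]
    iph = np.array([phase_map[tuple(h)] for h in sub_hkl.tolist()])
    if dark_phases.phase is None:
        raise ValueError("dark_phases set carries no phases")
    if weighting not in ("q", "none"):
        raise ValueError("weighting must be 'q' or 'none'")
    raw_delta = light.amplitude[il] - dark.amplitude[idk]
    sigma = np.sqrt(light.sigma[il] ** 2 + dark.sigma[idk] ** 2)
    w = weight_reflections(raw_delta, sigma)
    if weighting == "none":
        applied = np.ones_like(raw_delta)
    else:
        applied = w / w.mean() if normalize_weights else w
    n_total = len(light) + len(dark)
    diff = DifferenceSet(
        cell=light.cell,
        hkl=sub_hkl,
        delta=applied * raw_delta,
        sigma=sigma,
        weight=w,
        phase=dark_phases.phase[iph],
    )
    diff.n_dropped = n_total - 2 * len(sub_hkl)  # type: ignore[attr-defined]
    return diff


def ded_map(
    diff: DifferenceSet,
    d_low: float = 16.0,
    d_high: float = 1.9,
    grid: Sequence[int] | None = None,
) -> RealSpaceMap:
    """Difference electron density map from weighted coefficients.

    Only reflections with d_high <= d <= d_low enter the synthesis; the map
    is mean-zero because F(000) is never part of a difference set.
    """
    d = diff.d_spacings()
    keep = (d >= d_high) & (d <= d_low)
    if not keep.any():
        raise ValueError(
            f"resolution cutoffs [{d_high}, {d_low}] A exclude all {len(diff)} reflections"
        )
    sub = diff.select(keep)
    if grid is None:
        grid = default_grid(diff.cell, d_high)
    return synthesize_map(sub, grid=grid)
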