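"""Per-voxel model fitting for multi-b-value DWI.

The mono-exponential model is fitted linearly (ordinary least squares of
ln S on b); the IVIM and stretched-exponential models by bounded
non-linear least squares.  IVIM supports the standard segmented strategy
(slow diffusion from the high-b log-linear segment, then the perfusion
terms) with an optional full joint refinement started from the segmented
estimate.

All fitters are deterministic: non-linear fits are seeded from the
mono-exponential fit, with no random restarts, so voxelwise maps are
reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .models import (
    BValueScheme,
    IvimParams,
    MonoParams,
    SemParams,
    signal_ivim,
    signal_mono,
    signal_sem,
)

__all__ = [
    "VoxelSignal",
    "ModelFit",
    "FitConfig",
    "fit_mono",
    "fit_ivim",
    "fit_sem",
    "goodness_of_fit",
    "fit_volume",
    "MAP_NAMES",
]

logger = logging.getLogger(__name__)

# physiologic bounds, mm^2/s where dimensional
DIFFUSIVITY_BOUNDS = (1e-5, 5e-3)
D_STAR_UPPER = 0.1
ALPHA_BOUNDS = (0.01, 1.0)
SEGMENTATION_B = 200.0  # low/high-b split for segmented IVIM

_LSQ_KW = dict(method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=500)


@dataclass(frozen=True)
class VoxelSignal:
    """One voxel's measured magnitude signal across all b-values."""

    scheme: BValueScheme
    values: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.scheme.n,):
            raise ValueError("values length must match the b-value scheme")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def b(self) -> np.ndarray:
        return self.scheme.b


@dataclass(frozen=True)
class ModelFit:
    """A fitted model at one voxel or one mean-signal curve.

    ``converged`` is False when the optimiser failed, the estimates
    violate the model's parameter invariants, or (for IVIM) d_star is
    pinned at a bound; ``status`` carries a short reason.
    """

    model: Literal["mono", "ivim", "sem"]
    params: MonoParams | IvimParams | SemParams
    r_squared: float
    converged: bool
    status: str = "ok"


@dataclass(frozen=True)
class FitConfig:
    """Options shared by the fitters.

    weights="nex" weights residuals by sqrt(NEX) per b (noise-variance
    weighting for NEX-averaged magnitude data); default is unweighted.
    b_subset restricts fitting to the listed b-values (the full scheme is
    used by default).
    """

    ivim_strategy: Literal["segmented", "full"] = "full"
    segmentation_b: float = SEGMENTATION_B
    weights: Literal["none", "nex"] = "none"
    b_subset: tuple | None = None
    pseudo_diffusion_includes_d: bool = True


def _apply_subset(sig: VoxelSignal, config: FitConfig) -> VoxelSignal:
    if config.b_subset is None:
        return sig
    scheme = sig.scheme.subset(config.b_subset)
    keep = [i for i, b in enumerate(sig.scheme.b_values) if b in set(scheme.b_values)]
    return VoxelSignal(scheme, tuple(sig.values[i] for i in keep))


def _weights(sig: VoxelSignal, config: FitConfig) -> np.ndarray:
    if config.weights == "nex":
        return np.sqrt(np.asarray(sig.scheme.nex, dtype=float))
    return np.ones(sig.scheme.n)


def goodness_of_fit(sig: VoxelSignal, fit: ModelFit) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot on the signal scale.

    Returns NaN for a zero-variance signal, where R² is undefined.
    """
    y = sig.y
    if fit.model == "mono":
        yhat = signal_mono(sig.b, fit.params)
    elif fit.model == "ivim":
        yhat = signal_ivim(sig.b, fit.params)
    else:
        yhat = signal_sem(sig.b, fit.params)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def _loglinear(b: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted OLS of ln(y) on b; returns (slope, intercept)."""
    slope, intercept = np.polyfit(b, np.log(y), 1, w=w)
    return float(slope), float(intercept)


def fit_mono(sig: VoxelSignal, config: FitConfig = FitConfig()) -> ModelFit:
    """Log-linear mono-exponential fit: OLS of ln S on b.

    slope = −ADC, intercept = ln S0.  Voxels with any non-positive value
    are unfittable (the log is taken) and come back with converged=False
    rather than raising — fit_volume counts them.
    """
    sig = _apply_subset(sig, config)
    y = sig.y
    if np.any(y <= 0):
        return ModelFit(
            "mono", MonoParams(s0=float("nan"), adc=float("nan")), float("nan"), False, "nonpositive-signal"
        )
    slope, intercept = _loglinear(sig.b, y, _weights(sig, config))
    params = MonoParams(s0=float(np.exp(intercept)), adc=-slope)
    fit = ModelFit("mono", params, 0.0, params.is_valid(),
                   "ok" if params.is_valid() else "invalid-params")
    return _with_r2(sig, fit)


def _with_r2(sig: VoxelSignal, fit: ModelFit) -> ModelFit:
    return ModelFit(fit.model, fit.params, goodness_of_fit(sig, fit), fit.converged, fit.status)


def _mono_seed(sig: VoxelSignal, config: FitConfig) -> tuple[float, float]:
    """(s0, adc) start values; robust to non-positive entries."""
    y = sig.y
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = _loglinear(sig.b[pos], y[pos], _weights(sig, config)[pos])
        adc = float(np.clip(-slope, *DIFFUSIVITY_BOUNDS))
        s0 = float(np.clip(np.exp(intercept), 1e-12, None))
    else:
        adc, s0 = 1e-3, max(float(y[0]), 1e-12)
    return s0, adc


def fit_sem(sig: VoxelSignal, config: FitConfig = FitConfig()) -> ModelFit:
    """Bounded non-linear least squares of the stretched-exponential model.

    Fits (s0, ddc, alpha) with alpha in (0, 1], started from the
    mono-exponential fit with alpha = 0.9.
    """
    sig = _apply_subset(sig, config)
    y = sig.y
    if sig.scheme.n < 3 or y[0] <= 0:
        return ModelFit("sem", SemParams(float("nan"), float("nan"), float("nan")),
                        float("nan"), False, "unfittable")
    w = _weights(sig, config)
    s0_0, adc_0 = _mono_seed(sig, config)
    x0 = np.array([s0_0, adc_0, 0.9])
    lo = np.array([1e-12, DIFFUSIVITY_BOUNDS[0], ALPHA_BOUNDS[0]])
    hi = np.array([np.inf, DIFFUSIVITY_BOUNDS[1], ALPHA_BOUNDS[1]])
    b = sig.b

    def resid(x):
        return w * (x[0] * np.exp(-np.power(b * x[1], x[2])) - y)

    res = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi), **_LSQ_KW)
    params = SemParams(s0=float(res.x[0]), ddc=float(res.x[1]), alpha=float(res.x[2]))
    ok = res.success and params.is_valid()
    fit = ModelFit("sem", params, 0.0, ok, "ok" if ok else "no-convergence")
    return _with_r2(sig, fit)


def fit_ivim(
    sig: VoxelSignal,
    strategy: Literal["segmented", "full"] | None = None,
    config: FitConfig = FitConfig(),
) -> ModelFit:
    """Segmented or full IVIM fit.

    Segmented: d and s0·(1−f) from a log-linear fit over b ≥ the
    segmentation threshold (perfusion is assumed fully dephased there),
    then (s0, f, d_star) by non-linear least squares over all b with d
    fixed.  Full: all four parameters refined jointly, started from the
    segmented estimate.

    A d_star estimate pinned at its upper bound is flagged as
    non-converged ("dstar-at-bound").
    """
    sig = _apply_subset(sig, config)
    strategy = strategy or config.ivim_strategy
    y = sig.y
    b = sig.b
    hi_mask = b >= config.segmentation_b
    if sig.scheme.n < 5 or hi_mask.sum() < 2 or (~hi_mask).sum() < 2:
        return ModelFit("ivim", IvimParams(*[float("nan")] * 4), float("nan"), False, "unfittable")
    if np.any(y[hi_mask] <= 0) or y[0] <= 0:
        return ModelFit("ivim", IvimParams(*[float("nan")] * 4), float("nan"), False,
                        "nonpositive-signal")
    w = _weights(sig, config)
    incl_d = config.pseudo_diffusion_includes_d

    # -- stage 1: slow diffusion from the high-b segment
    slope, intercept = _loglinear(b[hi_mask], y[hi_mask], w[hi_mask])
    d = float(np.clip(-slope, *DIFFUSIVITY_BOUNDS))
    s0_tissue = float(np.exp(intercept))  # = s0·(1−f)
    f0 = float(np.clip(1.0 - s0_tissue / max(y[0], 1e-12), 0.0, 0.9))
    s0_0 = s0_tissue / max(1.0 - f0, 1e-6)

    def model(s0, dd, ds, ff):
        rate = dd + ds if incl_d else ds
        return s0 * ((1.0 - ff) * np.exp(-b * dd) + ff * np.exp(-b * rate))

    # -- stage 2: perfusion terms with d fixed
    x0 = np.array([s0_0, f0, 10e-3])
    lo = np.array([1e-12, 0.0, d if incl_d is False else DIFFUSIVITY_BOUNDS[0]])
    lo[2] = max(lo[2], DIFFUSIVITY_BOUNDS[0])
    hi = np.array([np.inf, 1.0, D_STAR_UPPER])

    def resid_seg(x):
        return w * (model(x[0], d, x[2], x[1]) - y)

    res = least_squares(resid_seg, np.clip(x0, lo, hi), bounds=(lo, hi), **_LSQ_KW)
    seg = IvimParams(s0=float(res.x[0]), d=d, d_star=float(res.x[2]), f=float(res.x[1]))
    success = bool(res.success)

    if strategy == "full":
        # -- stage 3: joint refinement; d_star parametrised as d + delta so
        # the d_star >= d ordering survives the joint fit (prevents the
        # slow/fast compartment identity swap).
        delta0 = max(seg.d_star - seg.d, 1e-6)
        x0 = np.array([seg.s0, seg.d, delta0, seg.f])
        lo = np.array([1e-12, DIFFUSIVITY_BOUNDS[0], 0.0, 0.0])
        hi = np.array([np.inf, DIFFUSIVITY_BOUNDS[1], D_STAR_UPPER, 1.0])

        def resid_full(x):
            return w * (model(x[0], x[1], x[1] + x[2], x[3]) - y)

        res = least_squares(resid_full, np.clip(x0, lo, hi), bounds=(lo, hi), **_LSQ_KW)
        seg = IvimParams(s0=float(res.x[0]), d=float(res.x[1]),
                         d_star=float(res.x[1] + res.x[2]), f=float(res.x[3]))
        success = bool(res.success)

    status = "ok"
    converged = success and seg.is_valid()
    if not converged:
        status = "no-convergence"
    elif seg.d_star >= D_STAR_UPPER * (1 - 1e-9):
        converged = False
        status = "dstar-at-bound"
    fit = ModelFit("ivim", seg, 0.0, converged, status)
    return _with_r2(sig, fit)


# parameter-map names produced by fit_volume, per model
MAP_NAMES = {
    "mono": ("adc", "r2_mono"),
    "ivim": ("d", "d_star", "f", "r2_ivim"),
    "sem": ("ddc", "alpha", "r2_sem"),
}


def fit_volume(
    volume: np.ndarray,
    mask: np.ndarray,
    scheme: BValueScheme,
    models: tuple = ("mono", "ivim", "sem"),
    config: FitConfig = FitConfig(),
) -> dict[str, np.ndarray]:
    """Fit the selected models at every mask voxel of a 4-D volume.

    Parameters
    ----------
    volume
        4-D array (x, y, z, b) of magnitude signals.
    mask
        3-D boolean (or 0/1) array on the same grid.
    scheme
        The b-value scheme of the fourth axis.
    models
        Which of "mono", "ivim", "sem" to fit.

    Returns
    -------
    dict of 3-D float arrays, one per parameter map (see ``MAP_NAMES``),
    plus ``"fit_status"``: 0 outside the mask, 1 all requested fits
    converged, 2 at least one did not.  Diffusivities are in mm²/s;
    unfittable voxels are NaN.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if volume.ndim != 4 or volume.shape[:3] != mask.shape:
        raise ValueError("volume must be 4-D and share its grid with the mask")
    if volume.shape[3] != scheme.n:
        raise ValueError("fourth axis must match the b-value scheme")

    names = [n for m in models for n in MAP_NAMES[m]]
    maps = {n: np.full(mask.shape, np.nan, dtype=float) for n in names}
    status = np.zeros(mask.shape, dtype=np.int8)

    idx = np.argwhere(mask)
    if idx.size == 0:
        warnings.warn("empty mask: no voxels fitted", stacklevel=2)
        maps["fit_status"] = status
        return maps

    n_unfittable = 0
    for i, j, k in idx:
        sig = VoxelSignal(scheme, tuple(volume[i, j, k, :]))
        all_ok = True
        for m in models:
            if m == "mono":
                fit = fit_mono(sig, config)
                if fit.converged:
                    maps["adc"][i, j, k] = fit.params.adc
                maps["r2_mono"][i, j, k] = fit.r_squared
            elif m == "ivim":
                fit = fit_ivim(sig, config=config)
                if fit.converged:
                    maps["d"][i, j, k] = fit.params.d
                    maps["d_star"][i, j, k] = fit.params.d_star
                    maps["f"][i, j, k] = fit.params.f
                maps["r2_ivim"][i, j, k] = fit.r_squared
            else:
                fit = fit_sem(sig, config)
                if fit.converged:
                    maps["ddc"][i, j, k] = fit.params.ddc
                    maps["alpha"][i, j, k] = fit.params.alpha
                maps["r2_sem"][i, j, k] = fit.r_squared
            all_ok = all_ok and fit.converged
        status[i, j, k] = 1 if all_ok else 2
        n_unfittable += 0 if all_ok else 1
    if n_unfittable:
        logger.info("fit_volume: %d/%d mask voxels had a non-converged fit",
                    n_unfittable, len(idx))
    maps["fit_status"] = status
    return maps
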