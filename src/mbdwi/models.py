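"""Forward signal equations for multi-b-value diffusion-weighted MRI.

Three decay models are implemented, each describing the magnitude signal
``S(b)`` of a voxel as a function of the diffusion weighting ``b`` (s/mm²):

* mono-exponential (Gaussian):      S(b) = S0 · exp(−b·ADC)
* intravoxel incoherent motion:     S(b) = S0 · [(1−f)·exp(−b·D) + f·exp(−b·(D + D*))]
* stretched exponential:            S(b) = S0 · exp(−(b·DDC)^α)

All diffusivities are carried internally in mm²/s; the conventional
reporting scale of ×10⁻³ mm²/s is applied only when tables are written
(see :func:`to_reporting_units` / :func:`from_reporting_units`).

The IVIM pseudo-diffusion exponent is −b·(D + D*) by default.  Some
implementations use −b·D* instead; ``pseudo_diffusion_includes_d=False``
selects that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "BValueScheme",
    "MonoParams",
    "IvimParams",
    "SemParams",
    "signal_mono",
    "signal_ivim",
    "signal_sem",
    "to_reporting_units",
    "from_reporting_units",
    "DEFAULT_B_VALUES",
    "DEFAULT_NEX",
]

# 12-b-value acquisition protocol with per-b excitation counts (NEX).
DEFAULT_B_VALUES = (0.0, 10.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 400.0, 800.0, 1000.0, 1500.0)
DEFAULT_NEX = (1, 3, 3, 3, 3, 2, 2, 2, 2, 3, 5, 6)

# Diffusivity scale of printed tables: 10^-3 mm^2/s.
REPORTING_SCALE = 1e-3


@dataclass(frozen=True)
class BValueScheme:
    """A diffusion-weighting protocol: b-values (s/mm²) with per-b NEX.

    The default corresponds to a 12-b-value cervix protocol with
    b = 0…1500 s/mm² and NEX increasing with b to compensate for the
    lower signal at strong weighting.
    """

    b_values: tuple = field(default=DEFAULT_B_VALUES)
    nex: tuple = field(default=DEFAULT_NEX)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        nex = np.asarray(self.nex)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need at least two b-values")
        if b[0] != 0:
            raise ValueError("first b-value must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly increasing")
        if nex.shape != b.shape:
            raise ValueError("nex must have the same length as b_values")
        if np.any(nex < 1) or not np.issubdtype(nex.dtype, np.integer):
            raise ValueError("nex must be integers >= 1")
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))
        object.__setattr__(self, "nex", tuple(int(x) for x in nex))

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    @property
    def n(self) -> int:
        return len(self.b_values)

    def subset(self, b_keep: Sequence[float]) -> "BValueScheme":
        """Scheme restricted to the given b-values (must include b=0)."""
        keep = [i for i, b in enumerate(self.b_values) if b in set(float(x) for x in b_keep)]
        return BValueScheme(
            tuple(self.b_values[i] for i in keep), tuple(self.nex[i] for i in keep)
        )

    # -- FSL-style .bval text I/O -------------------------------------
    @classmethod
    def from_bval(cls, path: str | Path, nex: Sequence[int] | None = None) -> "BValueScheme":
        """Read b-values from a whitespace-separated .bval file.

        .bval files carry no NEX information; pass ``nex`` explicitly
        (e.g. from a pipeline config) or every b gets NEX 1.
        """
        text = Path(path).read_text()
        b = [float(tok) for tok in text.split()]
        if nex is None:
            nex = [1] * len(b)
        return cls(tuple(b), tuple(int(x) for x in nex))

    def to_bval(self, path: str | Path) -> None:
        Path(path).write_text(" ".join(f"{b:g}" for b in self.b_values) + "\n")


@dataclass(frozen=True)
class MonoParams:
    """Mono-exponential (Gaussian) model: S0 and the ADC (mm²/s)."""

    s0: float
    adc: float

    def validate(self) -> None:
        if not self.s0 > 0:
            raise ValueError("s0 must be > 0")
        if not self.adc > 0:
            raise ValueError("adc must be > 0")

    def is_valid(self) -> bool:
        return self.s0 > 0 and self.adc > 0


@dataclass(frozen=True)
class IvimParams:
    """IVIM bi-exponential model.

    d is the slow (true tissue) diffusion coefficient, d_star the
    pseudo-diffusion coefficient attributed to capillary microcirculation
    (both mm²/s), and f the perfusion fraction in [0, 1].
    """

    s0: float
    d: float
    d_star: float
    f: float

    def validate(self) -> None:
        if not self.s0 > 0:
            raise ValueError("s0 must be > 0")
        if not self.d > 0:
            raise ValueError("d must be > 0")
        if not self.d_star > 0:
            raise ValueError("d_star must be > 0")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")

    def is_valid(self) -> bool:
        return self.s0 > 0 and self.d > 0 and self.d_star > 0 and 0.0 <= self.f <= 1.0


@dataclass(frozen=True)
class SemParams:
    """Stretched-exponential model.

    ddc is the distributed diffusion coefficient (mm²/s): the mean
    intravoxel diffusion rate.  alpha in (0, 1] is the heterogeneity
    index; alpha = 1 recovers Gaussian diffusion and smaller values
    indicate greater intravoxel diffusion heterogeneity.
    """

    s0: float
    ddc: float
    alpha: float

    def validate(self) -> None:
        if not self.s0 > 0:
            raise ValueError("s0 must be > 0")
        if not self.ddc > 0:
            raise ValueError("ddc must be > 0")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")

    def is_valid(self) -> bool:
        return self.s0 > 0 and self.ddc > 0 and 0.0 < self.alpha <= 1.0


def _check_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return b


def signal_mono(b, params: MonoParams) -> np.ndarray | float:
    """Mono-exponential signal S0·exp(−b·ADC)."""
    b = _check_b(b)
    return params.s0 * np.exp(-b * params.adc)


def signal_ivim(
    b, params: IvimParams, *, pseudo_diffusion_includes_d: bool = True
) -> np.ndarray | float:
    """IVIM bi-exponential signal.

    With the default convention the perfusion compartment decays as
    exp(−b·(D + D*)); with ``pseudo_diffusion_includes_d=False`` it decays
    as exp(−b·D*).
    """
    b = _check_b(b)
    if not 0.0 <= params.f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    rate = params.d + params.d_star if pseudo_diffusion_includes_d else params.d_star
    return params.s0 * (
        (1.0 - params.f) * np.exp(-b * params.d) + params.f * np.exp(-b * rate)
    )


def signal_sem(b, params: SemParams) -> np.ndarray | float:
    """Stretched-exponential signal S0·exp(−(b·DDC)^α)."""
    b = _check_b(b)
    if not 0.0 < params.alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    return params.s0 * np.exp(-np.power(b * params.ddc, params.alpha))


def to_reporting_units(value_mm2_s: float) -> float:
    """mm²/s → the ×10⁻³ mm²/s scale used in report tables."""
    return value_mm2_s / REPORTING_SCALE


def from_reporting_units(value_e3: float) -> float:
    """×10⁻³ mm²/s report scale → mm²/s."""
    return value_e3 * REPORTING_SCALE
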