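"""Synthetic phantoms and cohorts for the DWI response-prediction pipeline.

The generator emulates the statistical structure the analysis assumes,
so every pipeline stage is testable without patient data:

* per-group biomarker distributions (truncated normals on the reporting
  scale) matching a published responder / non-responder cervical-cancer
  cohort of 58 + 26 patients;
* 12-b-value voxel signals from a chosen forward model, corrupted by
  Rician noise whose per-b standard deviation reflects the per-b NEX
  averaging of the acquisition protocol;
* simple block phantoms (labelled regions, not anatomy) with tumor
  masks;
* longitudinal tumor-diameter trajectories constructed to classify back
  to their intended CR/PR/SD/PD category;
* two-reader measurement noise for concordance analysis.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import BValueScheme, IvimParams, MonoParams, SemParams, signal_ivim, signal_mono, signal_sem
from .response import CATEGORY_TO_GROUP

__all__ = [
    "GroupDistribution",
    "SimConfig",
    "TrajectoryConfig",
    "RESPONDER_DISTRIBUTION",
    "NONRESPONDER_DISTRIBUTION",
    "sample_patient_params",
    "generate_voxel_signals",
    "generate_cohort",
    "simulate_readers",
    "generate_trajectories",
    "CohortSim",
]

# reporting-scale truncation bounds keeping samples inside model invariants
# (diffusivities 10^-3 mm^2/s, f in %, alpha unitless)
_PARAM_BOUNDS = {
    "adc": (0.01, 5.0),
    "d": (0.01, 5.0),
    "d_star": (0.01, 100.0),
    "f": (0.0, 100.0),
    "alpha": (0.01, 1.0),
    "ddc": (0.01, 5.0),
}
PARAM_NAMES = tuple(_PARAM_BOUNDS)


@dataclass(frozen=True)
class GroupDistribution:
    """Per-parameter (mean, sd) of one patient group, on the reporting
    scale (diffusivities ×10⁻³ mm²/s, f in %, alpha unitless)."""

    params: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        for name, (mean, sd) in self.params.items():
            if name not in _PARAM_BOUNDS:
                raise ValueError(f"unknown parameter {name!r}")
            if sd <= 0:
                raise ValueError(f"{name}: sd must be > 0")
            del mean


# cohort defaults: responder / non-responder biomarker means ± SD
RESPONDER_DISTRIBUTION = GroupDistribution({
    "adc": (0.610, 0.072),
    "d": (0.443, 0.167),
    "d_star": (6.891, 5.588),
    "f": (25.318, 9.069),
    "alpha": (0.912, 0.043),
    "ddc": (0.831, 0.141),
})
NONRESPONDER_DISTRIBUTION = GroupDistribution({
    "adc": (0.980, 0.089),
    "d": (0.843, 0.235),
    "d_star": (8.820, 6.456),
    "f": (32.356, 10.723),
    "alpha": (0.612, 0.235),
    "ddc": (1.257, 0.167),
})

# responder / non-responder covariate proportions of the emulated cohort
_COVARIATES = {
    "tumor_size_class": (("<=4cm", ">4cm"), (0.750, 0.250), (0.231, 0.769)),
    "figo_stage": (("IIB", "III", "IV"), (0.138, 0.448, 0.414), (0.231, 0.385, 0.385)),
    "pathologic_type": (("squamous", "other"), (0.828, 0.172), (0.808, 0.192)),
    "histologic_grade": (("well-moderate", "poor"), (0.310, 0.690), (0.769, 0.231)),
}
_AGE_RANGE = {"responder": (25, 67), "non-responder": (29, 68)}


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation settings.

    snr_b0 is the signal-to-noise ratio at b = 0 (np.inf → noiseless);
    within_tumor_cv is the per-voxel coefficient of variation of the
    biomarkers inside one tumor (between-patient dispersion comes from
    the group distributions).  The generating forward model is "sem" by
    default; "mono" or "ivim" select the other families.
    """

    seed: int
    n_responders: int = 58
    n_nonresponders: int = 26
    scheme: BValueScheme = field(default_factory=BValueScheme)
    snr_b0: float = 100.0
    voxels_per_patient: int = 27
    n_slices: int = 3
    model: str = "sem"
    within_tumor_cv: float = 0.05

    def __post_init__(self):
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise ValueError("group sizes must be >= 1")
        if self.voxels_per_patient < 1:
            raise ValueError("voxels_per_patient must be >= 1")
        if self.model not in ("mono", "ivim", "sem"):
            raise ValueError("model must be one of mono/ivim/sem")
        if not self.snr_b0 > 0:
            raise ValueError("snr_b0 must be > 0")


def _truncnorm(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_patient_params(
    dist: GroupDistribution, rng: np.random.Generator, n: int = 1
) -> pd.DataFrame:
    """Draw per-patient true biomarker values (reporting scale).

    Truncated-normal draws per parameter, truncated at the model
    invariants (alpha ≤ 1, f within [0, 100]%, positive diffusivities);
    d_star is additionally kept above the patient's d so the pseudo- and
    true-diffusion compartments stay ordered.
    """
    out = {}
    for name in PARAM_NAMES:
        if name not in dist.params:
            continue
        mean, sd = dist.params[name]
        lo, hi = _PARAM_BOUNDS[name]
        out[name] = _truncnorm(mean, sd, lo, hi, n, rng)
    df = pd.DataFrame(out)
    if "d" in df and "d_star" in df:
        df["d_star"] = np.maximum(df["d_star"], df["d"] * 1.01)
    return df


def _forward_signal(model: str, b: np.ndarray, row: Mapping[str, float]) -> np.ndarray:
    """Noiseless signal (s0 = 1) from reporting-scale parameters."""
    if model == "mono":
        return signal_mono(b, MonoParams(1.0, row["adc"] * 1e-3))
    if model == "ivim":
        return signal_ivim(b, IvimParams(1.0, row["d"] * 1e-3, row["d_star"] * 1e-3,
                                         row["f"] / 100.0))
    return signal_sem(b, SemParams(1.0, row["ddc"] * 1e-3, row["alpha"]))


def add_rician_noise(
    signal: np.ndarray, scheme: BValueScheme, snr_b0: float,
    rng: np.random.Generator, s0: float = 1.0,
) -> np.ndarray:
    """Corrupt signals with magnitude-image (Rician) noise.

    The per-b noise standard deviation is s0 / (snr_b0 · sqrt(NEX_b /
    NEX_0)): averaging NEX excitations shrinks the complex-channel noise
    by sqrt(NEX).  snr_b0 = inf returns the input unchanged.
    """
    if np.isinf(snr_b0):
        return np.asarray(signal, dtype=float)
    nex = np.asarray(scheme.nex, dtype=float)
    sigma = s0 / (snr_b0 * np.sqrt(nex / nex[0]))
    shape = np.shape(signal)
    re = signal + rng.normal(0.0, sigma, size=shape)
    im = rng.normal(0.0, sigma, size=shape)
    return np.hypot(re, im)


def generate_voxel_signals(
    true_params: Mapping[str, float],
    scheme: BValueScheme,
    snr_b0: float,
    rng: np.random.Generator,
    model: str = "sem",
    n_voxels: int = 1,
    within_tumor_cv: float = 0.0,
) -> np.ndarray:
    """Voxel signals (n_voxels × n_b) for one patient.

    Each voxel's parameters are the patient's true values jittered by a
    multiplicative normal with the given CV (clipped to the parameter
    bounds), pushed through the chosen forward model and corrupted by
    Rician noise.
    """
    b = scheme.b
    rows = np.empty((n_voxels, scheme.n), dtype=float)
    for v in range(n_voxels):
        row = dict(true_params)
        if within_tumor_cv > 0:
            for name in list(row):
                if name in _PARAM_BOUNDS:
                    lo, hi = _PARAM_BOUNDS[name]
                    row[name] = float(np.clip(
                        row[name] * rng.normal(1.0, within_tumor_cv), lo, hi))
        rows[v] = _forward_signal(model, b, row)
    return add_rician_noise(rows, scheme, snr_b0, rng)


def _block_mask(voxels_per_patient: int, n_slices: int) -> np.ndarray:
    """Central square block mask holding >= voxels_per_patient voxels."""
    per_slice = math.ceil(voxels_per_patient / n_slices)
    side = math.ceil(math.sqrt(per_slice))
    dim = side + 2  # one-voxel background margin
    mask = np.zeros((dim, dim, n_slices), dtype=bool)
    mask[1:1 + side, 1:1 + side, :] = True
    return mask


@dataclass
class CohortSim:
    """In-memory simulated cohort.

    cohort: one row per patient with group label, true biomarkers
    (reporting scale), covariates and intended response category.
    volumes / masks: per-patient 4-D signal arrays and tumor masks,
    aligned with the cohort rows.
    """

    config: SimConfig
    cohort: pd.DataFrame
    volumes: list
    masks: list
    scheme: BValueScheme


def generate_cohort(
    config: SimConfig,
    responder_dist: GroupDistribution = RESPONDER_DISTRIBUTION,
    nonresponder_dist: GroupDistribution = NONRESPONDER_DISTRIBUTION,
) -> CohortSim:
    """Simulate the full two-group cohort with phantoms and true values.

    Each patient gets truth drawn from their group's distribution, a
    block-phantom 4-D volume of noisy voxel signals from the configured
    forward model, a tumor mask, categorical covariates drawn from the
    emulated cohort's proportions, and an intended response category
    (responders split CR/PR, non-responders SD/PD).
    """
    rng = np.random.default_rng(config.seed)
    groups = (["responder"] * config.n_responders
              + ["non-responder"] * config.n_nonresponders)
    dists = {"responder": responder_dist, "non-responder": nonresponder_dist}

    frames = []
    for g in ("responder", "non-responder"):
        n = groups.count(g)
        df = sample_patient_params(dists[g], rng, n)
        df.insert(0, "group", g)
        frames.append(df)
    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "patient_id", [f"P{i + 1:03d}" for i in range(len(cohort))])

    # covariates from the emulated cohort's printed proportions
    for name, (levels, p_resp, p_non) in _COVARIATES.items():
        probs = {"responder": np.asarray(p_resp) / np.sum(p_resp),
                 "non-responder": np.asarray(p_non) / np.sum(p_non)}
        cohort[name] = [
            levels[rng.choice(len(levels), p=probs[g])] for g in cohort["group"]
        ]
    cohort["age"] = [
        int(rng.integers(_AGE_RANGE[g][0], _AGE_RANGE[g][1] + 1))
        for g in cohort["group"]
    ]
    # intended response categories (responders mostly PR, some CR;
    # non-responders mostly SD) — the CR/PR and SD/PD splits are a
    # modelling choice, the group sizes are the emulated cohort's
    category = []
    for g in cohort["group"]:
        if g == "responder":
            category.append("CR" if rng.random() < 0.4 else "PR")
        else:
            category.append("PD" if rng.random() < 0.2 else "SD")
    cohort["category"] = category

    mask = _block_mask(config.voxels_per_patient, config.n_slices)
    n_vox = int(mask.sum())
    volumes, masks = [], []
    for _, row in cohort.iterrows():
        sig = generate_voxel_signals(
            row[list(PARAM_NAMES)].to_dict(), config.scheme, config.snr_b0,
            rng, model=config.model, n_voxels=n_vox,
            within_tumor_cv=config.within_tumor_cv,
        )
        vol = np.zeros(mask.shape + (config.scheme.n,), dtype=float)
        vol[mask] = sig
        volumes.append(vol)
        masks.append(mask.copy())
    return CohortSim(config, cohort, volumes, masks, config.scheme)


def simulate_readers(
    true_values: np.ndarray, reader_sd: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two radiologists' independent noisy measurements of the same
    per-patient values (additive N(0, reader_sd) each)."""
    if reader_sd < 0:
        raise ValueError("reader_sd must be >= 0")
    v = np.asarray(true_values, dtype=float)
    return (v + rng.normal(0.0, reader_sd, v.shape),
            v + rng.normal(0.0, reader_sd, v.shape))


@dataclass(frozen=True)
class TrajectoryConfig:
    """Diameter-trajectory settings.

    Visits follow the quarterly follow-up grid (first visit ~6 weeks
    after the start of treatment, then every 3 months, 18-month window).
    The per-category 12-month diameter-change ranges are chosen to sit
    safely inside their rule boundaries (PR: shrinkage > 30%; PD: growth
    ≥ 20%; SD in between).
    """

    visit_months: tuple = (1.5, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0)
    baseline_mean_mm: float = 40.0
    baseline_sd_mm: float = 10.0
    pr_shrinkage: tuple = (0.35, 0.75)
    sd_change: tuple = (-0.25, 0.15)
    pd_growth: tuple = (0.25, 0.60)
    cr_months: tuple = (3.0, 6.0, 9.0, 12.0)


def _trajectory(category: str, baseline: float, tcfg: TrajectoryConfig,
                rng: np.random.Generator) -> list[tuple[float, float]]:
    months = np.asarray(tcfg.visit_months)
    if category == "CR":
        gone = tcfg.cr_months[rng.integers(len(tcfg.cr_months))]
        diam = np.where(months >= gone, 0.0,
                        baseline * (1.0 - 0.9 * months / gone))
    else:
        if category == "PR":
            change = -rng.uniform(*tcfg.pr_shrinkage)
        elif category == "SD":
            change = rng.uniform(*tcfg.sd_change)
        else:
            change = rng.uniform(*tcfg.pd_growth)
        d12 = baseline * (1.0 + change)
        # linear drift toward the 12-month value, then stable
        frac = np.clip(months / 12.0, 0.0, 1.0)
        diam = baseline + (d12 - baseline) * frac
        diam = np.maximum(diam, 0.5)  # never "disappears" unless CR
    return list(zip(months.tolist(), [float(d) for d in diam]))


def generate_trajectories(
    labels: pd.DataFrame,
    tconfig: TrajectoryConfig = TrajectoryConfig(),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Diameter series realising each patient's intended category.

    ``labels`` has columns patient_id and category.  Returns a long
    table (patient_id, months, diameter_mm) including the baseline row
    at months = 0; by construction each series classifies back to its
    intended category (closure), which callers can verify with
    ``response.classify_table``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for _, rec in labels.iterrows():
        cat = rec["category"]
        if cat not in CATEGORY_TO_GROUP:
            raise ValueError(f"unknown category {cat!r}")
        baseline = float(np.clip(
            rng.normal(tconfig.baseline_mean_mm, tconfig.baseline_sd_mm), 15.0, 90.0))
        rows.append((rec["patient_id"], 0.0, baseline))
        for m, d in _trajectory(cat, baseline, tconfig, rng):
            rows.append((rec["patient_id"], m, d))
    return pd.DataFrame(rows, columns=["patient_id", "months", "diameter_mm"])
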