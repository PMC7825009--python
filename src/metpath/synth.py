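"""Synthetic metabolomics fixtures with known ground truth.

Generates case/control and survival datasets with the statistical
structure the pipeline assumes: log-normal metabolite intensities,
case shifts concentrated in designated pathways (in units of the
control standard deviation on the log scale), survival times from a
linear Cox model on latent pathway activities, and
missing-completely-at-random intensity dropout.  Every generator is
deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MetaboliteMatrix, PathwayDatabase, SurvivalData

__all__ = [
    "SynthSpec",
    "gen_classification_dataset",
    "gen_survival_dataset",
    "gen_missing",
    "default_pathways",
]


@dataclass
class SurvivalSpec:
    """Ground-truth survival model: hazard = baseline_rate * exp(z' beta)."""

    beta: dict[str, float]          # true log-hazard effect per pathway
    baseline_rate: float = 0.1
    censoring_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring fraction must lie in [0, 1)")


@dataclass
class SynthSpec:
    """Ground truth for a synthetic dataset.

    ``pathways`` maps pathway ID -> member metabolite indices;
    ``effect_pathways`` maps a subset of those IDs to an effect size in
    control-sd units (applied on the log scale to case samples).
    """

    n_controls: int = 100
    n_cases: int = 100
    n_metabolites: int = 100
    pathways: dict[str, list[int]] = field(default_factory=dict)
    effect_pathways: dict[str, float] = field(default_factory=dict)
    survival: SurvivalSpec | None = None
    missing_rate: float = 0.0
    log_sd: float = 0.5             # per-metabolite sd of log intensities
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.effect_pathways) - set(self.pathways)
        if unknown:
            raise ValueError(f"effect pathways not defined: {sorted(unknown)}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for pid, members in self.pathways.items():
            if any(m >= self.n_metabolites or m < 0 for m in members):
                raise ValueError(f"pathway {pid} references a metabolite out of range")


def default_pathways(
    n_pathways: int = 10, pathway_size: int = 8, n_metabolites: int = 100, overlap: int = 1
) -> dict[str, list[int]]:
    """Evenly spaced pathway memberships; consecutive pathways share
    ``overlap`` metabolites (overlap between pathways is realistic and
    deliberately exercised)."""
    step = max(1, pathway_size - overlap)
    out = {}
    for i in range(n_pathways):
        start = (i * step) % max(1, n_metabolites - pathway_size)
        out[f"PW{i:02d}"] = list(range(start, start + pathway_size))
    return out


def _pathway_db(spec: SynthSpec) -> PathwayDatabase:
    names = [f"M{j:03d}" for j in range(spec.n_metabolites)]
    pathways = {pid: {names[j] for j in members} for pid, members in spec.pathways.items()}
    return PathwayDatabase(pathways, name_map={}, descriptions={p: "synthetic" for p in pathways})


def _base_log_matrix(spec: SynthSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    base_mean = rng.uniform(2.0, 6.0, size=spec.n_metabolites)
    return base_mean + rng.normal(0.0, spec.log_sd, size=(n, spec.n_metabolites))


def gen_classification_dataset(
    spec: SynthSpec,
) -> tuple[MetaboliteMatrix, PathwayDatabase, pd.Series]:
    """Case/control dataset with pathway-concentrated mean shifts.

    Control intensities are log-normal; case samples have the member
    metabolites of each effect pathway shifted by ``effect_size``
    control standard deviations on the log scale.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_controls + spec.n_cases
    logx = _base_log_matrix(spec, rng, n)
    case_mask = np.zeros(n, dtype=bool)
    case_mask[spec.n_controls:] = True
    for pid, effect in spec.effect_pathways.items():
        for j in spec.pathways[pid]:
            logx[case_mask, j] += effect * spec.log_sd
    values = pd.DataFrame(
        np.exp(logx),
        index=[f"S{i:04d}" for i in range(n)],
        columns=[f"M{j:03d}" for j in range(spec.n_metabolites)],
    )
    labels = pd.Series(
        np.where(case_mask, "case", "control"), index=values.index, name="label"
    )
    matrix = MetaboliteMatrix(values, labels)
    if spec.missing_rate > 0:
        matrix = gen_missing(matrix, spec.missing_rate, seed=spec.seed + 1)
    return matrix, _pathway_db(spec), labels


def gen_survival_dataset(
    spec: SynthSpec,
) -> tuple[MetaboliteMatrix, PathwayDatabase, SurvivalData, pd.DataFrame]:
    """Survival dataset driven by latent pathway activities.

    Each sample carries a standard-normal activity score per pathway;
    the activity shifts the pathway's member metabolites on the log
    scale, and the hazard is ``baseline_rate * exp(z' beta_true)`` with
    exponential event times.  Censoring is independent uniform, with
    the upper bound calibrated by bisection so the realized censored
    fraction matches the request.  Returns the metabolite matrix, the
    pathway database, the survival data and the latent pathway-activity
    matrix (samples x pathways) for pathway-level modelling.
    """
    if spec.survival is None:
        raise ValueError("spec.survival is not set")
    sv = spec.survival
    rng = np.random.default_rng(spec.seed)
    n = spec.n_controls + spec.n_cases
    pids = list(spec.pathways)
    Z = rng.standard_normal((n, len(pids)))
    logx = _base_log_matrix(spec, rng, n)
    for k, pid in enumerate(pids):
        for j in spec.pathways[pid]:
            logx[:, j] += 0.8 * spec.log_sd * Z[:, k]
    beta = np.array([sv.beta.get(pid, 0.0) for pid in pids])
    theta = Z @ beta
    rate = sv.baseline_rate * np.exp(theta)
    T = rng.exponential(1.0 / rate)
    u = rng.uniform(size=n)
    if sv.censoring_fraction == 0:
        time, event = T, np.ones(n, dtype=int)
    else:
        lo, hi = 1e-9, float(T.max()) * 1e3
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            frac = float(np.mean(mid * u < T))  # censored fraction, decreasing in mid
            if frac > sv.censoring_fraction:
                lo = mid
            else:
                hi = mid
        c = 0.5 * (lo + hi)
        censored = c * u < T
        time = np.where(censored, c * u, T)
        event = (~censored).astype(int)
    ids = [f"S{i:04d}" for i in range(n)]
    values = pd.DataFrame(
        np.exp(logx), index=ids, columns=[f"M{j:03d}" for j in range(spec.n_metabolites)]
    )
    matrix = MetaboliteMatrix(values)
    if spec.missing_rate > 0:
        matrix = gen_missing(matrix, spec.missing_rate, seed=spec.seed + 1)
    surv = SurvivalData(ids, time, event)
    activities = pd.DataFrame(Z, index=ids, columns=pids)
    return matrix, _pathway_db(spec), surv, activities


def gen_missing(matrix: MetaboliteMatrix, rate: float, seed: int = 0) -> MetaboliteMatrix:
    """Mask entries missing-completely-at-random at the given rate,
    never blanking an entire feature."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    X = matrix.values.to_numpy(dtype=float).copy()
    n, p = X.shape
    mask = rng.random((n, p)) < rate
    full = mask.all(axis=0)
    if full.any():
        if rate > 1 - 1.0 / n:
            raise ValueError("rate too high: a feature would be fully missing")
        for j in np.where(full)[0]:
            keep = rng.integers(n)
            mask[keep, j] = False
    X[mask] = np.nan
    values = pd.DataFrame(X, index=matrix.values.index, columns=matrix.values.columns)
    return MetaboliteMatrix(values, matrix.labels)
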