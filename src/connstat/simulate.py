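"""Synthetic cohorts with planted connectivity effects.

Two generation modes serve different test depths:

* :func:`simulate_timeseries` builds region-level signals from stochastic
  narrowband oscillators (band-pass filtered white noise, so phase
  estimates have realistic variance) and plants group differences as
  phase-lagged shared sources on chosen edges.  Zero-lag coupling is
  rejected because the weighted phase lag index is blind to it by
  construction.
* :func:`simulate_fc_directly` skips signal generation and draws static
  edge weights from a logit-normal law bounded to [0, 1], shifting the
  location on planted edges per group.  This is the fast path used for the
  statistical engine's calibration and recovery simulations.

:func:`attach_hormone` adds a hormone-like column whose covariate-adjusted
(partial Pearson) correlation with a mean-network-connectivity vector is
calibrated to a target value through a linear-Gaussian link.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .connectivity import (
    DEFAULT_BANDS,
    BandDefinition,
    RegionTimeSeries,
    analytic_signal,
    bandpass,
)
from .io import CohortTable, FCBundle

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "STUDY_GROUP_SIZES",
    "simulate_timeseries",
    "simulate_fc_directly",
    "attach_hormone",
    "default_covariate_model",
]

#: Four-group cohort layout of the motivating study: drug-naive Parkinson's
#: disease patients and healthy controls, split by sex.
STUDY_GROUP_SIZES = {
    "female_PD": 27,
    "male_PD": 42,
    "female_HC": 30,
    "male_HC": 39,
}


def default_covariate_model() -> dict:
    """Distribution specs for study-like nuisance covariates.

    Age in years, disease duration in months, levodopa-equivalent daily
    dose (LEDD) in mg/day, most-affected side as a 0/1 indicator, and BMI;
    locations and spreads follow typical early, L-dopa-naive PD cohorts.
    """
    return {
        "age": ("normal", 60.0, 10.0),
        "duration": ("truncnormal", 28.0, 19.0),
        "ledd": ("truncnormal", 105.0, 135.0),
        "side": ("bernoulli", 0.5),
        "bmi": ("normal", 25.0, 3.0),
    }


@dataclass
class PlantedEffect:
    """A group-specific connectivity effect on a fixed edge set.

    ``group_deltas`` maps group label -> additive offset: coupling strength
    in time-series mode, location shift of the [0, 1] edge weight in direct
    mode.  ``phase_lag`` (radians, exclusive of 0 and pi) applies only to
    time-series mode; zero-lag coupling is invisible to wPLI and rejected.
    """

    band: str
    edges: list[tuple[int, int]]
    group_deltas: dict[str, float]
    phase_lag: float = math.pi / 4

    def __post_init__(self):
        for i, j in self.edges:
            if not (0 <= i < j):
                raise ValueError(f"edge ({i}, {j}) must satisfy 0 <= i < j")
        lag = self.phase_lag % (2 * math.pi)
        if min(abs(lag), abs(lag - math.pi), abs(lag - 2 * math.pi)) < 1e-9:
            raise ValueError(
                "phase_lag of 0 or pi produces coupling with no imaginary "
                "cross-spectrum, which wPLI cannot detect; choose a lag in "
                "(0, pi) excluding the endpoints"
            )


@dataclass
class SimulationConfig:
    """Cohort-level generation parameters.

    Defaults reproduce the study conditions: four groups (27/42/30/39
    subjects), 68 regions, 1024 Hz sampling, 180 s of signal, and the
    theta/alpha/beta/low-gamma band set.  Tests pass smaller desk-scale
    values explicitly.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(STUDY_GROUP_SIZES))
    n_regions: int = 68
    fs: float = 1024.0
    duration_s: float = 180.0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    base_coupling: float = 0.0
    noise_sd: float = 1.0
    fc_mean: float = 0.3
    fc_sigma: float = 0.5
    covariate_model: dict = field(default_factory=default_covariate_model)
    seed: int = 0

    def __post_init__(self):
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 subjects "
                             "(within-group variance is otherwise inestimable)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        fmax = max(b.f_high for b in self.bands)
        # 2.5x margin above the Nyquist rate: the zero-phase band-pass needs
        # transition room below fs/2 for its stop-band to be meaningful
        if self.fs < 2.5 * fmax:
            raise ValueError(
                f"fs={self.fs} Hz too low for a band reaching {fmax} Hz "
                f"(needs margin above the Nyquist rate; require fs >= {2.5 * fmax} Hz)"
            )
        if not (0 < self.fc_mean < 1):
            raise ValueError("fc_mean must be in (0, 1)")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def band_by_name(self, name: str) -> BandDefinition:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(f"effect references unknown band {name!r}")


def _draw_covariate(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    kind = spec[0]
    if kind == "normal":
        return rng.normal(spec[1], spec[2], n)
    if kind == "truncnormal":
        return np.abs(rng.normal(spec[1], spec[2], n))
    if kind == "bernoulli":
        return rng.binomial(1, spec[1], n).astype(float)
    raise ValueError(f"unknown covariate distribution {kind!r}")


def _make_cohort(cfg: SimulationConfig, rng: np.random.Generator) -> CohortTable:
    groups, ids = [], []
    for g, n in cfg.group_sizes.items():
        start = len(ids)
        groups.extend([g] * n)
        ids.extend(f"S{start + i:03d}" for i in range(n))
    df = pd.DataFrame({"group": groups}, index=pd.Index(ids, name="subject_id"))
    for name, spec in cfg.covariate_model.items():
        df[name] = _draw_covariate(rng, spec, cfg.n_subjects)
    return CohortTable(table=df, group_levels=list(cfg.group_sizes))


def _narrowband_source(rng: np.random.Generator, band: BandDefinition,
                       fs: float, n: int, shape: tuple) -> np.ndarray:
    """Unit-variance stochastic narrowband processes (filtered white noise)."""
    white = rng.standard_normal(shape + (n,))
    ts = RegionTimeSeries("_src", fs, white.reshape(-1, n))
    out = bandpass(ts, band).data
    out /= out.std(axis=-1, keepdims=True)
    return out.reshape(shape + (n,))


def simulate_timeseries(
    cfg: SimulationConfig, effects: list[PlantedEffect] | None = None
) -> tuple[list[RegionTimeSeries], CohortTable]:
    """Generate region-level signals with planted phase-lagged coupling.

    Each region signal is a sum over bands of its own narrowband oscillator
    plus, on planted edges, a shared narrowband latent source added to one
    region directly and to the other with a constant phase lag; white noise
    of sd ``cfg.noise_sd`` is superimposed.  The coupling strength for a
    subject in group g on a planted edge is
    ``cfg.base_coupling + group_deltas.get(g, 0)``.

    Deterministic given ``cfg.seed``.
    """
    effects = effects or []
    for eff in effects:
        cfg.band_by_name(eff.band)
        for i, j in eff.edges:
            if j >= cfg.n_regions:
                raise ValueError(f"edge ({i}, {j}) outside {cfg.n_regions} regions")
    rng = np.random.default_rng([cfg.seed, 1])  # stream disjoint from direct mode
    cohort = _make_cohort(cfg, rng)
    n_samp = int(round(cfg.duration_s * cfg.fs))
    subjects = []
    for sid, grp in zip(cohort.subjects, cohort.groups()):
        data = cfg.noise_sd * rng.standard_normal((cfg.n_regions, n_samp))
        for band in cfg.bands:
            data += _narrowband_source(rng, band, cfg.fs, n_samp, (cfg.n_regions,))
        for eff in effects:
            band = cfg.band_by_name(eff.band)
            coupling = cfg.base_coupling + eff.group_deltas.get(grp, 0.0)
            if coupling < 0:
                raise ValueError("net coupling strength below zero; "
                                 "group_deltas must be >= -base_coupling")
            if coupling == 0:
                continue
            for i, j in eff.edges:
                src = _narrowband_source(rng, band, cfg.fs, n_samp, ())[None, :]
                shifted = (analytic_signal(src) * np.exp(-1j * eff.phase_lag)).real
                data[i] += coupling * src[0]
                data[j] += coupling * shifted[0]
        subjects.append(RegionTimeSeries(sid, cfg.fs, data))
    return subjects, cohort


def simulate_fc_directly(
    cfg: SimulationConfig, effects: list[PlantedEffect] | None = None
) -> tuple[FCBundle, CohortTable]:
    """Draw static FC matrices directly from a logit-normal edge law.

    Every edge weight is ``expit(logit(m) + fc_sigma * z)`` with standard
    normal ``z``; the location ``m`` is ``cfg.fc_mean`` everywhere except on
    planted edges, where it is shifted by the group's delta on the [0, 1]
    scale.  Weights are independent across edges and subjects, which makes
    this the reference null model for permutation-calibration runs.

    Deterministic given ``cfg.seed``.
    """
    effects = effects or []
    rng = np.random.default_rng([cfg.seed, 2])
    cohort = _make_cohort(cfg, rng)
    r = cfg.n_regions
    iu = np.triu_indices(r, 1)
    n_edges = len(iu[0])
    edge_lookup = {(int(i), int(j)): e for e, (i, j) in enumerate(zip(*iu))}
    bands = [b.name for b in cfg.bands]

    # per-band location maps per group
    loc = {}
    for band in bands:
        for g in cfg.group_sizes:
            m = np.full(n_edges, cfg.fc_mean)
            for eff in effects:
                if eff.band != band:
                    continue
                delta = eff.group_deltas.get(g, 0.0)
                for edge in eff.edges:
                    if edge not in edge_lookup:
                        raise ValueError(f"edge {edge} outside {r} regions")
                    target = cfg.fc_mean + delta
                    if not (0 < target < 1):
                        raise ValueError(
                            f"shift {delta:+g} pushes edge location {target:g} "
                            "outside (0, 1)"
                        )
                    m[edge_lookup[edge]] = target
            loc[(band, g)] = logit(m)

    matrices = {}
    for sid, grp in zip(cohort.subjects, cohort.groups()):
        for band in bands:
            w = expit(loc[(band, grp)] + cfg.fc_sigma * rng.standard_normal(n_edges))
            mat = np.zeros((r, r))
            mat[iu] = w
            mat += mat.T
            matrices[(sid, band)] = mat
    bundle = FCBundle(
        subjects=cohort.subjects,
        bands=bands,
        matrices=matrices,
        manifest={"source": "simulate_fc_directly", "seed": cfg.seed},
    )
    return bundle, cohort


def attach_hormone(
    cohort: CohortTable,
    mnc: np.ndarray,
    r_target: float,
    noise_sd: float = 1.0,
    seed: int = 0,
    covariate_names: list[str] | None = None,
    name: str = "hormone",
    intercept: float = 0.0,
) -> CohortTable:
    """Add a hormone-like column with a calibrated partial correlation.

    The column is ``intercept + b * r(mnc) + eps`` where ``r(mnc)`` is mnc
    residualized on the covariates (or just centered when none are given),
    ``eps`` is Gaussian noise of sd ``noise_sd``, and ``b`` is chosen so the
    partial Pearson correlation between the hormone and mnc given the
    covariates equals ``r_target`` at the population level.

    Deterministic given ``seed``.  Returns a new CohortTable.
    """
    if not (-1 < r_target < 1):
        raise ValueError("r_target must lie strictly inside (-1, 1)")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    mnc = np.asarray(mnc, dtype=float)
    if len(mnc) != cohort.n:
        raise ValueError("mnc vector must align with cohort subjects")
    if covariate_names:
        c = np.column_stack([np.ones(cohort.n), cohort.covariate_matrix(covariate_names)])
    else:
        c = np.ones((cohort.n, 1))
    beta, *_ = np.linalg.lstsq(c, mnc, rcond=None)
    resid = mnc - c @ beta
    s = resid.std(ddof=1)
    if s <= 0:
        raise ValueError("mnc has no residual variance after covariate adjustment")
    b = r_target * noise_sd / (s * math.sqrt(1 - r_target**2))
    # stream keyed away from the cohort generators so reusing one study seed
    # across stages cannot alias the noise with a covariate draw
    rng = np.random.default_rng([seed, 3])
    hormone = intercept + b * resid + noise_sd * rng.standard_normal(cohort.n)
    table = cohort.table.copy()
    table[name] = hormone
    return CohortTable(table=table, group_levels=list(cohort.group_levels))
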