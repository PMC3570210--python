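"""Synthetic single-cell qPCR plates from the hurdle generative model.

Each gene j carries an expression frequency ``pi_j`` and a conditional
positive-et distribution N(mu_j, sigma_j^2) truncated to et > 0 (the
log-normal model's support; with the default parameter ranges the truncated
mass is negligible, and the configuration validator warns when mu < 4
sigma).  Wells are drawn independently: a detection indicator per gene,
then a positive et where detected.  On top of the clean model the generator
can inject

* empty wells — no cell loaded, every gene undetected;
* contaminated wells — a constant et inflation added to every expressed
  gene of the well, mimicking template contamination amplified through PCR;
* n-cell aggregate wells — the abundances of n independently simulated
  cells summed on the linear scale and re-logged, the physical composition
  of pooled mRNA.

Everything is driven by one root seed; per unit x group sub-streams are
spawned from it so partial re-simulation stays reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from .core_data import ConfigError, EtMatrix, concat_wells

__all__ = [
    "SimConfig",
    "simulate_plate",
    "simulate_aggregates",
    "simulate_two_group",
    "simulate_bundle",
    "aggregate_et_from_cells",
    "canonical_plate_config",
    "canonical_bundle_config",
    "contaminated_bundle_config",
]

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study design and gene-level parameters for one simulated experiment.

    Gene parameters may be given explicitly (``pi``, ``mu``, ``sigma``
    arrays of length ``m``) or sampled uniformly from the ``*_range``
    bounds.  ``dpi``/``dmu`` are per-gene group-1 effects for two-group
    designs.  Fractions refer to single-cell wells per unit x group.
    """

    m: int = 96
    n_wells: int = 96
    units: int = 1
    pi: Optional[Sequence[float]] = None
    mu: Optional[Sequence[float]] = None
    sigma: Optional[Sequence[float]] = None
    pi_range: tuple = (0.05, 0.9)
    mu_range: tuple = (10.0, 30.0)
    sigma_range: tuple = (1.0, 3.0)
    dpi: Optional[Sequence[float]] = None
    dmu: Optional[Sequence[float]] = None
    aggregate_cells: int = 100
    aggregate_reps: int = 2
    contamination_fraction: float = 0.0
    contamination_shift: float = 6.0
    empty_fraction: float = 0.0
    ct_max: float = 40.0
    seed: int = 0

    def validate(self) -> None:
        if self.m < 1 or self.n_wells < 1 or self.units < 1:
            raise ConfigError("m, n_wells and units must be >= 1")
        if self.aggregate_cells < 2:
            raise ConfigError("aggregate_cells must be >= 2")
        for name in ("contamination_fraction", "empty_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        if self.ct_max <= 0:
            raise ConfigError("ct_max must be positive")
        for name, arr in (("pi", self.pi), ("mu", self.mu), ("sigma", self.sigma),
                          ("dpi", self.dpi), ("dmu", self.dmu)):
            if arr is not None and len(arr) != self.m:
                raise ConfigError(f"{name} must have length m={self.m}")
        if self.pi is not None:
            p = np.asarray(self.pi, float)
            if np.any((p < 0) | (p > 1)):
                raise ConfigError("pi must lie in [0, 1]")
            if self.dpi is not None and np.any((p + np.asarray(self.dpi)) < 0) or (
                self.dpi is not None and np.any((p + np.asarray(self.dpi)) > 1)
            ):
                raise ConfigError("pi + dpi must lie in [0, 1]")
        if self.sigma is not None and np.any(np.asarray(self.sigma, float) <= 0):
            raise ConfigError("sigma must be positive")


def _gene_params(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve (pi, mu, sigma) arrays; sampling uses a dedicated sub-stream
    so the same config always describes the same genes."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xA11E]))
    m = config.m
    pi = np.asarray(config.pi, float) if config.pi is not None else rng.uniform(*config.pi_range, m)
    mu = np.asarray(config.mu, float) if config.mu is not None else rng.uniform(*config.mu_range, m)
    sg = np.asarray(config.sigma, float) if config.sigma is not None else rng.uniform(*config.sigma_range, m)
    # truncated mass P(N(mu, sigma^2) <= 0) above 1e-3 biases positive-part moments
    if np.any(mu / sg < 3.0902):
        warnings.warn(
            "some genes have mu close to 0 relative to sigma: the et > 0 "
            "truncation is no longer negligible and positive-part moments "
            "will be biased",
            stacklevel=2,
        )
    return pi, mu, sg


def _positive_et(rng: np.random.Generator, mu: np.ndarray, sigma: np.ndarray,
                 shape: tuple) -> np.ndarray:
    """Draw positive et values ~ N(mu, sigma^2) truncated to (0, inf),
    broadcast over genes on the last axis.

    Rejection sampling (redraw non-positive values) is exact and fast when
    the truncated mass is small; scipy's truncnorm takes over for heavily
    truncated genes where rejection would be wasteful.
    """
    a = (0.0 - np.asarray(mu, float)) / np.asarray(sigma, float)
    if np.any(a > -1.2816):  # > ~10% truncated
        return truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=shape, random_state=rng)
    mu_b = np.broadcast_to(np.asarray(mu, float), shape)
    sigma_b = np.broadcast_to(np.asarray(sigma, float), shape)
    x = rng.normal(mu_b, sigma_b)
    bad = x <= 0
    while bad.any():
        x[bad] = rng.normal(mu_b[bad], sigma_b[bad])
        bad = x <= 0
    return x


def _simulate_cells(
    rng: np.random.Generator,
    n: int,
    pi: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
) -> np.ndarray:
    """n independent single cells x m genes of et values."""
    m = pi.size
    u = rng.random((n, m)) < pi
    et = np.where(u, _positive_et(rng, mu, sigma, (n, m)), 0.0)
    return et


def _unit_names(config: SimConfig) -> list[str]:
    return [f"u{k}" for k in range(config.units)]


def _stream(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *key]))


def simulate_plate(config: SimConfig, group: str = "g0") -> EtMatrix:
    """Single-cell wells for every unit, with empty/contaminated injection.

    The returned matrix's ``meta`` records the true gene parameters and the
    ids of injected empty and contaminated wells for downstream evaluation.
    """
    config.validate()
    pi, mu, sigma = _gene_params(config)
    parts, empty_ids, contam_ids = [], [], []
    for k, unit in enumerate(_unit_names(config)):
        rng = _stream(config, 1, k, 0 if group == "g0" else 1)
        et = _simulate_cells(rng, config.n_wells, pi, mu, sigma)
        n_empty = int(round(config.empty_fraction * config.n_wells))
        n_contam = int(round(config.contamination_fraction * config.n_wells))
        special = rng.choice(config.n_wells, size=n_empty + n_contam, replace=False)
        empty, contam = special[:n_empty], special[n_empty:]
        et[empty] = 0.0
        et[contam] = np.where(et[contam] > 0, et[contam] + config.contamination_shift, 0.0)
        et = np.minimum(et, config.ct_max)
        well_ids = [f"{unit}-{group}-w{i}" for i in range(config.n_wells)]
        empty_ids += [well_ids[i] for i in empty]
        contam_ids += [well_ids[i] for i in contam]
        parts.append(
            EtMatrix(
                et=et,
                well_ids=well_ids,
                gene_ids=[f"gene{j}" for j in range(config.m)],
                cells_per_well=np.ones(config.n_wells, dtype=int),
                unit=[unit] * config.n_wells,
                group=[group] * config.n_wells,
                ct_max=config.ct_max,
            )
        )
    out = concat_wells(parts)
    out.meta.update(
        {
            "pi": pi,
            "mu": mu,
            "sigma": sigma,
            "empty_wells": empty_ids,
            "contaminated_wells": contam_ids,
        }
    )
    return out


def aggregate_et_from_cells(abundances: np.ndarray, ct_max: float = 40.0) -> float:
    """et of one aggregate well from its constituent cells' abundances.

    Pooled mRNA adds on the linear scale, so the aggregate abundance is the
    sum; the well records ``log2(sum)`` clipped to (0, ct_max], or 0
    (undetected) when every constituent cell is unexpressed.
    """
    total = float(np.sum(abundances))
    if total <= 0:
        return 0.0
    return float(np.clip(np.log2(total), np.nextafter(0, 1), ct_max))


def simulate_aggregates(config: SimConfig, group: str = "g0") -> EtMatrix:
    """Multi-cell aggregate wells: ``aggregate_reps`` wells per unit, each
    pooling ``aggregate_cells`` independently simulated cells per gene."""
    config.validate()
    pi, mu, sigma = _gene_params(config)
    parts = []
    for k, unit in enumerate(_unit_names(config)):
        rng = _stream(config, 2, k)
        et_agg = np.zeros((config.aggregate_reps, config.m))
        for r in range(config.aggregate_reps):
            cells = _simulate_cells(rng, config.aggregate_cells, pi, mu, sigma)
            y = np.where(cells > 0, np.exp2(cells), 0.0).sum(axis=0)
            et_agg[r] = [aggregate_et_from_cells([t], config.ct_max) for t in y]
        parts.append(
            EtMatrix(
                et=et_agg,
                well_ids=[f"{unit}-{group}-agg{r}" for r in range(config.aggregate_reps)],
                gene_ids=[f"gene{j}" for j in range(config.m)],
                cells_per_well=np.full(config.aggregate_reps, config.aggregate_cells, dtype=int),
                unit=[unit] * config.aggregate_reps,
                group=[group] * config.aggregate_reps,
                ct_max=config.ct_max,
            )
        )
    return concat_wells(parts)


def simulate_two_group(config: SimConfig, groups: tuple = ("g0", "g1")) -> EtMatrix:
    """Paired two-group design: within every unit, group 0 wells from
    (pi_j, mu_j) and group 1 wells from (pi_j + dpi_j, mu_j + dmu_j), with
    sigma_j shared."""
    config.validate()
    pi, mu, sigma = _gene_params(config)
    dpi = np.zeros(config.m) if config.dpi is None else np.asarray(config.dpi, float)
    dmu = np.zeros(config.m) if config.dmu is None else np.asarray(config.dmu, float)
    pi1 = pi + dpi
    if np.any((pi1 < 0) | (pi1 > 1)):
        raise ConfigError("pi + dpi must lie in [0, 1]")
    parts = []
    for k, unit in enumerate(_unit_names(config)):
        for g, (p, m_, label) in enumerate(((pi, mu, groups[0]), (pi1, mu + dmu, groups[1]))):
            rng = _stream(config, 1, k, g)
            et = np.minimum(_simulate_cells(rng, config.n_wells, p, m_, sigma), config.ct_max)
            parts.append(
                EtMatrix(
                    et=et,
                    well_ids=[f"{unit}-{label}-w{i}" for i in range(config.n_wells)],
                    gene_ids=[f"gene{j}" for j in range(config.m)],
                    cells_per_well=np.ones(config.n_wells, dtype=int),
                    unit=[unit] * config.n_wells,
                    group=[label] * config.n_wells,
                    ct_max=config.ct_max,
                )
            )
    out = concat_wells(parts)
    out.meta.update({"pi": pi, "mu": mu, "sigma": sigma, "dpi": dpi, "dmu": dmu})
    return out


def simulate_bundle(config: SimConfig) -> EtMatrix:
    """Single-cell wells plus aggregate wells in one matrix (the layout the
    concordance module consumes)."""
    sc = simulate_plate(config)
    agg = simulate_aggregates(config)
    out = concat_wells([sc, agg])
    out.meta.update(sc.meta)
    return out


def simulate_null_batch(
    reps: int,
    n_per_group: int,
    pi: float,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
    positive: str = "normal",
) -> tuple[np.ndarray, np.ndarray]:
    """Replicated null two-group datasets for LRT calibration studies.

    Returns two ``(reps, n_per_group)`` arrays of et values drawn from the
    same hurdle parameters in both groups.  ``positive`` selects the
    positive-part generator: ``"normal"`` (the model) or ``"t"`` — a
    shifted, scaled Student t with 5 df and standard deviation ``sigma``,
    for probing robustness of the chi-square reference to heavy tails.
    Truncation at zero is not applied; calibration settings keep mu many
    sigma above zero, where it is vacuous.
    """
    if positive == "normal":
        draw = lambda shape: mu + sigma * rng.standard_normal(shape)
    elif positive == "t":
        scale = sigma / np.sqrt(5.0 / 3.0)
        draw = lambda shape: mu + scale * rng.standard_t(5, shape)
    else:
        raise ConfigError(f"positive must be 'normal' or 't', got {positive!r}")
    out = []
    for _ in range(2):
        u = rng.random((reps, n_per_group)) < pi
        out.append(np.where(u, draw((reps, n_per_group)), 0.0))
    return out[0], out[1]


def canonical_plate_config(seed: int = 0) -> SimConfig:
    """The canonical 96 x 96 single-cell plate (9216 reactions)."""
    return SimConfig(m=96, n_wells=96, units=1, seed=seed)


def canonical_bundle_config(seed: int = 0) -> SimConfig:
    """Clean concordance bundle: 4 units x 100 single-cell wells plus two
    100-cell aggregate wells per unit."""
    return SimConfig(m=96, n_wells=100, units=4, aggregate_cells=100,
                     aggregate_reps=2, seed=seed)


def contaminated_bundle_config(seed: int = 0) -> SimConfig:
    """Contaminated concordance bundle for QC evaluation.

    5% of single-cell wells receive a +15-cycle et inflation on their
    expressed genes — gross pre-amplification contamination, which the
    exponential chemistry turns into a ~30,000-fold abundance error — and
    20% of wells are empty, stressing the null-well-first filtering order.
    """
    return SimConfig(
        m=96, n_wells=100, units=4, aggregate_cells=100, aggregate_reps=2,
        contamination_fraction=0.05, contamination_shift=15.0,
        empty_fraction=0.2, seed=seed,
    )
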