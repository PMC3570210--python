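"""Concordance between in-silico single-cell averages and multi-cell wells.

Plates that carry both single-cell wells and n-cell aggregate wells (e.g.
100 cells pooled into one reaction) allow a fidelity check: the average
abundance over single-cell wells of a unit ("in silico" average, zeros
included) should agree with the aggregate well's abundance divided by its
cell count ("in vitro" per-cell average).  Agreement is quantified by Lin's
concordance correlation coefficient rho_c on the shifted-log scale and by a
weighted squared deviance D, which doubles as the objective for tuning the
QC filtering thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    ConfigError,
    EtMatrix,
    ValidationError,
    abundance_from_et,
    concat_wells,
    shifted_log,
    subset_wells,
)
from .qc import filter_wells

__all__ = [
    "ConcordancePair",
    "insilico_average",
    "invitro_average",
    "build_pairs",
    "ccc",
    "concordance_ccc",
    "weighted_deviance",
    "tune_thresholds",
    "TuneResult",
    "DEFAULT_THRESHOLD_GRID",
    "pairs_to_frame",
]

logger = logging.getLogger(__name__)

#: default filter-threshold grid swept by tune_thresholds, on both axes
DEFAULT_THRESHOLD_GRID = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 12.0, 15.0)


@dataclass(frozen=True)
class ConcordancePair:
    """One gene x unit comparison point.

    ``n_pos`` is the *ex-ante* number of positive single-cell wells (counted
    before any filtering); it is the weight in the deviance D.
    """

    gene: str
    unit: str
    insilico_avg: float
    invitro_avg: float
    n_pos: int


def _single_mask(et: EtMatrix) -> np.ndarray:
    return et.cells_per_well == 1


def insilico_average(et: EtMatrix, gene: str, unit: str, treat_undetected: str = "zero") -> float:
    """Mean abundance over a unit's single-cell wells for one gene.

    ``treat_undetected="zero"`` includes unexpressed wells as exact zeros
    (the recommended convention); ``"missing"`` averages positive wells
    only, reproducing the treat-undetected-as-missing comparison.  Returns
    NaN when no well (or, in missing mode, no positive well) is available.
    """
    if treat_undetected not in ("zero", "missing"):
        raise ConfigError(f"treat_undetected must be 'zero' or 'missing', got {treat_undetected!r}")
    mask = _single_mask(et) & (et.unit == str(unit))
    if not mask.any():
        return float("nan")
    y = abundance_from_et(et.et[mask, et.gene_index(gene)])
    if treat_undetected == "missing":
        y = y[y > 0]
        if y.size == 0:
            return float("nan")
    return float(y.mean())


def invitro_average(et: EtMatrix, gene: str, unit: str) -> float:
    """Per-cell abundance from a unit's aggregate (multi-cell) wells.

    Each aggregate well's abundance is divided by its cell count; several
    aggregate wells are averaged after per-cell scaling.  An undetected
    aggregate contributes 0.  Returns NaN without aggregate wells.
    """
    mask = (et.cells_per_well > 1) & (et.unit == str(unit))
    if not mask.any():
        return float("nan")
    y = abundance_from_et(et.et[mask, et.gene_index(gene)])
    return float((y / et.cells_per_well[mask]).mean())


def build_pairs(
    et: EtMatrix,
    treat_undetected: str = "zero",
    exante: EtMatrix | None = None,
) -> list[ConcordancePair]:
    """All gene x unit pairs with both single-cell and aggregate wells.

    ``exante`` supplies the unfiltered matrix whose positive single-cell
    well counts become the weights; it defaults to ``et`` itself (no
    filtering applied yet).
    """
    if exante is None:
        exante = et
    pairs: list[ConcordancePair] = []
    single = _single_mask(et)
    agg = ~single
    units = [u for u in pd.unique(et.unit) if ((et.unit == u) & agg).any()]
    ex_single = _single_mask(exante)
    for unit in units:
        u_single = single & (et.unit == unit)
        u_agg = agg & (et.unit == unit)
        y_single = abundance_from_et(et.et[u_single])
        y_agg = abundance_from_et(et.et[u_agg]) / et.cells_per_well[u_agg][:, None]
        ex_mask = ex_single & (exante.unit == unit)
        n_pos = (exante.et[ex_mask] > 0).sum(axis=0)
        if treat_undetected == "zero":
            # empty unit after filtering reads as zero expression
            insilico = y_single.mean(axis=0) if u_single.any() else np.zeros(et.n_genes)
        elif treat_undetected == "missing":
            with np.errstate(invalid="ignore"):
                npos_now = (y_single > 0).sum(axis=0)
                insilico = np.where(
                    npos_now > 0,
                    y_single.sum(axis=0) / np.maximum(npos_now, 1),
                    np.nan,
                )
        else:
            raise ConfigError(f"treat_undetected must be 'zero' or 'missing', got {treat_undetected!r}")
        invitro = y_agg.mean(axis=0)
        for j, gene in enumerate(et.gene_ids):
            pairs.append(
                ConcordancePair(
                    gene=str(gene),
                    unit=str(unit),
                    insilico_avg=float(insilico[j]),
                    invitro_avg=float(invitro[j]),
                    n_pos=int(n_pos[j]),
                )
            )
    return pairs


def ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient (population moments).

    rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2).
    Penalizes both decorrelation and location/scale shift; NaN when the
    denominator vanishes (both inputs constant with equal means).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("ccc needs two equal-length vectors of size >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("ccc inputs must be finite")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = float(np.mean((x - mx) * (y - my)))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return float("nan")
    return float(2.0 * cov / denom)


def concordance_ccc(pairs: Iterable[ConcordancePair]) -> float:
    """rho_c between in-silico and in-vitro averages on the shifted-log scale.

    Pairs with a NaN average (possible in missing mode) are dropped first.
    """
    pts = [(p.insilico_avg, p.invitro_avg) for p in pairs
           if np.isfinite(p.insilico_avg) and np.isfinite(p.invitro_avg)]
    if len(pts) < 2:
        return float("nan")
    x, y = np.asarray(pts).T
    return ccc(shifted_log(x), shifted_log(y))


def weighted_deviance(pairs: Iterable[ConcordancePair]) -> float:
    """Weighted mean squared in-silico/in-vitro gap, shifted-log scale.

    D = sum_jk n_pos * (slog(insilico) - slog(invitro))^2 / sum_jk n_pos,
    with ex-ante positive-well counts as weights so gene x unit combinations
    with more expressed cells count more; the shifted-log scale damps
    extreme outliers.  NaN-averaged pairs are excluded; all-zero weights
    give NaN.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("weighted_deviance needs at least one pair")
    w, gap2 = [], []
    for p in pairs:
        if not (np.isfinite(p.insilico_avg) and np.isfinite(p.invitro_avg)):
            continue
        w.append(p.n_pos)
        gap2.append((shifted_log(p.insilico_avg) - shifted_log(p.invitro_avg)) ** 2)
    w = np.asarray(w, dtype=float)
    if w.sum() == 0:
        return float("nan")
    return float(np.average(np.asarray(gap2), weights=w))


def pairs_to_frame(pairs: Iterable[ConcordancePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": p.gene,
                "unit": p.unit,
                "insilico": p.insilico_avg,
                "invitro": p.invitro_avg,
                "weight": p.n_pos,
            }
            for p in pairs
        ]
    )


@dataclass(frozen=True)
class TuneResult:
    k_z: float
    k_zeta: float
    deviance: float
    surface: pd.DataFrame  # columns k_z, k_zeta, deviance


def tune_thresholds(
    et: EtMatrix,
    grid_z: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    grid_zeta: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> TuneResult:
    """Pick filter thresholds minimizing the weighted deviance D.

    For every (k_z, k_zeta) grid point the single-cell wells are filtered,
    pairs are rebuilt against the (unfiltered) aggregate wells with ex-ante
    weights, and D recomputed.  Ties are broken toward the largest (most
    permissive) thresholds so that, absent contamination, no data are
    discarded.
    """
    grid_z = list(grid_z)
    grid_zeta = list(grid_zeta)
    if not grid_z or not grid_zeta:
        raise ConfigError("threshold grids must be non-empty")
    single = _single_mask(et)
    if not single.any() or single.all():
        raise ConfigError("tune_thresholds needs both single-cell and aggregate wells")
    sc = subset_wells(et, single)
    agg = subset_wells(et, ~single)

    rows = []
    best = None
    for kz in sorted(grid_z):
        for kzeta in sorted(grid_zeta):
            filtered, _ = filter_wells(sc, k_z=kz, k_zeta=kzeta)
            pairs = build_pairs(concat_wells([filtered, agg]), exante=et)
            d = weighted_deviance(pairs)
            rows.append({"k_z": kz, "k_zeta": kzeta, "deviance": d})
            # >= so later (larger, more permissive) grid points win ties
            if best is None or d <= best[2]:
                best = (kz, kzeta, d)
    surface = pd.DataFrame(rows)
    logger.info("tune_thresholds: best D=%.4g at k_z=%g, k_zeta=%g", best[2], best[0], best[1])
    return TuneResult(k_z=best[0], k_zeta=best[1], deviance=best[2], surface=surface)
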