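"""Outlier detection and well filtering for single-cell qPCR plates.

Because PCR amplifies exponentially, even minute contamination of a well can
inflate its measurements by many cycles, and empty wells (no cell loaded)
read as all-undetected.  Two robust scores screen for both failure modes:

* ``z_ij``: per gene, the robust z-score of the positive et values, using
  the median and MAD (scaled by c = 1.4826 so the MAD estimates a normal
  standard deviation).  Flags wells with extreme expression *levels*.
* ``zeta_i``: per well, the robust z-score of the arcsine-square-root
  variance-stabilized fraction of genes detected.  Flags wells with an
  extreme *proportion* of detected genes.

Filtering proceeds in a fixed order: null (all-undetected) wells are removed
first so they cannot break the median/MAD estimates behind zeta, then any
well with |z| beyond ``k_z`` in some gene, or |zeta| beyond ``k_zeta``, is
dropped whole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import EtMatrix, ValidationError, subset_wells

__all__ = [
    "MAD_SCALE",
    "QcReport",
    "robust_z_positive",
    "zeta_scores",
    "filter_wells",
    "housekeeper_r2",
]

logger = logging.getLogger(__name__)

#: 1 / Phi^{-1}(3/4): rescales the MAD to a normal standard deviation
MAD_SCALE = 1.4826

#: reason codes used in QcReport.flagged
REASON_NULL = "null"
REASON_Z = "z-outlier"
REASON_ZETA = "zeta-outlier"


def _robust_z(values: np.ndarray) -> np.ndarray:
    """Robust z against median/MAD; MAD = 0 maps ties to 0, others to +/-inf."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        out = np.where(values == med, 0.0, np.inf)
        return np.copysign(out, values - med)
    return (values - med) / (MAD_SCALE * mad)


def robust_z_positive(et_column: np.ndarray, min_positive: int = 3) -> np.ndarray:
    """Robust z-scores of one gene's positive et values.

    Returns an array aligned with the input; entries are NaN where et = 0
    (the score is only defined on expressed wells) and everywhere when the
    gene has fewer than ``min_positive`` expressed wells (median/MAD too
    unstable to score).
    """
    col = np.asarray(et_column, dtype=float)
    out = np.full(col.shape, np.nan)
    pos = col > 0
    if pos.sum() < min_positive:
        return out
    out[pos] = _robust_z(col[pos])
    return out


def zeta_scores(et: EtMatrix) -> np.ndarray:
    """Robust z of the variance-stabilized detected-gene fraction per well.

    ``p_i`` is the fraction of the panel detected in well i,
    ``f_i = arcsin(sqrt(p_i))`` its variance-stabilizing transform, and
    zeta_i the robust z of f across wells.  Callers must remove null wells
    first; a plate with null wells still present would drag the median/MAD
    toward zero and mask genuine outliers.
    """
    p = et.detected.mean(axis=1)
    f = np.arcsin(np.sqrt(p))
    return _robust_z(f)


@dataclass
class QcReport:
    """Per-well audit trail of the filtering pass."""

    z_scores: pd.DataFrame
    zeta: pd.Series
    null_wells: list
    flagged: dict  # well_id -> sorted list of reason codes
    thresholds: tuple  # (k_z, k_zeta)

    @property
    def removed_wells(self) -> list:
        return sorted(self.flagged)

    def to_frame(self) -> pd.DataFrame:
        """One row per input well: zeta, worst |z|, reasons (CSV-ready)."""
        rows = []
        for well in list(self.z_scores.index) + self.null_wells:
            if well in self.z_scores.index:
                worst = np.nanmax(np.abs(self.z_scores.loc[well].to_numpy()), initial=np.nan)
                zeta = self.zeta.loc[well]
            else:
                worst, zeta = np.nan, np.nan
            rows.append(
                {
                    "well_id": well,
                    "zeta": zeta,
                    "worst_abs_z": worst,
                    "reasons": ";".join(self.flagged.get(well, [])),
                }
            )
        return pd.DataFrame(rows)


def filter_wells(
    et: EtMatrix,
    k_z: float = 9.0,
    k_zeta: float = 9.0,
    min_positive: int = 3,
) -> tuple[EtMatrix, QcReport]:
    """Remove null, contaminated and otherwise outlying wells.

    Steps: (1) drop wells with no detected genes; (2-3) compute z and zeta
    on the remainder; (4) drop wells with any |z_ij| > k_z or |zeta_i| >
    k_zeta.  Retained et values are untouched (pure row selection).

    Intended for single-cell wells; multi-cell aggregate wells should be
    split off before filtering.
    """
    if k_z <= 0 or k_zeta <= 0:
        raise ValidationError("thresholds must be positive")
    null_mask = ~et.detected.any(axis=1)
    null_wells = list(et.well_ids[null_mask])
    kept = subset_wells(et, ~null_mask)
    if kept.n_wells == 0:
        raise ValidationError("all wells null: no detected genes anywhere")

    z = np.column_stack(
        [robust_z_positive(kept.et[:, j], min_positive) for j in range(kept.n_genes)]
    )
    zeta = zeta_scores(kept)

    with np.errstate(invalid="ignore"):
        z_flag = np.nanmax(np.abs(z), axis=1, initial=0.0) > k_z
    zeta_flag = np.abs(zeta) > k_zeta

    flagged: dict = {w: [REASON_NULL] for w in null_wells}
    for i, well in enumerate(kept.well_ids):
        reasons = []
        if z_flag[i]:
            reasons.append(REASON_Z)
        if zeta_flag[i]:
            reasons.append(REASON_ZETA)
        if reasons:
            flagged[well] = reasons

    keep_mask = ~(z_flag | zeta_flag)
    retained = subset_wells(kept, keep_mask)
    logger.info(
        "filter_wells: %d null, %d z-flagged, %d zeta-flagged of %d wells",
        len(null_wells), int(z_flag.sum()), int(zeta_flag.sum()), et.n_wells,
    )
    report = QcReport(
        z_scores=pd.DataFrame(z, index=kept.well_ids, columns=kept.gene_ids),
        zeta=pd.Series(zeta, index=kept.well_ids),
        null_wells=null_wells,
        flagged=flagged,
        thresholds=(k_z, k_zeta),
    )
    return retained, report


def housekeeper_r2(et: EtMatrix, gene_a: str, gene_b: str, min_wells: int = 3) -> float:
    """Squared Pearson correlation of two genes over co-expressed wells.

    A diagnostic for whether housekeeping genes could normalize the plate:
    valid housekeepers should track each other (high R^2).  Returns NaN
    when fewer than ``min_wells`` wells express both genes.
    """
    a = et.gene_column(gene_a)
    b = et.gene_column(gene_b)
    both = (a > 0) & (b > 0)
    if both.sum() < min_wells:
        return float("nan")
    x, y = a[both], b[both]
    # guard constant columns: correlation undefined, but an exact affine
    # relation (incl. x == y) is perfect agreement
    if np.std(x) == 0 or np.std(y) == 0:
        return 1.0 if np.std(x) == np.std(y) == 0 else float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
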