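"""Plate-wide differential-expression screening.

Runs the combined hurdle LRT (and baselines: its Bernoulli and normal
components alone, and a Welch t-test on the zero-inflated et values) for
every gene within every biological unit, comparing two treatment groups.
P-values are adjusted per test by the Benjamini-Hochberg step-up procedure,
and the results can be summarized as discovery counts across an FDR grid or
as a signed -log10 p matrix (positive where the second group expresses
more) suitable for heatmapping.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import ConfigError, EtMatrix, ValidationError, split_by
from .hurdle import combined_lrt, permutation_pvalue

__all__ = [
    "run_screen",
    "ttest_zero_inflated",
    "bh_fdr",
    "discoveries_vs_fdr",
    "signed_logp",
    "KNOWN_TESTS",
]

logger = logging.getLogger(__name__)

KNOWN_TESTS = ("combined", "binomial", "normal", "ttest")


def ttest_zero_inflated(group0: np.ndarray, group1: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t-test on et values with zeros included.

    The naive baseline a bulk-expression analyst would reach for; it
    conflates frequency and level changes and is sensitive to single
    extreme wells.  Returns (nan, nan) when the pooled variance vanishes.
    """
    x0 = np.asarray(group0, dtype=float)
    x1 = np.asarray(group1, dtype=float)
    if x0.size < 2 or x1.size < 2:
        raise ValidationError("t-test needs >= 2 wells per group")
    if np.var(x0) == 0 and np.var(x1) == 0:
        if x0.mean() == x1.mean():
            return 0.0, 1.0
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(x0, x1, equal_var=False)
    return float(t), float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("need at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_screen(
    et: EtMatrix,
    group_pair: tuple,
    tests: Iterable[str] = KNOWN_TESTS,
    B: int = 0,
    seed=None,
) -> pd.DataFrame:
    """Test every gene within every unit for a two-group difference.

    One row per gene x unit x test with the statistic, raw and BH-adjusted
    p-value (adjusted within test, over the rows actually computed),
    direction and per-group positive-well counts.  Units missing either
    group label are skipped with a warning; genes with no expressed well in
    either group of a unit are skipped with a log message.  When ``B > 0``,
    hurdle tests whose expected expressed count is small additionally get a
    permutation p-value which replaces the asymptotic one for the combined
    test.
    """
    g0, g1 = str(group_pair[0]), str(group_pair[1])
    tests = list(tests)
    unknown = [t for t in tests if t not in KNOWN_TESTS]
    if unknown:
        raise ConfigError(f"unknown test(s) {unknown}; choose from {KNOWN_TESTS}")
    rng = np.random.default_rng(seed)

    rows = []
    for (unit,), sub in split_by(et, ["unit"]).items():
        in0 = sub.group == g0
        in1 = sub.group == g1
        if not in0.any() or not in1.any():
            logger.warning("unit %s lacks group %s; skipped", unit, g0 if not in0.any() else g1)
            continue
        et0_all, et1_all = sub.et[in0], sub.et[in1]
        for j, gene in enumerate(sub.gene_ids):
            x0, x1 = et0_all[:, j], et1_all[:, j]
            if not (x0 > 0).any() and not (x1 > 0).any():
                logger.info("gene %s unit %s: no expressed well in either group; skipped", gene, unit)
                continue
            res = combined_lrt(x0, x1)
            p_perm = None
            if B > 0 and res.small_sample_flag:
                p_perm = permutation_pvalue(x0, x1, B=B, seed=rng)
            base = {
                "gene": gene,
                "unit": unit,
                "group0": g0,
                "group1": g1,
                "direction": res.direction,
                "n_pos0": res.n_pos[0],
                "n_pos1": res.n_pos[1],
                "small_sample": res.small_sample_flag,
            }
            if "combined" in tests:
                rows.append({**base, "test": "combined",
                             "statistic": res.lambda_combined,
                             "p_raw": p_perm if p_perm is not None else res.p_asymptotic,
                             "p_source": "permutation" if p_perm is not None else "asymptotic"})
            if "binomial" in tests:
                rows.append({**base, "test": "binomial",
                             "statistic": res.lambda_binom,
                             "p_raw": _chi2_sf1(res.lambda_binom),
                             "p_source": "asymptotic"})
            if "normal" in tests:
                rows.append({**base, "test": "normal",
                             "statistic": res.lambda_normal,
                             "p_raw": _chi2_sf1(res.lambda_normal),
                             "p_source": "asymptotic"})
            if "ttest" in tests:
                t, p = ttest_zero_inflated(x0, x1)
                if math.isnan(p):
                    logger.info("gene %s unit %s: degenerate t-test; skipped", gene, unit)
                else:
                    rows.append({**base, "test": "ttest", "statistic": t,
                                 "p_raw": p, "p_source": "asymptotic"})

    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_raw"] = table["p_raw"].clip(lower=np.nextafter(0, 1), upper=1.0)
    table["p_adjusted"] = np.nan
    for t in tests:
        mask = table["test"] == t
        if mask.any():
            table.loc[mask, "p_adjusted"] = bh_fdr(table.loc[mask, "p_raw"].to_numpy())
    return table.reset_index(drop=True)


def _chi2_sf1(lam: float) -> float:
    from scipy.special import chdtrc

    return float(max(chdtrc(1, lam), np.nextafter(0, 1)))


def discoveries_vs_fdr(table: pd.DataFrame, fdr_grid: Sequence[float]) -> pd.DataFrame:
    """Discovery counts (rows with adjusted p <= threshold) per test per
    FDR level; the empirical analogue of a discoveries-versus-FDR curve."""
    out = []
    for t, sub in table.groupby("test"):
        for thr in fdr_grid:
            out.append({"test": t, "fdr": float(thr),
                        "discoveries": int((sub["p_adjusted"] <= thr).sum())})
    return pd.DataFrame(out)


def signed_logp(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed -log10 p matrix (genes x units) from the combined-test rows.

    Entries are ``-log10(p_raw) * direction``: positive where group 1
    expresses more.  Returns ``(matrix, tested)``; untested gene x unit
    cells hold 0 in the matrix and False in the mask.
    """
    sub = table[table["test"] == "combined"]
    if sub.empty:
        raise ValidationError("no combined-test rows in table")
    value = -np.log10(sub["p_raw"].to_numpy()) * sub["direction"].to_numpy()
    wide = (
        pd.DataFrame({"gene": sub["gene"], "unit": sub["unit"], "v": value})
        .pivot(index="gene", columns="unit", values="v")
    )
    mask = wide.notna()
    return wide.fillna(0.0), mask
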