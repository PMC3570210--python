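"""Data model for single-cell qPCR plates.

A Fluidigm-style microfluidic run produces a wells x genes matrix of
cycle-threshold (ct) values.  Lower ct means more starting template; a
reaction whose fluorescence never crosses the detection threshold within
``ct_max`` cycles is recorded as undetected.  Downstream analysis works on
the *expression threshold* ``et = ct_max - ct``, which is directly
proportional to log2 mRNA abundance (each PCR cycle doubles product), with
undetected reactions mapped to ``et = 0`` so that their abundance is exactly
zero.  Every other module in this package consumes :class:`EtMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchurdleError",
    "ConfigError",
    "ValidationError",
    "CtPlate",
    "EtMatrix",
    "read_ct_plate",
    "write_ct_plate",
    "write_et_matrix",
    "et_from_ct",
    "ct_from_et",
    "abundance_from_et",
    "shifted_log",
    "split_by",
    "subset_wells",
    "concat_wells",
]

#: annotation columns expected in a wide plate CSV, in canonical order
ANNOTATION_COLUMNS = ("well_id", "n_cells", "unit", "group")

#: sentinel written for undetected reactions
UNDETECTED_TOKEN = "N/A"

DEFAULT_CT_MAX = 40.0


class SchurdleError(Exception):
    """Base class for package errors."""


class ConfigError(SchurdleError):
    """Invalid configuration, missing columns/keys, malformed options."""


class ValidationError(SchurdleError):
    """Input data violates a structural invariant."""


def _as_str_array(labels: Sequence, name: str) -> np.ndarray:
    arr = np.asarray([str(x) for x in labels], dtype=object)
    return arr


def _check_unique(labels: np.ndarray, name: str) -> None:
    if len(set(labels)) != len(labels):
        dupes = pd.Series(labels).value_counts()
        dupes = list(dupes[dupes > 1].index)
        raise ValidationError(f"duplicate {name}: {dupes}")


@dataclass
class CtPlate:
    """Raw wells x genes ct matrix with per-well annotations.

    ``ct`` is a float array with NaN encoding undetected reactions; detected
    entries must satisfy ``0 < ct <= ct_max``.
    """

    ct: np.ndarray
    well_ids: np.ndarray
    gene_ids: np.ndarray
    cells_per_well: np.ndarray
    unit: np.ndarray
    group: np.ndarray
    ct_max: float = DEFAULT_CT_MAX

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        self.well_ids = _as_str_array(self.well_ids, "well_ids")
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cells_per_well = np.asarray(self.cells_per_well, dtype=int)
        self.unit = _as_str_array(self.unit, "unit")
        self.group = _as_str_array(self.group, "group")
        n, m = self.ct.shape
        for name, arr in [
            ("well_ids", self.well_ids),
            ("cells_per_well", self.cells_per_well),
            ("unit", self.unit),
            ("group", self.group),
        ]:
            if len(arr) != n:
                raise ValidationError(f"{name} length {len(arr)} != {n} wells")
        if len(self.gene_ids) != m:
            raise ValidationError(f"gene_ids length {len(self.gene_ids)} != {m} genes")
        _check_unique(self.well_ids, "well_ids")
        _check_unique(self.gene_ids, "gene_ids")
        if self.ct_max <= 0:
            raise ValidationError("ct_max must be positive")
        if np.any(self.cells_per_well < 1):
            raise ValidationError("cells_per_well must be >= 1")
        detected = ~np.isnan(self.ct)
        if np.any(self.ct[detected] <= 0):
            raise ValidationError("detected ct values must be positive")
        if np.any(self.ct[detected] > self.ct_max):
            raise ValidationError("detected ct values must be <= ct_max")

    @property
    def n_wells(self) -> int:
        return self.ct.shape[0]

    @property
    def n_genes(self) -> int:
        return self.ct.shape[1]


@dataclass
class EtMatrix:
    """Non-negative et values (``et = ct_max - ct``; 0 = undetected).

    ``meta`` carries optional simulation/provenance side information
    (e.g. true parameters and injected-outlier well ids for synthetic
    plates); it is never used by the statistical routines themselves.
    """

    et: np.ndarray
    well_ids: np.ndarray
    gene_ids: np.ndarray
    cells_per_well: np.ndarray
    unit: np.ndarray
    group: np.ndarray
    ct_max: float = DEFAULT_CT_MAX
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.et = np.asarray(self.et, dtype=float)
        self.well_ids = _as_str_array(self.well_ids, "well_ids")
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cells_per_well = np.asarray(self.cells_per_well, dtype=int)
        self.unit = _as_str_array(self.unit, "unit")
        self.group = _as_str_array(self.group, "group")
        if np.any(~np.isfinite(self.et)) or np.any(self.et < 0):
            raise ValidationError("et values must be finite and >= 0")
        _check_unique(self.well_ids, "well_ids")
        _check_unique(self.gene_ids, "gene_ids")
        if np.any(self.cells_per_well < 1):
            raise ValidationError("cells_per_well must be >= 1")

    @property
    def n_wells(self) -> int:
        return self.et.shape[0]

    @property
    def n_genes(self) -> int:
        return self.et.shape[1]

    @property
    def detected(self) -> np.ndarray:
        """Detection indicator u_ij = 1{et_ij > 0}."""
        return self.et > 0

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == str(gene))
        if idx.size == 0:
            raise ConfigError(f"unknown gene {gene!r}")
        return int(idx[0])

    def gene_column(self, gene: str) -> np.ndarray:
        return self.et[:, self.gene_index(gene)]

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: annotation columns then one column per gene."""
        df = pd.DataFrame(
            {
                "well_id": self.well_ids,
                "n_cells": self.cells_per_well,
                "unit": self.unit,
                "group": self.group,
            }
        )
        for j, g in enumerate(self.gene_ids):
            df[g] = self.et[:, j]
        return df


def et_from_ct(plate: CtPlate) -> EtMatrix:
    """Map ct to et: detected entries become ``ct_max - ct``, undetected 0.

    A detected reaction at exactly ``ct_max`` lands on et = 0, i.e. it is
    indistinguishable from undetected, matching the instrument convention
    that the maximum cycle is the detection bound.
    """
    et = np.where(np.isnan(plate.ct), 0.0, plate.ct_max - plate.ct)
    return EtMatrix(
        et=et,
        well_ids=plate.well_ids,
        gene_ids=plate.gene_ids,
        cells_per_well=plate.cells_per_well,
        unit=plate.unit,
        group=plate.group,
        ct_max=plate.ct_max,
    )


def ct_from_et(et: EtMatrix) -> CtPlate:
    """Inverse transform; et = 0 maps back to undetected (NaN ct)."""
    ct = np.where(et.et > 0, et.ct_max - et.et, np.nan)
    return CtPlate(
        ct=ct,
        well_ids=et.well_ids,
        gene_ids=et.gene_ids,
        cells_per_well=et.cells_per_well,
        unit=et.unit,
        group=et.group,
        ct_max=et.ct_max,
    )


def abundance_from_et(et):
    """Untransformed expression y = 2**et for et > 0, exactly 0 at et = 0.

    The map is discontinuous at 0 (limit from above is 1, value at 0 is 0);
    this is deliberate: an undetected reaction represents zero molecules,
    not one.  Detected reactions sit many cycles above the bound in
    practice, so the gap carries no data.
    """
    et_arr = np.asarray(et, dtype=float)
    if np.any(et_arr < 0):
        raise ValidationError("et must be >= 0")
    y = np.where(et_arr > 0, np.exp2(et_arr), 0.0)
    return float(y) if np.isscalar(et) else y


def shifted_log(y):
    """Shifted log transform log2(y + 1); maps 0 to 0.

    Used for display and for the weighted-deviance objective, so that zero
    expression stays at zero while large values return to the et scale.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0):
        raise ValidationError("abundance must be >= 0")
    out = np.log2(y_arr + 1.0)
    return float(out) if np.isscalar(y) else out


_SPLIT_KEYS = {"unit", "group", "n_cells"}


def subset_wells(et: EtMatrix, index) -> EtMatrix:
    """Pure row selection: a new EtMatrix over the given well indices/mask."""
    index = np.asarray(index)
    return EtMatrix(
        et=et.et[index],
        well_ids=et.well_ids[index],
        gene_ids=et.gene_ids,
        cells_per_well=et.cells_per_well[index],
        unit=et.unit[index],
        group=et.group[index],
        ct_max=et.ct_max,
        meta=dict(et.meta),
    )


def concat_wells(parts: Iterable[EtMatrix]) -> EtMatrix:
    parts = list(parts)
    if not parts:
        raise ConfigError("nothing to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if not np.array_equal(p.gene_ids, first.gene_ids):
            raise ValidationError("gene panels differ between parts")
        if p.ct_max != first.ct_max:
            raise ValidationError("ct_max differs between parts")
    meta: dict = {}
    for p in parts:
        meta.update(p.meta)
    return EtMatrix(
        et=np.vstack([p.et for p in parts]),
        well_ids=np.concatenate([p.well_ids for p in parts]),
        gene_ids=first.gene_ids,
        cells_per_well=np.concatenate([p.cells_per_well for p in parts]),
        unit=np.concatenate([p.unit for p in parts]),
        group=np.concatenate([p.group for p in parts]),
        ct_max=first.ct_max,
        meta=meta,
    )


def split_by(et: EtMatrix, keys: Sequence[str]) -> dict:
    """Partition wells by one or more annotations.

    Returns a mapping from annotation-value tuples to sub-matrices; the
    union of the parts is the input.
    """
    if isinstance(keys, str):
        keys = [keys]
    for k in keys:
        if k not in _SPLIT_KEYS:
            raise ConfigError(f"unknown split key {k!r}; expected one of {sorted(_SPLIT_KEYS)}")
    cols = {
        "unit": et.unit,
        "group": et.group,
        "n_cells": et.cells_per_well.astype(str),
    }
    labels = list(zip(*(cols[k] for k in keys)))
    out: dict = {}
    order = {}
    for i, lab in enumerate(labels):
        order.setdefault(lab, []).append(i)
    for lab, idx in order.items():
        out[lab] = subset_wells(et, np.asarray(idx))
    return out


def read_ct_plate(
    path,
    *,
    delimiter: str = ",",
    na_tokens: Sequence[str] = (UNDETECTED_TOKEN, "NA", ""),
    ct_max: float = DEFAULT_CT_MAX,
) -> CtPlate:
    """Read a wide delimited plate file into a :class:`CtPlate`.

    Expected header: ``well_id, n_cells, unit, group`` followed by one
    column per gene.  Undetected reactions may be encoded by any of
    ``na_tokens`` or by a ct at/above ``ct_max``.  Malformed numeric cells
    raise :class:`ValidationError` rather than being dropped.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"missing annotation column(s): {missing}")
    gene_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    if not gene_cols:
        raise ConfigError("no gene columns found")

    na_set = {t.strip() for t in na_tokens}
    raw = df[gene_cols].apply(lambda s: s.str.strip())
    is_na = raw.isin(na_set)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    malformed = numeric.isna() & ~is_na
    if malformed.to_numpy().any():
        rows, cols = np.nonzero(malformed.to_numpy())
        spots = [
            f"(well {df['well_id'].iloc[r]!r}, gene {gene_cols[c]!r}: {raw.iloc[r, c]!r})"
            for r, c in list(zip(rows, cols))[:5]
        ]
        raise ValidationError(f"malformed ct value(s): {', '.join(spots)}")
    ct = numeric.to_numpy(dtype=float)
    ct[is_na.to_numpy()] = np.nan
    # censor at the cycle bound: ct >= ct_max means the threshold was not crossed
    ct[ct >= ct_max] = np.nan
    if np.any(ct[~np.isnan(ct)] <= 0):
        raise ValidationError("negative or zero ct value in input")

    try:
        n_cells = pd.to_numeric(df["n_cells"]).astype(int).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"malformed n_cells column: {exc}") from exc
    return CtPlate(
        ct=ct,
        well_ids=df["well_id"].to_numpy(dtype=object),
        gene_ids=np.asarray(gene_cols, dtype=object),
        cells_per_well=n_cells,
        unit=df["unit"].to_numpy(dtype=object),
        group=df["group"].to_numpy(dtype=object),
        ct_max=ct_max,
    )


def write_ct_plate(plate: CtPlate, path, *, delimiter: str = ",") -> None:
    """Write a plate in the wide CSV dialect; undetected becomes ``N/A``."""
    df = pd.DataFrame(
        {
            "well_id": plate.well_ids,
            "n_cells": plate.cells_per_well,
            "unit": plate.unit,
            "group": plate.group,
        }
    )
    for j, g in enumerate(plate.gene_ids):
        col = plate.ct[:, j]
        df[g] = [UNDETECTED_TOKEN if np.isnan(v) else f"{v:.10g}" for v in col]
    df.to_csv(path, sep=delimiter, index=False)


def write_et_matrix(et: EtMatrix, path, *, delimiter: str = ",") -> None:
    """Write an EtMatrix as a ct-scale plate file (round-trips via reader)."""
    write_ct_plate(ct_from_et(et), path, delimiter=delimiter)
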