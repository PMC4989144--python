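"""Reading, validation and preprocessing of culture-condition and multiplex factor tables.

Two delimited text files describe an experiment: a *condition table* with one
row per cultured sample (scaffold material, cavity geometry, cytokine
background, donor, replicate, day-7 viable cell count) and a *factor table*
with the multiplex immunoassay concentrations (pg/mL) of the secreted factors
measured in the day-7 supernatant of the same samples.

Preprocessing follows the analysis convention of the study design:

* factor levels are normalized to the day-7 cell count of the same sample
  ("per-cell" levels), because total supernatant concentration confounds
  secretion per cell with population size;
* a sample missing the concentration of exactly one factor is completed with
  the mean per-cell level of that factor across samples; samples missing two
  or more factors are excluded from modeling (conservative; logged).

Files are comma-separated UTF-8 with one header row; empty cells and ``NA``
mark missing values.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Material",
    "Cavity",
    "SampleRecord",
    "FactorPanel",
    "SchemaError",
    "DEFAULT_FACTORS",
    "read_dataset",
    "write_dataset",
    "write_per_cell_panel",
    "per_cell_normalize",
    "impute_single_missing",
]

#: The 12 secreted factors assayed by the multiplex panel.
DEFAULT_FACTORS = (
    "IL8",
    "IL12",
    "ANG2",
    "GMCSF",
    "HGF",
    "FST",
    "MIP1B",
    "PDGF_AB_BB",
    "PECAM1",
    "RANTES",
    "TGFB1",
    "VEGF",
)

CONDITION_COLUMNS = (
    "sample_id",
    "material",
    "cavity",
    "cytokine_background_ng_ml",
    "donor_id",
    "replicate",
    "cell_count_day7",
)


class SchemaError(ValueError):
    """A table is missing required columns or has an unusable layout."""


class Material(str, enum.Enum):
    """Scaffold material of the culture carrier."""

    PDMS_FN = "PDMS_FN"      # fibronectin-functionalized PDMS microcavities
    SPEG_HEP = "SPEG_HEP"    # starPEG-heparin hydrogel microcavities
    SPEG_SPEG = "SPEG_SPEG"  # pure starPEG hydrogel microcavities
    TCP = "TCP"              # planar tissue-culture plastic control


class Cavity(str, enum.Enum):
    """Cavity geometry: single-cell 15 µm, multi-cell 40 µm, or planar."""

    CAV15 = "CAV15"
    CAV40 = "CAV40"
    PLANAR = "PLANAR"


_MATERIAL_ALIASES = {
    "PDMS_FN": Material.PDMS_FN,
    "PDMS-FN": Material.PDMS_FN,
    "PDMSFN": Material.PDMS_FN,
    "SPEG_HEP": Material.SPEG_HEP,
    "SPEG-HEP": Material.SPEG_HEP,
    "PEG_HEP": Material.SPEG_HEP,
    "PEG-HEP": Material.SPEG_HEP,
    "SPEG_SPEG": Material.SPEG_SPEG,
    "SPEG-SPEG": Material.SPEG_SPEG,
    "PEG_PEG": Material.SPEG_SPEG,
    "PEG-PEG": Material.SPEG_SPEG,
    "TCP": Material.TCP,
}

_CAVITY_ALIASES = {
    "CAV15": Cavity.CAV15,
    "15": Cavity.CAV15,
    "15UM": Cavity.CAV15,
    "CAV40": Cavity.CAV40,
    "40": Cavity.CAV40,
    "40UM": Cavity.CAV40,
    "PLANAR": Cavity.PLANAR,
    "FLAT": Cavity.PLANAR,
}


def parse_material(token: str) -> Material:
    key = str(token).strip().upper()
    try:
        return _MATERIAL_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown material token {token!r}") from None


def parse_cavity(token: str) -> Cavity:
    key = str(token).strip().upper()
    try:
        return _CAVITY_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown cavity token {token!r}") from None


@dataclass(frozen=True)
class SampleRecord:
    """One cultured sample of the condition table."""

    sample_id: str
    material: Material
    cavity: Cavity
    cytokine_background: float  # ng/mL of supplemented SCF/TPO/FLT3L
    donor_id: str
    replicate: int
    cell_count_day7: int

    def __post_init__(self) -> None:
        if (self.material is Material.TCP) != (self.cavity is Cavity.PLANAR):
            raise ValueError(
                f"sample {self.sample_id!r}: TCP controls are planar and only TCP "
                f"is planar (got material={self.material.value}, cavity={self.cavity.value})"
            )
        if self.cytokine_background <= 0:
            raise ValueError(f"sample {self.sample_id!r}: cytokine background must be positive")
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate must be a positive integer")
        if self.cell_count_day7 < 0:
            raise ValueError(f"sample {self.sample_id!r}: cell count must be non-negative")


@dataclass
class FactorPanel:
    """Secreted-factor concentrations for a set of samples.

    ``raw_levels`` holds supernatant concentrations in pg/mL with ``nan``
    marking missing assays. ``per_cell_levels`` (pg/mL per cell) is populated
    by :func:`per_cell_normalize`. ``missing_mask`` records which entries were
    missing in the source data; after imputation the filled entries stay
    flagged there (provenance) while ``imputed_mask`` marks them explicitly.
    """

    sample_ids: list[str]
    factor_names: list[str]
    raw_levels: np.ndarray
    per_cell_levels: np.ndarray | None = None
    missing_mask: np.ndarray | None = None
    imputed_mask: np.ndarray | None = None
    excluded_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.raw_levels = np.asarray(self.raw_levels, dtype=float)
        n, p = len(self.sample_ids), len(self.factor_names)
        if self.raw_levels.shape != (n, p):
            raise ValueError(
                f"raw_levels shape {self.raw_levels.shape} does not match "
                f"{n} samples x {p} factors"
            )
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.raw_levels)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros_like(self.missing_mask)
        present = self.raw_levels[~np.isnan(self.raw_levels)]
        if (present < 0).any():
            raise ValueError("factor concentrations must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    def values_for_modeling(self) -> np.ndarray:
        """Per-cell levels if available, else raw levels."""
        if self.per_cell_levels is not None:
            return self.per_cell_levels
        return self.raw_levels


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_dataset(
    condition_path: str | Path, factor_path: str | Path
) -> tuple[list[SampleRecord], FactorPanel]:
    """Read and validate a condition table / factor table pair.

    The two files are joined on ``sample_id``; the returned panel rows follow
    the condition-table order. Malformed rows raise with the offending data
    line number (header = line 1).
    """
    cond = pd.read_csv(condition_path, dtype={"sample_id": str, "donor_id": str},
                       na_values=["NA"], keep_default_na=True,
                       float_precision="round_trip")
    _require_columns(cond, CONDITION_COLUMNS, condition_path)

    dup = cond["sample_id"][cond["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{condition_path}: duplicate sample_id(s) {sorted(set(dup))}")

    records: list[SampleRecord] = []
    for pos, row in cond.iterrows():
        line = pos + 2  # header line + 1-based
        try:
            records.append(
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    material=parse_material(row["material"]),
                    cavity=parse_cavity(row["cavity"]),
                    cytokine_background=float(row["cytokine_background_ng_ml"]),
                    donor_id=str(row["donor_id"]),
                    replicate=int(row["replicate"]),
                    cell_count_day7=int(row["cell_count_day7"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{condition_path}, line {line}: {exc}") from exc

    keys = {(r.donor_id, r.material, r.cavity, r.replicate, r.cytokine_background) for r in records}
    if len(keys) != len(records):
        raise ValueError(
            f"{condition_path}: (donor, material, cavity, replicate, background) "
            "combinations are not unique"
        )

    fac = pd.read_csv(factor_path, dtype={"sample_id": str}, na_values=["NA"],
                      keep_default_na=True, float_precision="round_trip")
    _require_columns(fac, ["sample_id"], factor_path)
    factor_names = [c for c in fac.columns if c != "sample_id"]
    if not factor_names:
        raise SchemaError(f"{factor_path}: no factor columns found")
    dup = fac["sample_id"][fac["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{factor_path}: duplicate sample_id(s) {sorted(set(dup))}")

    cond_ids = [r.sample_id for r in records]
    fac = fac.set_index("sample_id")
    missing_ids = [s for s in cond_ids if s not in fac.index]
    extra_ids = [s for s in fac.index if s not in set(cond_ids)]
    if missing_ids or extra_ids:
        raise ValueError(
            f"sample_id mismatch between tables: missing from factor table {missing_ids}, "
            f"unmatched in factor table {extra_ids}"
        )
    fac = fac.loc[cond_ids]

    try:
        values = fac[factor_names].astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{factor_path}: non-numeric factor value ({exc})") from exc

    panel = FactorPanel(sample_ids=cond_ids, factor_names=factor_names, raw_levels=values)
    return records, panel


def write_dataset(
    records: Sequence[SampleRecord],
    panel: FactorPanel,
    condition_path: str | Path,
    factor_path: str | Path,
) -> None:
    """Write a condition/factor table pair in the format :func:`read_dataset` reads."""
    cond = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "material": [r.material.value for r in records],
            "cavity": [r.cavity.value for r in records],
            "cytokine_background_ng_ml": [r.cytokine_background for r in records],
            "donor_id": [r.donor_id for r in records],
            "replicate": [r.replicate for r in records],
            "cell_count_day7": [r.cell_count_day7 for r in records],
        }
    )
    cond.to_csv(condition_path, index=False, float_format="%.17g")
    fac = pd.DataFrame(panel.raw_levels, columns=panel.factor_names)
    fac.insert(0, "sample_id", panel.sample_ids)
    fac.to_csv(factor_path, index=False, na_rep="NA", float_format="%.17g")


def write_per_cell_panel(panel: FactorPanel, path: str | Path) -> None:
    """Emit the post-normalization (and post-imputation) per-cell panel for audit."""
    if panel.per_cell_levels is None:
        raise ValueError("panel has no per-cell levels; run per_cell_normalize first")
    df = pd.DataFrame(panel.per_cell_levels, columns=panel.factor_names)
    df.insert(0, "sample_id", panel.sample_ids)
    df["excluded"] = [s in set(panel.excluded_samples) for s in panel.sample_ids]
    df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")


def per_cell_normalize(panel: FactorPanel, records: Sequence[SampleRecord]) -> FactorPanel:
    """Divide each sample's factor levels by its day-7 cell count.

    Missing entries stay missing. A sample with present factor values but a
    zero cell count has no defined per-cell level and raises.
    """
    by_id = {r.sample_id: r for r in records}
    missing = [s for s in panel.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"no condition record for sample(s) {missing}")
    counts = np.array([by_id[s].cell_count_day7 for s in panel.sample_ids], dtype=float)

    has_value = (~np.isnan(panel.raw_levels)).any(axis=1)
    bad = [s for s, c, h in zip(panel.sample_ids, counts, has_value) if h and c == 0]
    if bad:
        raise ZeroDivisionError(
            f"cell_count_day7 is 0 for sample(s) {bad} with measured factor levels; "
            "per-cell normalization is undefined"
        )
    with np.errstate(invalid="ignore"):
        per_cell = panel.raw_levels / counts[:, None]
    return replace(panel, per_cell_levels=per_cell)


def impute_single_missing(panel: FactorPanel) -> FactorPanel:
    """Complete samples missing exactly one factor with that factor's mean per-cell level.

    Samples missing two or more factors cannot be completed by the
    single-factor rule; they are flagged in ``excluded_samples`` (with a
    warning) and do not contribute to the imputation means. Present values are
    never changed.
    """
    if panel.per_cell_levels is None:
        raise ValueError("run per_cell_normalize before imputation")
    values = panel.per_cell_levels.copy()
    miss = np.isnan(values)
    n_missing = miss.sum(axis=1)

    excluded_idx = np.flatnonzero(n_missing >= 2)
    excluded = [panel.sample_ids[i] for i in excluded_idx]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} sample(s) missing >=2 factors from modeling: {excluded}",
            stacklevel=2,
        )
    usable = np.ones(panel.n_samples, dtype=bool)
    usable[excluded_idx] = False

    imputed = panel.imputed_mask.copy()
    for i in np.flatnonzero(n_missing == 1):
        j = int(np.flatnonzero(miss[i])[0])
        col = values[usable, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            raise ValueError(
                f"factor {panel.factor_names[j]!r} is missing in every usable sample; "
                "imputation impossible"
            )
        values[i, j] = col.mean()
        imputed[i, j] = True

    return replace(
        panel,
        per_cell_levels=values,
        imputed_mask=imputed,
        excluded_samples=list(panel.excluded_samples) + excluded,
    )
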