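"""Mechanistic encoding of culture conditions into a linear design matrix.

The cell number after 7 days of culture, N, is modeled as a linear
combination of mechanistically motivated predictors built from the measured
per-cell factor concentrations c_x and three condition constants:

* ``n`` — cell–cell contact number set by cavity geometry (single-cell 15 µm
  cavities: 1; 40 µm cavities: 3.6, from hexagonal packing with on average 9
  of the 12 possible cells interacting; planar: 6);
* ``a`` — material-specific adhesion strength (FN-coated PDMS: 1, adhesive
  TCP: 0.5, non-adhesive PEG hydrogels: 0);
* ``h`` — heparin content indicator of the scaffold (starPEG-heparin: 1,
  otherwise 0), representing sequestration of heparin-affine factors.

    N = sum_x A_x * c_x * w_auto(n) + sum_x B_x * c_x * w_para(n)
        + C * n + D * a * w_adh(n) + E * h + intercept

Autocrine signaling is strongest when a cell sits alone (no neighbors compete
for its secreted factors), so the default autocrine weight is 1/n; paracrine
signaling needs neighbors and grows with occupancy, default weight n − 1
(zero for single cells); adhesion acts reciprocally to cell–cell contacts
(more cell–ECM contact area in small cavities), default weight 1/n. The
weights are configurable — the directions are mechanistic commitments, the
exact forms are not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .io import Cavity, FactorPanel, Material, SampleRecord

__all__ = [
    "ConditionParameters",
    "EncodingConfig",
    "DesignMatrix",
    "ArrayGeometry",
    "condition_parameters",
    "build_design_matrix",
    "center_scale",
    "inverse_scale_y",
    "array_capacity",
    "GEOMETRY_PRESETS",
    "DEFAULT_CONTACTS",
    "DEFAULT_ADHESION",
    "DEFAULT_HEPARIN",
]

#: cell–cell contact number by cavity geometry
DEFAULT_CONTACTS: Mapping[Cavity, float] = {
    Cavity.CAV15: 1.0,
    Cavity.CAV40: 3.6,
    Cavity.PLANAR: 6.0,
}

#: material-specific adhesion parameter
DEFAULT_ADHESION: Mapping[Material, float] = {
    Material.PDMS_FN: 1.0,
    Material.TCP: 0.5,
    Material.SPEG_HEP: 0.0,
    Material.SPEG_SPEG: 0.0,
}

#: heparin content indicator of the scaffold
DEFAULT_HEPARIN: Mapping[Material, float] = {
    Material.PDMS_FN: 0.0,
    Material.TCP: 0.0,
    Material.SPEG_HEP: 1.0,
    Material.SPEG_SPEG: 0.0,
}


@dataclass(frozen=True)
class ConditionParameters:
    """The (n, a, h) encoding constants of one culture condition."""

    n: float  # cell–cell contacts
    a: float  # adhesion, 0–1
    h: float  # heparin indicator, 0 or 1


def condition_parameters(
    material: Material,
    cavity: Cavity,
    lookup: Mapping[str, Mapping] | None = None,
) -> ConditionParameters:
    """Look up (n, a, h) for a material/cavity combination.

    ``lookup`` may override any of the three default tables with keys
    ``"contacts"``, ``"adhesion"``, ``"heparin"``.
    """
    if (material is Material.TCP) != (cavity is Cavity.PLANAR):
        raise ValueError(f"invalid combination ({material.value}, {cavity.value})")
    lookup = lookup or {}
    contacts = lookup.get("contacts", DEFAULT_CONTACTS)
    adhesion = lookup.get("adhesion", DEFAULT_ADHESION)
    heparin = lookup.get("heparin", DEFAULT_HEPARIN)
    try:
        return ConditionParameters(
            n=float(contacts[cavity]), a=float(adhesion[material]), h=float(heparin[material])
        )
    except KeyError as exc:
        raise ValueError(f"no parameter entry for {exc}") from exc


_WEIGHTS: dict[str, Callable[[float], float]] = {
    "reciprocal": lambda n: 1.0 / n,
    "n_minus_1": lambda n: n - 1.0,
    "identity": lambda n: n,
    "unit": lambda n: 1.0,  # e.g. material-only adhesion
}


@dataclass(frozen=True)
class EncodingConfig:
    """Weight-function choices for the mechanistic predictors."""

    autocrine_weight: str = "reciprocal"
    paracrine_weight: str = "n_minus_1"
    adhesion_weight: str = "reciprocal"

    def weight(self, which: str) -> Callable[[float], float]:
        name = getattr(self, f"{which}_weight")
        try:
            return _WEIGHTS[name]
        except KeyError:
            raise ValueError(
                f"unknown {which} weight {name!r}; choose from {sorted(_WEIGHTS)}"
            ) from None


@dataclass
class DesignMatrix:
    """Named predictor matrix plus response and (optional) scaling metadata.

    Column order: ``auto_<factor>`` for every factor, then ``para_<factor>``,
    then ``cellcell``, ``adhesion``, ``heparin`` (2·F + 3 columns).
    ``groups`` keeps the (material, cavity) label of each sample for
    stratified cross-validation folds.
    """

    sample_ids: list[str]
    column_names: list[str]
    X: np.ndarray
    y: np.ndarray
    groups: list[tuple[str, str]]
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    scaled: bool = False
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None
    y_mean: float | None = None
    y_sd: float | None = None

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def column_role(self, name: str) -> str:
        if name.startswith("auto_"):
            return "auto"
        if name.startswith("para_"):
            return "para"
        return name  # cellcell / adhesion / heparin

    def subset_columns(self, names: Sequence[str]) -> "DesignMatrix":
        """Unscaled design restricted to the named columns (training order kept)."""
        if self.scaled:
            raise ValueError("subset the unscaled design, then re-run center_scale")
        idx = [self.column_names.index(n) for n in names]
        return replace(self, column_names=[self.column_names[i] for i in idx],
                       X=self.X[:, idx].copy())

    def subset_samples(self, idx: Sequence[int]) -> "DesignMatrix":
        idx = list(idx)
        if self.scaled:
            raise ValueError("subset the unscaled design, then re-run center_scale")
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            X=self.X[idx, :].copy(),
            y=self.y[idx].copy(),
            groups=[self.groups[i] for i in idx],
        )


def build_design_matrix(
    records: Sequence[SampleRecord],
    panel: FactorPanel,
    encoding: EncodingConfig | None = None,
    lookup: Mapping[str, Mapping] | None = None,
) -> DesignMatrix:
    """Encode an imputed per-cell panel into the mechanistic design matrix.

    Samples flagged as excluded by the imputation step are dropped. The
    returned matrix is unscaled; run :func:`center_scale` before fitting.
    """
    encoding = encoding or EncodingConfig()
    if panel.per_cell_levels is None:
        raise ValueError("panel must be per-cell normalized before encoding")
    by_id = {r.sample_id: r for r in records}
    excluded = set(panel.excluded_samples)
    keep = [i for i, s in enumerate(panel.sample_ids) if s not in excluded]
    if len(keep) < 3:
        raise ValueError(f"need at least 3 usable samples to center/scale, got {len(keep)}")

    C = panel.per_cell_levels[keep, :]
    if np.isnan(C).any():
        bad = [panel.sample_ids[keep[i]] for i in np.unique(np.nonzero(np.isnan(C))[0])]
        raise ValueError(f"missing per-cell values remain for sample(s) {bad}; impute first")

    ids = [panel.sample_ids[i] for i in keep]
    recs = [by_id[s] for s in ids]
    params = [condition_parameters(r.material, r.cavity, lookup) for r in recs]
    n = np.array([p.n for p in params])
    a = np.array([p.a for p in params])
    h = np.array([p.h for p in params])

    w_auto = np.array([encoding.weight("autocrine")(v) for v in n])
    w_para = np.array([encoding.weight("paracrine")(v) for v in n])
    w_adh = np.array([encoding.weight("adhesion")(v) for v in n])

    cols = [C * w_auto[:, None], C * w_para[:, None],
            n[:, None], (a * w_adh)[:, None], h[:, None]]
    X = np.hstack(cols)
    names = (
        [f"auto_{f}" for f in panel.factor_names]
        + [f"para_{f}" for f in panel.factor_names]
        + ["cellcell", "adhesion", "heparin"]
    )
    y = np.array([r.cell_count_day7 for r in recs], dtype=float)
    groups = [(r.material.value, r.cavity.value) for r in recs]
    return DesignMatrix(sample_ids=ids, column_names=names, X=X, y=y,
                        groups=groups, encoding=encoding)


def center_scale(dm: DesignMatrix) -> DesignMatrix:
    """Center every predictor column and the response to mean 0, SD 1 (ddof=1)."""
    if dm.scaled:
        raise ValueError("design matrix is already scaled")
    means = dm.X.mean(axis=0)
    sds = dm.X.std(axis=0, ddof=1)
    tiny = 1e-12 * np.maximum(1.0, np.abs(means))
    dead = np.flatnonzero(sds <= tiny)
    if dead.size:
        names = [dm.column_names[i] for i in dead]
        raise ValueError(
            f"zero-variance column(s) {names}: the design is degenerate "
            "(e.g. all samples share the same material or cavity)"
        )
    y_mean = float(dm.y.mean())
    y_sd = float(dm.y.std(ddof=1))
    if y_sd <= 1e-12 * max(1.0, abs(y_mean)):
        raise ValueError("response has zero variance; nothing to model")
    return replace(
        dm,
        X=(dm.X - means) / sds,
        y=(dm.y - y_mean) / y_sd,
        scaled=True,
        column_means=means,
        column_sds=sds,
        y_mean=y_mean,
        y_sd=y_sd,
    )


def inverse_scale_y(dm: DesignMatrix, y_scaled: np.ndarray) -> np.ndarray:
    """Map a scaled response back to raw cell counts."""
    if not dm.scaled:
        raise ValueError("design matrix is not scaled")
    return dm.y_mean + dm.y_sd * np.asarray(y_scaled)


@dataclass(frozen=True)
class ArrayGeometry:
    """Microcavity array geometry (lengths in µm)."""

    array_diameter: float
    cavity_diameter: float
    wall_thickness: float
    cells_per_cavity: int = 1

    def __post_init__(self) -> None:
        if self.cavity_diameter <= 0 or self.wall_thickness < 0:
            raise ValueError("cavity diameter must be positive, wall thickness non-negative")
        if self.cells_per_cavity < 1:
            raise ValueError("cells_per_cavity must be a positive integer")

    @property
    def pitch(self) -> float:
        return self.cavity_diameter + self.wall_thickness


#: 11 mm carrier, 3 µm walls; 15 µm cavities hold one cell, 40 µm up to 12.
GEOMETRY_PRESETS: Mapping[str, ArrayGeometry] = {
    "cav15": ArrayGeometry(array_diameter=11_000.0, cavity_diameter=15.0,
                           wall_thickness=3.0, cells_per_cavity=1),
    "cav40": ArrayGeometry(array_diameter=11_000.0, cavity_diameter=40.0,
                           wall_thickness=3.0, cells_per_cavity=12),
}


def array_capacity(geom: ArrayGeometry) -> tuple[int, int]:
    """Idealized (cavity_count, max_cells) of a hexagonally packed circular array.

    Uses the ideal hexagonal lattice density 2 / (sqrt(3) * pitch^2) over the
    circular carrier area, ignoring edge truncation; an estimate good to a few
    percent for arrays thousands of pitches wide.
    """
    if geom.array_diameter < geom.cavity_diameter:
        return 0, 0
    area = math.pi * (geom.array_diameter / 2.0) ** 2
    density = 2.0 / (math.sqrt(3.0) * geom.pitch**2)
    cavity_count = int(math.floor(area * density))
    return cavity_count, cavity_count * geom.cells_per_cavity
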