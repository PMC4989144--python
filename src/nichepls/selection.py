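"""Latent-component selection and VIP-based variable pruning.

The number of PLS components is chosen by K-fold cross-validation: PRESS
(predicted residual error sum of squares) locates the optimum component
count, the Van der Voet T² randomization test asks which simpler models do
not predict significantly worse than that optimum, and the final count is the
smallest one that (a) is statistically indistinguishable from the optimum at
level alpha and (b) explains at least 90% of both the cumulative X and y
variance. If no count satisfies both, the PRESS optimum is used and flagged.

After fitting, predictors with VIP below a threshold (0.8 by default) are
deleted and the whole selection is re-run on the reduced design.

Fold handling: centering/scaling is re-estimated inside every training fold
(no information leaks from held-out samples); held-out residuals are taken on
the raw cell-count scale and divided by the full-data SD of the response so
that PRESS is comparable across folds and datasets. Folds are stratified by
(material, cavity) condition groups when available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import DesignMatrix, center_scale
from .pls import PLSModel, fit_nipals, _matrix_rank

__all__ = [
    "SelectionReport",
    "kfold_press",
    "van_der_voet_test",
    "choose_components",
    "select_model",
    "prune_and_refit",
]


@dataclass
class SelectionReport:
    """Record of one component-selection (and optional pruning) run."""

    k_folds: int
    fold_assignment_seed: int
    alpha: float
    n_perm: int
    candidates: list[int]
    press: list[float]
    press_null: float               # PRESS of the 0-component model (fold-mean prediction)
    optimum_components: int
    van_der_voet_p: list[float]
    chosen_components: int
    variance_rule_satisfied: bool
    fallback_to_optimum: bool
    explained_x: list[float]
    explained_y: list[float]
    kept_variables: list[str] | None = None
    vip_threshold: float | None = None
    fold_warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _fold_assignment(dm: DesignMatrix, k: int, seed: int, stratify: bool = True) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n = dm.n_samples
    folds = np.empty(n, dtype=int)
    if stratify and dm.groups:
        by_group: dict[tuple, list[int]] = {}
        for i, g in enumerate(dm.groups):
            by_group.setdefault(tuple(g), []).append(i)
        pos = 0
        for g in sorted(by_group):
            idx = np.array(by_group[g])
            rng.shuffle(idx)
            for i in idx:
                folds[i] = pos % k
                pos += 1
    else:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % k
    return folds


def _coef_path(model: PLSModel, n_components: int) -> np.ndarray:
    """Scaled-space coefficients of the model truncated to its first components."""
    A = min(n_components, model.n_components)
    W, P, q = model.W[:, :A], model.P[:, :A], model.q[:A]
    return W @ np.linalg.solve(P.T @ W, q)


def kfold_press(
    dm: DesignMatrix,
    max_components: int,
    k: int = 7,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[np.ndarray, np.ndarray, float, list[str]]:
    """K-fold PRESS for every candidate component count 1..max_components.

    Returns ``(press, residuals, press_null, warnings)`` where ``residuals``
    is the (n_samples, max_components) matrix of held-out residuals on the
    globally scaled response and ``press_null`` is the PRESS of predicting
    each held-out sample by its training-fold mean.
    """
    if dm.scaled:
        raise ValueError("kfold_press expects the unscaled design (folds re-scale internally)")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > dm.n_samples:
        raise ValueError(f"k={k} exceeds the number of samples ({dm.n_samples})")
    if max_components < 1:
        raise ValueError("max_components must be >= 1")

    folds = _fold_assignment(dm, k, seed, stratify)
    sd_global = float(dm.y.std(ddof=1))
    if sd_global == 0:
        raise ValueError("response has zero variance")

    resid = np.empty((dm.n_samples, max_components))
    resid_null = np.empty(dm.n_samples)
    notes: list[str] = []

    for f in range(k):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        sub = dm.subset_samples(train)

        sds = sub.X.std(axis=0, ddof=1)
        tiny = 1e-12 * np.maximum(1.0, np.abs(sub.X.mean(axis=0)))
        kept = [n for n, s, t in zip(sub.column_names, sds, tiny) if s > t]
        if len(kept) < len(sub.column_names):
            dropped = sorted(set(sub.column_names) - set(kept))
            notes.append(f"fold {f}: column(s) {dropped} constant in training split; excluded")
            warnings.warn(notes[-1], stacklevel=2)
            sub = sub.subset_columns(kept)

        scaled = center_scale(sub)
        a_max = min(max_components, _matrix_rank(scaled.X))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # early stop inside a fold is expected
            fold_model = fit_nipals(scaled, a_max)

        names = scaled.column_names
        idx = [dm.column_names.index(n) for n in names]
        X_test = dm.X[test][:, idx]
        Xs = (X_test - scaled.column_means) / scaled.column_sds
        for a in range(1, max_components + 1):
            b = _coef_path(fold_model, a)
            pred = scaled.y_mean + scaled.y_sd * (Xs @ b)
            resid[test, a - 1] = (dm.y[test] - pred) / sd_global
        resid_null[test] = (dm.y[test] - scaled.y_mean) / sd_global

    press = (resid**2).sum(axis=0)
    press_null = float((resid_null**2).sum())
    return press, resid, press_null, notes


def van_der_voet_test(
    resid_candidate: np.ndarray,
    resid_optimum: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Paired sign-flip randomization p-value for equal predictive squared error.

    The statistic is T = sum_i (e_cand,i^2 - e_opt,i^2). The null distribution
    flips the sign of each paired difference independently: exhaustively over
    all 2^n assignments when n <= 12, otherwise by ``n_perm`` seeded draws
    with add-one smoothing. Large p means the candidate does not predict
    significantly worse than the optimum.
    """
    e_c = np.asarray(resid_candidate, dtype=float)
    e_o = np.asarray(resid_optimum, dtype=float)
    if e_c.shape != e_o.shape:
        raise ValueError(f"residual vectors differ in length: {e_c.shape} vs {e_o.shape}")
    d = e_c**2 - e_o**2
    n = d.size
    T = abs(d.sum())
    tol = 1e-12 * max(1.0, float(np.abs(d).sum()))

    if n <= 12:
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1) * 2 - 1
        T_null = np.abs(signs @ d)
        return float((T_null >= T - tol).mean())
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    T_null = np.abs(signs @ d)
    return float((1 + (T_null >= T - tol).sum()) / (1 + n_perm))


def choose_components(
    press: Sequence[float],
    van_der_voet_p: Sequence[float],
    explained_x: Sequence[float],
    explained_y: Sequence[float],
    alpha: float = 0.10,
) -> tuple[int, bool]:
    """Smallest component count passing the Van der Voet and 90%-variance rules.

    Returns ``(chosen, fallback)``; ``fallback`` is True when no candidate
    satisfies both rules and the PRESS optimum is returned instead.
    """
    press = np.asarray(press, dtype=float)
    p = np.asarray(van_der_voet_p, dtype=float)
    ex = np.asarray(explained_x, dtype=float)
    ey = np.asarray(explained_y, dtype=float)
    m = min(press.size, p.size, ex.size, ey.size)
    if m == 0:
        raise ValueError("no candidate component counts")
    ok = (p[:m] > alpha) & (ex[:m] >= 0.9) & (ey[:m] >= 0.9)
    if ok.any():
        return int(np.flatnonzero(ok)[0] + 1), False
    return int(np.argmin(press) + 1), True


def select_model(
    dm: DesignMatrix,
    k: int = 7,
    alpha: float = 0.10,
    n_perm: int = 10_000,
    seed: int = 0,
    max_components: int = 15,
    stratify: bool = True,
) -> tuple[PLSModel, DesignMatrix, SelectionReport]:
    """Full component selection on an unscaled design: CV, T² test, variance rule, fit.

    Returns the fitted model at the chosen component count, the scaled design
    it was fitted on, and the selection report.
    """
    scaled = center_scale(dm)
    a_cap = min(max_components, _matrix_rank(scaled.X))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probe = fit_nipals(scaled, a_cap)
    a_cap = probe.n_components  # early stop can shorten the path

    press, resid, press_null, notes = kfold_press(dm, a_cap, k=k, seed=seed, stratify=stratify)
    opt = int(np.argmin(press))
    rng = np.random.default_rng(seed)
    perm_seeds = rng.integers(0, 2**31 - 1, size=a_cap)
    pvals = np.array([
        van_der_voet_test(resid[:, a], resid[:, opt], n_perm=n_perm, seed=int(perm_seeds[a]))
        for a in range(a_cap)
    ])
    chosen, fallback = choose_components(
        press, pvals, probe.explained_x, probe.explained_y, alpha=alpha
    )
    model = fit_nipals(scaled, chosen)
    report = SelectionReport(
        k_folds=k,
        fold_assignment_seed=seed,
        alpha=alpha,
        n_perm=n_perm,
        candidates=list(range(1, a_cap + 1)),
        press=[float(v) for v in press],
        press_null=press_null,
        optimum_components=opt + 1,
        van_der_voet_p=[float(v) for v in pvals],
        chosen_components=chosen,
        variance_rule_satisfied=not fallback,
        fallback_to_optimum=fallback,
        explained_x=[float(v) for v in probe.explained_x],
        explained_y=[float(v) for v in probe.explained_y],
        fold_warnings=notes,
    )
    return model, scaled, report


def prune_and_refit(
    dm: DesignMatrix,
    model: PLSModel,
    vip_threshold: float = 0.8,
    **selection_kwargs,
) -> tuple[DesignMatrix, PLSModel, SelectionReport]:
    """Delete predictors with VIP below the threshold and re-run the selection.

    ``dm`` is the unscaled design the full model was selected on; the reduced
    design keeps only columns with VIP >= ``vip_threshold``. The default
    threshold 0.8 is the conventional relevance cutoff for VIP scores.
    """
    kept = [n for n, v in zip(model.column_names, model.vip) if v >= vip_threshold]
    if not kept:
        raise ValueError(
            f"VIP threshold {vip_threshold} prunes every variable; "
            "lower the threshold or inspect the fit"
        )
    reduced = dm.subset_columns(kept)
    red_model, _, report = select_model(reduced, **selection_kwargs)
    report.kept_variables = kept
    report.vip_threshold = vip_threshold
    return reduced, red_model, report
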