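"""Model validation: cross-validated Q², component selection, and the
response-permutation validity test.

Q² conventions
--------------
Samples are assigned to exclusion groups round-robin in sample order
("venetian blinds", 7 groups by default) or leave-one-out. For every
left-out group the model is refit on the remainder — centering and
scaling recomputed on the training part only, so no information leaks —
and held-out predictions accumulate PRESS(a), the predictive residual sum
of squares of the a-component model, measured in globally scaled response
units. With SS(a) the residual sum of squares of the full-data model
after a components (SS(0) = n−1 on unit-variance y):

    Q²(a)    = 1 − PRESS(a) / SS(a−1)          (per component)
    Q²cum(A) = 1 − Π_{a≤A} PRESS(a) / SS(a−1)  (product rule)

A component is significant when its per-component Q² reaches the limit
(0.05 by default); the selected A is the longest prefix of significant
components, and A = 0 marks "no valid model".

Permutation (response-scrambling) test
--------------------------------------
The response is randomly permuted ``n_perm`` times (identity rejected)
with X unaltered; each permuted model is refit with the same A and
cross-validation scheme. A straight line is fit through the points
(|r|, statistic) — |r| the Pearson correlation between permuted and
original response, including the unpermuted model at |r| = 1 — separately
for R²cum and Q²cum. The intercepts at |r| = 0 estimate chance-level fit;
the model is declared valid when the R² intercept is below 0.4 and the
Q² intercept below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import Dataset
from .descriptors import assemble_x, resolve_x_set
from .pls import PLSRegressionNIPALS, _as_1d, _as_2d

#: Validity limits for the permutation intercepts.
R2_INTERCEPT_LIMIT = 0.4
Q2_INTERCEPT_LIMIT = 0.05


@dataclass
class ValidationConfig:
    """Knobs of the validation machinery (defaults follow common
    chemometrics practice: 7 venetian-blind groups, 20 permutations)."""

    folds: int = 7
    cv_mode: str = "venetian"  # or "loo"
    n_permutations: int = 20
    seed: int = 0
    q2_component_limit: float = 0.05
    r2_intercept_limit: float = R2_INTERCEPT_LIMIT
    q2_intercept_limit: float = Q2_INTERCEPT_LIMIT
    a_max: int | None = None
    n_components: int | None = None  # force A instead of selecting


@dataclass
class CrossValResult:
    folds: int
    mode: str
    a_max: int
    press: np.ndarray          # PRESS(a), a = 1..a_max
    ss: np.ndarray             # SS(a), a = 0..a_max (full-model residual SS)
    q2_component: np.ndarray   # Q²(a)
    q2_cumulative: np.ndarray  # Q²cum(a)

    def q2(self, a: int) -> float:
        """Cumulative Q² of the a-component model."""
        return float(self.q2_cumulative[a - 1])


@dataclass
class PermutationResult:
    n_permutations: int
    seed: int
    a: int
    correlations: np.ndarray  # |r| per point, original model last at 1.0
    r2_values: np.ndarray
    q2_values: np.ndarray
    r2_intercept: float
    q2_intercept: float
    r2_limit: float = R2_INTERCEPT_LIMIT
    q2_limit: float = Q2_INTERCEPT_LIMIT

    @property
    def valid(self) -> bool:
        return (self.r2_intercept < self.r2_limit
                and self.q2_intercept < self.q2_limit)


@dataclass
class ValidationReport:
    """One summary row per fitted model (the stable report schema)."""

    n: int
    x_set: str
    a: int
    r2: float
    q2cv: float
    perm_r2_intercept: float
    perm_q2_intercept: float
    valid: bool
    activity: str = ""
    notes: str = ""


def _fold_assignment(n: int, folds: int, mode: str) -> np.ndarray:
    if mode == "loo":
        return np.arange(n)
    if mode != "venetian":
        raise ValueError(f"unknown cv_mode {mode!r}; expected 'venetian' or 'loo'")
    if not 2 <= folds <= n:
        raise ValueError(f"fold count must be in [2, {n}], got {folds}")
    return np.arange(n) % folds


def cross_validate(
    X,
    y,
    a_max: int | None = None,
    folds: int = 7,
    mode: str = "venetian",
) -> CrossValResult:
    """Cross-validated PRESS and Q² per component count (see module docs)."""
    Xa, names, _ = _as_2d(X)
    ya = _as_1d(y)
    n = len(ya)
    if Xa.shape[0] != n:
        raise ValueError(f"X has {Xa.shape[0]} rows but y has {n}")
    groups = _fold_assignment(n, folds, mode)
    n_groups = groups.max() + 1

    full = PLSRegressionNIPALS(n_components=1, scale=True).fit(Xa, ya)
    rank = full.rank_
    if a_max is None:
        a_max = max(1, min(rank, n - 2, 10))
    if a_max > rank:
        raise ValueError(f"a_max={a_max} exceeds rank {rank}")
    full = PLSRegressionNIPALS(n_components=a_max, scale=True).fit(Xa, ya)
    y_scale = full.y_std_
    ss = np.empty(a_max + 1)
    ss[0] = n - 1.0
    ss[1:] = (n - 1.0) * (1.0 - full.r2_)

    press = np.zeros(a_max)
    for g in range(n_groups):
        test = groups == g
        train = ~test
        if train.sum() < 2:
            raise ValueError(
                f"exclusion group {g} leaves only {int(train.sum())} training samples"
            )
        Xtr, ytr = Xa[train], ya[train]
        sd = Xtr.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            bad = int(np.argmin(sd))
            label = names[bad] if names else bad
            raise ValueError(
                f"column {label!r} is constant within the training part of "
                f"exclusion group {g}"
            )
        a_fold = min(a_max, np.linalg.matrix_rank((Xtr - Xtr.mean(0)) / sd))
        sub = PLSRegressionNIPALS(n_components=a_fold, scale=True).fit(Xtr, ytr)
        preds = sub.predict_components(Xa[test])
        if a_fold < a_max:  # rank-deficient fold: carry the deepest model
            pad = np.repeat(preds[:, -1:], a_max - a_fold, axis=1)
            preds = np.hstack([preds, pad])
        resid = (ya[test, None] - preds) / y_scale
        press += (resid ** 2).sum(axis=0)

    ratio = press / ss[:-1]
    q2_component = 1.0 - ratio
    q2_cumulative = 1.0 - np.cumprod(ratio)
    return CrossValResult(
        folds=int(n_groups), mode=mode, a_max=a_max, press=press, ss=ss,
        q2_component=q2_component, q2_cumulative=q2_cumulative,
    )


def select_components(
    X,
    y,
    folds: int = 7,
    mode: str = "venetian",
    q2_limit: float = 0.05,
    a_max: int | None = None,
) -> int:
    """Number of significant components: the largest A such that every
    component a ≤ A has per-component Q²(a) ≥ ``q2_limit``; 0 if none."""
    cv = cross_validate(X, y, a_max=a_max, folds=folds, mode=mode)
    a = 0
    for q in cv.q2_component:
        if q >= q2_limit:
            a += 1
        else:
            break
    return a


def _model_stats(X, y, a: int, folds: int, mode: str) -> tuple[float, float]:
    model = PLSRegressionNIPALS(n_components=a, scale=True).fit(X, y)
    cv = cross_validate(X, y, a_max=a, folds=folds, mode=mode)
    return float(model.r2_[a - 1]), cv.q2(a)


def permutation_test(
    X,
    y,
    n_perm: int = 20,
    seed: int = 0,
    a: int = 1,
    folds: int = 7,
    mode: str = "venetian",
) -> PermutationResult:
    """Response-scrambling validity test (see module docs).

    Deterministic under ``seed``; identity permutations are rejected so
    every scrambled model really is scrambled.
    """
    Xa, _, _ = _as_2d(X)
    ya = _as_1d(y)
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    if np.std(ya) == 0:
        raise ValueError("y is constant; permutation test undefined")
    rng = np.random.default_rng(seed)
    n = len(ya)

    corrs, r2s, q2s = [], [], []
    for _ in range(n_perm):
        while True:
            perm = rng.permutation(n)
            if not np.array_equal(perm, np.arange(n)):
                break
        yp = ya[perm]
        corrs.append(abs(stats.pearsonr(yp, ya)[0]))
        r2, q2 = _model_stats(Xa, yp, a, folds, mode)
        r2s.append(r2)
        q2s.append(q2)
    r2_orig, q2_orig = _model_stats(Xa, ya, a, folds, mode)
    corrs.append(1.0)
    r2s.append(r2_orig)
    q2s.append(q2_orig)

    corrs_a = np.asarray(corrs)
    r2_line = np.polyfit(corrs_a, np.asarray(r2s), 1)
    q2_line = np.polyfit(corrs_a, np.asarray(q2s), 1)
    return PermutationResult(
        n_permutations=n_perm, seed=seed, a=a,
        correlations=corrs_a, r2_values=np.asarray(r2s),
        q2_values=np.asarray(q2s),
        r2_intercept=float(r2_line[1]), q2_intercept=float(q2_line[1]),
    )


def validate_model(
    dataset: Dataset,
    activity: str | pd.Series,
    x_set: str = "all",
    config: ValidationConfig | None = None,
) -> ValidationReport:
    """Full validation of one (activity, descriptor-set) model: assemble
    X, select the component count, fit, cross-validate, run the
    permutation test, and summarise as one report row.

    When no component is significant (A = 0) the summary statistics are
    reported for the 1-component fit as diagnostics and the model is
    marked invalid.
    """
    cfg = config or ValidationConfig()
    if isinstance(activity, str):
        if activity not in dataset.activities:
            raise KeyError(
                f"activity {activity!r} not found; available: "
                f"{sorted(dataset.activities)}"
            )
        y = dataset.activities[activity]
        name = activity
    else:
        y = activity
        name = str(y.name)
    x = assemble_x(dataset, x_set).loc[y.index]
    x_label = resolve_x_set(x_set)

    if cfg.n_components is not None:
        a = int(cfg.n_components)
        selected = a
    else:
        selected = select_components(
            x, y, folds=cfg.folds, mode=cfg.cv_mode,
            q2_limit=cfg.q2_component_limit, a_max=cfg.a_max,
        )
        a = max(selected, 1)

    model = PLSRegressionNIPALS(n_components=a, scale=True).fit(x, y)
    cv = cross_validate(x, y, a_max=a, folds=cfg.folds, mode=cfg.cv_mode)
    perm = permutation_test(
        x, y, n_perm=cfg.n_permutations, seed=cfg.seed, a=a,
        folds=cfg.folds, mode=cfg.cv_mode,
    )
    valid = (
        selected >= 1
        and perm.r2_intercept < cfg.r2_intercept_limit
        and perm.q2_intercept < cfg.q2_intercept_limit
    )
    return ValidationReport(
        n=len(y), x_set=x_label, a=selected,
        r2=float(model.r2_[a - 1]), q2cv=cv.q2(a),
        perm_r2_intercept=perm.r2_intercept,
        perm_q2_intercept=perm.q2_intercept,
        valid=bool(valid), activity=name,
        notes="" if selected >= 1 else "no significant component; stats at A=1",
    )
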