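"""Region-wise stepwise selection and conditional analysis.

Stepwise selection is forward with backward elimination after each entry
(classic bidirectional, entry threshold = retention threshold): at each step
the candidate with the smallest Wald p in the current model enters if that p
is below its applicable threshold — ``alpha_a`` for index-correlated
candidates, ``alpha_b`` for novel ones — then any selected variant whose
final-model p has risen above its own threshold is dropped.  Missing hard
calls are mean-filled so the original sample size is preserved.  A
forward-only switch is provided.

The dense multi-signal scan (the 8q24-style procedure) restricts the
candidate pool to variants with single-SNP p < 0.05 and uses a retention
threshold of 0.001 for the multivariate model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .association import (
    SeparationError,
    design_matrix,
    logistic_fit,
    trend_test,
)
from .containers import DosageMatrix
from .ld import pairwise_r2


@dataclass
class StepwiseResult:
    """Outcome of a stepwise region scan."""

    region: str
    selected: list[str]
    entry_p: dict[str, float]
    final_model: pd.DataFrame  # variant_id, beta, se, or, ci_lo, ci_hi, p
    alpha_used: dict[str, float]
    candidate_pool: list[str] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)
    order: list[str] = field(default_factory=list)


def _candidate_columns(
    dosages: DosageMatrix, candidates: list[str], mean_fill: bool
) -> dict[str, np.ndarray]:
    cols = {}
    for v in candidates:
        d = dosages.dosage_of(v)
        if mean_fill and np.isnan(d).any():
            d = d.copy()
            d[np.isnan(d)] = np.nanmean(d)
        cols[v] = d
    return cols


def _fit_model(
    y: np.ndarray,
    cov_X: np.ndarray,
    cols: dict[str, np.ndarray],
    model_vars: list[str],
):
    X = np.column_stack(
        [cov_X[:, :1]] + [cols[v] for v in model_vars] + [cov_X[:, 1:]]
    )
    return logistic_fit(X, y, ["const"] + model_vars + ["c"] * (cov_X.shape[1] - 1))


def stepwise_select(
    dosages: DosageMatrix,
    candidates: list[str],
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
    alpha: Mapping[str, float] | float = 0.05,
    region: str = "",
    mean_fill: bool = True,
    forward_only: bool = False,
    max_steps: int = 50,
) -> StepwiseResult:
    """Forward/backward stepwise selection over region candidates.

    ``alpha`` maps each candidate id to its applicable threshold (use
    :func:`admixfine.ld.derive_alphas` to build the two-tier map), or a
    single float applied to all candidates.  Candidates perfectly collinear
    (r^2 = 1) with an already-selected variant are skipped with a reason.
    Ties on entry p go to the smaller p then the lower genomic position.
    """
    status = np.asarray(status, dtype=float)
    if isinstance(alpha, Mapping):
        alpha_map = dict(alpha)
    else:
        alpha_map = {v: float(alpha) for v in candidates}
    missing_alpha = [v for v in candidates if v not in alpha_map]
    if missing_alpha:
        raise ValueError(f"no alpha threshold for candidates: {missing_alpha}")
    pos = {
        v: int(dosages.variants["pos"].iloc[dosages.variant_index(v)]) for v in candidates
    }
    cols = _candidate_columns(dosages, candidates, mean_fill)
    cov_mask = np.ones(len(status), dtype=bool)
    if covariates is not None:
        num = covariates.select_dtypes(include=[np.number])
        if not num.empty:
            cov_mask &= ~num.isna().any(axis=1).to_numpy()
    if not mean_fill:
        for v in candidates:
            cov_mask &= ~np.isnan(cols[v])
    y = status[cov_mask]
    cols = {v: c[cov_mask] for v, c in cols.items()}
    cov = covariates.loc[cov_mask].reset_index(drop=True) if covariates is not None else None
    cov_X, _ = design_matrix(cov, len(y))

    selected: list[str] = []
    order: list[str] = []
    entry_p: dict[str, float] = {}
    skipped: dict[str, str] = {}
    remaining = [v for v in candidates if np.ptp(cols[v][~np.isnan(cols[v])]) > 0]
    for v in candidates:
        if v not in remaining:
            skipped[v] = "constant dosage"

    for _ in range(max_steps):
        # entry: smallest Wald p among admissible candidates
        best = None
        for v in remaining:
            if v in selected:
                continue
            if any(
                np.isclose(pairwise_r2(cols[v], cols[s]), 1.0, atol=1e-12)
                for s in selected
            ):
                skipped.setdefault(v, "collinear with selected variant")
                continue
            try:
                fit = _fit_model(y, cov_X, cols, selected + [v])
            except SeparationError:
                skipped.setdefault(v, "separation")
                continue
            p = fit.wald_p(1 + len(selected))
            key = (p, pos[v], v)
            if best is None or key < best[0]:
                best = (key, v, p)
        if best is None:
            break
        _, v_new, p_new = best
        if not (p_new < alpha_map[v_new]):
            break
        selected.append(v_new)
        order.append(v_new)
        entry_p[v_new] = p_new

        if not forward_only:
            # backward: drop any selected variant now above its threshold
            while len(selected) > 1:
                fit = _fit_model(y, cov_X, cols, selected)
                ps = {v: fit.wald_p(1 + i) for i, v in enumerate(selected)}
                worst = max(selected, key=lambda v: ps[v])
                if ps[worst] >= alpha_map[worst]:
                    selected.remove(worst)
                else:
                    break

    rows = []
    if selected:
        fit = _fit_model(y, cov_X, cols, selected)
        for i, v in enumerate(selected):
            b, s = float(fit.params[1 + i]), float(fit.bse[1 + i])
            rows.append(
                {
                    "variant_id": v,
                    "beta": b,
                    "se": s,
                    "or": float(np.exp(b)),
                    "ci_lo": float(np.exp(b - 1.96 * s)),
                    "ci_hi": float(np.exp(b + 1.96 * s)),
                    "p": fit.wald_p(1 + i),
                }
            )
    final = pd.DataFrame(rows, columns=["variant_id", "beta", "se", "or", "ci_lo", "ci_hi", "p"])
    return StepwiseResult(
        region=region,
        selected=selected,
        entry_p=entry_p,
        final_model=final,
        alpha_used={v: alpha_map[v] for v in candidates},
        candidate_pool=list(candidates),
        skipped=skipped,
        order=order,
    )


def region_scan_dense(
    dosages: DosageMatrix,
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
    variant_ids: list[str] | None = None,
    entry_pool_p: float = 0.05,
    retention_p: float = 0.001,
    region: str = "dense",
    mean_fill: bool = True,
    forward_only: bool = False,
) -> StepwiseResult:
    """Multi-signal stepwise scan of a dense window (the 8q24 procedure).

    Candidates are restricted to variants with single-SNP trend p <
    ``entry_pool_p``; the stepwise machinery then enters/retains at
    ``retention_p`` in the multivariate model.
    """
    ids = variant_ids if variant_ids is not None else dosages.variant_ids
    pool = []
    for v in ids:
        r = trend_test(dosages.dosage_of(v), status, covariates, v, mean_fill)
        if r.estimable and r.p_trend < entry_pool_p:
            pool.append(v)
    res = stepwise_select(
        dosages,
        pool,
        status,
        covariates,
        alpha=retention_p,
        region=region,
        mean_fill=mean_fill,
        forward_only=forward_only,
    )
    res.candidate_pool = pool
    return res


@dataclass
class ConditionalResult:
    variant_id: str
    conditioning: list[str]
    beta: float
    se: float
    odds_ratio: float
    ci_lo: float
    ci_hi: float
    p: float
    n: int
    flags: list[str] = field(default_factory=list)


def conditional_test(
    dosages: DosageMatrix,
    variant_id: str,
    conditioning: list[str],
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
    mean_fill: bool = True,
) -> ConditionalResult:
    """Association of one variant conditional on a set of others.

    With an empty conditioning set this reduces exactly to the trend test.
    Conditioning on a perfect proxy (r^2 = 1) leaves no residual
    information: the result is flagged collinear with beta 0 and p 1.
    """
    if variant_id in conditioning:
        raise ValueError("conditioning set must exclude the tested variant")
    cols = _candidate_columns(dosages, [variant_id] + list(conditioning), mean_fill)
    target = cols[variant_id]
    for c in conditioning:
        if np.isclose(pairwise_r2(target, cols[c]), 1.0, atol=1e-12):
            return ConditionalResult(
                variant_id, list(conditioning), 0.0, np.nan, 1.0, np.nan, np.nan,
                1.0, len(target), flags=["collinear"],
            )
    status = np.asarray(status, dtype=float)
    mask = np.ones(len(status), dtype=bool)
    if covariates is not None:
        num = covariates.select_dtypes(include=[np.number])
        if not num.empty:
            mask &= ~num.isna().any(axis=1).to_numpy()
    if not mean_fill:
        for v in cols:
            mask &= ~np.isnan(cols[v])
    y = status[mask]
    cc = {v: c[mask] for v, c in cols.items()}
    cov = covariates.loc[mask].reset_index(drop=True) if covariates is not None else None
    cov_X, _ = design_matrix(cov, len(y))
    model_vars = [variant_id] + list(conditioning)
    try:
        fit = _fit_model(y, cov_X, cc, model_vars)
    except SeparationError as exc:
        return ConditionalResult(
            variant_id, list(conditioning), np.nan, np.nan, np.nan, np.nan, np.nan,
            np.nan, len(y), flags=[f"separation: {exc}"],
        )
    b, s = float(fit.params[1]), float(fit.bse[1])
    return ConditionalResult(
        variant_id,
        list(conditioning),
        b,
        s,
        float(np.exp(b)),
        float(np.exp(b - 1.96 * s)),
        float(np.exp(b + 1.96 * s)),
        fit.wald_p(1),
        len(y),
    )


def variance_explained_by_others(
    dosages: DosageMatrix, variant_id: str, others: list[str], mean_fill: bool = True
) -> float:
    """Multiple-R^2 of a variant's dosage regressed on other variants'
    dosages (least squares via pseudo-inverse; clipped to [0, 1])."""
    if not others:
        raise ValueError("need >= 1 other variant")
    cols = _candidate_columns(dosages, [variant_id] + list(others), mean_fill)
    y = cols[variant_id]
    X = np.column_stack([np.ones(len(y))] + [cols[v] for v in others])
    ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    y, X = y[ok], X[ok]
    if y.var() == 0:
        return float("nan")
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    r2 = 1.0 - resid.var() / y.var()
    return float(np.clip(r2, 0.0, 1.0))


__all__ = [
    "ConditionalResult",
    "StepwiseResult",
    "conditional_test",
    "region_scan_dense",
    "stepwise_select",
    "variance_explained_by_others",
]
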