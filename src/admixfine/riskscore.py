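"""Unweighted risk-allele score and familial-risk decomposition.

The score for each individual is the summed count of risk alleles over the
score variants; a missing genotype contributes twice the control risk-allele
frequency (its expected count).  Downstream analyses: the per-allele OR of
the aggregate count, quartile ORs with cutpoints from the control
distribution (overall and stratified by first-degree family history), a
case-only severity test, and the closed-form fraction of familial relative
risk explained by the score.

Familial-risk decomposition.  With the allele count approximately normal —
mean ``m0``, SD ``s0`` in controls; mean ``m1`` in cases — and the count
correlation between first-degree relatives equal to ``r`` = 0.5, the mean
count among (unaffected) individuals with one affected first-degree relative
is ``m_rel = m0 (1 - r^2) + m1 r^2``.  The excess ``delta = m_rel - m0``
alleles times the per-allele log odds ratio ``log(lambda)`` gives the
score-implied familial relative risk ``rho_score = exp(log(lambda) delta)``,
and the fraction of the observed familial relative risk ``rho_obs``
explained by the score is ``(rho_score - 1) / (rho_obs - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import (
    SeparationError,
    design_matrix,
    logistic_fit,
)
from .containers import DosageMatrix


def build_score(dosages: DosageMatrix, score_variants: pd.DataFrame) -> np.ndarray:
    """Per-sample risk-allele count over the score variants.

    ``score_variants`` needs columns ``variant_id`` and ``raf`` (control
    risk-allele frequency).  Missing genotypes contribute ``2 * raf``.
    """
    if not {"variant_id", "raf"}.issubset(score_variants.columns):
        raise ValueError("score_variants needs 'variant_id' and 'raf' columns")
    missing = [
        v for v in score_variants["variant_id"] if v not in set(dosages.variant_ids)
    ]
    if missing:
        raise KeyError(f"score variants absent from panel: {missing}")
    counts = np.zeros(dosages.n_samples)
    for _, row in score_variants.iterrows():
        d = dosages.dosage_of(row["variant_id"])
        fill = 2.0 * float(row["raf"])
        counts += np.where(np.isnan(d), fill, d)
    return counts


@dataclass
class PerAlleleOR:
    odds_ratio: float
    ci_lo: float
    ci_hi: float
    p: float
    beta: float
    se: float
    n: int


def per_allele_or(
    counts: np.ndarray,
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> PerAlleleOR:
    """Logistic OR per risk allele for the aggregate count."""
    counts = np.asarray(counts, dtype=float)
    if np.ptp(counts) == 0:
        raise ValueError("count variance is zero")
    y = np.asarray(status, dtype=float)
    Xc, names = design_matrix(covariates, len(counts))
    X = np.column_stack([Xc[:, :1], counts, Xc[:, 1:]])
    fit = logistic_fit(X, y, ["const", "count"] + names[1:])
    b, s = float(fit.params[1]), float(fit.bse[1])
    return PerAlleleOR(
        float(np.exp(b)),
        float(np.exp(b - 1.96 * s)),
        float(np.exp(b + 1.96 * s)),
        fit.wald_p(1),
        b,
        s,
        len(counts),
    )


def control_quartile_cutpoints(counts: np.ndarray, status: np.ndarray) -> np.ndarray:
    """Quartile cutpoints of the count distribution in controls (linear
    interpolation / type-7 quantiles, matching one-decimal printed
    cutpoints such as 28.7 / 30.9 / 32.8)."""
    controls = np.asarray(counts, dtype=float)[np.asarray(status) == 0]
    if controls.size == 0:
        raise ValueError("no controls to define quartiles")
    return np.quantile(controls, [0.25, 0.5, 0.75], method="linear")


def assign_quartiles(counts: np.ndarray, cutpoints: np.ndarray) -> np.ndarray:
    """Quartile index 1-4 per sample (Q1 lowest)."""
    return np.searchsorted(cutpoints, np.asarray(counts, dtype=float), side="right") + 1


@dataclass
class QuartileAnalysis:
    cutpoints: np.ndarray
    overall: pd.DataFrame  # quartile, or, ci_lo, ci_hi, p, n_cases, n_controls
    by_family_history: pd.DataFrame | None = None


def quartile_analysis(
    counts: np.ndarray,
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
    family_history: np.ndarray | None = None,
) -> QuartileAnalysis:
    """Quartile ORs vs the bottom quartile of the control distribution.

    Overall: indicator contrasts Q2-Q4 vs Q1.  Stratified (when a
    family-history column is passed): one model over samples with known
    family history, with indicators for every (stratum, quartile) cell and
    the family-history-negative Q1 cell as reference; rows with missing
    family history are dropped from the stratified table only.
    """
    counts = np.asarray(counts, dtype=float)
    y = np.asarray(status, dtype=float)
    cut = control_quartile_cutpoints(counts, y)
    q = assign_quartiles(counts, cut)

    def _fit_table(idx: np.ndarray, groups: np.ndarray, labels: list, ref) -> pd.DataFrame:
        yy = y[idx]
        Xc, _ = design_matrix(
            covariates.loc[idx].reset_index(drop=True) if covariates is not None else None,
            int(idx.sum()),
        )
        cols, kept = [], []
        for lab in labels:
            if lab == ref:
                continue
            ind = (groups[idx] == lab).astype(float)
            if ind.sum() == 0:
                continue
            cols.append(ind)
            kept.append(lab)
        X = np.column_stack([Xc[:, :1]] + cols + [Xc[:, 1:]])
        rows = [
            {
                "group": ref,
                "or": 1.0,
                "ci_lo": np.nan,
                "ci_hi": np.nan,
                "p": np.nan,
                "n_cases": int(((groups == ref) & (y == 1) & idx).sum()),
                "n_controls": int(((groups == ref) & (y == 0) & idx).sum()),
            }
        ]
        try:
            fit = logistic_fit(X, yy)
            for i, lab in enumerate(kept, start=1):
                b, s = float(fit.params[i]), float(fit.bse[i])
                rows.append(
                    {
                        "group": lab,
                        "or": float(np.exp(b)),
                        "ci_lo": float(np.exp(b - 1.96 * s)),
                        "ci_hi": float(np.exp(b + 1.96 * s)),
                        "p": fit.wald_p(i),
                        "n_cases": int(((groups == lab) & (y == 1) & idx).sum()),
                        "n_controls": int(((groups == lab) & (y == 0) & idx).sum()),
                    }
                )
        except SeparationError:
            for lab in kept:
                rows.append({"group": lab, "or": np.nan, "ci_lo": np.nan,
                             "ci_hi": np.nan, "p": np.nan, "n_cases": 0, "n_controls": 0})
        return pd.DataFrame(rows)

    all_idx = np.ones(len(y), dtype=bool)
    overall = _fit_table(all_idx, q, [1, 2, 3, 4], 1)
    overall = overall.rename(columns={"group": "quartile"})

    strat = None
    if family_history is not None:
        fh = np.asarray(family_history, dtype=float)
        known = ~np.isnan(fh)
        cells = np.array(
            [f"FH{int(f)}_Q{qq}" if k else "NA" for f, qq, k in zip(np.nan_to_num(fh), q, known)]
        )
        labels = [f"FH{f}_Q{qq}" for f in (0, 1) for qq in (1, 2, 3, 4)]
        strat = _fit_table(known, cells, labels, "FH0_Q1").rename(columns={"group": "cell"})
    return QuartileAnalysis(cut, overall, strat)


@dataclass
class SeverityTest:
    odds_ratio: float
    ci_lo: float
    ci_hi: float
    p: float
    n_cases: int


def severity_case_only_test(
    counts: np.ndarray,
    severity: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> SeverityTest:
    """Case-only test of score vs disease severity.

    Logistic regression of advanced (1) vs non-advanced (0) disease on the
    allele count among cases.  Raises when only one severity class is
    present.
    """
    counts = np.asarray(counts, dtype=float)
    sev = np.asarray(severity, dtype=float)
    ok = ~np.isnan(sev)
    counts, sev = counts[ok], sev[ok]
    cov = covariates.loc[ok].reset_index(drop=True) if covariates is not None else None
    if len(np.unique(sev)) < 2:
        raise ValueError("need both severity classes among cases")
    Xc, names = design_matrix(cov, len(counts))
    X = np.column_stack([Xc[:, :1], counts, Xc[:, 1:]])
    fit = logistic_fit(X, sev, ["const", "count"] + names[1:])
    b, s = float(fit.params[1]), float(fit.bse[1])
    return SeverityTest(
        float(np.exp(b)),
        float(np.exp(b - 1.96 * s)),
        float(np.exp(b + 1.96 * s)),
        fit.wald_p(1),
        len(counts),
    )


@dataclass
class FamilialRR:
    odds_ratio: float
    ci_lo: float
    ci_hi: float
    p: float
    n: int


def familial_rr_estimate(
    status: np.ndarray,
    family_history: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> FamilialRR:
    """Odds ratio of case status for a positive first-degree family history
    (rows with missing family history are dropped)."""
    y = np.asarray(status, dtype=float)
    fh = np.asarray(family_history, dtype=float)
    ok = ~np.isnan(fh)
    y, fh = y[ok], fh[ok]
    cov = covariates.loc[ok].reset_index(drop=True) if covariates is not None else None
    if np.ptp(fh) == 0:
        raise ValueError("family history has no variation")
    Xc, names = design_matrix(cov, len(y))
    X = np.column_stack([Xc[:, :1], fh, Xc[:, 1:]])
    fit = logistic_fit(X, y, ["const", "family_history"] + names[1:])
    b, s = float(fit.params[1]), float(fit.bse[1])
    return FamilialRR(
        float(np.exp(b)),
        float(np.exp(b - 1.96 * s)),
        float(np.exp(b + 1.96 * s)),
        fit.wald_p(1),
        len(y),
    )


@dataclass
class FamilialRiskResult:
    """Closed-form familial-risk decomposition.

    Full-precision fields plus a printed-rounding path (``*_display``):
    the relatives' mean and excess are shown to 2 decimals, the
    score-implied RR is rounded to 2 decimals *before* the fraction is
    formed, and the fraction is shown as a whole percent — reproducing the
    conventional hand calculation digit for digit.
    """

    m0: float
    m1: float
    per_allele_or: float
    rho_obs: float
    r: float
    m_rel: float = field(init=False)
    delta: float = field(init=False)
    rho_score: float = field(init=False)
    fraction: float = field(init=False)
    m_rel_display: float = field(init=False)
    delta_display: float = field(init=False)
    rho_score_display: float = field(init=False)
    fraction_pct_display: float = field(init=False)

    def __post_init__(self) -> None:
        r2 = self.r**2
        self.m_rel = self.m0 * (1.0 - r2) + self.m1 * r2
        self.delta = self.m_rel - self.m0
        self.rho_score = float(np.exp(np.log(self.per_allele_or) * self.delta))
        self.fraction = (self.rho_score - 1.0) / (self.rho_obs - 1.0)
        # printed-rounding path
        self.m_rel_display = round(self.m_rel, 2)
        self.delta_display = round(self.m_rel_display - self.m0, 2)
        self.rho_score_display = round(
            float(np.exp(np.log(self.per_allele_or) * self.delta_display)), 2
        )
        self.fraction_pct_display = round(
            100.0 * (self.rho_score_display - 1.0) / (self.rho_obs - 1.0)
        )

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "m0", "m1", "per_allele_or", "rho_obs", "r", "m_rel", "delta",
                "rho_score", "fraction", "m_rel_display", "delta_display",
                "rho_score_display", "fraction_pct_display",
            )
        }


def familial_risk_explained(
    m0: float,
    m1: float,
    per_allele_or: float,
    rho_obs: float,
    r: float = 0.5,
) -> FamilialRiskResult:
    """Fraction of the observed familial relative risk explained by the
    score (see module docstring for the model).

    ``r`` is the allele-count correlation between first-degree relatives
    (0.5 under independent inheritance).  Note the relatives' mean is the
    ``r^2``-weighted mixture of the case and control means, as in the
    conventional hand calculation; ``r`` is exposed so other weightings can
    be explored.
    """
    if per_allele_or <= 0:
        raise ValueError("per-allele OR must be positive")
    if rho_obs <= 1.0:
        raise ValueError("fraction undefined for observed familial RR <= 1")
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    return FamilialRiskResult(m0, m1, per_allele_or, rho_obs, r)


@dataclass
class IndependenceCheck:
    table: pd.DataFrame  # variant_id, beta_single, se_single, beta_joint, se_joint
    max_abs_rel_diff: float
    collinear: list[str]


def independence_check(
    dosages: DosageMatrix,
    variant_ids: list[str],
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
    mean_fill: bool = True,
) -> IndependenceCheck:
    """Compare single-SNP betas with betas from the all-SNP joint model.

    Consistent betas support the score's independence assumption.  Variants
    perfectly collinear with an earlier listed variant are flagged and
    excluded from the joint fit.
    """
    if len(variant_ids) < 2:
        raise ValueError("need >= 2 variants for the independence check")
    from .association import trend_test  # local import to avoid cycle noise

    cols = {}
    collinear = []
    for v in variant_ids:
        d = dosages.dosage_of(v)
        if mean_fill and np.isnan(d).any():
            d = d.copy()
            d[np.isnan(d)] = np.nanmean(d)
        if any(np.isclose(pairwise_r2_safe(d, c), 1.0, atol=1e-12) for c in cols.values()):
            collinear.append(v)
            continue
        cols[v] = d
    y = np.asarray(status, dtype=float)
    Xc, _ = design_matrix(covariates, len(y))
    X = np.column_stack([Xc[:, :1]] + list(cols.values()) + [Xc[:, 1:]])
    joint = logistic_fit(X, y)
    rows = []
    diffs = []
    for i, v in enumerate(cols, start=1):
        single = trend_test(cols[v], status, covariates, v, mean_fill)
        bj, sj = float(joint.params[i]), float(joint.bse[i])
        rows.append(
            {
                "variant_id": v,
                "beta_single": single.beta,
                "se_single": single.se,
                "beta_joint": bj,
                "se_joint": sj,
            }
        )
        if np.isfinite(single.beta) and single.se > 0:
            diffs.append(abs(bj - single.beta) / single.se)
    return IndependenceCheck(
        pd.DataFrame(rows), float(np.max(diffs)) if diffs else np.nan, collinear
    )


def pairwise_r2_safe(a: np.ndarray, b: np.ndarray) -> float:
    from .ld import pairwise_r2

    try:
        r2 = pairwise_r2(a, b)
    except ValueError:
        return float("nan")
    return r2


__all__ = [
    "FamilialRR",
    "FamilialRiskResult",
    "IndependenceCheck",
    "PerAlleleOR",
    "QuartileAnalysis",
    "SeverityTest",
    "assign_quartiles",
    "build_score",
    "control_quartile_cutpoints",
    "familial_risk_explained",
    "familial_rr_estimate",
    "independence_check",
    "per_allele_or",
    "quartile_analysis",
    "severity_case_only_test",
]
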