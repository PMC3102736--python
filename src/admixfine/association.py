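"""Per-variant logistic association tests for admixed case-control data.

The workhorse is the 1-df Wald trend test: an unconditional logistic
regression of case status on risk-allele dosage, adjusted for age, study,
global-ancestry eigenvectors and the region-average local ancestry.  The
per-allele odds ratio is ``exp(beta)`` with Wald 95% CI
``exp(beta +/- 1.96 SE)`` and p-value from the chi-square of ``(beta/SE)^2``
on 1 df.  Imputed variants are analyzed on their continuous dosage (standard
dosage practice); single-variant fits use complete cases by default, with an
optional mean-genotype fill matching the stepwise procedure.

Study heterogeneity is assessed with Cochran's Q over study-specific
per-allele log odds ratios with inverse-variance weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

try:  # statsmodels moved/renamed this across versions
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    class PerfectSeparationError(Exception):
        pass


class SeparationError(RuntimeError):
    """The logistic likelihood has no finite maximizer (data separation)."""


@dataclass
class LogisticFit:
    params: np.ndarray
    bse: np.ndarray
    names: list[str]
    n: int
    llf: float
    converged: bool

    def wald_p(self, i: int) -> float:
        z = self.params[i] / self.bse[i]
        return float(stats.chi2.sf(z * z, 1))


def design_matrix(
    covariates: pd.DataFrame | None, n: int
) -> tuple[np.ndarray, list[str]]:
    """Intercept + numeric covariates; string/categorical columns become
    treatment-coded indicators.  Constant columns are dropped (they are
    collinear with the intercept and must not change any estimate)."""
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["const"]
    if covariates is not None:
        if len(covariates) != n:
            raise ValueError("covariate rows do not match samples")
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=name, drop_first=True)
                for dname in dummies.columns:
                    cols.append(dummies[dname].to_numpy(dtype=float))
                    names.append(str(dname))
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(str(name))
    X = np.column_stack(cols)
    keep = [0] + [i for i in range(1, X.shape[1]) if np.ptp(X[:, i]) > 0]
    return X[:, keep], [names[i] for i in keep]


def logistic_fit(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic fit (Newton), raising
    :class:`SeparationError` on (quasi-)separation or a singular design."""
    y = np.asarray(y, dtype=float)
    names = names or [f"x{i}" for i in range(X.shape[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(method="newton", disp=0, maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(str(exc)) from exc
    if not np.isfinite(res.bse).all() or np.any(res.bse > 1e4):
        raise SeparationError("non-finite or exploding standard errors")
    return LogisticFit(
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        names=list(names),
        n=len(y),
        llf=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
    )


@dataclass
class AssocResult:
    """Per-variant trend-test summary (log-additive allele-dosage model)."""

    variant_id: str
    beta: float = np.nan
    se: float = np.nan
    odds_ratio: float = np.nan
    ci_lo: float = np.nan
    ci_hi: float = np.nan
    p_trend: float = np.nan
    n: int = 0
    covariates: str = ""
    raf_cases: float = np.nan
    raf_controls: float = np.nan
    skip_reason: str | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def estimable(self) -> bool:
        return self.skip_reason is None and np.isfinite(self.beta)


def _complete_mask(dosage: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    ok = ~np.isnan(dosage)
    if covariates is not None:
        num = covariates.select_dtypes(include=[np.number])
        if not num.empty:
            ok &= ~num.isna().any(axis=1).to_numpy()
    return ok


def trend_test(
    dosage: np.ndarray,
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
    variant_id: str = "",
    mean_fill: bool = False,
) -> AssocResult:
    """1-df Wald chi-square trend test of case status on allele dosage.

    Parameters
    ----------
    dosage
        Risk-allele dosage in [0, 2], NaN = missing.
    status
        0/1 case status.
    covariates
        Optional adjustment frame (age, study, eigenvectors, local
        ancestry); string columns are indicator-expanded.
    mean_fill
        Replace missing dosages with the mean of observed dosages instead of
        dropping those samples (the stepwise procedure's convention).
    """
    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status)
    if mean_fill and np.isnan(dosage).any():
        dosage = dosage.copy()
        dosage[np.isnan(dosage)] = np.nanmean(dosage)
    mask = _complete_mask(dosage, covariates)
    d = dosage[mask]
    y = status[mask]
    cov = covariates.loc[mask].reset_index(drop=True) if covariates is not None else None
    res = AssocResult(variant_id=variant_id, n=int(mask.sum()))
    res.covariates = ",".join(covariates.columns) if covariates is not None else ""
    if len(d) == 0 or np.ptp(d) == 0:
        res.skip_reason = "constant dosage"
        return res
    if len(np.unique(y)) < 2:
        res.skip_reason = "no case/control contrast"
        return res

    Xc, names = design_matrix(cov, len(d))
    X = np.column_stack([Xc[:, :1], d, Xc[:, 1:]])
    try:
        fit = logistic_fit(X, y, ["const", "dosage"] + names[1:])
    except SeparationError as exc:
        res.skip_reason = f"separation: {exc}"
        res.flags.append("separation")
        return res
    res.beta = float(fit.params[1])
    res.se = float(fit.bse[1])
    res.odds_ratio = float(np.exp(res.beta))
    res.ci_lo = float(np.exp(res.beta - 1.96 * res.se))
    res.ci_hi = float(np.exp(res.beta + 1.96 * res.se))
    res.p_trend = fit.wald_p(1)
    res.raf_cases = float(np.nanmean(d[y == 1]) / 2.0) if (y == 1).any() else np.nan
    res.raf_controls = float(np.nanmean(d[y == 0]) / 2.0) if (y == 0).any() else np.nan
    if not fit.converged:
        res.flags.append("not_converged")
    return res


@dataclass
class GenotypeClassResult:
    """ORs for heterozygotes and risk-homozygotes vs reference homozygotes."""

    variant_id: str
    or_het: float = np.nan
    ci_het: tuple[float, float] = (np.nan, np.nan)
    p_het_class: float = np.nan
    or_hom: float = np.nan
    ci_hom: tuple[float, float] = (np.nan, np.nan)
    p_hom_class: float = np.nan
    n: int = 0


def genotype_class_test(
    dosage: np.ndarray,
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
    variant_id: str = "",
) -> GenotypeClassResult:
    """Logistic fit with separate indicators for the het and hom-risk classes.

    Requires hard genotype calls (0/1/2).  A class that is absent yields NA
    for its contrast; the other contrast is still estimated.
    """
    dosage = np.asarray(dosage, dtype=float)
    mask = _complete_mask(dosage, covariates)
    g = dosage[mask]
    if not np.isin(g, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype-class test requires typed 0/1/2 calls")
    y = np.asarray(status)[mask]
    cov = covariates.loc[mask].reset_index(drop=True) if covariates is not None else None
    out = GenotypeClassResult(variant_id=variant_id, n=int(mask.sum()))

    have_het = (g == 1).any()
    have_hom = (g == 2).any()
    if not (g == 0).any() or not (have_het or have_hom):
        return out
    indicators = []
    labels = []
    if have_het:
        indicators.append((g == 1).astype(float))
        labels.append("het")
    if have_hom:
        indicators.append((g == 2).astype(float))
        labels.append("hom")
    Xc, names = design_matrix(cov, len(g))
    X = np.column_stack([Xc[:, :1]] + indicators + [Xc[:, 1:]])
    try:
        fit = logistic_fit(X, y, ["const"] + labels + names[1:])
    except SeparationError:
        return out
    for k, lab in enumerate(labels, start=1):
        b, s = float(fit.params[k]), float(fit.bse[k])
        ci = (float(np.exp(b - 1.96 * s)), float(np.exp(b + 1.96 * s)))
        if lab == "het":
            out.or_het, out.ci_het, out.p_het_class = float(np.exp(b)), ci, fit.wald_p(k)
        else:
            out.or_hom, out.ci_hom, out.p_hom_class = float(np.exp(b)), ci, fit.wald_p(k)
    return out


def cochran_q(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float, int]:
    """Cochran's Q over stratum effects with inverse-variance weights.

    Returns ``(Q, p, df)`` with p from chi-square on ``len(betas) - 1`` df.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ok = np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
    betas, ses = betas[ok], ses[ok]
    k = len(betas)
    if k < 2:
        raise ValueError("need >= 2 estimable strata for heterogeneity")
    w = 1.0 / ses**2
    pooled = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - pooled) ** 2))
    df = k - 1
    return q, float(stats.chi2.sf(q, df)), df


@dataclass
class HeterogeneityResult:
    variant_id: str
    q: float
    p_het: float
    df: int
    per_study: pd.DataFrame


def heterogeneity_by_study(
    dosage: np.ndarray,
    status: np.ndarray,
    covariates: pd.DataFrame | None,
    studies: np.ndarray | pd.Series,
    variant_id: str = "",
) -> HeterogeneityResult:
    """Test heterogeneity of the per-allele effect across studies.

    Fits the trend model separately within each study stratum (the study
    indicator itself is removed from the covariates) and combines the
    stratum betas with Cochran's Q.  Inestimable strata are dropped with a
    warning and the degrees of freedom reduced.
    """
    studies = np.asarray(studies)
    cov = None
    if covariates is not None:
        cov = covariates.drop(columns=[c for c in covariates.columns if c == "study"])
        if cov.shape[1] == 0:
            cov = None
    rows = []
    for s in pd.unique(studies):
        sel = studies == s
        sub_cov = cov.loc[sel].reset_index(drop=True) if cov is not None else None
        r = trend_test(np.asarray(dosage)[sel], np.asarray(status)[sel], sub_cov)
        rows.append({"study": s, "beta": r.beta, "se": r.se, "n": r.n, "skip": r.skip_reason})
        if r.skip_reason:
            warnings.warn(f"study {s} dropped from heterogeneity test: {r.skip_reason}")
    per_study = pd.DataFrame(rows)
    q, p, df = cochran_q(per_study["beta"].to_numpy(), per_study["se"].to_numpy())
    return HeterogeneityResult(variant_id, q, p, df, per_study)


def covariate_frame(
    sample_table: pd.DataFrame,
    eigenvectors: np.ndarray | None = None,
    n_eigenvectors: int = 10,
    local_ancestry: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the standard adjustment frame: age, study, top eigenvectors
    and (optionally) region-average local ancestry."""
    cov = pd.DataFrame(
        {"age": sample_table["age"].to_numpy(dtype=float), "study": sample_table["study"].astype(str)}
    )
    if eigenvectors is not None:
        k = min(n_eigenvectors, eigenvectors.shape[1])
        for j in range(k):
            cov[f"EV{j + 1}"] = eigenvectors[:, j]
    if local_ancestry is not None:
        cov["local_ancestry"] = np.asarray(local_ancestry, dtype=float)
    return cov


def association_scan(
    dosages,
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
    variant_ids: list[str] | None = None,
    mean_fill: bool = False,
) -> pd.DataFrame:
    """Run the trend test over many variants; returns a tidy results frame."""
    ids = variant_ids if variant_ids is not None else dosages.variant_ids
    rows = []
    for vid in ids:
        j = dosages.variant_index(vid)
        r = trend_test(dosages.dosages[:, j], status, covariates, vid, mean_fill)
        meta = dosages.variants.iloc[j]
        rows.append(
            {
                "variant_id": vid,
                "chrom": meta["chrom"],
                "pos": meta["pos"],
                "risk_allele": meta["risk_allele"],
                "raf_controls": r.raf_controls,
                "beta": r.beta,
                "se": r.se,
                "or": r.odds_ratio,
                "ci_lo": r.ci_lo,
                "ci_hi": r.ci_hi,
                "p_trend": r.p_trend,
                "n": r.n,
                "flags": ";".join(r.flags) if not r.skip_reason else r.skip_reason,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "AssocResult",
    "GenotypeClassResult",
    "HeterogeneityResult",
    "LogisticFit",
    "SeparationError",
    "association_scan",
    "cochran_q",
    "covariate_frame",
    "design_matrix",
    "genotype_class_test",
    "heterogeneity_by_study",
    "logistic_fit",
    "trend_test",
]
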