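"""Global and local ancestry handling.

Global ancestry is summarized by principal components of the standardized
genotype matrix (center ``2 p-hat``, scale ``sqrt(2 p-hat (1 - p-hat))`` —
the EIGENSTRAT convention), with a 4-SD outlier rule on the first two
eigenvectors.  Local ancestry (expected count of population-1 chromosomes,
0-2) is an input contract — estimated upstream or taken from simulator truth
— summarized per risk region as the arithmetic mean over the region's
variants and used as a covariate in association models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import SeparationError, design_matrix, logistic_fit
from .containers import DataError, DosageMatrix, LocalAncestryTrack, RiskRegion


@dataclass
class GlobalAncestry:
    """Sample coordinates on the top-K eigenvectors.

    ``coordinates`` columns are unit-norm eigenvectors of the sample
    covariance (zero mean across samples); ``eigenvalues`` holds the full
    spectrum so variance explained can be computed for any K.  The sign of
    each eigenvector is fixed by making the first sample's loading
    non-negative.
    """

    coordinates: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray  # full spectrum, descending
    samples: list[str]

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def variance_explained(self, k: int | None = None) -> float:
        k = k if k is not None else self.k
        total = self.eigenvalues.sum()
        if total <= 0:
            return 0.0
        return float(self.eigenvalues[:k].sum() / total)


def compute_pca(dosages: DosageMatrix, k: int = 10) -> GlobalAncestry:
    """Top-k principal components of the standardized dosage matrix.

    Missing calls are mean-imputed for the decomposition only.  Monomorphic
    variants are dropped.  Raises on a degenerate (zero-variance) matrix or
    when ``k`` exceeds the achievable rank.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = dosages.mean_filled()
    p_hat = X.mean(axis=0) / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    X = X[:, poly]
    p_hat = p_hat[poly]
    if X.shape[1] == 0:
        raise DataError("degenerate dosage matrix: no polymorphic variants")
    Z = (X - 2.0 * p_hat) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    # columns of Z are centered, so eigenvector coordinates have zero mean
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    n = dosages.n_samples
    eigenvalues = s**2 / max(n - 1, 1)
    rank = int(np.sum(s > s[0] * 1e-9)) if s.size else 0
    if rank == 0:
        raise DataError("degenerate dosage matrix: zero variance")
    if k > rank or k > n - 1:
        raise ValueError(f"k={k} exceeds rank ({min(rank, n - 1)})")
    coords = U[:, :k]
    signs = np.where(coords[0] < 0, -1.0, 1.0)
    return GlobalAncestry(coords * signs, eigenvalues, list(dosages.samples))


def flag_ancestry_outliers(ga: GlobalAncestry, n_sd: float = 4.0) -> list[str]:
    """Samples beyond ``n_sd`` SDs of the mean on eigenvector 1 or 2."""
    if len(ga.samples) < 10:
        raise DataError("need >= 10 samples for outlier flagging")
    flagged: set[int] = set()
    for j in range(min(2, ga.k)):
        v = ga.coordinates[:, j]
        sd = v.std()
        if sd == 0:
            continue
        flagged.update(np.flatnonzero(np.abs(v - v.mean()) / sd > n_sd).tolist())
    return [ga.samples[i] for i in sorted(flagged)]


def summarize_local_ancestry(
    track: LocalAncestryTrack, region: RiskRegion, variants: pd.DataFrame
) -> np.ndarray:
    """Per-sample arithmetic mean of local-ancestry estimates within the
    region bounds; used as the region's adjustment covariate."""
    # track variants absent from the table (e.g. QC-removed) cannot be
    # placed on the map and are excluded from the average
    meta = variants.set_index("variant_id").reindex(track.variant_ids)
    mask = (
        (meta["chrom"].astype(str) == region.chrom)
        & (meta["pos"] >= region.start)
        & (meta["pos"] <= region.end)
    ).fillna(False).to_numpy()
    if not mask.any():
        raise DataError(f"region {region.name} has no local-ancestry estimates")
    return track.values[:, mask].mean(axis=1)


@dataclass
class AncestryAssociation:
    odds_ratio: float  # per population-1 chromosome
    ci_lo: float
    ci_hi: float
    p: float
    beta: float
    se: float
    n: int


def local_ancestry_association(
    region_average: np.ndarray,
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> AncestryAssociation:
    """Logistic model of case status on region-average local ancestry.

    The OR is per population-1 chromosome; adjust for age, study and global
    eigenvectors via ``covariates``.  Raises :class:`SeparationError` with a
    diagnostic when the fit separates.
    """
    x = np.asarray(region_average, dtype=float)
    y = np.asarray(status)
    Xc, names = design_matrix(covariates, len(x))
    X = np.column_stack([Xc[:, :1], x, Xc[:, 1:]])
    try:
        fit = logistic_fit(X, y, ["const", "local_ancestry"] + names[1:])
    except SeparationError as exc:
        raise SeparationError(
            f"local-ancestry association separated (n={len(x)}): {exc}"
        ) from exc
    b, s = float(fit.params[1]), float(fit.bse[1])
    return AncestryAssociation(
        odds_ratio=float(np.exp(b)),
        ci_lo=float(np.exp(b - 1.96 * s)),
        ci_hi=float(np.exp(b + 1.96 * s)),
        p=fit.wald_p(1),
        beta=b,
        se=s,
        n=len(x),
    )


__all__ = [
    "AncestryAssociation",
    "GlobalAncestry",
    "compute_pca",
    "flag_ancestry_outliers",
    "local_ancestry_association",
    "summarize_local_ancestry",
]
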