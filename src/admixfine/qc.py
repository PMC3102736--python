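"""Sample and variant quality control.

Implements the exclusion rules of a typical array-based case-control study:
sample call rate < 95%, variant call rate < 95%, MAF < 1% (strictly below;
a variant at exactly 1% is retained), more than one discordant call across
replicate pairs, and imputation quality Rsq < 0.3 for imputed dosages.

Relatedness is inferred with the PLINK-style method-of-moments IBD
estimator: identity-by-state counts across typed variants are converted to
the probabilities (Z0, Z1, Z2) of sharing 0/1/2 alleles identical by
descent, using allele frequencies estimated from the full post-filter
sample.  A pair is labelled MZ / parent-offspring / full-sibling /
half-sibling when every component of the observed Z vector lies within one
configurable SD of that relationship's expectation; related individuals are
pruned by iteratively removing the maximum-degree member of the related-pair
graph (ties and isolated pairs resolved by a seeded random choice).

Note: the moment estimator assumes homogeneous allele frequencies; in an
admixed sample, ancestry stratification inflates apparent relatedness for
pairs of similar ancestry.  Truly related pairs still stand far above this
background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import DataError, DosageMatrix

EXPECTED_Z = {
    "MZ": np.array([0.0, 0.0, 1.0]),
    "parent-offspring": np.array([0.0, 1.0, 0.0]),
    "full-sibling": np.array([0.25, 0.5, 0.25]),
    "half-sibling": np.array([0.5, 0.5, 0.0]),
}


@dataclass
class IBDEstimate:
    """Method-of-moments IBD sharing probabilities for one sample pair."""

    id1: str
    id2: str
    z0: float
    z1: float
    z2: float
    n_variants: int
    label: str = "unrelated"

    @property
    def z(self) -> np.ndarray:
        return np.array([self.z0, self.z1, self.z2])

    @property
    def pi_hat(self) -> float:
        return 0.5 * self.z1 + self.z2


@dataclass
class QCReport:
    """Removal log: every removal cites exactly one triggering rule."""

    samples_removed: list[tuple[str, str, float]] = field(default_factory=list)
    variants_removed: list[tuple[str, str, float]] = field(default_factory=list)
    concordance: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", sid, reason, value) for sid, reason, value in self.samples_removed]
        rows += [("variant", vid, reason, value) for vid, reason, value in self.variants_removed]
        return pd.DataFrame(rows, columns=["entity_type", "entity", "reason", "value"])


def filter_samples(
    dosages: DosageMatrix, call_rate_min: float = 0.95, report: QCReport | None = None
) -> tuple[DosageMatrix, QCReport]:
    """Remove samples whose call rate over typed variants is below threshold."""
    report = report or QCReport()
    typed = dosages.variants["typed"].to_numpy(dtype=bool)
    if typed.any():
        rates = (~np.isnan(dosages.dosages[:, typed])).mean(axis=1)
    else:
        rates = np.ones(dosages.n_samples)
    bad = np.flatnonzero(rates < call_rate_min)
    for i in bad:
        report.samples_removed.append((dosages.samples[i], "call_rate", float(rates[i])))
    keep = np.setdiff1d(np.arange(dosages.n_samples), bad)
    return dosages.subset(sample_idx=keep), report


def _variant_mismatch_counts(
    dosages: DosageMatrix, replicate_pairs: list[tuple[str, str]]
) -> np.ndarray:
    counts = np.zeros(dosages.n_variants, dtype=int)
    for a, b in replicate_pairs:
        ga = dosages.dosages[dosages.sample_index(a)]
        gb = dosages.dosages[dosages.sample_index(b)]
        ok = ~np.isnan(ga) & ~np.isnan(gb)
        counts += (ok & (ga != gb)).astype(int)
    return counts


def filter_variants(
    dosages: DosageMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    max_qc_mismatch: int = 1,
    replicate_pairs: list[tuple[str, str]] | None = None,
) -> tuple[DosageMatrix, QCReport]:
    """Apply the variant exclusion rules.

    Rules (checked in order; the first failure is the cited reason):
    call rate < ``call_rate_min`` (typed variants only — imputed dosages are
    complete by construction), MAF strictly below ``maf_min`` (computed on
    non-missing calls), and more than ``max_qc_mismatch`` discordant calls
    across replicate pairs.
    """
    if dosages.n_variants == 0 or dosages.n_samples == 0:
        raise DataError("empty dosage matrix")
    if not (0 <= call_rate_min <= 1 and 0 <= maf_min <= 1):
        raise DataError("thresholds must lie in [0, 1]")
    report = QCReport()
    typed = dosages.variants["typed"].to_numpy(dtype=bool)
    call = dosages.call_rate("variant")
    maf = dosages.maf()
    mismatch = (
        _variant_mismatch_counts(dosages, replicate_pairs)
        if replicate_pairs
        else np.zeros(dosages.n_variants, dtype=int)
    )
    drop = []
    for j, vid in enumerate(dosages.variant_ids):
        if typed[j] and call[j] < call_rate_min:
            report.variants_removed.append((vid, "call_rate", float(call[j])))
        elif maf[j] < maf_min:
            report.variants_removed.append((vid, "maf", float(maf[j])))
        elif mismatch[j] > max_qc_mismatch:
            report.variants_removed.append((vid, "qc_mismatch", float(mismatch[j])))
        else:
            continue
        drop.append(j)
    keep = np.setdiff1d(np.arange(dosages.n_variants), drop)
    return dosages.subset(variant_idx=keep), report


def filter_imputation_quality(
    dosages: DosageMatrix, rsq_min: float = 0.3, report: QCReport | None = None
) -> tuple[DosageMatrix, QCReport]:
    """Drop imputed variants with Rsq below threshold (typed are untouched)."""
    report = report or QCReport()
    typed = dosages.variants["typed"].to_numpy(dtype=bool)
    rsq = dosages.variants["rsq"].to_numpy(dtype=float)
    drop = np.flatnonzero(~typed & (rsq < rsq_min))
    for j in drop:
        report.variants_removed.append((dosages.variant_ids[j], "rsq", float(rsq[j])))
    keep = np.setdiff1d(np.arange(dosages.n_variants), drop)
    return dosages.subset(variant_idx=keep), report


def replicate_concordance(
    dosages: DosageMatrix, replicate_pairs: list[tuple[str, str]]
) -> dict[tuple[str, str], float]:
    """Per-pair concordance: matching non-missing integer calls over
    comparable calls; NA (NaN) when a pair has no comparable calls."""
    typed = dosages.variants["typed"].to_numpy(dtype=bool)
    out: dict[tuple[str, str], float] = {}
    for a, b in replicate_pairs:
        ga = dosages.dosages[dosages.sample_index(a)][typed]
        gb = dosages.dosages[dosages.sample_index(b)][typed]
        ok = ~np.isnan(ga) & ~np.isnan(gb)
        out[(a, b)] = float((ga[ok] == gb[ok]).mean()) if ok.any() else float("nan")
    return out


# ----------------------------------------------------------------------
# IBD
# ----------------------------------------------------------------------


def estimate_ibd(
    dosages: DosageMatrix,
    pair: tuple[str, str],
    freqs: np.ndarray | None = None,
    min_variants: int = 1000,
) -> IBDEstimate:
    """Method-of-moments (Z0, Z1, Z2) for one pair from IBS counts.

    Uses typed, polymorphic variants where both samples are called.  Allele
    frequencies default to the full-sample estimate.  Components are clipped
    to [0, 1] and renormalized to sum to one.
    """
    a, b = pair
    ia, ib = dosages.sample_index(a), dosages.sample_index(b)
    typed = dosages.variants["typed"].to_numpy(dtype=bool)
    p_all = freqs if freqs is not None else dosages.allele_freq()
    ga = dosages.dosages[ia]
    gb = dosages.dosages[ib]
    ok = typed & ~np.isnan(ga) & ~np.isnan(gb) & (p_all > 0) & (p_all < 1)
    m = int(ok.sum())
    if m == 0:
        raise DataError(f"no overlapping typed calls for pair {pair}")
    if m < min_variants:
        warnings.warn(f"only {m} overlapping variants for pair {pair}; IBD is noisy")
    ga, gb, p = ga[ok], gb[ok], p_all[ok]
    q = 1.0 - p
    ibs = 2.0 - np.abs(ga - gb)
    n_ibs0 = float((ibs == 0).sum())
    n_ibs1 = float((ibs == 1).sum())
    n_ibs2 = float((ibs == 2).sum())

    # expected per-variant IBS counts conditional on IBD state
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_ibd0 = float(np.sum(p**4 + 4 * p**2 * q**2 + q**4))
    e1_ibd1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_ibd1 = float(np.sum(p**3 + p**2 * q + p * q**2 + q**3))

    z0 = n_ibs0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    z1 = (n_ibs1 - z0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    z2 = (n_ibs2 - z0 * e2_ibd0 - z1 * e2_ibd1) / m
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    total = z.sum()
    if total > 0:
        z = z / total
    est = IBDEstimate(a, b, float(z[0]), float(z[1]), float(z[2]), m)
    assert abs(est.z0 + est.z1 + est.z2 - 1.0) < 1e-6
    return est


def classify_relationship(estimate: IBDEstimate, sd: float = 0.1) -> str:
    """Label a pair by the 1-SD rule.

    The pair gets a relationship label iff every component of its observed Z
    lies within ``sd`` of that relationship's expected vector; no match means
    "unrelated"; multiple matches are broken toward the smallest Euclidean
    distance.
    """
    z = estimate.z
    matches = [
        (float(np.linalg.norm(z - exp)), name)
        for name, exp in EXPECTED_Z.items()
        if np.all(np.abs(z - exp) <= sd + 1e-12)
    ]
    if not matches:
        return "unrelated"
    return min(matches)[1]


def find_related_pairs(
    dosages: DosageMatrix,
    sd: float = 0.1,
    freqs: np.ndarray | None = None,
    min_variants: int = 1000,
) -> list[IBDEstimate]:
    """Scan all sample pairs; return those classified as related."""
    p = freqs if freqs is not None else dosages.allele_freq()
    out = []
    n = dosages.n_samples
    for i in range(n):
        for j in range(i + 1, n):
            est = estimate_ibd(
                dosages, (dosages.samples[i], dosages.samples[j]), p, min_variants
            )
            est.label = classify_relationship(est, sd)
            if est.label != "unrelated":
                out.append(est)
    return out


def prune_related(
    pairs: list[tuple[str, str]], seed: int | np.random.Generator = 0
) -> list[str]:
    """Choose samples to remove so no related pair survives.

    Iteratively removes the node with the highest degree in the related-pair
    graph; degree ties (including isolated pairs, where both members have
    degree one) are broken by a seeded random choice.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = nx.Graph()
    g.add_edges_from(pairs)
    removed: list[str] = []
    while g.number_of_edges() > 0:
        degrees = dict(g.degree())
        top = max(degrees.values())
        candidates = sorted(n for n, d in degrees.items() if d == top)
        node = candidates[0] if len(candidates) == 1 else candidates[int(rng.integers(len(candidates)))]
        removed.append(node)
        g.remove_node(node)
    return removed


__all__ = [
    "EXPECTED_Z",
    "IBDEstimate",
    "QCReport",
    "classify_relationship",
    "estimate_ibd",
    "filter_imputation_quality",
    "filter_samples",
    "filter_variants",
    "find_related_pairs",
    "prune_related",
    "replicate_concordance",
]
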