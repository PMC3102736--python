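"""Linkage disequilibrium, tag-SNP selection and significance thresholds.

``r^2`` is the squared Pearson correlation of allele dosages (composite LD;
works for unphased and imputed data).  ``D'`` is computed from haplotype
frequencies estimated by EM over the 3x3 genotype table and is used to
define LD blocks for window extension.  Fine-mapping windows span +/- 250 kb
around each index signal, extended to cover any containing D'-block and
merged across nearby indices.

The two-tier significance thresholds derive from greedy tag-SNP counts:
``alpha_a`` (index-correlated candidates) is 0.05 over the number of tags
needed to capture the correlated set at r^2 >= 0.8 — either per region or,
by default, the cross-region average count; ``alpha_b`` (novel candidates)
is 0.05 over the total number of tags needed to capture all common alleles
across regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DosageMatrix


@dataclass
class LDResult:
    id1: str
    id2: str
    r2: float
    dprime: float
    n: int


def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation over samples where both dosages are
    observed; NaN when either variant has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        raise ValueError("need >= 2 complete pairs for r^2")
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return float("nan")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def r2_matrix(dosages: DosageMatrix, variant_ids: list[str] | None = None) -> pd.DataFrame:
    """Symmetric pairwise r^2 matrix (diagonal 1 for polymorphic variants)."""
    ids = variant_ids if variant_ids is not None else dosages.variant_ids
    cols = np.column_stack([dosages.dosage_of(v) for v in ids])
    k = len(ids)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                out[i, j] = 1.0 if np.nanvar(cols[:, i]) > 0 else np.nan
            else:
                out[i, j] = out[j, i] = pairwise_r2(cols[:, i], cols[:, j])
    return pd.DataFrame(out, index=ids, columns=ids)


# ----------------------------------------------------------------------
# D' via genotype EM
# ----------------------------------------------------------------------


def em_haplotype_freqs(
    ga: np.ndarray, gb: np.ndarray, max_iter: int = 500, tol: float = 1e-10
) -> np.ndarray:
    """Haplotype frequencies (AB, Ab, aB, ab) from unphased genotype pairs.

    Standard EM: only the double-heterozygote class is phase-ambiguous; its
    expected split between AB/ab and Ab/aB couplings is updated from the
    current haplotype frequencies.
    """
    ga = np.asarray(ga, dtype=float)
    gb = np.asarray(gb, dtype=float)
    ok = ~np.isnan(ga) & ~np.isnan(gb)
    ga, gb = ga[ok].astype(int), gb[ok].astype(int)
    if len(ga) == 0:
        raise ValueError("no complete genotype pairs")
    n = len(ga)
    # genotype table counts
    table = np.zeros((3, 3))
    for i, j in zip(ga, gb):
        table[i, j] += 1

    pA = ga.mean() / 2.0
    pB = gb.mean() / 2.0
    # haplotype counts contributed unambiguously by each genotype class:
    # class (i, j) with i, j in {0,1,2}; double het (1,1) is ambiguous.
    h = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    h = np.clip(h, 1e-6, None)
    h /= h.sum()
    # haplotypes contributed unambiguously by each genotype class (AB, Ab, aB, ab)
    unambiguous = {
        (0, 0): (0, 0, 0, 2),
        (0, 1): (0, 0, 1, 1),
        (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1),
        (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0),
        (2, 1): (1, 1, 0, 0),
        (2, 2): (2, 0, 0, 0),
    }
    base = np.zeros(4)
    for (i, j), contrib in unambiguous.items():
        if table[i, j]:
            base += table[i, j] * np.asarray(contrib, dtype=float)
    for _ in range(max_iter):
        c = base.copy()
        dh = table[1, 1]
        if dh > 0:
            coupling = h[0] * h[3]
            repulsion = h[1] * h[2]
            denom = coupling + repulsion
            w = 0.5 if denom == 0 else coupling / denom
            c += dh * np.array([w, 1 - w, 1 - w, w])
        new = c / (2.0 * n)
        if np.max(np.abs(new - h)) < tol:
            h = new
            break
        h = new
    return h


def dprime(ga: np.ndarray, gb: np.ndarray) -> float:
    """Normalized disequilibrium |D| / D_max from EM haplotype frequencies;
    NaN for a monomorphic variant."""
    ga = np.asarray(ga, dtype=float)
    gb = np.asarray(gb, dtype=float)
    ok = ~np.isnan(ga) & ~np.isnan(gb)
    if ok.sum() == 0 or np.nanvar(ga[ok]) == 0 or np.nanvar(gb[ok]) == 0:
        return float("nan")
    h = em_haplotype_freqs(ga, gb)
    pA = h[0] + h[1]
    pB = h[0] + h[2]
    d = h[0] - pA * pB
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax <= 0:
        return float("nan")
    return float(min(abs(d) / dmax, 1.0))


def dprime_blocks(
    dosages: DosageMatrix, threshold: float = 0.8, typed_only: bool = True
) -> list[tuple[int, int]]:
    """Greedy LD blocks: maximal runs of consecutive variants whose adjacent
    pairs all have D' >= threshold.  Returns 1-based closed position bounds."""
    meta = dosages.variants
    use = meta["typed"].to_numpy(dtype=bool) if typed_only else np.ones(len(meta), bool)
    idx = np.flatnonzero(use)
    blocks = []
    start = None
    for a, b in zip(idx[:-1], idx[1:]):
        dp = dprime(dosages.dosages[:, a], dosages.dosages[:, b])
        linked = np.isfinite(dp) and dp >= threshold
        if linked and start is None:
            start = a
        if not linked and start is not None:
            blocks.append((int(meta["pos"].iloc[start]), int(meta["pos"].iloc[a])))
            start = None
    if start is not None:
        blocks.append((int(meta["pos"].iloc[start]), int(meta["pos"].iloc[idx[-1]])))
    return blocks


# ----------------------------------------------------------------------
# windows, correlated sets, tags, alphas
# ----------------------------------------------------------------------


def build_window(
    index_positions: list[int],
    flank: int = 250_000,
    blocks: list[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Fine-mapping window(s): +/- ``flank`` around each index position,
    extended to cover any D'-block containing the index, merged when
    overlapping.  1-based closed intervals."""
    if not index_positions:
        raise ValueError("need at least one index position")
    intervals = []
    for pos in index_positions:
        # 1-based closed interval of width 2 * flank containing the index
        lo, hi = max(1, pos - flank + 1), pos + flank
        for b0, b1 in blocks or []:
            if b0 <= pos <= b1:
                lo, hi = min(lo, b0), max(hi, b1)
        intervals.append((lo, hi))
    intervals.sort()
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def correlated_set(
    dosages: DosageMatrix,
    index_ids: list[str],
    window: list[tuple[int, int]],
    r2_index: float = 0.2,
    reference_idx: np.ndarray | None = None,
) -> list[str]:
    """Window variants with r^2 >= ``r2_index`` to any index signal.

    ``reference_idx`` restricts the samples used for LD (e.g. controls only
    or a designated reference subset).  Index variants absent from the panel
    contribute nothing; an isolated, absent index yields an empty set.
    """
    meta = dosages.variants
    pos = meta["pos"].to_numpy()
    in_window = np.zeros(len(meta), dtype=bool)
    for lo, hi in window:
        in_window |= (pos >= lo) & (pos <= hi)
    present = [v for v in index_ids if v in set(meta["variant_id"])]
    if not present:
        return []
    d = dosages.dosages if reference_idx is None else dosages.dosages[reference_idx]
    index_cols = [d[:, dosages.variant_index(v)] for v in present]
    out = []
    for j in np.flatnonzero(in_window):
        col = d[:, j]
        for icol in index_cols:
            r2 = pairwise_r2(col, icol)
            if np.isfinite(r2) and r2 >= r2_index:
                out.append(meta["variant_id"].iloc[j])
                break
    return out


def greedy_tags(
    variant_ids: list[str],
    ld: pd.DataFrame,
    r2_tag: float = 0.8,
    positions: dict[str, int] | None = None,
) -> list[str]:
    """Greedy maximum-coverage tag selection.

    Repeatedly picks the variant covering the most uncovered members (a
    variant covers itself and every member with r^2 >= ``r2_tag``); ties go
    to the lowest genomic position (then lexical id) for determinism.
    Guarantees every member is covered by >= 1 tag.
    """
    members = list(variant_ids)
    if not members:
        return []
    pos = positions or {v: i for i, v in enumerate(members)}
    cover = {
        v: {
            u
            for u in members
            if u == v or (np.isfinite(ld.loc[v, u]) and ld.loc[v, u] >= r2_tag)
        }
        for v in members
    }
    uncovered = set(members)
    tags: list[str] = []
    while uncovered:
        best = min(
            members,
            key=lambda v: (-len(cover[v] & uncovered), pos.get(v, 0), v),
        )
        gain = cover[best] & uncovered
        if not gain:  # cannot happen: every variant covers itself
            tags.extend(sorted(uncovered))
            break
        tags.append(best)
        uncovered -= gain
    return tags


def derive_alphas(
    tag_counts_per_region: dict[str, int],
    total_tags: int,
    mode: str = "global_average",
) -> tuple[dict[str, float], float]:
    """Two-tier significance thresholds from tag counts.

    ``alpha_a`` per region is 0.05 over the number of tags capturing that
    region's index-correlated set — or, in the default ``global_average``
    mode, 0.05 over the cross-region average tag count (one shared
    threshold, the convention that yields a global ~0.004 level).
    ``alpha_b`` is 0.05 over the total tag count across regions (e.g. 8,929
    tags give 5.6e-6).
    """
    if not tag_counts_per_region or any(c < 1 for c in tag_counts_per_region.values()):
        raise ValueError("tag counts must be >= 1 for every region")
    if total_tags < 1:
        raise ValueError("total tag count must be >= 1")
    if mode == "global_average":
        avg = float(np.mean(list(tag_counts_per_region.values())))
        alpha_a = {r: 0.05 / avg for r in tag_counts_per_region}
    elif mode == "per_region":
        alpha_a = {r: 0.05 / c for r, c in tag_counts_per_region.items()}
    else:
        raise ValueError("mode must be 'global_average' or 'per_region'")
    return alpha_a, 0.05 / total_tags


@dataclass
class TagPlan:
    """Per-region tagging summary feeding the two-tier thresholds."""

    region: str
    correlated: list[str]
    tags: list[str]
    alpha_a: float
    alpha_b: float
    tag_count: int = 0
    total_tags: int = 0

    def __post_init__(self) -> None:
        self.tag_count = self.tag_count or len(self.tags)
        if not (0 < self.alpha_a < 1 and 0 < self.alpha_b < 1):
            raise ValueError("alpha thresholds must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "correlated": self.correlated,
            "tags": self.tags,
            "alpha_a": self.alpha_a,
            "alpha_b": self.alpha_b,
            "tag_count": self.tag_count,
            "total_tags": self.total_tags,
        }


__all__ = [
    "LDResult",
    "TagPlan",
    "build_window",
    "correlated_set",
    "derive_alphas",
    "dprime",
    "dprime_blocks",
    "em_haplotype_freqs",
    "greedy_tags",
    "pairwise_r2",
    "r2_matrix",
]
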