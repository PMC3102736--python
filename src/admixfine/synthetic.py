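"""Synthetic admixed case-control genotype datasets with known ground truth.

The generator emulates the data regime of an admixed (two-way) case-control
genome-wide study: two ancestral populations whose allele frequencies diverge
under a Balding-Nichols model with divergence parameter ``F``; block-wise
linkage disequilibrium produced by drawing haplotypes from a small set of
founder haplotypes per block; admixed individuals carrying mosaic haplotypes
with Poisson ancestry-switch events; causal risk alleles with per-allele odds
ratios in the 1.05-1.4 range; logistic case-control phenotypes with age and
study covariates, family-history and severity labels; injected related pairs
(MZ, parent-offspring, full/half siblings); missing hard calls; and imputed
dosages with a per-variant imputation quality (Rsq).

Every stochastic choice flows from a single :class:`numpy.random.Generator`
seeded from :class:`SimulationConfig.seed`, so the same configuration is
byte-reproducible.  The emitted :class:`TruthRecord` retains phased
haplotypes, true local ancestry, causal effects, injected relationships and
realized imputation quality, which is what makes every downstream stage
testable without external data.

Population 1 is the "European-like" reference ancestry (the population in
which index signals were discovered); population 2 the "African-like"
ancestry.  ``theta`` is the expected fraction of population-1 chromosomes,
so an African-American-like cohort uses ``theta`` around 0.2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import DosageMatrix, LocalAncestryTrack

RELATIONSHIPS = ("MZ", "parent-offspring", "full-sibling", "half-sibling")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class SimulationError(RuntimeError):
    """The configured dataset could not be generated."""


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------


@dataclass
class CausalVariant:
    variant_id: str
    log_or: float


@dataclass
class SimulationConfig:
    """All knobs of the generator; nothing is hard-coded downstream.

    Defaults describe a modest admixed case-control study: ``theta`` = 0.2
    population-1 (European-like) ancestry with individual variation
    (Dirichlet-like Beta spread), divergence ``fst`` = 0.15 (roughly the
    CEU-YRI range), founder-block LD, ~1% missing hard calls, 30% imputed
    variants with imputation quality drawn uniformly on [0.25, 1].
    """

    n_cases: int = 1000
    n_controls: int = 1000
    theta: float = 0.2  # expected fraction of population-1 chromosomes
    theta_concentration: float | None = 10.0  # Beta concentration; None = fixed theta
    switch_rate: float = 1.0  # expected ancestry-switch events per haplotype
    n_variants: int = 200
    block_len_range: tuple[int, int] = (2, 6)
    fst: float = 0.15
    n_founders_range: tuple[int, int] = (2, 8)
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    causal: list[CausalVariant] = field(default_factory=list)
    prevalence: float = 0.12
    age_mean: float = 65.0
    age_sd: float = 8.0
    age_beta: float = 0.02  # log-odds per year of age
    n_studies: int = 4
    study_betas: tuple[float, ...] | None = None
    fh_prevalence: float = 0.10
    fh_log_or: float = float(np.log(1.55))
    fh_score_dep: float = 0.0  # dependence of family history on genetic score
    fh_missing_rate_cases: float = 0.10
    fh_missing_rate_controls: float = 0.16
    severity_fraction: float = 0.3
    severity_score_beta: float = 0.0
    missing_rate: float = 0.01
    imputed_fraction: float = 0.3
    rsq_range: tuple[float, float] = (0.25, 1.0)
    related_pairs: list[tuple[str, int]] = field(default_factory=list)
    crossover_rate: float = 1.0  # meioses: expected crossovers per transmission
    pool_haplotypes: int = 5000
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 2_500
    max_attempts: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigurationError("theta must lie in [0, 1]")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigurationError("fst must lie in [0, 1)")
        for name in ("prevalence", "missing_rate", "imputed_fraction", "fh_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must lie in (0, 1)")
        if self.switch_rate < 0 or self.crossover_rate < 0:
            raise ConfigurationError("rates must be non-negative")
        lo, hi = self.rsq_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ConfigurationError("rsq_range must satisfy 0 < lo <= hi <= 1")
        if self.block_len_range[0] < 1 or self.block_len_range[0] > self.block_len_range[1]:
            raise ConfigurationError("invalid block_len_range")
        if self.n_founders_range[0] < 2 or self.n_founders_range[0] > self.n_founders_range[1]:
            raise ConfigurationError("invalid n_founders_range")
        for kind, count in self.related_pairs:
            if kind not in RELATIONSHIPS:
                raise ConfigurationError(f"unknown relationship: {kind!r}")
            if count < 1:
                raise ConfigurationError("relationship count must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["causal"] = [dataclasses.asdict(c) for c in self.causal]
        return d


# ----------------------------------------------------------------------
# ancestral panels
# ----------------------------------------------------------------------


@dataclass
class AncestralPanel:
    """A reference haplotype pool for one ancestral population.

    ``freqs`` are the *declared* per-variant allele frequencies (the exact
    expectation of the pool construction); the materialized ``pool`` is a
    multinomial draw over founder haplotypes, so empirical pool frequencies
    sit within binomial noise of ``freqs``.  ``blocks`` are half-open
    variant-index intervals; every variant belongs to exactly one block and
    blocks are mutually independent.
    """

    label: str
    freqs: np.ndarray
    pool: np.ndarray  # (n_haplotypes, n_variants) int8
    blocks: list[tuple[int, int]]
    founders: list[np.ndarray] = field(default_factory=list)
    founder_weights: list[np.ndarray] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return self.pool.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.pool.shape[0]

    def empirical_freqs(self) -> np.ndarray:
        return self.pool.mean(axis=0)


def balding_nichols_freqs(
    p_ancestral: np.ndarray | float,
    fst: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw descendant-population allele frequencies.

    Under the Balding-Nichols model the descendant frequency given ancestral
    frequency ``p`` and divergence ``F`` follows Beta(p(1-F)/F, (1-p)(1-F)/F),
    with mean ``p`` and variance ``F p (1-p)``.  ``F = 0`` returns ``p``
    unchanged.
    """
    rng = _as_rng(rng)
    p = np.atleast_1d(np.asarray(p_ancestral, dtype=float))
    if not 0.0 <= fst < 1.0:
        raise ConfigurationError("fst must lie in [0, 1)")
    if fst == 0.0:
        return p.copy()
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b)


def _draw_blocks(n_variants: int, len_range: tuple[int, int], rng: np.random.Generator):
    blocks: list[tuple[int, int]] = []
    start = 0
    lo, hi = len_range
    while start < n_variants:
        length = int(rng.integers(lo, hi + 1))
        end = min(start + length, n_variants)
        blocks.append((start, end))
        start = end
    return blocks


def _founder_alleles(
    targets: np.ndarray,
    cum: np.ndarray,
    weights: np.ndarray,
    directions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign founder alleles so expected pool frequency equals ``targets``.

    Founders occupy disjoint weight intervals on [0, 1].  For each variant the
    allele-1 carrier mass is the bottom (or top, per ``directions``) ``p`` of
    the interval stack; the single founder straddling the threshold carries
    the allele with the probability that makes the expectation exact.
    """
    n_f = len(weights)
    lower = cum - weights  # interval starts
    out = np.zeros((n_f, len(targets)), dtype=np.int8)
    for j, (p, d) in enumerate(zip(targets, directions)):
        t = p if d == 0 else 1.0 - p
        full = cum <= t + 1e-12
        straddle = (~full) & (lower < t)
        col = full.astype(np.int8)
        if straddle.any():
            f = int(np.argmax(straddle))
            frac = (t - lower[f]) / weights[f]
            col[f] = np.int8(rng.random() < frac)
        if d == 1:
            col = 1 - col
        out[:, j] = col
    return out


def simulate_ancestral_panels(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> tuple[AncestralPanel, AncestralPanel]:
    """Generate two ancestral reference panels over a shared variant list.

    Both panels diverge from a common ancestral frequency via the
    Balding-Nichols draw; within each LD block haplotypes come from a small
    founder set (high within-block LD), and blocks are independent.  With no
    explicit ``rng`` the generator is seeded from ``config.seed``.
    """
    config.validate()
    rng = _as_rng(rng if rng is not None else config.seed)
    V = config.n_variants
    blocks = _draw_blocks(V, config.block_len_range, rng)
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=V)
    directions = rng.integers(0, 2, size=V)

    panels = []
    for label in ("POP1", "POP2"):
        targets = np.clip(balding_nichols_freqs(p_anc, config.fst, rng), 0.02, 0.98)
        founders: list[np.ndarray] = []
        weights: list[np.ndarray] = []
        freqs = np.empty(V)
        pool = np.empty((config.pool_haplotypes, V), dtype=np.int8)
        for (b0, b1) in blocks:
            k = int(rng.integers(config.n_founders_range[0], config.n_founders_range[1] + 1))
            w = rng.dirichlet(np.full(k, 2.0))
            cum = np.cumsum(w)
            A = _founder_alleles(targets[b0:b1], cum, w, directions[b0:b1], rng)
            founders.append(A)
            weights.append(w)
            freqs[b0:b1] = w @ A
            choice = rng.choice(k, size=config.pool_haplotypes, p=w)
            pool[:, b0:b1] = A[choice]
        panels.append(
            AncestralPanel(label, freqs, pool, list(blocks), founders, weights)
        )
    return panels[0], panels[1]


def panel_from_founders(
    label: str,
    founders: np.ndarray,
    weights: np.ndarray,
    blocks: list[tuple[int, int]] | None = None,
    pool_size: int = 5000,
    rng: np.random.Generator | int | None = None,
) -> AncestralPanel:
    """Build a panel from an explicit founder-haplotype matrix.

    Used to engineer designated LD between variants (e.g. index/causal pairs
    whose correlation differs between ancestries).  ``founders`` is
    (n_founders, n_variants); ``weights`` the founder frequencies.
    """
    rng = _as_rng(rng)
    founders = np.asarray(founders, dtype=np.int8)
    weights = np.asarray(weights, dtype=float)
    if founders.ndim != 2 or len(weights) != founders.shape[0]:
        raise ConfigurationError("founders/weights mismatch")
    weights = weights / weights.sum()
    V = founders.shape[1]
    if blocks is None:
        blocks = [(0, V)]
    freqs = weights @ founders
    choice = rng.choice(len(weights), size=pool_size, p=weights)
    pool = founders[choice]
    return AncestralPanel(label, freqs, pool.copy(), blocks, [founders], [weights])


# ----------------------------------------------------------------------
# admixed cohorts
# ----------------------------------------------------------------------


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort (internal phased representation)."""

    haplotypes: np.ndarray  # (n, 2, V) int8
    hap_ancestry: np.ndarray  # (n, 2, V) int8; 1 = population 1
    genotypes: np.ndarray  # (n, V) int8, = haplotype sum
    theta: np.ndarray  # (n,) individual admixture proportions
    switch_counts: np.ndarray  # (n, 2) Poisson ancestry-switch events
    causal: list[CausalVariant]
    variant_ids: list[str]
    typed: np.ndarray  # (V,) bool
    rsq_target: np.ndarray  # (V,) declared imputation quality (1 for typed)
    rsq_realized: np.ndarray  # (V,) squared correlation of emitted vs true dosage
    noise_sd: np.ndarray  # (V,) Gaussian imputation-noise SD
    relationships: list[dict] = field(default_factory=list)
    seed: int | None = None

    def local_ancestry(self) -> np.ndarray:
        """True per-sample per-variant count of population-1 chromosomes."""
        return self.hap_ancestry.sum(axis=1).astype(float)

    def validate_causal(self) -> None:
        ids = set(self.variant_ids)
        missing = [c.variant_id for c in self.causal if c.variant_id not in ids]
        if missing:
            raise ConfigurationError(f"causal variants absent from panel: {missing}")


def _simulate_haplotypes(
    panels: tuple[AncestralPanel, AncestralPanel],
    theta_i: np.ndarray,
    switch_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mosaic haplotypes for individuals with admixture proportions theta_i.

    Ancestry-switch events are Poisson along the variant-index coordinate;
    at each event (and at the start) ancestry is redrawn Bernoulli(theta_i),
    which keeps the marginal ancestry fraction at theta_i.  Returns
    (haplotypes, ancestries, switch_counts), each with a leading axis of
    2 * n individuals (haplotype-major: individual i owns rows 2i, 2i+1).
    """
    p1, p2 = panels
    V = p1.n_variants
    n_hap = 2 * len(theta_i)
    theta_h = np.repeat(theta_i, 2)
    hap = np.empty((n_hap, V), dtype=np.int8)
    anc = np.empty((n_hap, V), dtype=np.int8)
    n_switch = rng.poisson(switch_rate, size=n_hap)

    # bulk path: haplotypes with no switch event copy one pool row
    simple = np.flatnonzero(n_switch == 0)
    if simple.size:
        states = (rng.random(simple.size) < theta_h[simple]).astype(np.int8)
        rows1 = rng.integers(0, p1.n_haplotypes, size=simple.size)
        rows2 = rng.integers(0, p2.n_haplotypes, size=simple.size)
        sel1 = states == 1
        hap[simple[sel1]] = p1.pool[rows1[sel1]]
        hap[simple[~sel1]] = p2.pool[rows2[~sel1]]
        anc[simple] = states[:, None]

    for h in np.flatnonzero(n_switch > 0):
        cuts = np.sort(rng.integers(1, V, size=n_switch[h])) if V > 1 else np.array([], int)
        bounds = np.concatenate(([0], cuts, [V]))
        for s0, s1 in zip(bounds[:-1], bounds[1:]):
            if s1 <= s0:
                continue
            state = np.int8(rng.random() < theta_h[h])
            panel = p1 if state == 1 else p2
            row = int(rng.integers(0, panel.n_haplotypes))
            hap[h, s0:s1] = panel.pool[row, s0:s1]
            anc[h, s0:s1] = state
    return hap, anc, n_switch.reshape(-1, 2)


def _variant_table(config: SimulationConfig, typed: np.ndarray, rsq: np.ndarray) -> pd.DataFrame:
    V = config.n_variants
    return pd.DataFrame(
        {
            "variant_id": [f"var{i:05d}" for i in range(V)],
            "chrom": config.chrom,
            "pos": config.pos_start + config.pos_step * np.arange(V),
            "risk_allele": "A",
            "other_allele": "G",
            "typed": typed,
            "rsq": rsq,
        }
    )


def _calibrate_imputation_noise(
    genotypes: np.ndarray,
    imputed: np.ndarray,
    rsq_target: np.ndarray,
    rng: np.random.Generator,
    n_bisect: int = 30,
) -> np.ndarray:
    """Per-variant Gaussian noise SD such that the *clipped* noisy dosage has
    squared correlation with the true dosage equal to the target Rsq.

    Clipping to [0, 2] attenuates the injected noise, so the naive
    ``var_g (1 - R) / R`` solution overshoots the target; the SD is
    calibrated by bisection against the realized clipped correlation on a
    reference noise draw.
    """
    noise_sd = np.zeros(len(rsq_target))
    idx = np.flatnonzero(imputed)
    if idx.size == 0:
        return noise_sd
    n = genotypes.shape[0]
    eps = rng.normal(size=(n, idx.size))
    for t, j in enumerate(idx):
        g = genotypes[:, j].astype(float)
        var_g = g.var()
        target = rsq_target[j]
        if var_g < 1e-9 or target >= 1.0 - 1e-12:
            continue
        e = eps[:, t]

        def realized(s: float) -> float:
            d = np.clip(g + s * e, 0.0, 2.0)
            vd = d.var()
            if vd < 1e-12:
                return 0.0
            c = ((d - d.mean()) * (g - g.mean())).mean()
            return c * c / (vd * var_g)

        lo = 0.0
        hi = float(np.sqrt(var_g * (1.0 - target) / target))
        for _ in range(20):
            if realized(hi) < target:
                break
            hi *= 1.6
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            if realized(mid) > target:
                lo = mid
            else:
                hi = mid
        noise_sd[j] = 0.5 * (lo + hi)
    return noise_sd


def _emit_dosages(
    genotypes: np.ndarray,
    typed: np.ndarray,
    noise_sd: np.ndarray,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Observed dosages: missing hard calls for typed variants, noisy
    clipped dosages for imputed ones."""
    d = genotypes.astype(float)
    imputed = ~typed
    if imputed.any():
        noise = rng.normal(0.0, 1.0, size=(d.shape[0], int(imputed.sum())))
        d[:, imputed] = np.clip(d[:, imputed] + noise * noise_sd[imputed], 0.0, 2.0)
    if missing_rate > 0 and typed.any():
        mask = rng.random((d.shape[0], int(typed.sum()))) < missing_rate
        block = d[:, typed]
        block[mask] = np.nan
        d[:, typed] = block
    return d


def _realized_rsq(dosages: np.ndarray, genotypes: np.ndarray) -> np.ndarray:
    """Squared correlation of emitted dosage with true dosage per variant."""
    V = dosages.shape[1]
    out = np.full(V, np.nan)
    for j in range(V):
        d = dosages[:, j]
        g = genotypes[:, j].astype(float)
        ok = ~np.isnan(d)
        if ok.sum() < 3 or d[ok].std() == 0 or g[ok].std() == 0:
            continue
        out[j] = np.corrcoef(d[ok], g[ok])[0, 1] ** 2
    return out


def simulate_admixed_cohort(
    panels: tuple[AncestralPanel, AncestralPanel],
    config: SimulationConfig,
    n_samples: int | None = None,
    rng: np.random.Generator | int | None = None,
    sample_prefix: str = "S",
) -> tuple[DosageMatrix, LocalAncestryTrack, TruthRecord]:
    """Simulate ``n_samples`` admixed individuals (no phenotype ascertainment).

    Each individual carries two mosaic haplotypes; emitted local ancestry is
    the exact per-variant count of population-1 chromosomes; typed variants
    emit integer dosages with missing calls, imputed variants continuous
    dosages whose squared correlation with the true dosage matches the drawn
    target Rsq.
    """
    config.validate()
    p1, p2 = panels
    if p1.n_variants != p2.n_variants:
        raise ConfigurationError("panels must share a variant list")
    rng = _as_rng(rng if rng is not None else config.seed)
    n = int(n_samples if n_samples is not None else config.n_cases + config.n_controls)

    if config.theta_concentration is None or config.theta in (0.0, 1.0):
        theta_i = np.full(n, config.theta)
    else:
        nu = config.theta_concentration
        theta_i = rng.beta(config.theta * nu, (1.0 - config.theta) * nu, size=n)

    hap, anc, switches = _simulate_haplotypes(panels, theta_i, config.switch_rate, rng)
    V = p1.n_variants
    haplotypes = hap.reshape(n, 2, V)
    hap_anc = anc.reshape(n, 2, V)
    genotypes = haplotypes.sum(axis=1, dtype=np.int8)

    typed = rng.random(V) >= config.imputed_fraction
    rsq_target = np.ones(V)
    imputed = ~typed
    rsq_target[imputed] = rng.uniform(*config.rsq_range, size=int(imputed.sum()))
    noise_sd = _calibrate_imputation_noise(genotypes, imputed, rsq_target, rng)

    dosages = _emit_dosages(genotypes, typed, noise_sd, config.missing_rate, rng)
    variants = _variant_table(config, typed, rsq_target)
    samples = [f"{sample_prefix}{i:06d}" for i in range(n)]

    dm = DosageMatrix(dosages, samples, variants)
    track = LocalAncestryTrack(
        hap_anc.sum(axis=1).astype(float), list(samples), variants["variant_id"].tolist()
    )
    truth = TruthRecord(
        haplotypes=haplotypes,
        hap_ancestry=hap_anc,
        genotypes=genotypes,
        theta=theta_i,
        switch_counts=switches,
        causal=list(config.causal),
        variant_ids=variants["variant_id"].tolist(),
        typed=typed,
        rsq_target=rsq_target,
        rsq_realized=_realized_rsq(dosages, genotypes),
        noise_sd=noise_sd,
        seed=config.seed,
    )
    truth.validate_causal()
    return dm, track, truth


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------


def assign_phenotypes(
    dosages: DosageMatrix,
    truth: TruthRecord,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw phenotypes for a fixed cohort under the logistic disease model.

    logit P(case) = intercept + sum_i beta_i * g_i + age/study/family-history
    terms, with the intercept anchored so the population (pre-ascertainment)
    prevalence matches ``config.prevalence`` when genetic and covariate
    effects are null.  Causal effects act on true genotypes.
    """
    config.validate()
    rng = _as_rng(rng)
    n = dosages.n_samples
    truth.validate_causal()

    score = np.zeros(n)
    for cv in truth.causal:
        j = truth.variant_ids.index(cv.variant_id)
        score += cv.log_or * truth.genotypes[:, j]

    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 40.0, 90.0)
    study = rng.integers(0, config.n_studies, size=n)
    study_betas = (
        np.asarray(config.study_betas, dtype=float)
        if config.study_betas is not None
        else np.zeros(config.n_studies)
    )
    if len(study_betas) != config.n_studies:
        raise ConfigurationError("study_betas length must equal n_studies")

    fh_lin = logit(config.fh_prevalence) + config.fh_score_dep * (score - score.mean())
    fh = (rng.random(n) < expit(fh_lin)).astype(float)

    intercept = logit(config.prevalence)
    lin = (
        intercept
        + (score - score.mean())
        + config.age_beta * (age - config.age_mean)
        + study_betas[study]
        + config.fh_log_or * (fh - config.fh_prevalence)
    )
    prob = expit(lin)
    if not np.isfinite(prob).all():
        raise SimulationError("disease probabilities are degenerate")
    status = (rng.random(n) < prob).astype(int)

    severity = np.full(n, np.nan)
    cases = status == 1
    if cases.any():
        sev_lin = logit(config.severity_fraction) + config.severity_score_beta * (
            score[cases] - score.mean()
        )
        severity[cases] = (rng.random(int(cases.sum())) < expit(sev_lin)).astype(float)

    fh_out = fh.copy()
    miss_fh = np.where(
        status == 1,
        rng.random(n) < config.fh_missing_rate_cases,
        rng.random(n) < config.fh_missing_rate_controls,
    )
    fh_out[miss_fh] = np.nan

    return pd.DataFrame(
        {
            "sample_id": dosages.samples,
            "status": status,
            "age": np.round(age, 1),
            "study": [f"study{s}" for s in study],
            "family_history": fh_out,
            "severity": severity,
            "sex": "M",
        }
    )


# ----------------------------------------------------------------------
# relatives
# ----------------------------------------------------------------------


def _transmit(
    parent: np.ndarray, crossover_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis: recombine the parent's two haplotypes.

    Returns the transmitted haplotype and the 0/1 mask recording which
    parental haplotype was copied at each variant (used for IBD truth).
    """
    V = parent.shape[1]
    n_x = rng.poisson(crossover_rate)
    cuts = np.sort(rng.integers(1, V, size=n_x)) if (n_x and V > 1) else np.array([], int)
    mask = np.empty(V, dtype=np.int8)
    state = int(rng.integers(0, 2))
    bounds = np.concatenate(([0], cuts, [V]))
    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        mask[s0:s1] = state
        state = 1 - state
    child = np.where(mask == 0, parent[0], parent[1]).astype(np.int8)
    return child, mask


def inject_relatives(
    dosages: DosageMatrix,
    truth: TruthRecord,
    relationships: list[tuple[str, int]],
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[DosageMatrix, TruthRecord]:
    """Append related samples constructed by copying/transmitting haplotypes.

    MZ pairs copy both haplotypes of an existing sample; parent-offspring
    transmit one recombined haplotype (the co-parent is a random existing
    sample); full/half siblings are two new children of shared parent(s).
    Emission (missingness, imputation noise) matches the base cohort.
    """
    rng = _as_rng(rng)
    n0 = dosages.n_samples
    if n0 < 3:
        raise ConfigurationError("need at least 3 base samples to inject relatives")
    V = dosages.n_variants

    new_h: list[np.ndarray] = []
    new_a: list[np.ndarray] = []
    new_ids: list[str] = []
    records: list[dict] = []
    counter = 0

    def add_sample(h: np.ndarray, a: np.ndarray, tag: str) -> str:
        nonlocal counter
        sid = f"REL{counter:04d}_{tag}"
        counter += 1
        new_h.append(h)
        new_a.append(a)
        new_ids.append(sid)
        return sid

    for kind, count in relationships:
        if kind not in RELATIONSHIPS:
            raise ConfigurationError(f"unknown relationship: {kind!r}")
        for _ in range(count):
            if kind == "MZ":
                i = int(rng.integers(0, n0))
                sid = add_sample(truth.haplotypes[i].copy(), truth.hap_ancestry[i].copy(), "MZ")
                records.append({"kind": "MZ", "members": [dosages.samples[i], sid]})
            elif kind == "parent-offspring":
                i, j = rng.choice(n0, size=2, replace=False)
                # ancestry mask must follow the genotype transmission mask
                h1, m1 = _transmit(truth.haplotypes[i], config.crossover_rate, rng)
                a1 = np.where(m1 == 0, truth.hap_ancestry[i][0], truth.hap_ancestry[i][1])
                h2, m2 = _transmit(truth.haplotypes[j], config.crossover_rate, rng)
                a2 = np.where(m2 == 0, truth.hap_ancestry[j][0], truth.hap_ancestry[j][1])
                child_h = np.stack([h1, h2])
                child_a = np.stack([a1, a2]).astype(np.int8)
                sid = add_sample(child_h, child_a, "PO")
                records.append({"kind": "parent-offspring", "members": [dosages.samples[i], sid]})
            else:  # full or half siblings: two new children
                i, j, k = rng.choice(n0, size=3, replace=False)
                shared, other = i, j
                co2 = j if kind == "full-sibling" else k
                sibs = []
                masks = []
                for co in (other, co2):
                    hA, mA = _transmit(truth.haplotypes[shared], config.crossover_rate, rng)
                    aA = np.where(mA == 0, truth.hap_ancestry[shared][0], truth.hap_ancestry[shared][1])
                    hB, mB = _transmit(truth.haplotypes[co], config.crossover_rate, rng)
                    aB = np.where(mB == 0, truth.hap_ancestry[co][0], truth.hap_ancestry[co][1])
                    tag = "FS" if kind == "full-sibling" else "HS"
                    sid = add_sample(
                        np.stack([hA, hB]), np.stack([aA, aB]).astype(np.int8), tag
                    )
                    sibs.append(sid)
                    masks.append((mA, mB))
                (mA1, mB1), (mA2, mB2) = masks
                share_shared = (mA1 == mA2).mean()
                if kind == "full-sibling":
                    ibd_frac = 0.5 * (share_shared + (mB1 == mB2).mean())
                else:
                    ibd_frac = 0.5 * share_shared  # co-parents unrelated
                records.append({"kind": kind, "members": sibs, "ibd_fraction": float(ibd_frac)})

    if not new_ids:
        return dosages, truth

    add_h = np.stack(new_h)
    add_a = np.stack(new_a)
    add_g = add_h.sum(axis=1, dtype=np.int8)
    add_d = _emit_dosages(add_g, truth.typed, truth.noise_sd, config.missing_rate, rng)

    dm = DosageMatrix(
        np.vstack([dosages.dosages, add_d]),
        list(dosages.samples) + new_ids,
        dosages.variants,
    )
    m = add_h.shape[0]
    truth2 = dataclasses.replace(
        truth,
        haplotypes=np.concatenate([truth.haplotypes, add_h]),
        hap_ancestry=np.concatenate([truth.hap_ancestry, add_a]),
        genotypes=np.concatenate([truth.genotypes, add_g]),
        theta=np.concatenate([truth.theta, add_a.mean(axis=(1, 2))]),
        switch_counts=np.concatenate([truth.switch_counts, np.zeros((m, 2), dtype=int)]),
        relationships=truth.relationships + records,
    )
    return dm, truth2


# ----------------------------------------------------------------------
# case-control ascertainment
# ----------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    dosages: DosageMatrix
    local_ancestry: LocalAncestryTrack
    samples: pd.DataFrame
    truth: TruthRecord
    panels: tuple[AncestralPanel, AncestralPanel]
    config: SimulationConfig


def simulate_case_control(
    config: SimulationConfig,
    panels: tuple[AncestralPanel, AncestralPanel] | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimulatedDataset:
    """Generate a complete case-control dataset by rejection sampling.

    Batches of admixed individuals are simulated and phenotyped until the
    configured case and control counts are reached (matching a case-control
    design without modelling a full cohort).  Raises
    :class:`SimulationError` if the configured prevalence cannot produce
    enough cases within the attempt budget.
    """
    config.validate()
    rng = _as_rng(rng if rng is not None else config.seed)
    if panels is None:
        panels = simulate_ancestral_panels(config, rng)

    need_cases, need_controls = config.n_cases, config.n_controls
    prev = config.prevalence
    got_rows: list[dict] = []
    chunks: list[tuple] = []
    n_cases = n_controls = 0
    for _ in range(config.max_attempts):
        if n_cases >= need_cases and n_controls >= need_controls:
            break
        batch = int(
            np.ceil(
                1.4
                * max(
                    (need_cases - n_cases) / max(prev, 1e-6),
                    (need_controls - n_controls) / max(1.0 - prev, 1e-6),
                )
            )
        )
        batch = int(np.clip(batch, 200, 50_000))
        dm, track, truth = simulate_admixed_cohort(panels, config, batch, rng)
        pheno = assign_phenotypes(dm, truth, config, rng)
        status = pheno["status"].to_numpy()
        take_cases = np.flatnonzero(status == 1)[: need_cases - n_cases]
        take_controls = np.flatnonzero(status == 0)[: need_controls - n_controls]
        take = np.concatenate([take_cases, take_controls])
        n_cases += len(take_cases)
        n_controls += len(take_controls)
        if len(take):
            chunks.append((dm, track, truth, pheno, take))
    else:
        if n_cases < need_cases or n_controls < need_controls:
            raise SimulationError(
                "could not reach configured case/control counts "
                f"({n_cases}/{need_cases} cases, {n_controls}/{need_controls} controls); "
                "prevalence may be unreachable"
            )

    base = chunks[0][2]
    dosage_rows, track_rows, pheno_rows = [], [], []
    hap_rows, anc_rows, geno_rows, theta_rows, sw_rows = [], [], [], [], []
    for dm, track, truth, pheno, take in chunks:
        dosage_rows.append(dm.dosages[take])
        track_rows.append(track.values[take])
        pheno_rows.append(pheno.iloc[take])
        hap_rows.append(truth.haplotypes[take])
        anc_rows.append(truth.hap_ancestry[take])
        geno_rows.append(truth.genotypes[take])
        theta_rows.append(truth.theta[take])
        sw_rows.append(truth.switch_counts[take])

    n_total = need_cases + need_controls
    samples = [f"S{i:06d}" for i in range(n_total)]
    dm_all = DosageMatrix(np.vstack(dosage_rows), samples, chunks[0][0].variants)
    track_all = LocalAncestryTrack(
        np.vstack(track_rows), list(samples), dm_all.variants["variant_id"].tolist()
    )
    pheno_all = pd.concat(pheno_rows, ignore_index=True)
    pheno_all["sample_id"] = samples
    truth_all = dataclasses.replace(
        base,
        haplotypes=np.concatenate(hap_rows),
        hap_ancestry=np.concatenate(anc_rows),
        genotypes=np.concatenate(geno_rows),
        theta=np.concatenate(theta_rows),
        switch_counts=np.concatenate(sw_rows),
        relationships=[],
        seed=config.seed,
    )

    if config.related_pairs:
        dm_all, truth_all = inject_relatives(
            dm_all, truth_all, config.related_pairs, config, rng
        )
        extra = dm_all.n_samples - n_total
        if extra:
            dm_extra = dm_all.subset(sample_idx=np.arange(n_total, dm_all.n_samples))
            truth_extra = dataclasses.replace(
                truth_all,
                genotypes=truth_all.genotypes[n_total:],
                haplotypes=truth_all.haplotypes[n_total:],
                hap_ancestry=truth_all.hap_ancestry[n_total:],
                causal=truth_all.causal,
            )
            pheno_extra = assign_phenotypes(dm_extra, truth_extra, config, rng)
            pheno_all = pd.concat([pheno_all, pheno_extra], ignore_index=True)
            track_all = LocalAncestryTrack(
                truth_all.hap_ancestry.sum(axis=1).astype(float),
                list(dm_all.samples),
                track_all.variant_ids,
            )

    return SimulatedDataset(dm_all, track_all, pheno_all, truth_all, panels, config)


__all__ = [
    "AncestralPanel",
    "CausalVariant",
    "ConfigurationError",
    "RELATIONSHIPS",
    "SimulatedDataset",
    "SimulationConfig",
    "SimulationError",
    "TruthRecord",
    "assign_phenotypes",
    "balding_nichols_freqs",
    "inject_relatives",
    "panel_from_founders",
    "simulate_admixed_cohort",
    "simulate_ancestral_panels",
    "simulate_case_control",
]
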