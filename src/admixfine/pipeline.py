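"""End-to-end orchestration: QC -> ancestry -> association -> fine-mapping
-> risk modeling, with per-stage TSV/JSON artifacts and a structured log.

Every output directory receives a ``summary.json`` carrying provenance
metadata (configuration hash, seed, per-stage sample/variant counts), so a
rerun with the same configuration is byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc_mod
from . import association as assoc_mod
from . import finemap as fm_mod
from . import io as io_mod
from . import ld as ld_mod
from . import qc as qc_mod
from . import riskscore as rs_mod
from .containers import DataError, RiskRegion


@dataclass
class PipelineConfig:
    """Validated thresholds and paths for a pipeline run."""

    genotypes: str
    phenotypes: str
    regions: str
    local_ancestry: str | None = None
    output_dir: str = "admixfine_out"
    sample_call_rate_min: float = 0.95
    variant_call_rate_min: float = 0.95
    maf_min: float = 0.01
    max_qc_mismatch: int = 1
    rsq_min: float = 0.3
    ibd_sd: float = 0.1
    outlier_sd: float = 4.0
    n_eigenvectors: int = 10
    stepwise_eigenvectors: int = 1  # stepwise models adjust for EV1 only
    r2_index: float = 0.2
    r2_tag: float = 0.8
    flank: int = 250_000
    alpha_mode: str = "global_average"
    dense_entry_p: float = 0.05
    dense_retention_p: float = 0.001
    relatives_min_variants: int = 200
    familial_r: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "sample_call_rate_min", "variant_call_rate_min", "maf_min",
            "rsq_min", "r2_index", "r2_tag",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must lie in [0, 1]; got {v}")
        for name in ("dense_entry_p", "dense_retention_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DataError(f"{name} must lie in (0, 1); got {v}")
        if self.outlier_sd <= 0 or self.ibd_sd <= 0:
            raise DataError("SD scales must be positive")
        if self.alpha_mode not in ("global_average", "per_region"):
            raise DataError("alpha_mode must be 'global_average' or 'per_region'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        # provenance hash covers the analysis parameters, not where the
        # artifacts happen to be written
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StageLog:
    entries: list[dict] = field(default_factory=list)

    def add(self, stage: str, **info) -> None:
        self.entries.append({"stage": stage, **info})


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order; returns the artifact directory.

    Stage errors abort with a stage-labelled message; artifacts written up
    to that point are retained.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = StageLog()
    t0 = time.time()

    def fail(stage: str, exc: Exception):
        (out / "log.json").write_text(json.dumps(log.entries, indent=1, default=str))
        raise RuntimeError(f"[{stage}] {exc}") from exc

    # ---- load ----
    try:
        dosages = io_mod.read_genotypes(config.genotypes)
        pheno = io_mod.read_phenotypes(config.phenotypes)
        regions = io_mod.read_regions(config.regions)
        track = (
            io_mod.read_local_ancestry(config.local_ancestry)
            if config.local_ancestry
            else None
        )
    except Exception as exc:
        fail("load", exc)
    pheno = pheno.set_index("sample_id").loc[dosages.samples].reset_index()
    log.add("load", n_samples=dosages.n_samples, n_variants=dosages.n_variants)

    # ---- QC ----
    try:
        dosages, sreport = qc_mod.filter_samples(dosages, config.sample_call_rate_min)
        dosages, vreport = qc_mod.filter_variants(
            dosages, config.variant_call_rate_min, config.maf_min, config.max_qc_mismatch
        )
        dosages, rsq_report = qc_mod.filter_imputation_quality(dosages, config.rsq_min)
        related = qc_mod.find_related_pairs(
            dosages, sd=config.ibd_sd, min_variants=config.relatives_min_variants
        ) if dosages.n_samples <= 2000 else []
        removed = qc_mod.prune_related([(e.id1, e.id2) for e in related], rng)
        dosages = dosages.drop_samples(removed)
        report = qc_mod.QCReport(
            samples_removed=sreport.samples_removed
            + [(s, "related", np.nan) for s in removed],
            variants_removed=vreport.variants_removed + rsq_report.variants_removed,
        )
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        if related:
            pd.DataFrame(
                [
                    {"id1": e.id1, "id2": e.id2, "z0": e.z0, "z1": e.z1,
                     "z2": e.z2, "label": e.label}
                    for e in related
                ]
            ).to_csv(out / "ibd_pairs.tsv", sep="\t", index=False)
    except Exception as exc:
        fail("qc", exc)
    log.add("qc", n_samples=dosages.n_samples, n_variants=dosages.n_variants,
            related_pairs=len(related))

    # ---- ancestry ----
    try:
        k = min(config.n_eigenvectors, dosages.n_samples - 2)
        ga = anc_mod.compute_pca(dosages, k=k)
        outliers = anc_mod.flag_ancestry_outliers(ga, config.outlier_sd)
        if outliers:
            keep = [i for i, s in enumerate(dosages.samples) if s not in set(outliers)]
            dosages = dosages.subset(sample_idx=keep)
            ga = anc_mod.compute_pca(dosages, k=k)
        ev = pd.DataFrame(
            ga.coordinates, columns=[f"EV{i+1}" for i in range(ga.k)]
        )
        ev.insert(0, "sample_id", dosages.samples)
        ev.to_csv(out / "eigenvectors.tsv", sep="\t", index=False)
    except Exception as exc:
        fail("ancestry", exc)
    pheno = pheno.set_index("sample_id").loc[dosages.samples].reset_index()
    if track is not None:
        idx = [track.samples.index(s) for s in dosages.samples]
        track = track.subset_samples(idx)
    log.add("ancestry", n_samples=dosages.n_samples, outliers=len(outliers),
            variance_explained=ga.variance_explained())

    # ---- per-region association + tagging + stepwise ----
    status = pheno["status"].to_numpy()
    results = {}
    try:
        region_tags = {}
        all_assoc = []
        for region in regions:
            mask = region.variant_mask(dosages.variants)
            ids = [v for v, m in zip(dosages.variant_ids, mask) if m]
            if not ids:
                continue
            la = (
                anc_mod.summarize_local_ancestry(track, region, dosages.variants)
                if track is not None
                else None
            )
            cov = assoc_mod.covariate_frame(
                pheno, ga.coordinates, config.n_eigenvectors, la
            )
            scan = assoc_mod.association_scan(dosages, status, cov, ids)
            scan.insert(0, "region", region.name)
            all_assoc.append(scan)

            sub = dosages.subset(variant_idx=np.flatnonzero(mask))
            ld = ld_mod.r2_matrix(sub)
            pos = dict(zip(sub.variant_ids, sub.variants["pos"]))
            idx_pos = [
                pos[v] for v in region.index_variants if v in pos
            ] or [int((region.start + region.end) / 2)]
            window = ld_mod.build_window(idx_pos, config.flank)
            corr = ld_mod.correlated_set(
                sub, list(region.index_variants), window, config.r2_index
            )
            tags_corr = ld_mod.greedy_tags(corr, ld, config.r2_tag, pos) if corr else []
            common = [v for v, m in zip(sub.variant_ids, sub.maf() > 0.05) if m]
            tags_all = ld_mod.greedy_tags(common, ld, config.r2_tag, pos) if common else []
            region_tags[region.name] = {
                "corr": corr, "tags_corr": tags_corr, "tags_all": tags_all,
                "cov": cov, "ids": ids, "la": la,
            }
        assoc_df = (
            pd.concat(all_assoc, ignore_index=True) if all_assoc else pd.DataFrame()
        )
        assoc_df.to_csv(out / "association.tsv", sep="\t", index=False)

        counts = {
            r: max(len(t["tags_corr"]), 1) for r, t in region_tags.items()
        }
        total = max(sum(len(t["tags_all"]) for t in region_tags.values()), 1)
        alpha_a, alpha_b = ld_mod.derive_alphas(counts, total, config.alpha_mode)

        stepwise_rows = []
        for region in regions:
            t = region_tags.get(region.name)
            if t is None:
                continue
            cov_step = assoc_mod.covariate_frame(
                pheno, ga.coordinates, config.stepwise_eigenvectors, t["la"]
            )
            amap = {
                v: (alpha_a[region.name] if v in set(t["corr"]) else alpha_b)
                for v in t["ids"]
            }
            res = fm_mod.stepwise_select(
                dosages, t["ids"], status, cov_step, amap, region=region.name
            )
            plan = ld_mod.TagPlan(
                region.name, t["corr"], t["tags_corr"],
                alpha_a[region.name], alpha_b, total_tags=total,
            )
            (out / f"tagplan_{region.name}.json").write_text(
                json.dumps(plan.to_dict(), indent=1)
            )
            for _, row in res.final_model.iterrows():
                stepwise_rows.append({"region": region.name, **row.to_dict()})
        pd.DataFrame(stepwise_rows).to_csv(out / "stepwise.tsv", sep="\t", index=False)
        results["alpha_a"] = alpha_a
        results["alpha_b"] = alpha_b
        results["stepwise_selected"] = [r["variant_id"] for r in stepwise_rows]
    except Exception as exc:
        fail("finemap", exc)
    log.add("finemap", selected=len(results.get("stepwise_selected", [])))

    # ---- risk score ----
    try:
        score_ids = results.get("stepwise_selected") or []
        if not score_ids:  # fall back to index variants present in the panel
            present = set(dosages.variant_ids)
            score_ids = [
                v for r in regions for v in r.index_variants if v in present
            ]
        famrisk = None
        if len(score_ids) >= 2:
            raf = {
                v: float(np.nanmean(dosages.dosage_of(v)[status == 0]) / 2.0)
                for v in score_ids
            }
            sv = pd.DataFrame(
                {"variant_id": score_ids, "raf": [raf[v] for v in score_ids]}
            )
            counts_arr = rs_mod.build_score(dosages, sv)
            cov = assoc_mod.covariate_frame(pheno, ga.coordinates, config.n_eigenvectors)
            pa = rs_mod.per_allele_or(counts_arr, status, cov)
            fh = pheno["family_history"].to_numpy(dtype=float)
            quart = rs_mod.quartile_analysis(counts_arr, status, cov, fh)
            quart.overall.to_csv(out / "score_quartiles.tsv", sep="\t", index=False)
            pd.DataFrame({"sample_id": dosages.samples, "count": counts_arr}).to_csv(
                out / "score.tsv", sep="\t", index=False
            )
            try:
                frr = rs_mod.familial_rr_estimate(status, fh, cov)
                if frr.odds_ratio > 1.0:
                    m0 = float(counts_arr[status == 0].mean())
                    m1 = float(counts_arr[status == 1].mean())
                    famrisk = rs_mod.familial_risk_explained(
                        m0, m1, pa.odds_ratio, frr.odds_ratio, config.familial_r
                    )
                    (out / "familial_risk.json").write_text(
                        json.dumps(famrisk.to_dict(), indent=1)
                    )
            except ValueError:
                pass
            results["per_allele_or"] = pa.odds_ratio
            results["score_variants"] = score_ids
    except Exception as exc:
        fail("riskscore", exc)
    log.add("riskscore", n_score_variants=len(results.get("score_variants", [])))

    log.add("done", elapsed_s=round(time.time() - t0, 2))
    summary = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": log.entries[:-1],
        "alpha_a": results.get("alpha_a"),
        "alpha_b": results.get("alpha_b"),
        "stepwise_selected": results.get("stepwise_selected"),
        "per_allele_or": results.get("per_allele_or"),
        "familial_risk": famrisk.to_dict() if famrisk else None,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    (out / "log.json").write_text(json.dumps(log.entries, indent=1, default=str))
    return out


__all__ = ["PipelineConfig", "run_pipeline"]
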