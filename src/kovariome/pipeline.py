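"""Configuration-driven orchestration of the full analysis.

Stage order mirrors the study design: sample filters -> unrelated
selection -> allele-balance batch filter -> genotyping-rate filter ->
allele-frequency profiling -> (population specificity) -> WGWAS ->
phenomics -> (imputation evaluation).  A run manifest records every
threshold, seed, input digest and per-stage record count so that a rerun
with the same configuration is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gwas as gw
from . import phenomics as ph
from . import profile as pr
from . import qc
from .cohort import GenotypeMatrix
from .synthetic import CohortConfig, TraitModel, simulate_cohort

# thresholds default to the study's stated cut-offs
DEFAULT_THRESHOLDS = {
    "sample_max_missing": 0.10,
    "het_hom_sd": 3.0,
    "pi_hat": 0.05,
    "ab_sd": 1.0,
    "min_genotyping_rate": 0.9,
    "maf_min": 0.01,
    "hwe_p_min": 1e-6,
    "suggestive_p": 1e-5,
    "significant_p": 5e-8,
    "clump_r2": 0.1,
    "clump_kb": 250.0,
    "mr_instrument_p": 1e-5,
    "presso_nb_distribution": 10000,
    "fdr": 0.05,
}

_KNOWN_KEYS = {
    "seed", "out_dir", "stages", "thresholds", "cohort", "traits",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "kovariome_run"
    stages: dict = field(
        default_factory=lambda: {
            "qc": True, "profile": True, "gwas": True, "phenomics": True,
        }
    )
    thresholds: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    traits: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages on a synthetic cohort; returns the
    manifest.  Outputs are written under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {
        "seed": config.seed,
        "thresholds": thr,
        "stages": config.stages,
        "config_digest": _digest(
            {"seed": config.seed, "thresholds": thr, "cohort": config.cohort,
             "traits": config.traits, "stages": config.stages}
        ),
        "counts": {},
    }

    cohort_cfg = CohortConfig(seed=config.seed, **config.cohort)
    trait_model = TraitModel(**config.traits) if config.traits else TraitModel()
    cohort = simulate_cohort(cohort_cfg, trait_model)
    genotypes = cohort.genotypes
    manifest["counts"]["input_samples"] = genotypes.n_samples
    manifest["counts"]["input_variants"] = genotypes.n_variants

    if config.stages.get("qc", True):
        sq = qc.sample_qc(
            genotypes,
            missing_threshold=thr["sample_max_missing"],
            ratio_sd=thr["het_hom_sd"],
        )
        kept_ids = list(sq.loc[sq["kept"], "sample_id"])
        removed_sample_qc = genotypes.n_samples - len(kept_ids)
        genotypes = genotypes.select_samples(kept_ids)

        pairs = qc.estimate_ibd(genotypes, maf_min=thr["maf_min"])
        unrelated = qc.select_unrelated(
            pairs, threshold=thr["pi_hat"], all_samples=genotypes.sample_ids
        )
        removed_related = genotypes.n_samples - len(unrelated)
        keep_rows = [genotypes.sample_ids.index(s) for s in unrelated]
        genotypes = genotypes.take_samples(keep_rows)
        if cohort.read_counts is not None:
            rc = (cohort.read_counts[0][keep_rows], cohort.read_counts[1][keep_rows])
            ab = qc.compute_allele_balance(genotypes, rc)
            ab_keep = qc.filter_batch_effect(ab)
        else:
            ab_keep = np.ones(genotypes.n_variants, bool)
        vq = qc.variant_qc(
            genotypes, ab_keep, min_genotyping_rate=thr["min_genotyping_rate"]
        )
        genotypes = genotypes.take_variants(vq["kept"].to_numpy())
        sq.to_csv(out / "sample_qc.tsv", sep="\t", index=False)
        vq.to_csv(out / "variant_qc.tsv", sep="\t", index=False)
        pairs.to_csv(out / "kinship.tsv", sep="\t", index=False)
        manifest["counts"].update(
            {
                "removed_sample_qc": removed_sample_qc,
                "removed_related": removed_related,
                "kept_samples": genotypes.n_samples,
                "removed_ab_filter": int((~ab_keep).sum()),
                "kept_variants": genotypes.n_variants,
            }
        )

    if config.stages.get("profile", True):
        prof = pr.profile_variants(genotypes)
        prof.to_csv(out / "af_categories.tsv", sep="\t", index=False)
        sat = pr.saturation_curve(genotypes, seed=config.seed)
        pd.DataFrame(
            {"k": np.arange(1, genotypes.n_samples + 1), **sat.curves}
        ).to_csv(out / "saturation.tsv", sep="\t", index=False)
        manifest["counts"]["categorized_variants"] = int(
            (prof["category"] != "").sum()
        )

    summary_by_trait: dict[str, pd.DataFrame] = {}
    if config.stages.get("gwas", True) and cohort.traits is not None:
        traits = cohort.traits.set_index("sample_id").loc[genotypes.sample_ids]
        keep = gw.prefilter_variants(
            genotypes, maf_min=thr["maf_min"], hwe_p_min=thr["hwe_p_min"],
            max_missing=1 - thr["min_genotyping_rate"],
        )
        gt_assoc = genotypes.take_variants(keep)
        spec = gw.CovariateSpec()
        trait_cols = [c for c in traits.columns if c.startswith("trait_")]
        for t in trait_cols:
            cov = gw.build_covariates(traits.reset_index(), spec, t)
            ss = gw.run_gwas(gt_assoc, traits[t].to_numpy(), cov, trait_name=t)
            ss.to_csv(out / f"gwas_{t}.tsv", sep="\t", index=False)
            summary_by_trait[t] = ss
        manifest["counts"]["gwas_variants"] = gt_assoc.n_variants
        manifest["counts"]["gwas_traits"] = len(trait_cols)

    if config.stages.get("phenomics", True) and summary_by_trait:
        traits = cohort.traits.set_index("sample_id").loc[genotypes.sample_ids]
        trait_cols = [c for c in traits.columns if c.startswith("trait_")]
        pc = ph.phenotypic_correlation(traits, trait_cols)
        pc.to_csv(out / "phenotypic_correlation.tsv", sep="\t", index=False)
        if len(summary_by_trait) >= 2:
            pleio, vsi = ph.detect_pleiotropy(
                summary_by_trait, p_threshold=thr["suggestive_p"]
            )
            pleio.to_csv(out / "pleiotropic_variants.tsv", sep="\t", index=False)
            vsi.to_csv(out / "vsi.tsv", sep="\t", index=False)
            manifest["counts"]["pleiotropic_variants"] = len(pleio)
    elif not config.stages.get("phenomics", True):
        manifest["counts"]["phenomics"] = "skipped"

    manifest["counts_digest"] = _digest(manifest["counts"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
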