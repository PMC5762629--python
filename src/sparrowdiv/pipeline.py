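"""End-to-end orchestration: locus QC -> diversity -> differentiation ->
isolation by distance -> trait scoring -> region comparisons -> P_ST-F_ST.

Every stochastic stage takes its seed from the config, so a rerun with an
identical config produces a byte-identical JSON report.  Missing optional
inputs skip their stage with a warning instead of failing the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats, phenotype, pstfst, spatial, study
from .popgen import (
    amova,
    bottleneck_test,
    diversity_summary,
    pairwise_theta,
    screen_loci,
    weir_cockerham_theta,
)
from .types import LocalityTable, MicrosatDataset, PhenotypeTable

log = logging.getLogger("sparrowdiv.pipeline")


@dataclass
class RunConfig:
    genotypes: str | None = None  # GenePop path
    phenotypes: str | None = None  # long CSV
    localities: str | None = None  # CSV
    assays: str | None = None  # event CSV
    spectra: str | None = None  # CSV
    output_dir: str = "results"
    region_of: dict = field(default_factory=dict)  # population -> region
    population_locality: dict = field(default_factory=dict)
    seed: int = 0
    n_perm: int = 1000
    n_boot: int = 1000
    bottleneck_n_sim: int = 200
    null_allele_threshold: float = 0.15
    hwe_alpha: float = 0.05
    alpha: float = 0.05
    strong_threshold: float = 0.125
    chain_iterations: int = 65000
    chain_burn_in: int = 15000
    chain_thin: int = 50
    fst_upper_ci_override: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @property
    def config_hash(self) -> str:
        """Hash of the analysis settings (the output destination excluded)."""
        payload = asdict(self)
        payload.pop("output_dir")
        text = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the inputs allow; returns the JSON-ready report.

    Writes one TSV per stage plus ``report.json`` under
    ``config.output_dir``.  Locus QC exclusions are applied before all
    downstream genetic stages; the exclusion log accounts for every input
    locus.  Any stage failure aborts with the stage name, keeping the
    tables written so far.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # abort, preserve partial outputs
                (out / "report.json").write_text(
                    json.dumps(_round_floats(report), indent=1, sort_keys=True)
                )
                raise StageError(name, exc) from exc
            dt = time.perf_counter() - t0
            log.info("stage=%s wall=%.2fs", name, dt)
            report["stages"][name] = result
            return result
        return wrap

    dataset: MicrosatDataset | None = None
    if config.genotypes:
        dataset = io_formats.read_genepop(config.genotypes, region_of=config.region_of)

        @stage("locus_qc")
        def _qc():
            qc = screen_loci(
                dataset,
                null_threshold=config.null_allele_threshold,
                hwe_alpha=config.hwe_alpha,
                n_perm=min(config.n_perm, 500),
                seed=config.seed,
            )
            qc.to_csv(out / "locus_qc.tsv", sep="\t", index=False)
            return {
                "n_loci_in": len(dataset.loci),
                "excluded": list(qc.loc[qc["exclude"], "locus"]),
                "kept": list(qc.loc[~qc["exclude"], "locus"]),
            }

        excluded = report["stages"]["locus_qc"]["excluded"]
        if excluded:
            dataset = dataset.drop_loci(excluded)

        @stage("diversity")
        def _div():
            tab = diversity_summary(
                dataset,
                bottleneck_kwargs=dict(n_sim=config.bottleneck_n_sim),
                seed=config.seed,
            )
            tab.to_csv(out / "diversity.tsv", sep="\t", index=False)
            return {"n_populations": len(tab), "mean_H_E": float(tab["H_E"].mean())}

        @stage("fst")
        def _fst():
            res = weir_cockerham_theta(dataset, n_boot=config.n_boot, seed=config.seed)
            theta_m, p_m = pairwise_theta(
                dataset, n_perm=min(config.n_perm, 500), seed=config.seed
            )
            io_formats.write_matrix_tsv(theta_m, out / "pairwise_theta.tsv")
            io_formats.write_matrix_tsv(p_m, out / "pairwise_theta_p.tsv")
            return {
                "theta": res.theta,
                "ci": [res.ci_low, res.ci_high],
                "n_significant_pairs": int(
                    (p_m.condensed() < config.alpha).sum()
                ),
            }

        @stage("amova")
        def _amova():
            res = amova(dataset, n_perm=min(config.n_perm, 200), seed=config.seed)
            pd.DataFrame(
                {
                    "level": ["among_groups", "among_pops_within_groups", "within_pops"],
                    "variance": [res.sigma2_among_groups, res.sigma2_among_pops,
                                 res.sigma2_within],
                    "percent": list(res.percentages),
                    "p": [res.p_among_groups, res.p_among_pops, res.p_within],
                }
            ).to_csv(out / "amova.tsv", sep="\t", index=False)
            return {"percent_within": res.percent_within, "phi_st": res.phi_st}

    localities: LocalityTable | None = None
    if config.localities:
        localities = io_formats.read_table(config.localities, "locality")

    if dataset is not None and localities is not None and config.population_locality:

        @stage("ibd")
        def _ibd():
            theta_m = io_formats.read_matrix_tsv(out / "pairwise_theta.tsv")
            geo = spatial.distance_matrix(localities, config.population_locality)
            geo = geo.reorder(theta_m.labels)
            res = spatial.mantel(
                geo, theta_m.clip_negative(), n_perm=config.n_perm, seed=config.seed
            )
            return {"mantel_r": res.r, "mantel_z": res.z, "p": res.p}

    elif dataset is not None:
        log.warning("IBD stage skipped: locality table or population map missing")
        report["stages"]["ibd"] = {"skipped": "locality inputs missing"}

    scored_traits = []
    if config.assays:
        @stage("behavior")
        def _behavior():
            logs = io_formats.read_table(config.assays, "assay")
            expl = phenotype.exploration_score(logs)
            neo = pd.DataFrame(
                [vars(phenotype.neophobia_score(l)) for l in logs]
            )
            expl.to_csv(out / "exploration_scores.tsv", sep="\t", index=False)
            neo.to_csv(out / "neophobia_scores.tsv", sep="\t", index=False)
            return {
                "n_birds": len(expl),
                "mean_exploration": float(expl["exploration_total"].mean()),
                "mean_neophobia": float(neo["score"].mean()),
            }

    if config.spectra:
        @stage("brightness")
        def _brightness():
            table = io_formats.read_table(config.spectra, "spectrum")
            bright = phenotype.brightness_table(table)
            bright.to_csv(out / "brightness.tsv", sep="\t", index=False)
            return {"n_samples": len(bright),
                    "mean_brightness": float(bright["brightness"].mean())}

    phen: PhenotypeTable | None = None
    if config.phenotypes:
        phen = io_formats.read_table(config.phenotypes, "phenotype")

        @stage("region_comparisons")
        def _regions():
            traits = phen.traits
            rows = []
            for trait in traits:
                cmp_res = phenotype.compare_regions(
                    phen, trait, alpha=config.alpha, bonferroni_family=len(traits)
                )
                rows.append(
                    dict(trait=trait, test=cmp_res.test, statistic=cmp_res.statistic,
                         p_raw=cmp_res.p_raw, p_adjusted=cmp_res.p_adjusted,
                         letters=";".join(f"{k}={v}" for k, v in cmp_res.letters.items()))
                )
            df = pd.DataFrame(rows)
            df.to_csv(out / "region_comparisons.tsv", sep="\t", index=False)
            return {"n_traits": len(rows),
                    "significant": list(df.loc[df["p_adjusted"] < config.alpha, "trait"])}

        if localities is not None and config.population_locality:

            @stage("latitude_regressions")
            def _latreg():
                rows = []
                for trait in phen.traits:
                    reg = phenotype.latitude_regression(
                        phen, trait, localities, config.population_locality
                    )
                    rows.append(dict(trait=trait, slope=reg.slope,
                                     r_squared=reg.r_squared, F=reg.f_statistic,
                                     p=reg.p_value))
                pd.DataFrame(rows).to_csv(out / "latitude_regressions.tsv",
                                          sep="\t", index=False)
                return {"traits": {r["trait"]: r["slope"] for r in rows}}

    if phen is not None and dataset is not None:

        @stage("pst_fst")
        def _pst():
            genotyped = {ind.id for ind in dataset.individuals}
            sub = phen.restrict_to(genotyped)
            fst_res = weir_cockerham_theta(dataset, n_boot=config.n_boot,
                                           seed=config.seed)
            fst_upper = (
                config.fst_upper_ci_override
                if config.fst_upper_ci_override is not None
                else fst_res.ci_high
            )
            chain = pstfst.ChainSettings(
                iterations=config.chain_iterations, burn_in=config.chain_burn_in,
                thin=config.chain_thin, seed=config.seed,
            )
            results = []
            for trait in sub.traits:
                fixed = ("year",) if "brightness" in trait.lower() else ("sex",)
                post = pstfst.fit_variance_components(sub, trait, fixed, chain)
                results.append(
                    pstfst.pst_fst_row(post, fst_upper,
                                       strong_threshold=config.strong_threshold)
                )
            table = pstfst.pst_fst_table(results)
            table.to_csv(out / "pst_fst.tsv", sep="\t", index=False)
            return {
                "fst_upper_ci": fst_upper,
                "verdicts": dict(zip(table["trait"], table["verdict"])),
            }

    (out / "report.json").write_text(
        json.dumps(_round_floats(report), indent=1, sort_keys=True)
    )
    return report
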