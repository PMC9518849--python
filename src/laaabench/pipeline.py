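"""End-to-end study orchestration.

``run_study`` drives the full benchmark from one config: simulate admixed
cohorts, simulate the phenotype scenario grid, derive the true and
corrupted ("inferred") ancestry conditions, scan every phenotype with each
requested regression model, score hits against the known causal sites, and
write summary tables.  Everything is reproducible from the master seed:
each stage derives a child seed from the seed plus its scenario tag, so
adding scenarios never perturbs existing random streams.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from ._random import child_seed
from .ancestry import CorruptionSpec, corrupt_local_ancestry, global_from_local
from .evaluation import (
    LDExclusionRule,
    average_replicates,
    count_hits,
    ld_exclusion_mask,
    summarize,
)
from .genotypes import simulate_cohort
from .gwas import GENOMEWIDE_ALPHA, MODELS, ModelSpec, genome_scan, maf_filter
from .phenotypes import (
    KINDS,
    N_REPLICATES,
    enumerate_scenarios,
    kinship_matrix,
    make_covariates,
    simulate_phenotype,
)
from .presets import NAMA3_LAI_ACCURACY, SAC5_LAI_ACCURACY, get_preset

log = logging.getLogger("laaabench")

DEFAULT_ACCURACIES = {"nama3": NAMA3_LAI_ACCURACY, "sac5": SAC5_LAI_ACCURACY}


@dataclass
class RunConfig:
    """Serializable description of one study run."""

    presets: list[str] = field(default_factory=lambda: ["nama3", "sac5"])
    seed: int = 0
    n_admixed: int = 500
    n_reference_per_source: int = 200
    n_sites: int = 10_000
    kinds: list[str] = field(default_factory=lambda: list(KINDS))
    models: list[str] = field(default_factory=lambda: list(MODELS))
    conditions: list[str] = field(default_factory=lambda: ["true", "inferred"])
    ancestries: list[str] | None = None  # None = all preset sources
    n_replicates: int = N_REPLICATES
    threshold: float = GENOMEWIDE_ALPHA
    r2_threshold: float = 0.2
    accuracies: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ACCURACIES.items()}
    )
    out_dir: str = "laaabench_run"
    write_cohort_files: bool = False
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def validate_config(config: RunConfig) -> list[dict]:
    """Check a config for internal consistency; returns a list of issues
    (empty when valid)."""
    issues: list[dict] = []

    def issue(what: str, detail: str):
        issues.append({"check": what, "detail": detail})

    for name in config.presets:
        try:
            preset = get_preset(name)
        except ValueError as exc:
            issue("preset", str(exc))
            continue
        total = sum(preset.final_proportions.values())
        if abs(total - 1.0) > 1e-12:
            issue("proportions", f"{name}: proportions sum to {total}")
        if config.ancestries:
            unknown = set(config.ancestries) - set(preset.sources)
            if unknown:
                issue("ancestries", f"{name}: unknown ancestry labels {sorted(unknown)}")
        acc = config.accuracies.get(name, {})
        for src in preset.sources:
            a = acc.get(src)
            if a is None:
                issue("accuracies", f"{name}: no LAI accuracy for {src}")
            elif not 0.0 < a <= 1.0:
                issue("accuracies", f"{name}: accuracy for {src} is {a}")
        # variance budgets of the scenario grid must sum to 1
        from .phenotypes import budget_for

        for kind in config.kinds:
            if kind not in KINDS:
                issue("kinds", f"unknown phenotype kind {kind!r}")
                continue
            for src in preset.sources:
                b = budget_for(name, kind, src)
                total_b = sum(b.values()) + 0.16 + 0.24
                if abs(total_b - 1.0) > 1e-12:
                    issue(
                        "budget",
                        f"{name}/{kind}/{src}: variance budget sums to {total_b}",
                    )
    for model in config.models:
        if model not in MODELS:
            issue("models", f"unknown model {model!r}")
    for cond in config.conditions:
        if cond not in ("true", "inferred"):
            issue("conditions", f"unknown ancestry condition {cond!r}")
    if not 0.0 < config.threshold < 1.0:
        issue("threshold", f"significance threshold {config.threshold} not in (0,1)")
    if not 0.0 <= config.r2_threshold <= 1.0:
        issue("r2", f"LD r^2 threshold {config.r2_threshold} not in [0,1]")
    if config.n_replicates < 1:
        issue("replicates", "need at least one replicate")
    return issues


def run_study(config: RunConfig) -> "StudyResult":
    """Run the complete benchmark described by ``config``.

    Returns the summary plus per-scenario results; also writes the resolved
    config, summary TSV and (optionally) cohort files and plots under
    ``config.out_dir``.  A failing scenario is recorded and skipped; the run
    continues.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError(f"invalid config: {issues}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    results = []
    failures: list[dict] = []
    for preset_name in config.presets:
        preset = get_preset(
            preset_name,
            n_admixed=config.n_admixed,
            n_reference_per_source=config.n_reference_per_source,
            n_sites=config.n_sites,
        )
        t0 = time.time()
        cohort_seed = child_seed(config.seed, "cohort", preset_name)
        cohort = simulate_cohort(preset, seed=cohort_seed)
        log.info(
            "cohort %s: n=%d sites=%d seed=%d %.1fs",
            preset_name, preset.n_admixed, preset.n_sites, cohort_seed,
            time.time() - t0,
        )
        if config.write_cohort_files:
            from .io import write_cohort

            write_cohort(
                cohort,
                out / f"{preset_name}.vcf",
                out / f"{preset_name}.truth.msp.tsv",
            )

        covariates = make_covariates(
            preset.n_admixed, child_seed(config.seed, "covariates", preset_name)
        )
        kin_chol = np.linalg.cholesky(
            kinship_matrix(cohort) + 1e-6 * np.eye(preset.n_admixed)
        )
        site_mask = maf_filter(cohort.genotypes)

        locals_by_condition = {"true": cohort.truth}
        if "inferred" in config.conditions:
            corrupt_seed = child_seed(config.seed, "corrupt", preset_name)
            locals_by_condition["inferred"] = corrupt_local_ancestry(
                cohort,
                CorruptionSpec(accuracy=config.accuracies[preset_name]),
                seed=corrupt_seed,
            )
        globals_by_condition = {
            cond: global_from_local(lam, cohort.samples)
            for cond, lam in locals_by_condition.items()
        }

        ancestries = config.ancestries or list(preset.sources)
        specs = [
            s
            for s in enumerate_scenarios(preset_name, preset.sources, config.n_replicates)
            if s.kind in config.kinds and s.ancestry_of_interest in ancestries
        ]
        rule = LDExclusionRule(config.r2_threshold)
        # counts[(kind, ancestry, model, condition)] -> list of (tp, fp)
        counts: dict[tuple, list[tuple[int, int]]] = {}
        for spec in specs:
            tag = (preset_name, spec.kind, spec.ancestry_of_interest, spec.replicate)
            try:
                pheno = simulate_phenotype(
                    cohort, spec, seed=config.seed,
                    covariates=covariates, kinship_chol=kin_chol,
                )
                mask = ld_exclusion_mask(cohort.genotypes, pheno.causal.sites, rule)
                for model_name in config.models:
                    mspec = ModelSpec(model_name, spec.ancestry_of_interest)
                    for cond in config.conditions:
                        scan = genome_scan(
                            pheno.y, covariates, cohort,
                            locals_by_condition[cond], mspec,
                            global_table=globals_by_condition[cond],
                            threshold=config.threshold, site_mask=site_mask,
                        )
                        tp, fp = count_hits(scan.significant, pheno.causal.sites, mask)
                        key = (spec.kind, spec.ancestry_of_interest, model_name, cond)
                        counts.setdefault(key, []).append((tp, fp))
                        log.info(
                            "scan %s %s-%s rep%d %s/%s: TP=%d FP=%d",
                            preset_name, spec.kind, spec.ancestry_of_interest,
                            spec.replicate, model_name, cond, tp, fp,
                        )
            except Exception as exc:  # pragma: no cover - resilience path
                log.exception("scenario failed: %s", tag)
                failures.append({"scenario": tag, "error": str(exc)})
        for (kind, anc, model_name, cond), pairs in counts.items():
            results.append(
                average_replicates(preset_name, kind, anc, model_name, cond, pairs)
            )

    summary = summarize(results)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    if failures:
        (out / "failures.json").write_text(json.dumps(failures, default=str, indent=2))
    if config.make_plots:
        from .evaluation import plot_summary

        for preset_name in config.presets:
            for cond in config.conditions:
                try:
                    plot_summary(
                        summary, preset_name, cond,
                        out / f"{preset_name}_{cond}.png",
                    )
                except ValueError:
                    pass
    return StudyResult(config=config, summary=summary, scenario_results=results,
                       failures=failures)


@dataclass
class StudyResult:
    config: RunConfig
    summary: "object"
    scenario_results: list
    failures: list[dict]
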