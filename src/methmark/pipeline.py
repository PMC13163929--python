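"""End-to-end orchestration: discover -> design -> evaluate.

Mirrors the three-phase biomarker development workflow — discovery of
tissue-specific DMRs from a methylation atlas, in-silico MSP design on the
candidate regions, and assay/clinical performance statistics — as one
reproducible run.  Every stage writes plain files with stable names into
the output directory, logs the thresholds it actually used, and accounts
for every probe entering a filter (retained + excluded = input), so stages
can be audited or rerun independently.

Inputs may be real files or, when paths are omitted, generated by the
seeded synthetic module at the default study-scale conditions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import simulate as sim
from .design import DesignRules, design_assays
from .discovery import DmcThresholds, discover
from .evaluate import clinical_summary, clopper_pearson, fisher_exact
from .io import (BetaMatrix, load_config, read_beta_matrix,
                 read_probe_annotation, read_sample_sheet, write_beta_matrix,
                 write_regions_bed)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "methmark_run"
    target_tissue: str = "Kidney"
    # stage switches
    run_discover: bool = True
    run_design: bool = True
    run_evaluate: bool = True
    # optional input paths; when None the synthetic module supplies data
    beta_matrix: str | None = None
    sample_sheet: str | None = None
    probe_annotation: str | None = None
    blood_matrix: str | None = None
    regions_fasta: str | None = None
    variant_mask_bed: str | None = None
    # thresholds
    thresholds: DmcThresholds = field(default_factory=DmcThresholds)
    design_rules: DesignRules = field(default_factory=DesignRules)
    blood_median_max: float = 0.1
    blood_positivity_max: float = 0.02
    blood_positivity_cutoff: float = 0.2

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        raw = load_config(path)
        thr = DmcThresholds(**raw.pop("thresholds", {}))
        rules = DesignRules(**raw.pop("design_rules", {}))
        return cls(thresholds=thr, design_rules=rules, **raw)


def _designs_table(designs) -> pd.DataFrame:
    rows = []
    for d in designs:
        row = {
            "region": d.region, "start": d.start, "end": d.end,
            "length": d.length, "overall": d.overall,
            "total_cpg": d.total_cpg,
        }
        for o in (d.forward, d.reverse, d.probe):
            row[f"{o.role}_seq"] = o.seq
            row[f"{o.role}_start"] = o.start
            row[f"{o.role}_end"] = o.end
            row[f"{o.role}_n_cpg"] = o.n_cpg
            row[f"{o.role}_n_ch"] = o.n_ch
            row[f"{o.role}_gc"] = round(o.gc_fraction, 4)
        for crit, rating in d.ratings.items():
            row[f"rating_{crit}"] = rating
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write the run report.

    Returns the report dictionary (also written to ``report.json``).  A
    stage failure aborts downstream stages; the report records partial
    completion with the error.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    report: dict = {
        "seed": config.seed,
        "target_tissue": config.target_tissue,
        "thresholds": dataclasses.asdict(config.thresholds),
        "stages": {},
        "completed": [],
    }

    def log(msg: str) -> None:
        log_lines.append(msg)

    try:
        if config.run_discover:
            if config.beta_matrix:
                matrix = read_beta_matrix(config.beta_matrix)
                sheet = read_sample_sheet(config.sample_sheet)
                annotation = read_probe_annotation(config.probe_annotation)
            else:
                matrix, sheet, annotation, _ = sim.simulate_beta_matrix(
                    config.seed, target_tissue=config.target_tissue)
                write_beta_matrix(matrix, out / "simulated_beta.tsv")
            if config.blood_matrix:
                blood = read_beta_matrix(config.blood_matrix)
            elif not config.beta_matrix:
                blood = sim.simulate_blood_reference(
                    config.seed, matrix.probe_ids)
            else:
                blood = None
            run = discover(matrix, sheet, annotation, config.target_tissue,
                           blood=blood, thresholds=config.thresholds,
                           positivity_cutoff=config.blood_positivity_cutoff,
                           median_max=config.blood_median_max,
                           positivity_max=config.blood_positivity_max)
            run.dmc.to_csv(out / "dmc_statistics.tsv", sep="\t", index=False)
            pd.DataFrame({"probe_id": run.blood_pass}).to_csv(
                out / "retained_probes.tsv", sep="\t", index=False)
            write_regions_bed(run.dmrs, out / "dmrs.bed")
            report["stages"]["discover"] = run.stage_counts
            report["completed"].append("discover")
            log(f"discover: {run.stage_counts}")
            log(f"discover thresholds: {dataclasses.asdict(config.thresholds)}")

        if config.run_design:
            if config.regions_fasta:
                from .io import read_bed_intervals, read_fasta_regions

                regions = read_fasta_regions(config.regions_fasta)
                if config.variant_mask_bed:
                    mask = read_bed_intervals(config.variant_mask_bed)
                    masked = []
                    for r in regions:
                        pos = set()
                        sub = mask[mask["chrom"] == r.chrom]
                        for _, row in sub.iterrows():
                            pos.update(range(max(row["start"], r.start),
                                             min(row["end"], r.end) + 1))
                        masked.append(dataclasses.replace(
                            r, variant_mask=frozenset(pos)))
                    regions = masked
            else:
                regions = [sim.simulate_genomic_region(
                    config.seed, length=300, cpg_density=0.06, clustered=True)]
            all_designs = []
            fail_totals: dict[str, int] = {}
            for region in regions:
                designs, fails = design_assays(region, rules=config.design_rules)
                all_designs.extend(designs)
                for k, v in fails.items():
                    fail_totals[k] = fail_totals.get(k, 0) + v
            table = _designs_table(all_designs)
            table.to_csv(out / "designs.tsv", sep="\t", index=False)
            by_rating = (table["overall"].value_counts().to_dict()
                         if len(table) else {})
            report["stages"]["design"] = {
                "regions": len(regions), "candidates": len(all_designs),
                "by_rating": by_rating, "constraint_failures": fail_totals,
            }
            report["completed"].append("design")
            log(f"design: {report['stages']['design']}")

        if config.run_evaluate:
            screens = [
                sim.simulate_replicate_screen(config.seed, 0.17, eff,
                                              n_replicates=343,
                                              assay_id=f"assay_{i+1}")
                for i, eff in enumerate([1.0, 0.6])
            ]
            perf_rows = []
            for s in screens:
                ci = clopper_pearson(s.k_positive, s.n_replicates)
                perf_rows.append({
                    "assay_id": s.assay_id, "n": s.n_replicates,
                    "k_positive": s.k_positive,
                    "positivity_pct": 100 * s.positivity,
                    "ci_low_pct": 100 * ci.lower, "ci_high_pct": 100 * ci.upper,
                })
            perf = pd.DataFrame(perf_rows)
            perf.to_csv(out / "assay_performance.tsv", sep="\t", index=False)
            p_cmp = fisher_exact(screens[0].k_positive, screens[0].n_replicates,
                                 screens[1].k_positive, screens[1].n_replicates)
            results, csheet, truth = sim.simulate_clinical_cohort(config.seed)
            summary = clinical_summary(results, csheet)
            summary.per_sample.to_csv(out / "clinical_per_sample.tsv",
                                      sep="\t", index=False)
            summary.group_summary.to_csv(out / "clinical_groups.tsv",
                                         sep="\t", index=False)
            report["stages"]["evaluate"] = {
                "n_screens": len(screens),
                "screen_fisher_p": p_cmp,
                "clinical_n": int(len(summary.per_sample)),
                "kw_absolute_p": summary.kw_absolute[1],
                "kw_relative_p": summary.kw_relative[1],
            }
            report["completed"].append("evaluate")
            log(f"evaluate: {report['stages']['evaluate']}")
    except Exception as e:  # noqa: BLE001 - report partial completion
        report["error"] = f"{type(e).__name__}: {e}"
        log(f"aborted: {report['error']}")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
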