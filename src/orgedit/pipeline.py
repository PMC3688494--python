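"""End-to-end pipeline: rates -> call -> select -> differential -> overlap.

Wires the modules into the full analysis: per-library error-model
estimation with automatic masking of obvious editing columns, LRT site
calling over every template C, cross-library candidate selection,
differential classification per genotype comparison (with replicate pooling
and Bonferroni control per organelle), and cross-factor overlap analysis.
Every threshold used is recorded in the outputs and the run log; a rerun on
the same inputs is byte-identical (the pipeline itself has no randomness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential, error_model, overlap, site_caller
from .formats_io import (SampleSheet, TemplateSet, pileup_from_sam,
                         write_site_table)


class ConfigurationError(ValueError):
    """Invalid run configuration; raised before any computation starts."""


@dataclass
class RunConfig:
    templates: str
    sample_sheet: str
    out_dir: str
    template_metadata: str | None = None
    alpha_site: float = site_caller.DEFAULT_ALPHA_SITE
    min_fraction: float = site_caller.DEFAULT_MIN_FRACTION
    min_mean_depth: float = site_caller.DEFAULT_MIN_MEAN_DEPTH
    alpha_family: float = differential.DEFAULT_ALPHA_FAMILY
    delta_ee_cut: float = differential.DEFAULT_DELTA_EE_CUT
    mask_threshold: float = error_model.DEFAULT_MASK_THRESHOLD
    pseudocount: float = error_model.DEFAULT_PSEUDOCOUNT
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("alpha_site", "min_fraction", "min_mean_depth",
                     "alpha_family", "delta_ee_cut"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class RunResult:
    candidate_sites: set
    calls_by_site: dict
    classifications: dict
    summaries: pd.DataFrame
    out_dir: Path
    log: list[str] = field(default_factory=list)


def run_pipeline(config: RunConfig) -> RunResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def _log(msg: str) -> None:
        log.append(msg)

    templates = TemplateSet.from_fasta(config.templates,
                                       config.template_metadata)
    sheet = SampleSheet.from_tsv(config.sample_sheet)
    if "sam" not in sheet.table.columns:
        raise ConfigurationError("sample sheet must carry a 'sam' column "
                                 "with per-library alignment paths")
    _log(f"templates: {len(templates)}; libraries: {len(sheet.libraries)}")
    _log(f"thresholds: alpha_site={config.alpha_site} "
         f"min_fraction={config.min_fraction} "
         f"min_mean_depth={config.min_mean_depth} "
         f"alpha_family={config.alpha_family} "
         f"delta_ee_cut={config.delta_ee_cut} "
         f"mask_threshold={config.mask_threshold}")

    # --- pileups and per-library error models -----------------------------
    pileups = {}
    for _, row in sheet.table.iterrows():
        pileups[row.library_id] = pileup_from_sam(row.sam, templates)
    mask = error_model.auto_mask(list(pileups.values()),
                                 config.mask_threshold)
    _log(f"auto-masked columns: {len(mask)}")
    rates = {
        lib: error_model.estimate_mismatch_rates(
            pileup, templates, mask, pseudocount=config.pseudocount,
            library_id=lib)
        for lib, pileup in pileups.items()
    }
    for lib, table in rates.items():
        table.to_tsv(out / f"rates_{lib}.tsv")

    # --- site calling and candidate selection -----------------------------
    calls_by_site: dict = {}
    for lib, pileup in pileups.items():
        calls, _sig = site_caller.call_sample(pileup, rates[lib], lib,
                                              config.alpha_site)
        rows = []
        for call in calls:
            calls_by_site.setdefault(
                (call.template_id, call.position), {})[lib] = call
            rows.append({
                "template": call.template_id,
                "gene": templates[call.template_id].gene,
                "position": call.position, "ref": "C",
                "C_count": call.c_count, "T_count": call.t_count,
                "depth": call.depth,
                "T_fraction": call.t_fraction
                if call.t_fraction is not None else float("nan"),
                "theta_hat": call.theta_hat, "lrt": call.lrt,
                "pvalue": call.pvalue,
            })
        write_site_table(rows, out / f"calls_{lib}.tsv")
    candidates = site_caller.select_candidates(
        calls_by_site, sheet.libraries, config.alpha_site,
        config.min_fraction, config.min_mean_depth)
    final = candidates.final
    _log(f"union of significant sites: {len(candidates.union)}; "
         f"candidates after filters: {len(final)}")
    pd.DataFrame(
        sorted(final), columns=["template", "position"]
    ).to_csv(out / "candidate_sites.tsv", sep="\t", index=False)

    # --- differential classification per comparison ------------------------
    def _pooled(site, libs):
        pairs = []
        for lib in libs:
            call = calls_by_site.get(site, {}).get(lib)
            if call is not None:
                pairs.append((call.c_count, call.t_count))
        return differential.pool_replicates(pairs) if pairs else (0, 0)

    def _sites_for(organelle: str) -> list:
        return [s for s in sorted(final)
                if (templates[s[0]].organelle or "all") == organelle]

    classifications: dict[str, dict] = {}
    summaries = []
    partitions = sorted({templates[s[0]].organelle or "all" for s in final})
    for organelle in partitions:
        sites = _sites_for(organelle)
        if not sites:
            continue
        nominal = differential.bonferroni_threshold(config.alpha_family,
                                                    len(sites))
        _log(f"{organelle}: analyzed universe {len(sites)} sites, "
             f"nominal threshold {nominal:.2g}")
        for comp in sheet.comparisons():
            results = [
                differential.classify_vs_wildtype(
                    _pooled(s, comp["wildtype_libraries"]),
                    _pooled(s, comp["mutant_libraries"]),
                    nominal, config.delta_ee_cut, site=s)
                for s in sites
            ]
            _store(classifications, summaries, comp["genotype"], organelle,
                   sites, results, out, templates, _log)
        for comp in sheet.silenced_comparisons():
            results = [
                differential.classify_silenced(
                    _pooled(s, comp["silenced_libraries"]),
                    _pooled(s, comp["uninoculated_libraries"]),
                    _pooled(s, comp["gfp_libraries"]),
                    nominal, config.delta_ee_cut, site=s)
                for s in sites
            ]
            _store(classifications, summaries, comp["genotype"], organelle,
                   sites, results, out, templates, _log)

    summary_df = (pd.concat(summaries, ignore_index=True)
                  if summaries else pd.DataFrame())
    if not summary_df.empty:
        summary_df.to_csv(out / "classification_summary.tsv", sep="\t",
                          index=False)

    # --- overlap across factors -------------------------------------------
    factors = sorted(classifications)
    if len(factors) >= 2:
        matrix = overlap.classification_matrix(classifications)
        rows = []
        for i, fa in enumerate(factors):
            for fb in factors[i + 1:]:
                test, table = overlap.factor_independence_test(matrix, fa, fb)
                rows.append({
                    "factor_a": fa, "factor_b": fb,
                    "chisq": test.chisq, "pvalue": test.pvalue,
                    "excluded": test.excluded,
                })
        pd.DataFrame(rows).to_csv(out / "factor_independence.tsv", sep="\t",
                                  index=False)

    (out / "run.log").write_text("\n".join(log) + "\n")
    return RunResult(candidate_sites=final, calls_by_site=calls_by_site,
                     classifications=classifications, summaries=summary_df,
                     out_dir=out, log=log)


def _store(classifications, summaries, genotype, organelle, sites, results,
           out, templates, _log) -> None:
    key = f"{genotype}:{organelle}"
    classifications[key] = {r.site: r.klass for r in results}
    summary = differential.summarize_classification(results, key)
    summaries.append(summary)
    rows = []
    for r in results:
        tid, pos = r.site
        rows.append({
            "template": tid, "gene": templates[tid].gene, "position": pos,
            "site": templates[tid].site_name(pos),
            "wt_extent": r.wt_extent, "mut_extent": r.mut_extent,
            "delta_EE": r.delta_ee,
            "chisq": r.test.chisq if r.test else float("nan"),
            "chisq_p": r.test.pvalue if r.test else float("nan"),
            "class": r.klass, "reason": r.reason,
            "nominal_threshold": r.nominal_threshold,
        })
    pd.DataFrame(rows).to_csv(
        out / f"diff_{genotype}_{organelle}.tsv", sep="\t", index=False)
    row = summary.iloc[0]
    _log(f"{key}: dependent {row.dependent} ({row.dependent_pct}%), "
         f"independent {row.independent} ({row.independent_pct}%), "
         f"excluded {row.excluded} of {row.analyzed} analyzed")
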