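"""End-to-end pipeline orchestration and the report bundle.

``run_pipeline`` wires the stages together on synthetic inputs: simulate ->
differential -> classify -> cluster -> enrich (two backgrounds) -> qPCR
panel, writing one TSV per stage plus a JSON summary in which every
percentage is accompanied by its numerator and denominator. The bundle is a
pure function of the stage outputs and is byte-identical across reruns with
the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from pamptx import classify as _classify
from pamptx import clustering, enrichment, qpcr, summary, tables
from pamptx.differential import default_contrasts, run_contrasts
from pamptx.simulate import SimConfig, simulate_annotations, simulate_expression, simulate_qpcr_panel

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    n_genes: int = 2000
    n_replicates: int = 3
    noise_cv: float = 0.2
    responsive_effect_log2: float = 2.0
    mkp1_effect_log2: float = 1.0
    pseudocount: float = 1.0
    lfc_min: float = 1.0
    q_resp: float = 0.01
    dep_fold_min: float = 1.5
    q_dep: float = 0.01
    max_unit_change: int = 2
    max_profiles: int = 50
    n_terms: int = 50
    n_enriched: int = 5
    enrich_odds_ratio: float = 8.0
    enrich_q_cutoff: float = 0.05
    qpcr_enabled: bool = True
    qpcr_noise_sd: float = 0.01
    log_level: str = "INFO"
    _extra: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` configuration file (# comments allowed)."""
        fields = {f.name: f.type for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
            kwargs[key] = _coerce(value, fields[key])
        return cls(**kwargs)

    def thresholds(self) -> _classify.Thresholds:
        return _classify.Thresholds(
            lfc_min=self.lfc_min, q_resp=self.q_resp, dep_fold_min=self.dep_fold_min, q_dep=self.q_dep
        )

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_genes=self.n_genes,
            n_replicates=self.n_replicates,
            responsive_effect_log2=self.responsive_effect_log2,
            mkp1_effect_log2=self.mkp1_effect_log2,
            noise_cv=self.noise_cv,
            seed=self.seed,
        )


def _coerce(value: str, annotation) -> object:
    text = str(annotation)
    if "bool" in text:
        if value.lower() in ("1", "true", "yes", "on"):
            return True
        if value.lower() in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"cannot parse boolean from {value!r}")
    if "int" in text:
        return int(value)
    if "float" in text:
        return float(value)
    return value


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON).

    Any stage failure aborts with :class:`PipelineError` naming the stage,
    and removes the partial outputs written by the failed run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def _write(df: pd.DataFrame, name: str, writer=tables.write_table) -> Path:
        path = out / name
        writer(df, path)
        written.append(path)
        return path

    try:
        stage = "simulate"
        matrix, truth = simulate_expression(config.sim_config())
        _write(matrix, "expression.tsv", tables.write_expression_long)
        _write(truth, "truth_genes.tsv")

        stage = "differential"
        diffs = run_contrasts(matrix, default_contrasts(), pseudocount=config.pseudocount)
        _write(diffs, "diff_table.tsv", tables.write_diff_table)

        stage = "classify"
        calls, stats = _classify.classify_calls(diffs, config.thresholds())
        _write(calls, "gene_calls.tsv", tables.write_gene_calls)
        cat_summary = summary.summarize_categories(calls)
        _write(cat_summary, "classify_summary.tsv")

        stage = "cluster"
        responsive = sorted(set(calls.loc[calls["responsive"], "gene_id"]))
        profiles = clustering.enumerate_profiles(T=3, c=config.max_unit_change, m=config.max_profiles)
        ratios = clustering.ratio_vectors(matrix, genes=responsive, pseudocount=config.pseudocount)
        assignments = clustering.assign_genes(ratios, profiles)
        profile_stats = clustering.profile_significance(ratios, profiles, assignments)
        _write(assignments, "cluster_assignments.tsv")
        _write(profile_stats, "profile_stats.tsv")
        crosstabs = {}
        for t in (30, 90):
            ct = summary.crosstab_cluster_by_category(calls, assignments, t)
            _write(ct.reset_index(), f"crosstab_{t}.tsv")
            crosstabs[t] = ct

        stage = "enrich"
        all_genes = sorted(set(matrix["gene_id"]))
        dependent = sorted(set(calls.loc[calls["mkp1_dependent"], "gene_id"]))
        term_map, term_truth = simulate_annotations(
            all_genes,
            dependent,
            n_terms=config.n_terms,
            n_enriched=config.n_enriched,
            odds_ratio=config.enrich_odds_ratio,
            seed=config.seed + 1,
        )
        _write(term_map, "term_map.tsv", tables.write_annotation_map)
        _write(term_truth, "truth_terms.tsv")
        enr_resp = enrichment.fisher_enrich(dependent, responsive, term_map) if responsive else pd.DataFrame()
        enr_all = enrichment.fisher_enrich(dependent, all_genes, term_map)
        _write(enr_resp, "enrichment_responsive_bg.tsv")
        _write(enr_all, "enrichment_genome_bg.tsv")

        qpcr_summary = {}
        if config.qpcr_enabled:
            stage = "qpcr"
            targets = _pick_panel_genes(truth)
            curves, sample_map, qpcr_truth = simulate_qpcr_panel(
                matrix, targets, noise_sd=config.qpcr_noise_sd, seed=config.seed + 2
            )
            _write(curves, "qpcr_curves.tsv", tables.write_qpcr_curves)
            _write(sample_map, "qpcr_sample_map.tsv")
            estimates = qpcr.estimate_reactions(curves)
            levels = qpcr.quantify_samples(estimates, sample_map, reference_gene="REF")
            folds, tests = qpcr.normalize_and_test(levels)
            _write(folds, "qpcr_levels.tsv")
            _write(tests, "qpcr_tests.tsv")
            qpcr_summary = {
                "n_reactions": int(len(qpcr_truth)),
                "n_reliable": int(estimates["reliable"].sum()),
                "n_tests": int(len(tests)),
            }

        stage = "summary"
        n_resp_union = len(responsive)
        n_assigned = int(assignments["profile_id"].notna().sum())
        report = {
            "seed": config.seed,
            "n_genes": config.n_genes,
            "responsive_union": n_resp_union,
            "cluster_assignment": {
                "assigned": n_assigned,
                "total": len(assignments),
                "percent": summary.assigned_percent(n_assigned, len(assignments)),
            },
            "categories": cat_summary.to_dict(orient="records"),
            "enrichment": {
                "responsive_background_hits": int(
                    len(enrichment.significant_terms(enr_resp, config.enrich_q_cutoff)) if len(enr_resp) else 0
                ),
                "genome_background_hits": int(
                    len(enrichment.significant_terms(enr_all, config.enrich_q_cutoff)) if len(enr_all) else 0
                ),
            },
            "qpcr": qpcr_summary,
            "gaps": {
                "missing_contrasts": stats.missing_contrasts,
                "direction_conflicts": stats.direction_conflicts,
            },
        }
        path = out / "summary.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n")
        written.append(path)
        return report
    except Exception as exc:  # noqa: BLE001 - abort with stage name, clean partials
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise PipelineError(stage, exc) from exc


def _json_default(obj):
    if obj is pd.NA or (isinstance(obj, float) and pd.isna(obj)):
        return None
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _pick_panel_genes(truth: pd.DataFrame, per_category: int = 1) -> list[str]:
    """A small validation panel: first gene(s) of each responsive category."""
    targets = []
    for cat in (_classify.CAT_BOTH, _classify.CAT_MPK6_INDEP, _classify.CAT_INDEPENDENT):
        sub = truth[truth["category"] == cat]
        targets.extend(sub["gene_id"].head(per_category).tolist())
    if not targets:
        targets = truth["gene_id"].head(3).tolist()
    return targets
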