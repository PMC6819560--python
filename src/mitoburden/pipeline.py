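"""End-to-end pipeline: inputs → annotated/classified variants → summary
tables → burden statistics → report bundle.

Outputs are deterministic for a fixed config and inputs: rows are sorted,
floats are formatted with a fixed precision, and the run log records the
package version, a hash of the serialized config and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .classification import DEFAULT_RARE_MAF_THRESHOLD, ExclusionConfig
from .cohort import (
    CATEGORIES,
    RARITIES,
    group_summary,
    mutational_load,
    rank_tests,
    rare_common_burden_test,
    rare_common_ratio_of_ratios,
)
from .errors import ConfigError, DegenerateTableError, MitoError, \
    ValidationError
from .haplogroups import load_tree
from .reference import load_reference
from .simulate import SimulationConfig, simulate_cohort
from .variants import (
    read_frequency_table,
    read_metadata,
    read_pathogenicity_table,
    read_profiles,
    write_profiles_hsd,
)
from .workflow import analyze_profiles, counts_by_group, \
    load_demo_frequency_table, load_demo_pathogenicity_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    profiles_path: str | None = None       # None -> simulate a cohort
    profiles_format: str = "hsd"
    metadata_path: str | None = None
    frequency_table_path: str | None = None     # None -> packaged demo
    pathogenicity_table_path: str | None = None
    tree_path: str | None = None
    reference_fasta_path: str | None = None
    exclusions_path: str | None = None
    rare_maf_threshold: float = DEFAULT_RARE_MAF_THRESHOLD
    missing_maf_policy: str = "zero"
    load_mode: str = "all"                 # "all" | "nonneutral"
    burden_mode: str = "pooled"            # "pooled" | "permutation"
    out_dir: str = "mitoburden-run"
    seed: int = 0

    def to_json(self) -> str:
        """Serialized analysis config; out_dir is an output location, not
        an analysis input, and is excluded so the config hash identifies
        the analysis."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return json.dumps(payload, sort_keys=True, indent=2)


def _require_files(config: PipelineConfig) -> None:
    for name in ("profiles_path", "metadata_path", "frequency_table_path",
                 "pathogenicity_table_path", "tree_path",
                 "reference_fasta_path", "exclusions_path"):
        path = getattr(config, name)
        if path is not None and not os.path.exists(path):
            raise ConfigError(f"{name} does not exist: {path}")


def _summary_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for rarity in RARITIES:
            for cat in CATEGORIES:
                rows.append({
                    "group": s.group, "n": s.n, "rarity": rarity,
                    "category": cat,
                    "mean": round(s.means[(cat, rarity)], 2),
                    "sd": round(s.sds[(cat, rarity)], 2),
                })
            rows.append({
                "group": s.group, "n": s.n, "rarity": rarity,
                "category": "total",
                "mean": round(s.totals[rarity], 2), "sd": float("nan"),
            })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict with the in-memory results (analyses, summaries, test
    results) for programmatic use. Any stage failure aborts with the stage
    name attached.
    """
    _require_files(config)
    stage = "load-inputs"
    try:
        reference = load_reference(config.reference_fasta_path)
        tree = load_tree(config.tree_path)
        freqs = (read_frequency_table(config.frequency_table_path)
                 if config.frequency_table_path
                 else load_demo_frequency_table())
        path_table = (read_pathogenicity_table(
            config.pathogenicity_table_path)
            if config.pathogenicity_table_path
            else load_demo_pathogenicity_table())
        exclusions = (ExclusionConfig.from_json(config.exclusions_path)
                      if config.exclusions_path else ExclusionConfig())
        if config.profiles_path is None:
            cohort = simulate_cohort(
                SimulationConfig(seed=config.seed), reference, tree, freqs,
                exclusions)
            profiles = list(cohort.profiles)
        else:
            metadata = (read_metadata(config.metadata_path)
                        if config.metadata_path else None)
            profiles = read_profiles(config.profiles_path,
                                     config.profiles_format,
                                     reference=reference, metadata=metadata)
        profiles.sort(key=lambda p: p.subject_id)

        stage = "analyze"
        analyses = analyze_profiles(profiles, reference, tree, freqs,
                                    exclusions, config.rare_maf_threshold,
                                    config.missing_maf_policy)

        stage = "summarize"
        all_counts = [a.counts for a in analyses]
        by_group = group_summary(all_counts, "group")
        by_jk = group_summary(all_counts, "jk")

        stage = "load"
        loads = [mutational_load(a.profile.subject_id, a.classified,
                                 path_table, exclusions.load_exclusions,
                                 config.load_mode, a.profile.group, a.jk)
                 for a in analyses]

        stage = "stats"
        results: dict = {}
        grouped = counts_by_group(analyses)
        try:
            burden = rare_common_burden_test(grouped,
                                             mode=config.burden_mode,
                                             seed=config.seed)
            results["burden_test"] = {
                "groups": list(burden.groups),
                "table_rare_common": [list(r) for r in burden.table],
                "statistic": burden.statistic, "dof": burden.dof,
                "p_value": burden.p_value, "mode": burden.mode,
            }
        except (DegenerateTableError, ValidationError) as exc:
            results["burden_test"] = {"error": str(exc)}
        jk_counts = [c for c in all_counts if c.jk]
        other_counts = [c for c in all_counts if not c.jk]
        try:
            results["jk_ratio_of_ratios"] = rare_common_ratio_of_ratios(
                jk_counts, other_counts)
        except ValidationError as exc:
            results["jk_ratio_of_ratios"] = None
            results["jk_ratio_error"] = str(exc)
        if jk_counts and other_counts:
            strata = {"J and K": [c.rarity_total("rare") for c in jk_counts],
                      "Other": [c.rarity_total("rare") for c in other_counts]}
            rt = rank_tests(strata)
            results["jk_rare_rank_test"] = {
                "test": rt.test, "statistic": rt.statistic,
                "p_value": rt.p_value, "flags": list(rt.flags)}

        stage = "write-report"
        _write_report(config, profiles, analyses, by_group, by_jk, loads,
                      results)
    except MitoError:
        raise
    except Exception as exc:  # attach the failing stage for diagnosis
        raise MitoError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {"profiles": profiles, "analyses": analyses,
            "summary_by_group": by_group, "summary_by_jk": by_jk,
            "loads": loads, "test_results": results}


def _write_report(config, profiles, analyses, by_group, by_jk, loads,
                  results) -> None:
    out = config.out_dir
    os.makedirs(out, exist_ok=True)

    annotated_rows = []
    for a in analyses:
        for cv in a.classified:
            v = cv.variant
            annotated_rows.append({
                "subject_id": a.profile.subject_id,
                "group": a.profile.group or "",
                "haplogroup": a.haplogroup,
                "variant": v.label,
                "genes": ";".join(cv.annotated.gene_names),
                "category": cv.category,
                "aa_change": ";".join(str(c) for c in cv.annotated.aa_changes),
                "functional": int(cv.functional),
                "rarity": cv.rarity,
                "maf": "" if cv.maf is None else f"{cv.maf:.6g}",
                "heteroplasmy": ("" if v.heteroplasmy is None
                                 else f"{v.heteroplasmy:.4g}"),
                "het_flag": int(v.het_flag),
            })
    pd.DataFrame(annotated_rows).to_csv(
        os.path.join(out, "annotated_variants.tsv"), sep="\t", index=False)

    count_rows = []
    for a in analyses:
        row = {"subject_id": a.profile.subject_id,
               "group": a.profile.group or "",
               "haplogroup": a.haplogroup, "jk": int(a.jk)}
        for cat in CATEGORIES:
            for rar in RARITIES:
                row[f"{rar}_{cat}"] = a.counts.cell(cat, rar)
        row["total_functional"] = a.counts.total
        count_rows.append(row)
    pd.DataFrame(count_rows).to_csv(
        os.path.join(out, "subject_counts.tsv"), sep="\t", index=False)

    _summary_frame(by_group).to_csv(
        os.path.join(out, "summary_by_group.tsv"), sep="\t", index=False)
    _summary_frame(by_jk).to_csv(
        os.path.join(out, "summary_by_jk.tsv"), sep="\t", index=False)

    pd.DataFrame([{
        "subject_id": l.subject_id, "group": l.group or "", "jk": int(l.jk),
        "common_load": f"{l.common_load:.6g}",
        "rare_load": f"{l.rare_load:.6g}",
        "unscored": ";".join(l.missing),
    } for l in loads]).to_csv(
        os.path.join(out, "load_summary.tsv"), sep="\t", index=False)

    write_profiles_hsd(profiles, os.path.join(out, "profiles.hsd"))

    with open(os.path.join(out, "test_results.json"), "w") as handle:
        json.dump(results, handle, indent=2, sort_keys=True)

    config_json = config.to_json()
    run_log = {
        "package": "mitoburden",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "config": json.loads(config_json),
        "n_subjects": len(profiles),
    }
    with open(os.path.join(out, "run_log.json"), "w") as handle:
        json.dump(run_log, handle, indent=2, sort_keys=True)
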