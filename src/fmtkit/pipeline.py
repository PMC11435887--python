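"""End-to-end orchestration: ingest -> filters -> aggregation -> scaling ->
{composition, diversity, differential abundance, engraftment} -> clinical.

Every stage writes plain-text tables under the output directory and
registers itself in the run report; warnings (zero-total samples,
mixed-model fallbacks, skipped stages) are collected into the report rather
than only logged. Re-running with the same config and inputs reproduces
all outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import clinical as clin
from . import differential_abundance as da
from . import diversity as div
from . import engraftment as eng
from .config import InputPaths, PipelineConfig
from .feature_table import (
    AsvTable,
    RelAbundTable,
    SampleMetadata,
    aggregate_taxa,
    collapse_other,
    low_count_filter,
    low_variance_filter,
    read_asv_table,
    read_metadata,
    remove_rare_asvs,
    total_sum_scaling,
)
from .synthetic import make_fixture_dataset

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    seed: int
    version: str = __version__
    parameters: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # stage -> {name: path}
    warnings: list = field(default_factory=list)
    skipped: dict = field(default_factory=dict)  # stage -> reason

    def register(self, stage: str, name: str, path: Path) -> Path:
        self.outputs.setdefault(stage, {})[name] = str(path)
        return path


def write_report(report: RunReport, path) -> None:
    doc = dataclasses.asdict(report)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, lineterminator="\n")


def _cohort_labels(metadata: SampleMetadata, sample_ids: list[str]) -> pd.Series:
    meta = metadata.frame.set_index("sample_id")
    labels = {}
    for s in sample_ids:
        group, visit = meta.loc[s, "group"], meta.loc[s, "visit"]
        labels[s] = group if group in ("donor", "healthy") else f"{group}:{visit}"
    return pd.Series(labels)[sample_ids]


def run_pipeline(config: PipelineConfig, out_dir) -> RunReport:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, parameters=config.echo())

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _run_stages(config, out, report)
        report.warnings.extend(str(w.message) for w in caught)

    write_report(report, out / "report.json")
    return report


def _run_stages(config: PipelineConfig, out: Path, report: RunReport) -> None:
    # -- ingest ------------------------------------------------------------
    try:
        inputs = config.inputs
        if inputs is None:
            sim_dir = out / "inputs"
            make_fixture_dataset(config.simulate, sim_dir)
            inputs = InputPaths.from_dir(sim_dir)
            report.register("ingest", "simulated_inputs", sim_dir)
        table = read_asv_table(inputs.feature_table, taxonomy_path=inputs.taxonomy or None)
        metadata = read_metadata(inputs.metadata)
        metadata.require_covers(table)
    except Exception as exc:  # noqa: BLE001 - stage-tagged error propagation
        raise PipelineError("ingest", str(exc)) from exc

    ft = config.feature_table
    table_rare = remove_rare_asvs(table, ft.rare_max_total)

    # -- microbiome processing branch -------------------------------------
    try:
        processed: AsvTable | RelAbundTable = table_rare
        for step in ft.order:
            if step == "low_count":
                processed = low_count_filter(processed, ft.min_count, ft.min_prevalence)
            elif step == "aggregate":
                processed = aggregate_taxa(processed, ft.aggregate_rank)
            elif step == "low_variance":
                processed = low_variance_filter(processed, ft.low_variance_drop)
            elif step == "scale":
                processed = total_sum_scaling(processed)
            else:
                raise ValueError(f"unknown processing step {step!r}")
        if not isinstance(processed, RelAbundTable):
            processed = total_sum_scaling(processed)
        rel: RelAbundTable = processed
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("feature_table", str(exc)) from exc

    # -- composition summaries --------------------------------------------
    if "composition" in config.stages:
        try:
            threshold = (
                ft.other_threshold_species
                if ft.aggregate_rank == "species"
                else ft.other_threshold_genus
            )
            summary = collapse_other(rel, threshold)
            _write_tsv(
                summary.proportions.rename_axis("sample_id"),
                report.register("composition", "relative_abundance",
                                out / "composition_relabund.tsv"),
                index=True,
            )
        except Exception as exc:
            raise PipelineError("composition", str(exc)) from exc

    # -- diversity ----------------------------------------------------------
    if "diversity" in config.stages:
        try:
            alpha = div.alpha_diversity(rel, base=config.diversity.log_base)
            alpha_frame = alpha.rename("shannon").rename_axis("sample_id").reset_index()
            labels = _cohort_labels(metadata, rel.sample_ids)
            alpha_frame["cohort"] = labels.to_numpy()
            _write_tsv(alpha_frame, report.register("diversity", "alpha", out / "alpha_shannon.tsv"))

            pairwise = div.pairwise_kruskal(
                alpha, labels, adjust=config.diversity.adjust_pairwise
            )
            _write_tsv(pairwise, report.register("diversity", "alpha_pairwise",
                                                 out / "alpha_kruskal_pairwise.tsv"))

            dist = div.bray_curtis_matrix(rel)
            _write_tsv(dist.to_frame().rename_axis("sample_id"),
                       report.register("diversity", "bray_curtis", out / "bray_curtis.tsv"),
                       index=True)
            _write_tsv(div.pcoa_coordinates(dist).rename_axis("sample_id"),
                       report.register("diversity", "pcoa", out / "pcoa_coordinates.tsv"),
                       index=True)

            counts = labels.value_counts()
            keep = [s for s in rel.sample_ids if counts[labels[s]] >= 2]
            sub_ids = [i for i, s in enumerate(rel.sample_ids) if s in set(keep)]
            sub = div.DistanceMatrix(keep, dist.distances[sub_ids][:, sub_ids])
            perma = div.permanova(
                sub, labels[keep],
                n_permutations=config.diversity.n_permutations,
                seed=config.seed,
            )
            _write_tsv(
                pd.DataFrame([{
                    "groups": ";".join(sorted(set(labels[keep]))),
                    "pseudo_F": perma.pseudo_F,
                    "p_value": perma.p_value,
                    "n_permutations": perma.n_permutations,
                    "seed": perma.seed,
                    "exhaustive": perma.exhaustive,
                }]),
                report.register("diversity", "permanova", out / "permanova.tsv"),
            )
        except Exception as exc:
            raise PipelineError("diversity", str(exc)) from exc

    # -- differential abundance (per arm, pre vs post) ----------------------
    if "differential_abundance" in config.stages:
        try:
            cfg = da.DaConfig(
                prevalence_cutoff=config.differential_abundance.prevalence_cutoff,
                winsor_quantile=config.differential_abundance.winsor_quantile,
                pseudocount=config.differential_abundance.pseudocount,
            )
            agg = aggregate_taxa(table_rare, ft.aggregate_rank)
            for arm in ("FMT", "placebo"):
                arm_samples = [
                    s for s in agg.sample_ids
                    if s in set(metadata.samples_where(group=arm))
                ]
                if not arm_samples:
                    report.skipped[f"differential_abundance:{arm}"] = "no samples for arm"
                    continue
                arm_table = agg.select_samples(arm_samples)
                filtered = da.prevalence_filter(arm_table, cfg.prevalence_cutoff)
                arm_rel = total_sum_scaling(filtered)
                arm_rel = da.winsorize(arm_rel, cfg.winsor_quantile)
                results = da.fit_da(arm_rel, metadata, cfg)
                _write_tsv(
                    da.da_table(results),
                    report.register("differential_abundance", arm,
                                    out / f"da_{arm.lower()}_pre_vs_post.tsv"),
                )
        except Exception as exc:
            raise PipelineError("differential_abundance", str(exc)) from exc

    # -- engraftment ---------------------------------------------------------
    if "engraftment" in config.stages:
        donor_samples = metadata.samples_where(group="donor")
        fmt_dogs = metadata.dogs_in_group("FMT")
        if not donor_samples or not fmt_dogs:
            report.skipped["engraftment"] = (
                "requires donor samples and FMT recipients; "
                f"found {len(donor_samples)} donor sample(s), {len(fmt_dogs)} FMT dog(s)"
            )
        else:
            try:
                donor_profile = eng.build_presence(table_rare, metadata, "donor", "donor")
                results = []
                for dog in fmt_dogs:
                    baseline = config.engraftment.baseline_visit_overrides.get(dog)
                    pre = eng.build_presence(
                        table_rare, metadata, dog, "pre_fmt", baseline_visit=baseline
                    )
                    post = eng.build_presence(table_rare, metadata, dog, "post_fmt")
                    results.append(eng.engraftment_rate(donor_profile, pre, post))
                summary = eng.summarize_engraftment(results)
                _write_tsv(eng.engraftment_table(results),
                           report.register("engraftment", "per_dog", out / "engraftment_rates.tsv"))
                freq_rows = [
                    {
                        "asv_id": asv,
                        "n_recipients_engrafted": n,
                        "taxonomy": (
                            table.taxonomy[asv].label("species")
                            if table.taxonomy and asv in table.taxonomy else ""
                        ),
                    }
                    for asv, n in sorted(
                        summary.asv_frequency.items(), key=lambda kv: (-kv[1], kv[0])
                    )
                ]
                _write_tsv(
                    pd.DataFrame(freq_rows,
                                 columns=["asv_id", "n_recipients_engrafted", "taxonomy"]),
                    report.register("engraftment", "asv_frequency",
                                    out / "engraftment_asv_frequency.tsv"),
                )
                _write_tsv(
                    pd.DataFrame([{
                        "n_recipients": len(results),
                        "mean_percent": round(summary.mean_percent, 2),
                        "median_percent": round(summary.median_percent, 2),
                        "min_percent": round(summary.min_percent, 2),
                        "max_percent": round(summary.max_percent, 2),
                    }]),
                    report.register("engraftment", "summary", out / "engraftment_summary.tsv"),
                )
            except Exception as exc:
                raise PipelineError("engraftment", str(exc)) from exc

    # -- clinical ------------------------------------------------------------
    if "clinical" in config.stages:
        if not inputs.disposition:
            report.skipped["clinical"] = "no clinical input files configured"
            return
        try:
            records = clin.read_disposition(inputs.disposition)
            outcomes, p_values = clin.phase_outcomes(records)
            rows = [
                {
                    "group": o.group, "phase": o.phase,
                    "n_evaluable": o.n_evaluable, "n_relapsed": o.n_relapsed,
                    "responder_percent": o.responder_percent,
                    "relapse_percent": o.relapse_percent,
                    "n_excluded": len(o.exclusions),
                    "exact_test_p": p_values.get(o.phase, float("nan")),
                }
                for o in outcomes
            ]
            _write_tsv(pd.DataFrame(rows),
                       report.register("clinical", "disposition", out / "disposition_summary.tsv"))

            fdm = clin.read_fdm(inputs.fdm, convention=config.clinical.fdm_convention)
            diary = clin.read_fcs_diary(inputs.fcs_diary)
            pairs = []
            eval_day = {"treatment": 28, "post_treatment": 56}
            for m in fdm:
                if m.visit not in eval_day:
                    continue
                entries = [e for e in diary if e.dog_id == m.dog_id]
                try:
                    mean_score = clin.mean_fcs(
                        entries, eval_day[m.visit], config.clinical.fcs_window_days
                    )
                except clin.ClinicalError:
                    continue
                pairs.append((m.fdm_percent, mean_score))
            if len(pairs) >= 3:
                reg = clin.fcs_fdm_regression(pairs)
                _write_tsv(pd.DataFrame([reg]),
                           report.register("clinical", "fcs_fdm_regression",
                                           out / "fcs_fdm_regression.tsv"))
            else:
                report.skipped["clinical:fcs_fdm_regression"] = "fewer than 3 (FDM, FCS) pairs"
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("clinical", str(exc)) from exc
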