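"""End-to-end orchestration: raw table -> normalized profile ->
composition and differential outputs, plus the cross-experiment
direction comparison.

``run_pipeline`` is a pure function of its inputs: repeated runs on the
same files and configuration write byte-identical outputs.  Every
warning emitted by the stages (missing replicates, undefined ratios,
degenerate tests) is captured into the run log with a count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import (
    CarnitineRatios,
    carnitine_ratios,
    category_molpct,
    molpct,
    saturation_ratios,
)
from .differential import (
    AnalysisConfig,
    build_direction_table,
    class_summaries,
    differential_table,
    direction_fisher,
    ratio_group_change,
    volcano_table,
)
from .errors import DegenerateStatisticsError, MissingDataError
from .quantify import (
    MatrixEffectReport,
    NormalizedProfile,
    StandardMap,
    aggregate_technical,
    matrix_effect,
    normalize_to_standard,
    read_raw_table,
    validate_raw_table,
)
from .species import ChainLengthBins, LipidClass

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "compare_experiments"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the full pipeline needs besides the raw table itself."""

    reference_group: str
    out_dir: Path
    standards: StandardMap = field(default_factory=StandardMap)
    analysis: AnalysisConfig | None = None
    bins: ChainLengthBins = field(default_factory=ChainLengthBins)
    emit_plots: bool = False
    drop_missing: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.analysis is None:
            self.analysis = AnalysisConfig(reference_group=self.reference_group)


@dataclass
class PipelineResult:
    profile: NormalizedProfile
    matrix_report: MatrixEffectReport
    differential: pd.DataFrame
    class_summary: pd.DataFrame
    composition: pd.DataFrame
    ratio_changes: pd.DataFrame
    carnitine: CarnitineRatios
    out_dir: Path


class _CountingHandler(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.counts: dict[str, int] = {}

    def emit(self, record: logging.LogRecord) -> None:
        msg = record.getMessage()
        self.counts[msg] = self.counts.get(msg, 0) + 1


def run_pipeline(raw: pd.DataFrame | str | Path,
                 config: PipelineConfig) -> PipelineResult:
    """Execute read -> normalize -> aggregate -> QC -> composition ->
    differential and write all CSV outputs plus ``run_log.txt``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _CountingHandler()
    logging.getLogger("mrmlipid").addHandler(handler)
    try:
        if isinstance(raw, (str, Path)):
            records = read_raw_table(raw)
        else:
            records = validate_raw_table(raw)

        groups = list(dict.fromkeys(records["group"]))
        if config.reference_group not in groups:
            raise MissingDataError(
                f"reference group {config.reference_group!r} absent from "
                f"table groups {groups}")
        other_groups = [g for g in groups if g != config.reference_group]
        if len(other_groups) != 1:
            raise MissingDataError(
                f"expected one non-reference group, found {other_groups}")
        other = other_groups[0]

        ratios = normalize_to_standard(records, config.standards)
        profile = aggregate_technical(ratios, drop_missing=config.drop_missing)
        profile.to_csv(out / "normalized.csv")

        report = matrix_effect(records, config.reference_group, other)
        report.to_frame().to_csv(out / "matrix_effect.csv", index=False)

        diff = differential_table(profile, config.analysis)
        diff.to_csv(out / "differential.csv", index=False)
        summary = class_summaries(diff)
        summary.to_csv(out / "class_summary.csv", index=False)

        comp_rows, ratio_rows = _composition_outputs(profile, config)
        comp_rows.to_csv(out / "composition.csv", index=False)
        ratio_rows.to_csv(out / "ratio_changes.csv", index=False)

        carn = _carnitine_outputs(profile, out)

        for cls, sub in diff.groupby("lipid_class", sort=False):
            row = summary.loc[summary["lipid_class"] == cls].iloc[0].to_dict()
            volc = volcano_table(sub, row, config.analysis)
            volc.to_csv(out / f"volcano_{cls}.csv", index=False)
            if config.emit_plots:
                from .differential import plot_volcano
                plot_volcano(volc, out / f"volcano_{cls}.svg", title=cls)

        _write_run_log(out, config, records, handler.counts)
        return PipelineResult(profile, report, diff, summary, comp_rows,
                              ratio_rows, carn, out)
    finally:
        logging.getLogger("mrmlipid").removeHandler(handler)


def _composition_outputs(profile: NormalizedProfile,
                         config: PipelineConfig
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format category mol% table and group-change rows for the
    derived quantities (category mol% and saturation ratios)."""
    comp_records = []
    change_records = []
    present = sorted({c.value for c in profile.species_classes.values()})
    for code in present:
        cls = LipidClass(code)
        frag = molpct(profile, cls)
        schemes = []
        if cls is not LipidClass.CAR:
            schemes.append("saturation")
        if config.bins.applicable(cls):
            schemes.append("chain_length")
        for scheme in schemes:
            cat = category_molpct(frag, scheme, config.bins)
            for category, row in cat.iterrows():
                for sample_id, value in row.items():
                    comp_records.append(
                        (sample_id, code, scheme, category, float(value)))
                try:
                    pct, sem, p = ratio_group_change(
                        row, profile.sample_groups, config.analysis)
                except DegenerateStatisticsError as exc:
                    logger.warning("group change for %s %s:%s skipped: %s",
                                   code, scheme, category, exc)
                    continue
                change_records.append(
                    (code, f"{scheme}:{category}", pct, sem, p))
        if "saturation" in schemes:
            sat = saturation_ratios(category_molpct(frag, "saturation"))
            for ratio_name, row in sat.iterrows():
                try:
                    pct, sem, p = ratio_group_change(
                        row, profile.sample_groups, config.analysis)
                except DegenerateStatisticsError as exc:
                    logger.warning("group change for %s %s skipped: %s",
                                   code, ratio_name, exc)
                    continue
                change_records.append((code, ratio_name, pct, sem, p))
    comp = pd.DataFrame(
        comp_records,
        columns=["sample_id", "lipid_class", "scheme", "category", "mol_pct"])
    changes = pd.DataFrame(
        change_records,
        columns=["lipid_class", "quantity", "percent_of_reference",
                 "sem_percent", "p"])
    return comp, changes


def _carnitine_outputs(profile: NormalizedProfile,
                       out: Path) -> CarnitineRatios | None:
    if not any(c is LipidClass.CAR for c in profile.species_classes.values()):
        return None
    try:
        carn = carnitine_ratios(profile)
    except MissingDataError as exc:
        logger.warning("carnitine ratios skipped: %s", exc)
        return None
    long = (carn.ratios.reset_index(names="ratio_name")
            .melt(id_vars="ratio_name", var_name="sample_id",
                  value_name="value"))
    long[["sample_id", "ratio_name", "value"]].to_csv(
        out / "carnitine_ratios.csv", index=False)
    return carn


def _write_run_log(out: Path, config: PipelineConfig, records: pd.DataFrame,
                   warning_counts: dict[str, int]) -> None:
    lines = [
        f"mrmlipid {__version__}",
        f"reference_group: {config.reference_group}",
        f"alpha_levels: {list(config.analysis.alpha_levels)}",
        f"welch: {config.analysis.welch}",
        f"direction_filter: {config.analysis.direction_filter}",
        f"n_records: {len(records)}",
        f"n_samples: {records['sample_id'].nunique()}",
        "warnings:",
    ]
    if warning_counts:
        lines += [f"  [{count}x] {msg}"
                  for msg, count in sorted(warning_counts.items())]
    else:
        lines.append("  none")
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")


def compare_experiments(diff_a: pd.DataFrame, diff_b: pd.DataFrame,
                        direction_filter: str = "all") -> pd.DataFrame:
    """Fisher direction test between two differential tables.

    Builds the increased/decreased 2x2 table per lipid class and
    overall, returning one row each with the counts and the two-sided
    Fisher exact p.  Classes sharing fewer than 2 species are skipped.
    """
    rows = []
    classes = sorted(set(diff_a["lipid_class"]) & set(diff_b["lipid_class"]))
    scopes = [("overall", diff_a, diff_b)]
    scopes += [(cls,
                diff_a[diff_a["lipid_class"] == cls],
                diff_b[diff_b["lipid_class"] == cls]) for cls in classes]
    for label, sub_a, sub_b in scopes:
        try:
            table = build_direction_table(sub_a, sub_b, direction_filter)
        except MissingDataError:
            if label == "overall":
                raise
            continue
        rows.append({
            "scope": label,
            "up_a": int(table[0, 0]), "down_a": int(table[0, 1]),
            "up_b": int(table[1, 0]), "down_b": int(table[1, 1]),
            "fisher_p": direction_fisher(table),
        })
    return pd.DataFrame(rows)
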