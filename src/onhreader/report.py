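"""End-to-end pipeline: simulate or load grades, run every stage, write reports.

Every number written to a report file is produced by the corresponding stage
operation on the same inputs; the pipeline adds no computation of its own. Runs
with the same configuration and seed produce byte-identical report files (the
run manifest records the configuration and seed, never wall-clock time).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import pairwise_agreement
from .anova import LongDataset, fit_mixed_anova, posthoc_pairwise
from .confidence import modality_pair_tests
from .core import GradeRecord, StudyDesign, UnitDefinition, read_grades, write_grades
from .scoring import DEFAULT_SCHEME, ScoringScheme, accuracy_table
from .simulate import SimulationConfig, generate_cohort, preset_study_like

__all__ = ["PipelineConfig", "run_pipeline", "REPORT_FILES"]

logger = logging.getLogger("onhreader")

REPORT_FILES = (
    "accuracy_table.csv",
    "chi_square.csv",
    "agreement_table.csv",
    "anova_table.csv",
    "posthoc.csv",
    "manifest.json",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Exactly one of ``input_path`` (a grade CSV) or ``simulation`` must be set."""

    output_dir: Path
    input_path: Path | None = None
    simulation: SimulationConfig | None = None
    scheme: ScoringScheme = DEFAULT_SCHEME
    alpha: float = 0.05
    unit_definition: UnitDefinition = UnitDefinition.EYE_BY_GRADER

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("set exactly one of input_path or simulation")


def _float_fmt(x) -> str:
    return f"{x:.6g}"


def _write_csv(df: pd.DataFrame, path: Path, index: bool) -> None:
    df.to_csv(path, index=index, float_format="%.6g", lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every analysis stage and write the report bundle.

    Writes the accuracy table, the confidence-by-modality chi-square listing,
    the interrater agreement table, the ANOVA table with sphericity block and
    Bonferroni post-hoc comparisons, and a JSON run manifest. Returns the map
    of report name to written path.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        logger.info("simulating cohort (seed=%d)", config.simulation.seed)
        records = generate_cohort(config.simulation)
        source = {"simulation_seed": config.simulation.seed,
                  "n_records": len(records)}
        write_grades(records, out / "grades.csv")
    else:
        logger.info("reading grades from %s", config.input_path)
        records = read_grades(config.input_path, StudyDesign())
        source = {"input_path": str(config.input_path), "n_records": len(records)}

    paths: dict[str, Path] = {}

    # stage: scoring
    acc = accuracy_table(records, config.scheme).reset_index()
    paths["accuracy"] = out / "accuracy_table.csv"
    _write_csv(acc, paths["accuracy"], index=False)

    # stage: confidence chi-square listing (Table-4-style)
    chi = modality_pair_tests(records, alpha=config.alpha)
    paths["chi_square"] = out / "chi_square.csv"
    _write_csv(chi, paths["chi_square"], index=False)

    # stage: interrater agreement
    graders = sorted({r.grader_id for r in records})
    if len(graders) != 2:
        raise ValueError(f"pipeline expects exactly 2 graders, found {graders}")
    agree = pairwise_agreement(records, graders[0], graders[1])
    agree_df = agree.table.round(3).reset_index()
    paths["agreement"] = out / "agreement_table.csv"
    _write_csv(agree_df, paths["agreement"], index=False)

    # stage: mixed ANOVA + sphericity + post-hoc
    data = LongDataset.from_records(records, config.scheme, config.unit_definition)
    result = fit_mixed_anova(data, alpha=config.alpha)
    if result.excluded_units:
        logger.warning("excluded %d incomplete unit(s)", len(result.excluded_units))
    table = result.table()
    paths["anova"] = out / "anova_table.csv"
    _write_csv(table, paths["anova"], index=False)

    posthoc_rows = []
    for factor in ("diagnosis", "modality"):
        for cmp_ in posthoc_pairwise(data, factor, alpha=config.alpha):
            posthoc_rows.append(
                {
                    "factor": factor,
                    "level_a": cmp_.level_a,
                    "level_b": cmp_.level_b,
                    "t": cmp_.t,
                    "df": cmp_.df,
                    "p_raw": cmp_.p_raw,
                    "p_bonferroni": cmp_.p_adjusted,
                    "reject": cmp_.reject,
                }
            )
    paths["posthoc"] = out / "posthoc.csv"
    _write_csv(pd.DataFrame(posthoc_rows), paths["posthoc"], index=False)

    sph = result.sphericity
    manifest = {
        "package_version": __version__,
        "alpha": config.alpha,
        "unit_definition": config.unit_definition.value,
        "scheme": list(config.scheme.accuracy_for_true_edema),
        "source": source,
        "n_units": result.n_units,
        "excluded_units": list(result.excluded_units),
        "sphericity": None
        if sph is None
        else {"W": sph.w, "p": sph.p_value, "epsilon_gg": sph.epsilon_gg, "k": sph.k},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    logger.info("wrote %d report files to %s", len(paths), out)
    return paths
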