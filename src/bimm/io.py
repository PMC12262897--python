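"""Cohort file reading, run configuration, and experiment output writing.

The input format is a plain CSV with a header: an id column, a side column
(1 = left, 2 = right), a binary outcome column, and any number of numeric
covariate columns. Column names are configurable via :class:`RunConfig`
and normalised to the package's internal schema on read. Rows with missing
values are excluded, and persons lacking one of their two knees are
dropped, both with logged counts — matching a complete-case,
both-knees-available analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .cohort import OUTCOME_COL, PERSON_COL, SIDE_COL, validate_cohort
from .exceptions import BimmError, CohortValidationError
from .evaluation import EvaluationSummary

logger = logging.getLogger("bimm")


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    Loadable from YAML (:meth:`from_yaml`); CLI flags override fields.
    """

    input_path: str | None = None
    person_col: str = PERSON_COL
    side_col: str = SIDE_COL
    outcome_col: str = OUTCOME_COL
    split_kind: str = "h1"  # h1 | h2 | h3 | grid-search
    split_constant: float | None = 0.25
    n_trees: int = 500
    majority_class_weight: float | None = None
    tolerance: float = 0.5
    max_iter: int = 50
    n_partitions: int = 100
    train_fraction: float = 0.7
    threshold: float = 0.5
    output_dir: str = "bimm_output"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise BimmError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def read_cohort(path, config: RunConfig | None = None) -> pd.DataFrame:
    """Read and validate a knee-level cohort CSV.

    Applies the complete-case and both-knees filters with logged counts;
    raises on missing columns, non-binary outcomes, or duplicate
    (person, side) rows.
    """
    config = config or RunConfig()
    df = pd.read_csv(path)
    rename = {
        config.person_col: PERSON_COL,
        config.side_col: SIDE_COL,
        config.outcome_col: OUTCOME_COL,
    }
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise CohortValidationError(f"input lacks required columns: {missing}")
    df = df.rename(columns=rename)

    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("dropped %d row(s) with missing values", n0 - len(df))

    if not df[OUTCOME_COL].isin([0, 1]).all():
        bad = sorted(set(df[OUTCOME_COL]) - {0, 1})
        raise CohortValidationError(
            f"outcome column '{config.outcome_col}' must be binary 0/1; found {bad}"
        )
    if df.duplicated([PERSON_COL, SIDE_COL]).any():
        raise CohortValidationError("duplicate (person, side) rows in input")

    counts = df.groupby(PERSON_COL)[SIDE_COL].count()
    incomplete = counts.index[counts != 2]
    if len(incomplete) > 0:
        logger.info(
            "dropped %d person(s) without both knees", len(incomplete)
        )
        df = df[~df[PERSON_COL].isin(incomplete)]
    df = df.reset_index(drop=True)
    return validate_cohort(df)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def summary_text(summary: EvaluationSummary) -> str:
    """Human-readable report of an evaluation summary."""
    lines = [
        f"Repeated-partition evaluation ({summary.n_partitions} partitions, "
        f"threshold {summary.threshold})",
        "",
        summary.summary.round(4).to_string(),
        "",
        "AUC difference (BiMM - RF): "
        f"t = {summary.t_statistic:.4f}, p = {summary.p_value:.4f}, "
        f"95% CI [{summary.ci_low:.6f}, {summary.ci_high:.6f}]",
        "",
    ]
    for method, count in summary.unique_top_variables.items():
        lines.append(f"{method}: {count} unique variables in per-partition top lists")
    for method, top in summary.top10_mean_gini.items():
        lines.append(f"{method} top variables by average Mean Decrease Gini:")
        for name, score in top:
            lines.append(f"  {name:>8s}  {score:.5f}")
    return "\n".join(lines) + "\n"


def plot_auc_boxplot(summary: EvaluationSummary, path) -> None:
    """Side-by-side box plot of per-partition AUC distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = [
        summary.metrics.loc[summary.metrics["method"] == m, "auc"]
        for m in ("BiMM", "RF")
    ]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(data, tick_labels=["BiMM", "RF"])
    ax.set_ylabel("test-set AUC")
    ax.set_title(f"AUC over {summary.n_partitions} partitions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_outputs(
    summary: EvaluationSummary,
    outdir,
    models: dict | None = None,
    grid_trace: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    make_plot: bool = True,
) -> dict:
    """Write the experiment artefacts and return the file manifest.

    Produces per-partition metrics CSV, summary CSV and text report, the
    AUC box plot, optional BiMM iteration trajectories and grid-search
    trace, the resolved run config, and ``manifest.json`` listing every
    file with its SHA-256 checksum. Reruns with identical seeds reproduce
    identical CSV contents.
    """
    if summary.metrics.empty:
        raise BimmError("refusing to write an empty evaluation summary")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written.append(path)

    emit("partition_metrics.csv", lambda p: summary.metrics.to_csv(p, index=False))
    emit("summary.csv", lambda p: summary.summary.to_csv(p))
    emit("summary.txt", lambda p: p.write_text(summary_text(summary)))
    if make_plot:
        emit("auc_boxplot.png", lambda p: plot_auc_boxplot(summary, p))
    if grid_trace is not None:
        emit("grid_search_trace.csv", lambda p: grid_trace.to_csv(p, index=False))
    if models:
        for name, model in models.items():
            emit(
                f"trajectory_{name}.csv",
                lambda p, m=model: m.trajectory.to_csv(p, index=False),
            )
    if config is not None:
        emit("run_config.yaml", config.to_yaml)

    manifest = {
        "files": [
            {"name": p.name, "sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in written
        ]
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
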