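"""Pipeline orchestration and reporting.

Runs the study stages in order — simulate or load, impute, summarize
(baseline-table style), logistic baseline, MMHC structure learning, ML
parameter learning, prior marginals and posterior queries — and writes
every artifact (CSV tables, DOT/BIF network, JSON manifest) to an output
directory. All randomness flows from one config seed through named
sub-streams, so a persisted config reproduces its outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import serialize
from .bn import BayesianNetwork, InferenceError, fit_mle
from .codebook import CODEBOOK, MISSING, VARIABLES, validate_dataset
from .impute import rf_impute
from .logistic import fit_logistic_irls, forest_plot_data, odds_ratio_table
from .simulate import MissingnessSpec, ancestral_sample, charls_like_network, inject_missingness
from .structure import mmhc, trace_to_frame

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "table1_summary",
    "query_report",
    "read_dataset",
    "write_dataset",
    "plot_forest",
]


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read a coded CSV; empty cells and "NA" become the missing sentinel."""
    df = pd.read_csv(path, na_values=["NA", ""])
    validate_dataset(df, [c for c in VARIABLES if c in df.columns])
    return df.fillna(MISSING).astype(int)


def write_dataset(data: pd.DataFrame, path: str | Path) -> None:
    """Write a coded CSV; the missing sentinel becomes an empty cell."""
    out = data.astype(object).mask(data == MISSING, "")
    out.to_csv(path, index=False)


def _pct(count: int, total: int) -> float:
    """Column percentage rounded half-up to 1 dp (reporting convention)."""
    if total == 0:
        return 0.0
    return float(
        Decimal(100 * count / total).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def table1_summary(data: pd.DataFrame, outcome: str = "mmd") -> pd.DataFrame:
    """Stratified frequency table: per variable/category counts and column
    percentages within each outcome stratum (baseline-characteristics layout)."""
    if outcome not in data.columns:
        raise ValueError(f"outcome column {outcome!r} absent")
    strata = {0: data[data[outcome] == 0], 1: data[data[outcome] == 1]}
    for code, frame in strata.items():
        if len(frame) == 0:
            logger.warning("outcome stratum %s is empty", code)
    records = []
    for var in data.columns:
        if var == outcome:
            continue
        codes = (
            CODEBOOK[var].domain
            if var in CODEBOOK
            else sorted(int(v) for v in data[var].unique() if v != MISSING)
        )
        for code in codes:
            row: dict[str, object] = {"variable": var, "category": code}
            if var in CODEBOOK:
                row["label"] = CODEBOOK[var].label_of(code)
            for s, frame in strata.items():
                count = int((frame[var] == code).sum())
                row[f"n_mmd{s}"] = count
                row[f"pct_mmd{s}"] = _pct(count, len(frame))
            records.append(row)
    return pd.DataFrame.from_records(records)


def query_report(
    bn: BayesianNetwork,
    queries: Sequence[tuple[str, dict[str, int]]],
) -> pd.DataFrame:
    """Answer posterior queries in order; per-query failures become error rows.

    Evidence is rendered in application order, supporting sequential
    risk-reasoning narratives (grow the evidence set query by query and
    watch the target's posterior move).
    """
    rows = []
    for target, evidence in queries:
        entry: dict[str, object] = {
            "target": target,
            "evidence": "; ".join(f"{k}={v}" for k, v in evidence.items()) or "(none)",
        }
        try:
            post = bn.eliminate_query(target, evidence)
            for code, p in post.as_dict().items():
                entry[f"p_{code}"] = p
            entry["error"] = ""
        except (InferenceError, ValueError, KeyError) as exc:
            entry["error"] = str(exc)
        rows.append(entry)
    return pd.DataFrame.from_records(rows)


def plot_forest(plot_data, path: str | Path) -> None:
    """Render the odds-ratio forest plot to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = plot_data.rows
    fig, ax = plt.subplots(figsize=(6, 0.5 * max(len(rows), 2) + 1))
    ypos = np.arange(len(rows))[::-1]
    ax.errorbar(
        rows["odds_ratio"], ypos,
        xerr=[rows["odds_ratio"] - rows["ci_low"], rows["ci_high"] - rows["odds_ratio"]],
        fmt="s", color="black", capsize=3,
    )
    ax.axvline(plot_data.reference, linestyle=":", color="grey")
    ax.set_yticks(ypos)
    ax.set_yticklabels(rows["variable"])
    ax.set_xlabel("Odds ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class PipelineConfig:
    """Everything a run needs; serialized next to its outputs for replay."""

    output_dir: str = "mmdbn_run"
    input_csv: str | None = None  # None -> simulate a synthetic cohort
    n: int = 20_000
    seed: int = 0
    alpha: float = 0.05
    max_cond: int = 3
    pseudo_count: float = 0.0
    missing_rate: float = 0.0  # applied to simulated data to exercise imputation
    missing_mechanism: str = "MCAR"
    impute_trees: int = 100
    impute_max_iter: int = 10
    queries: list[tuple[str, dict[str, int]]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute the full analysis per config; returns the in-memory artifacts.

    Stage order mirrors the study: impute missing values, fit the logistic
    baseline, learn structure with MMHC, estimate CPTs by maximum
    likelihood, then report marginals and posterior queries.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    sub_seed = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]

    if config.input_csv is not None:
        data = read_dataset(config.input_csv)
        logger.info("loaded %d rows from %s", len(data), config.input_csv)
    else:
        bn_true = charls_like_network()
        data = ancestral_sample(bn_true, config.n, seed=sub_seed[0])
        if config.missing_rate > 0:
            data, _ = inject_missingness(
                data,
                MissingnessSpec(
                    mechanism=config.missing_mechanism,
                    rate=config.missing_rate,
                    driver="age" if config.missing_mechanism == "MAR" else None,
                    seed=sub_seed[1],
                ),
            )
        logger.info("simulated %d rows (seed %d)", len(data), config.seed)
    write_dataset(data, out / "dataset.csv")

    artifacts: dict[str, object] = {"data": data}
    if (data.to_numpy() == MISSING).any():
        imp = rf_impute(
            data,
            max_iter=config.impute_max_iter,
            trees=config.impute_trees,
            seed=sub_seed[2],
        )
        complete = imp.completed
        (out / "imputation.json").write_text(
            json.dumps({"iterations": imp.iterations, "disagreement": imp.disagreement})
        )
        logger.info("imputation converged after %d iteration(s)", imp.iterations)
    else:
        complete = data
    artifacts["complete"] = complete
    write_dataset(complete, out / "dataset_complete.csv")

    summary = table1_summary(complete)
    summary.to_csv(out / "summary.csv", index=False)
    artifacts["summary"] = summary

    predictors = [c for c in complete.columns if c != "mmd"]
    fit = fit_logistic_irls(complete[predictors], complete["mmd"].to_numpy())
    or_table = odds_ratio_table(fit)
    or_table.to_csv(out / "odds_ratios.csv", index=False)
    plot_forest(forest_plot_data(or_table), out / "forest.png")
    artifacts["logistic"] = fit
    artifacts["odds_ratios"] = or_table

    dag, skeleton, trace = mmhc(complete, alpha=config.alpha, max_cond=config.max_cond)
    trace_to_frame(trace).to_csv(out / "search_trace.csv", index=False)
    bn = fit_mle(dag, complete, pseudo_count=config.pseudo_count)
    (out / "network.dot").write_text(serialize.to_dot(bn))
    (out / "network.bif").write_text(serialize.to_bif(bn))
    serialize.cpts_to_frame(bn).to_csv(out / "cpts.csv", index=False)
    artifacts["dag"], artifacts["skeleton"], artifacts["bn"] = dag, skeleton, bn

    marginals = pd.DataFrame(
        [
            {"node": n, "category": code, "probability": p}
            for n, post in bn.prior_marginals().items()
            for code, p in post.as_dict().items()
        ]
    )
    marginals.to_csv(out / "prior_marginals.csv", index=False)
    artifacts["marginals"] = marginals

    if config.queries:
        report = query_report(bn, config.queries)
        report.to_csv(out / "queries.csv", index=False)
        artifacts["queries"] = report
    logger.info("artifacts written to %s", out)
    return artifacts
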