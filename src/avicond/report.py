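"""Pipeline orchestration: run every analysis stage on one input CSV and
export publication-style tables and figures.

Output bundle (all CSVs comma-separated, UTF-8, percents and indices
rounded to 2 d.p. — full precision stays available through the library
API):

* ``coi.csv`` — tidy monthly occurrence index per scope
* ``freq.csv`` — per-cause counts and percent shares
* ``asi.csv`` — adjusted seasonal index per scope and calendar month
* ``groups.csv`` — species-mix group comparison per variable
* ``correlations.csv`` — pairwise Spearman rho with strength grades
* ``tukey.csv`` / ``asi_tests.csv`` — seasonal inference tables
* ``coi.png``, ``asi.png``, ``heatmap.png`` — likeness plots
* ``run.log`` — versions, seed, exclusions, data-quality warnings

Any stage failure aborts the run with a stage-named error and removes the
partial outputs already written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from . import __version__
from .data import (
    DEFAULT_CAUSES,
    CauseDefinition,
    Dataset,
    MonthKey,
    assign_groups,
    flag_exclusions,
    read_dataset,
)
from .errors import AvicondError, InsufficientDataError, PipelineError, UndefinedRateError
from .indices import OVERALL, DEFAULT_SCALE, compute_asi, coi_series, frequency_table
from .inference import compare_groups, month_inference, spearman_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input: Path
    outdir: Path
    exclude: list[MonthKey] = field(default_factory=list)
    causes: tuple[CauseDefinition, ...] = DEFAULT_CAUSES
    denominator_policy: str = "sum_of_causes"
    scale: float = DEFAULT_SCALE
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise AvicondError(f"alpha must be in (0,1), got {self.alpha}")
        if self.scale <= 0:
            raise AvicondError(f"scale must be positive, got {self.scale}")
        self.input = Path(self.input)
        self.outdir = Path(self.outdir)


def _round(df: pd.DataFrame, cols: dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, nd in cols.items():
        if col in out.columns:
            out[col] = out[col].astype(float).round(nd)
    return out


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full analysis on ``cfg.input`` and write the bundle to
    ``cfg.outdir``. Returns a name -> path map of the outputs written."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    log_lines: list[str] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = cfg.outdir / name
        df.to_csv(path, index=False, float_format="%.6f")
        written[name] = path

    stage = "read"
    try:
        ds = read_dataset(cfg.input, causes=cfg.causes)
        ds = flag_exclusions(ds, cfg.exclude)
        log_lines.append(f"input: {cfg.input} ({len(ds.records)} months)")
        log_lines.append(f"excluded: {[str(m) for m in cfg.exclude]}")

        stage = "coi"
        scopes = [OVERALL] + ds.cause_codes()
        coi_rows = []
        series_by_scope = {}
        for scope in scopes:
            s = coi_series(ds, scope, cfg.scale)
            series_by_scope[scope] = s
            for key, v in sorted(s.values.items()):
                coi_rows.append((scope, key.year, key.month, v))
        coi_df = pd.DataFrame(coi_rows, columns=["scope", "year", "month", "value"])
        emit("coi.csv", _round(coi_df, {"value": 2}))

        stage = "freq"
        ft = frequency_table(ds, cfg.denominator_policy)
        emit("freq.csv", _round(ft.table, {"percent": 2}))

        stage = "groups"
        groups = assign_groups(ds)
        group_rows = []
        for variable in [OVERALL] + ds.cause_codes():
            try:
                cmp = compare_groups(ds, variable, groups)
            except InsufficientDataError as exc:
                logger.warning("group comparison skipped: %s", exc)
                log_lines.append(f"group comparison skipped: {exc}")
                continue
            for label, st in (("A", cmp.group_a), ("B", cmp.group_b)):
                group_rows.append(
                    (variable, label, st.n, st.mean, st.sd, st.se,
                     cmp.p_value, cmp.rank_biserial, cmp.point_biserial)
                )
        emit("groups.csv", _round(
            pd.DataFrame(group_rows, columns=[
                "variable", "group", "n", "mean", "sd", "se",
                "p_value", "rank_biserial", "point_biserial",
            ]),
            {"mean": 3, "sd": 3, "se": 3, "p_value": 4,
             "rank_biserial": 3, "point_biserial": 3},
        ))

        stage = "correlate"
        corr_causes = [c.code for c in ds.causes if c.asi_eligible]
        report = spearman_matrix(ds, corr_causes)
        corr_rows = []
        for i, c1 in enumerate(report.causes):
            for c2 in report.causes[i + 1:]:
                corr_rows.append((
                    c1, c2, report.rho.loc[c1, c2], report.p_values.loc[c1, c2],
                    report.strength.loc[c1, c2],
                ))
        emit("correlations.csv", _round(
            pd.DataFrame(corr_rows, columns=["cause_1", "cause_2", "rho", "p_value", "strength"]),
            {"rho": 3, "p_value": 4},
        ))

        stage = "asi"
        asi_scopes = [OVERALL] + corr_causes
        asi_rows, tukey_rows, test_rows = [], [], []
        for scope in asi_scopes:
            try:
                asi = compute_asi(series_by_scope[scope])
            except (UndefinedRateError, InsufficientDataError) as exc:
                logger.warning("ASI skipped for %s: %s", scope, exc)
                log_lines.append(f"ASI skipped for {scope}: {exc}")
                continue
            for m in sorted(asi.asi):
                asi_rows.append((scope, m, asi.asi[m], asi.n_years_per_month[m]))
            inf = month_inference(asi.ratios, scope, alpha=cfg.alpha)
            for _, row in inf.tukey.iterrows():
                tukey_rows.append((scope, *row.tolist()))
            for _, row in inf.vs_one.iterrows():
                test_rows.append((scope, *row.tolist()))
        emit("asi.csv", _round(
            pd.DataFrame(asi_rows, columns=["scope", "month", "asi", "n_years"]),
            {"asi": 2},
        ))
        emit("tukey.csv", _round(
            pd.DataFrame(tukey_rows, columns=[
                "scope", "month_1", "month_2", "estimate", "p_adj",
                "lower", "upper", "reject",
            ]),
            {"estimate": 4, "p_adj": 4, "lower": 4, "upper": 4},
        ))
        emit("asi_tests.csv", _round(
            pd.DataFrame(test_rows, columns=["scope", "month", "n", "mean", "t", "p_value"]),
            {"mean": 4, "t": 3, "p_value": 4},
        ))

        stage = "plots"
        written.update(_plots(cfg, series_by_scope, report,
                              pd.DataFrame(asi_rows, columns=["scope", "month", "asi", "n_years"])))

        stage = "log"
        import scipy
        import statsmodels
        log_lines[:0] = [
            f"avicond {__version__}",
            f"numpy {np.__version__}, pandas {pd.__version__}, "
            f"scipy {scipy.__version__}, statsmodels {statsmodels.__version__}",
            f"seed: {cfg.seed}",
            f"alpha: {cfg.alpha}, scale: {cfg.scale}, "
            f"denominator: {cfg.denominator_policy}",
        ]
        log_path = cfg.outdir / "run.log"
        log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        written["run.log"] = log_path
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    return written


def _plots(cfg: RunConfig, series_by_scope, corr_report, asi_df) -> dict[str, Path]:
    out: dict[str, Path] = {}

    overall = series_by_scope[OVERALL]
    keys = sorted(overall.values)
    x = [k.year + (k.month - 1) / 12 for k in keys]
    y = [overall.values[k] for k in keys]
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(x, y, marker="o", ms=2.5, lw=1, label="monthly COI")
    if len(x) > 2:
        coef = np.polyfit(x, y, 1)
        ax.plot(x, np.polyval(coef, x), "r--", lw=1.2, label="linear trend")
    ax.set_xlabel("year")
    ax.set_ylabel(f"condemnations per {cfg.scale:,.0f} head")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = cfg.outdir / "coi.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    out["coi.png"] = path

    scopes = asi_df["scope"].unique()
    if len(scopes):
        ncol = 2
        nrow = int(np.ceil(len(scopes) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(9, 2.4 * nrow), squeeze=False)
        for ax, scope in zip(axes.flat, scopes):
            sub = asi_df[asi_df["scope"] == scope]
            ax.bar(sub["month"], sub["asi"], color="#4878a8")
            ax.axhline(1.0, color="k", lw=0.8, ls=":")
            ax.set_title(scope, fontsize=9)
            ax.set_xticks(range(1, 13))
        for ax in axes.flat[len(scopes):]:
            ax.axis("off")
        fig.supylabel("adjusted seasonal index")
        fig.tight_layout()
        path = cfg.outdir / "asi.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        out["asi.png"] = path

    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    sns.heatmap(corr_report.rho, vmin=-1, vmax=1, cmap="vlag", annot=True,
                fmt=".2f", ax=ax, cbar_kws={"label": "Spearman rho"})
    fig.tight_layout()
    path = cfg.outdir / "heatmap.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    out["heatmap.png"] = path
    return out
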