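"""End-to-end orchestration: quantify, fit, detect, report.

``run_pipeline`` takes a study configuration pointing at either a raw Ct
table or an already-quantified expression table and produces, per
tissue x gene panel: the rhythm-parameter table (mesor/amplitude/acrophase
with SEs and the 99% amplitude CI), the rhythm-decision table (ANOVA p,
cosinor zero-amplitude p, SNK letters, verdict), optional per-panel plots
(group mean +/- SEM by ZT, dark-phase shading, feeding arrow, dashed
fitted sinusoid only for rhythmic panels), and a machine-readable run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cosinor import CosinorFit, fit_cosinor
from .design import (
    ALPHA_ANOVA,
    ALPHA_COSINOR,
    AMPLITUDE_CI_LEVEL,
    DARK_ONSET_ZT,
    FEEDING_ZT,
    REFERENCE_GENES,
)
from .io import read_ct_table, read_expression_table, write_expression_table
from .qpcr import QuantConfig, RelativeExpressionTable, relative_expression
from .rhythm import RhythmDecision, detect_rhythm

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


@dataclass
class StudyConfig:
    """Configuration of one pipeline run.

    Exactly one of ``ct_table`` / ``expression_table`` must be set.
    ``lights_on_zt``/``dark_onset_zt``/``feeding_zt`` are annotations used
    only for plotting.
    """

    ct_table: str | None = None
    expression_table: str | None = None
    reference_genes: tuple[str, ...] = REFERENCE_GENES
    ref_aggregation: str = "geometric_mean_expression"
    alpha_anova: float = ALPHA_ANOVA
    alpha_cosinor: float = ALPHA_COSINOR
    ci_level: float = AMPLITUDE_CI_LEVEL
    lights_on_zt: float = 0.0
    dark_onset_zt: float = DARK_ONSET_ZT
    feeding_zt: float = FEEDING_ZT
    out_dir: str = "results"
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        if (self.ct_table is None) == (self.expression_table is None):
            raise PipelineError(
                "config: exactly one of ct_table / expression_table must be given"
            )
        for name in ("alpha_anova", "alpha_cosinor", "ci_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise PipelineError(f"config: {name} must be in (0, 1), got {v}")
        self.reference_genes = tuple(self.reference_genes)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise PipelineError(f"config: {path} is not a key/value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)} in {path}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class PipelineResult:
    """Outputs of one run: tables, per-panel decisions, artifact paths."""

    parameters: pd.DataFrame
    decisions: pd.DataFrame
    decision_objects: list[RhythmDecision]
    fits: dict[tuple[str, str], CosinorFit]
    expression: pd.DataFrame
    quantification: RelativeExpressionTable | None
    paths: dict[str, str] = field(default_factory=dict)


def _letters_string(decision: RhythmDecision) -> str:
    if decision.snk is None:
        return ""
    return ";".join(f"ZT{zt:g}:{letter}" for zt, letter in sorted(decision.snk.letters.items()))


def analyze_expression(
    expression: pd.DataFrame,
    alpha_anova: float = ALPHA_ANOVA,
    alpha_cosinor: float = ALPHA_COSINOR,
    ci_level: float = AMPLITUDE_CI_LEVEL,
) -> tuple[pd.DataFrame, pd.DataFrame, list[RhythmDecision], dict[tuple[str, str], CosinorFit]]:
    """Fit the cosinor and apply the dual rhythm criterion per panel.

    Returns the rhythm-parameter table, the decision table, the decision
    objects, and the fits, with every (tissue, gene) in the input
    appearing exactly once.
    """
    param_rows, decision_rows, decisions, fits = [], [], [], {}
    for (tissue, gene), panel in expression.groupby(["tissue", "gene"], sort=True):
        t = panel["zt_h"].to_numpy(dtype=float)
        y = panel["rq"].to_numpy(dtype=float)
        try:
            fit = fit_cosinor(t, y, ci_level=ci_level)
            groups = {
                float(zt): sub["rq"].to_numpy(dtype=float)
                for zt, sub in panel.groupby("zt_h")
            }
            decision = detect_rhythm(
                tissue, gene, groups, fit,
                alpha_anova=alpha_anova, alpha_cosinor=alpha_cosinor,
            )
        except ValueError as exc:
            raise PipelineError(f"analysis stage ({tissue}, {gene}): {exc}") from exc
        fits[(tissue, gene)] = fit
        decisions.append(decision)
        param_rows.append(
            {
                "tissue": tissue,
                "gene": gene,
                "n": fit.n,
                "mesor": fit.mesor,
                "se_mesor": fit.se_mesor,
                "amplitude": fit.amplitude,
                "se_amplitude": fit.se_amplitude,
                "amplitude_ci_low": fit.amplitude_ci[0],
                "amplitude_ci_high": fit.amplitude_ci[1],
                "ci_level": fit.ci_level,
                "acrophase_h": fit.acrophase_h,
                "se_acrophase_h": fit.se_acrophase_h,
                "rss": fit.rss,
            }
        )
        decision_rows.append(
            {
                "tissue": tissue,
                "gene": gene,
                "anova_f": decision.anova.f,
                "anova_p": decision.anova.p,
                "cosinor_f": fit.f_zero_amplitude,
                "cosinor_p": fit.p_zero_amplitude,
                "snk_letters": _letters_string(decision),
                "is_rhythmic": decision.is_rhythmic,
            }
        )
    parameters = pd.DataFrame(param_rows)
    table = pd.DataFrame(decision_rows)
    return parameters, table, decisions, fits


def _plot_panel(ax, panel: pd.DataFrame, fit: CosinorFit, decision: RhythmDecision, config: StudyConfig):
    stats_by_zt = panel.groupby("zt_h")["rq"].agg(["mean", "sem"])
    zts = stats_by_zt.index.to_numpy(dtype=float)
    ax.axvspan(config.dark_onset_zt, 24.0, color="0.85", zorder=0)
    ax.errorbar(
        zts, stats_by_zt["mean"], yerr=stats_by_zt["sem"],
        fmt="o", color="black", capsize=3, zorder=3,
    )
    if decision.snk is not None:
        top = (stats_by_zt["mean"] + stats_by_zt["sem"].fillna(0.0)).to_numpy()
        for zt, y in zip(zts, top):
            ax.annotate(
                decision.snk.letters[float(zt)], (zt, y),
                textcoords="offset points", xytext=(0, 6), ha="center", fontsize=8,
            )
    if decision.is_rhythmic:
        tt = np.linspace(0.0, 24.0, 241)
        ax.plot(tt, fit.predict(tt), "k--", lw=1, zorder=2)
    ymax = ax.get_ylim()[1]
    ax.annotate(
        "", xy=(config.feeding_zt, 0.0), xytext=(config.feeding_zt, 0.12 * ymax),
        arrowprops=dict(arrowstyle="-|>", color="black"),
        annotation_clip=False,
    )
    ax.set_xticks(np.arange(0, 25, 4))
    ax.set_xlim(-0.8, 24.8)
    ax.set_xlabel("ZT (h)")
    ax.set_ylabel("Relative expression")
    ax.set_title(f"{decision.tissue} - {decision.gene}", fontsize=9)


def _write_plots(expression: pd.DataFrame, result_fits, decisions, config: StudyConfig, out: Path) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = out / "figures"
    plot_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for decision in decisions:
        panel = expression[
            (expression["tissue"] == decision.tissue) & (expression["gene"] == decision.gene)
        ]
        fig, ax = plt.subplots(figsize=(4.2, 3.0), layout="constrained")
        _plot_panel(ax, panel, result_fits[(decision.tissue, decision.gene)], decision, config)
        path = plot_dir / f"{decision.tissue}_{decision.gene}.png".replace("/", "-")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(str(path))
    return paths


def run_pipeline(config: StudyConfig) -> PipelineResult:
    """Run quantification (if starting from Ct), rhythm analysis, reporting."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    quant: RelativeExpressionTable | None = None
    if config.ct_table is not None:
        try:
            cts = read_ct_table(config.ct_table)
        except ValueError as exc:
            raise PipelineError(f"input stage: {exc}") from exc
        qc = QuantConfig(
            reference_genes=tuple(config.reference_genes),
            ref_aggregation=config.ref_aggregation,
        )
        try:
            quant = relative_expression(cts, qc)
        except ValueError as exc:
            raise PipelineError(f"quantification stage: {exc}") from exc
        expression = quant.records
    else:
        try:
            expression = read_expression_table(config.expression_table)
        except ValueError as exc:
            raise PipelineError(f"input stage: {exc}") from exc

    parameters, table, decisions, fits = analyze_expression(
        expression,
        alpha_anova=config.alpha_anova,
        alpha_cosinor=config.alpha_cosinor,
        ci_level=config.ci_level,
    )

    paths: dict[str, str] = {}
    params_path = out / "rhythm_parameters.csv"
    parameters.to_csv(params_path, index=False)
    paths["parameters"] = str(params_path)
    dec_path = out / "rhythm_decisions.csv"
    table.to_csv(dec_path, index=False)
    paths["decisions"] = str(dec_path)
    if quant is not None:
        expr_path = out / "relative_expression.csv"
        write_expression_table(expression, expr_path)
        paths["expression"] = str(expr_path)
        cal_path = out / "calibration_log.csv"
        quant.calibration_log.to_csv(cal_path, index=False)
        paths["calibration_log"] = str(cal_path)
    if config.make_plots:
        paths["figures"] = json.dumps(
            _write_plots(expression, fits, decisions, config, out)
        )

    log = {
        "package_version": __version__,
        "versions": _library_versions(),
        "seed": config.seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "calibrators": (
            {f"{t}|{g}": zt for (t, g), zt in quant.calibrators.items()} if quant else None
        ),
        "quant_method": quant.method if quant else None,
        "decisions": [
            {
                "tissue": d.tissue,
                "gene": d.gene,
                "is_rhythmic": d.is_rhythmic,
                "snk_run": d.snk is not None,
                "perfect_fit": d.cosinor.perfect_fit,
            }
            for d in decisions
        ],
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, default=str), encoding="utf-8")
    paths["run_log"] = str(log_path)

    return PipelineResult(
        parameters=parameters,
        decisions=table,
        decision_objects=decisions,
        fits=fits,
        expression=expression,
        quantification=quant,
        paths=paths,
    )


def _library_versions() -> dict[str, str]:
    import scipy

    return {"numpy": np.__version__, "scipy": scipy.__version__, "pandas": pd.__version__}
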