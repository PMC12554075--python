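"""End-to-end pipeline: simulate/load -> entropy metrics -> comparisons -> report.

`analyze` computes one entropy spectrum per trace (per temporal scale),
`compare` runs the configured paired condition contrasts on the
experiment-level metric values, and `report` renders a plain-text summary.
All stages are deterministic given the input data, the configuration and the
seed, and every skipped trace is recorded with its reason.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .renyi import ALPHA_GRID, EntropySpectrum, KdeParams, coarse_grain, renyi_spectrum
from .sampen import DegenerateInputError, SampEnParams, SeriesTooShortError
from .stats import ConditionComparison, compare_with_ci, summarize
from .traces import ExperimentSet, metrics_to_frame

logger = logging.getLogger("bretropy")

#: metric slices reported by default: SampEn plus normalized entropy at the
#: Shannon order, a deep negative order (rare states) and the min-entropy.
DEFAULT_METRICS: tuple[tuple[str, float], ...] = (
    ("sampen", math.nan),
    ("H_norm", 1.0),
    ("H_norm", -5.0),
    ("H_norm", math.inf),
)


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis knobs in one place.

    ``segment`` picks the part of each trace the entropies are computed on
    (post-stimulation by default — the ligand-response dynamics); ``tau_list``
    the temporal coarse-graining scales (1 = no coarse-graining);
    ``comparisons`` the ordered condition pairs to contrast.
    """

    segment: str = "post_stim"
    sampen: SampEnParams = field(default_factory=SampEnParams)
    kde: KdeParams = field(default_factory=KdeParams)
    alpha_grid: tuple[float, ...] = ALPHA_GRID
    tau_list: tuple[int, ...] = (1,)
    comparisons: tuple[tuple[str, str], ...] = ()
    metrics: tuple[tuple[str, float], ...] = DEFAULT_METRICS
    n_boot: int = 1000
    seed: int = 0
    # False: entropy per well, then averaged (richer variance structure);
    # True: wells averaged into one mean trace per experiment first.
    average_wells: bool = False

    def __post_init__(self) -> None:
        if self.segment not in ("post_stim", "full", "baseline"):
            raise ValueError(f"unknown segment {self.segment!r}")
        if any(t < 1 for t in self.tau_list):
            raise ValueError("tau scales must be >= 1")


DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("AngII", "AngII+LVV-H7"),
    ("AngII", "LVV-H7"),
    ("LVV-H7", "AngII+LVV-H7"),
)


def analysis_config_from_dict(d: dict) -> AnalysisConfig:
    d = dict(d)
    if "sampen" in d:
        d["sampen"] = SampEnParams(**d["sampen"])
    if "kde" in d:
        d["kde"] = KdeParams(**d["kde"])
    if "comparisons" in d:
        d["comparisons"] = tuple(tuple(pair) for pair in d["comparisons"])
    if "tau_list" in d:
        d["tau_list"] = tuple(d["tau_list"])
    if "metrics" in d:

        def _alpha(a) -> float:
            if a in (None, "nan"):
                return math.nan
            if a == "inf":
                return math.inf
            return float(a)

        d["metrics"] = tuple((name, _alpha(a)) for name, a in (tuple(mv) for mv in d["metrics"]))
    return AnalysisConfig(**d)


def load_analysis_config(path: str | Path, seed: int | None = None) -> AnalysisConfig:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh) or {}
    cfg = analysis_config_from_dict(d.get("analysis", d))
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg


def analyze(
    exp_set: ExperimentSet, config: AnalysisConfig = AnalysisConfig()
) -> tuple[list[EntropySpectrum], list[dict]]:
    """One entropy spectrum per (trace, tau); returns (spectra, skip log).

    Traces whose selected segment is degenerate (zero variance, too short
    for the scale) are skipped, each with a logged reason; a run where every
    trace is skipped is an error.
    """
    spectra: list[EntropySpectrum] = []
    skipped: list[dict] = []
    traces = _average_wells(exp_set) if config.average_wells else exp_set.traces
    for trace in traces:
        segment = trace.segment(config.segment)
        for tau in config.tau_list:
            try:
                series = coarse_grain(segment, tau)
                with warnings.catch_warnings():
                    warnings.simplefilter("error", RuntimeWarning)
                    spec = renyi_spectrum(
                        series,
                        kde=config.kde,
                        sampen_params=config.sampen,
                        alpha_grid=config.alpha_grid,
                        experiment_id=trace.experiment_id,
                        well_id=trace.well_id,
                        condition=trace.condition,
                        tau=tau,
                    )
            except (DegenerateInputError, SeriesTooShortError, ValueError, RuntimeWarning) as e:
                entry = {
                    "experiment_id": trace.experiment_id,
                    "well_id": trace.well_id,
                    "condition": trace.condition,
                    "tau": tau,
                    "reason": str(e),
                }
                skipped.append(entry)
                logger.warning("skipping trace %s: %s", trace.key, e)
                continue
            spectra.append(spec)
    if not spectra:
        raise RuntimeError("no analyzable traces (all skipped); see skip log")
    return spectra, skipped


def _average_wells(exp_set: ExperimentSet) -> list:
    """One mean trace per (experiment, condition), averaging replicate wells."""
    from .traces import KineticTrace

    groups: dict[tuple[str, str], list] = {}
    for t in exp_set.traces:
        groups.setdefault((t.experiment_id, t.condition), []).append(t)
    out = []
    for (exp, cond), members in groups.items():
        ref = members[0]
        if any(not np.array_equal(m.times, ref.times) for m in members[1:]):
            raise ValueError(f"wells of ({exp}, {cond}) do not share a time grid")
        out.append(
            KineticTrace(
                experiment_id=exp,
                well_id="mean",
                condition=cond,
                times=ref.times,
                values=np.mean([m.values for m in members], axis=0),
                stim_time=ref.stim_time,
            )
        )
    return out


def experiment_level_metric(
    metrics: pd.DataFrame, metric: str, alpha: float, condition: str, tau: int = 1
) -> pd.Series:
    """Average a metric over wells within each experiment for one condition."""
    sel = (
        (metrics["metric"] == metric)
        & (metrics["condition"] == condition)
        & (metrics["tau"] == tau)
    )
    if metric != "sampen":
        if math.isnan(alpha):
            raise ValueError(f"metric {metric} needs an alpha value")
        sel &= metrics["alpha"] == alpha
    sub = metrics[sel].dropna(subset=["value"])
    return sub.groupby("experiment_id", sort=False)["value"].mean()


def compare(
    spectra: Sequence[EntropySpectrum] | pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[ConditionComparison]:
    """Run every configured (condition pair x metric) paired comparison.

    Pairing unit is the independent experiment (well values averaged first).
    Comparison seeds derive from ``config.seed`` so a rerun is identical.
    """
    metrics = spectra if isinstance(spectra, pd.DataFrame) else metrics_to_frame(spectra)
    pairs = config.comparisons or DEFAULT_COMPARISONS
    available = set(metrics["condition"])
    results: list[ConditionComparison] = []
    for i, (cond_a, cond_b) in enumerate(pairs):
        for j, (metric, alpha) in enumerate(config.metrics):
            for cond in (cond_a, cond_b):
                if cond not in available:
                    raise ValueError(f"condition {cond!r} not present in metrics table")
            xa = experiment_level_metric(metrics, metric, alpha, cond_a)
            xb = experiment_level_metric(metrics, metric, alpha, cond_b)
            common = xa.index.intersection(xb.index)
            label = metric if metric == "sampen" else f"{metric}[alpha={_fmt_alpha(alpha)}]"
            results.append(
                compare_with_ci(
                    xa.loc[common].to_numpy(),
                    xb.loc[common].to_numpy(),
                    metric=label,
                    condition_a=cond_a,
                    condition_b=cond_b,
                    n_boot=config.n_boot,
                    seed=int(
                        np.random.SeedSequence(config.seed, spawn_key=(i, j)).generate_state(1)[0]
                        % (2**31)
                    ),
                )
            )
    return results


def _fmt_alpha(alpha: float) -> str:
    if math.isinf(alpha):
        return "inf"
    return str(int(alpha)) if float(alpha).is_integer() else str(alpha)


def report(
    spectra: Sequence[EntropySpectrum],
    comparisons: Sequence[ConditionComparison],
    path: str | Path | None = None,
    skipped: Sequence[dict] = (),
) -> str:
    """Plain-text/Markdown summary: mean +/- SEM per condition + comparisons."""
    metrics = metrics_to_frame(spectra)
    key_rows = metrics[
        (metrics["metric"] == "sampen")
        | ((metrics["metric"] == "H_norm") & metrics["alpha"].isin([1.0, -5.0, math.inf]))
    ].copy()
    summary = summarize(key_rows)
    lines = ["# Entropy analysis report", ""]
    lines.append(f"Traces analyzed: {metrics[['experiment_id','well_id','condition','tau']].drop_duplicates().shape[0]}"
                 f" (skipped: {len(skipped)})")
    lines.append("")
    lines.append("## Condition means (mean ± SEM across experiments)")
    lines.append("")
    lines.append("| condition | metric | alpha | tau | mean | SEM | n |")
    lines.append("|---|---|---|---|---|---|---|")
    for _, r in summary.iterrows():
        alpha = "" if math.isnan(r["alpha"]) else _fmt_alpha(r["alpha"])
        sem = "n/a" if pd.isna(r["sem"]) else f"{r['sem']:.4g}"
        lines.append(
            f"| {r['condition']} | {r['metric']} | {alpha} | {int(r['tau'])} "
            f"| {r['mean']:.4g} | {sem} | {int(r['n_experiments'])} |"
        )
    if comparisons:
        lines.append("")
        lines.append("## Paired comparisons (paired t, percentile bootstrap 95% CI)")
        lines.append("")
        lines.append("| metric | A | B | n | mean diff | t | df | p | 95% CI |")
        lines.append("|---|---|---|---|---|---|---|---|---|")
        for c in comparisons:
            lines.append(
                f"| {c.metric} | {c.condition_a} | {c.condition_b} | {c.n} "
                f"| {c.mean_diff:.4g} | {c.t_stat:.4g} | {c.df} | {c.p_value:.4g} "
                f"| [{c.ci_low:.4g}, {c.ci_high:.4g}] |"
            )
    if skipped:
        lines.append("")
        lines.append("## Skipped traces")
        lines.append("")
        for s in skipped:
            lines.append(
                f"- ({s['experiment_id']}, {s['well_id']}, {s['condition']}, tau={s['tau']}): "
                f"{s['reason']}"
            )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(text, encoding="utf-8")
    return text


def run(
    exp_set: ExperimentSet, config: AnalysisConfig = AnalysisConfig()
) -> tuple[list[EntropySpectrum], list[ConditionComparison], str]:
    """analyze -> compare -> report in one call (the `run` pipeline stage)."""
    spectra, skipped = analyze(exp_set, config)
    pairs = config.comparisons or tuple(
        p for p in DEFAULT_COMPARISONS
        if p[0] in exp_set.conditions and p[1] in exp_set.conditions
    )
    comparisons = compare(spectra, replace(config, comparisons=pairs)) if pairs else []
    text = report(spectra, comparisons, skipped=skipped)
    return spectra, comparisons, text
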