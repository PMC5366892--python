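"""End-to-end analysis pipeline.

Stages are strictly separated:

1. ``simulate`` (or external data) -> long-format community CSV,
2. ``compute_stability_table`` -> one StabilityRecord per microcosm and
   trophic component (CV, stability, synchrony, asynchrony, dominance,
   richness),
3. ``run_figures_analysis`` -> treatment ANOVAs with Tukey letters and the
   stability-mechanism correlations, as one machine-readable report.

Stage 3 only ever sees the metrics table, never raw densities, so the same
report is obtained from a metrics CSV regardless of where it came from.
All floats are serialised with 12 significant digits so reruns at a fixed
seed are byte-identical.
"""

from __future__ import annotations

import json
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import inference, stability_metrics as sm
from .domain_model import (
    CommunityTimeSeries,
    StabilityRecord,
    Treatment,
    TrophicGroup,
    subset_by_trophic,
)

__all__ = [
    "compute_stability_table",
    "records_to_frame",
    "write_metrics_csv",
    "read_metrics_csv",
    "run_figures_analysis",
    "validate_report",
    "report_to_text",
]

METRIC_COLUMNS = [
    "microcosm_id",
    "treatment",
    "trophic_subset",
    "temporal_variability",
    "temporal_stability",
    "synchrony",
    "asynchrony",
    "dominance",
    "dominant_species",
    "dominant_species_variability",
    "richness",
    "flags",
]


def _record_for_subset(series: CommunityTimeSeries, subset: str,
                       residents_only: bool) -> StabilityRecord:
    sub = subset_by_trophic(series, subset)
    if residents_only:
        sub = sub.residents_only()

    flags: list[str] = []
    cv = stability = None
    try:
        cv = sm.temporal_variability(sub.total_density())
        stability = 1.0 / cv if cv > 0 else None
        if cv == 0:
            flags.append("constant-total:infinite-stability")
    except sm.UndefinedMetricError as e:
        flags.append(f"variability:{e}")

    phi = asyn = None
    try:
        phi = sm.synchrony(sub)
        asyn = 1.0 - phi
    except sm.UndefinedMetricError as e:
        flags.append(f"synchrony:{e}")

    dom = dom_sp = dom_cv = None
    try:
        dom, dom_sp = sm.dominance(sub, "auto")
        dom_cv = sm.population_variability(sub)[dom_sp]
    except sm.UndefinedMetricError as e:
        flags.append(f"dominance:{e}")

    return StabilityRecord(
        microcosm_id=series.microcosm_id,
        treatment=series.treatment,
        trophic_subset=subset,
        temporal_variability=cv,
        temporal_stability=stability,
        synchrony=phi,
        asynchrony=asyn,
        dominance=dom,
        dominant_species=dom_sp,
        dominant_species_variability=dom_cv,
        richness=sm.richness(sub, residents_only=True),
        flags=";".join(flags),
    )


def compute_stability_table(
    series: Iterable[CommunityTimeSeries],
    subsets: Sequence[str] = ("alga", "protozoan"),
    residents_only: bool = False,
) -> list[StabilityRecord]:
    """Derive stability metrics per microcosm and trophic component.

    By default every counted protist (residents and established invaders)
    contributes to totals, synchrony and dominance — invaders are part of
    the censused community — while richness always counts residents only.
    Pass ``residents_only=True`` to drop invaders from all metrics.
    Metric failures are recorded in the ``flags`` field, never dropped.
    """
    series = list(series)
    if not series:
        raise ValueError("need at least one community time series")
    return [_record_for_subset(s, subset, residents_only) for s in series for subset in subsets]


def records_to_frame(records: Sequence[StabilityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "microcosm_id": r.microcosm_id,
                "treatment": r.treatment.value,
                "trophic_subset": r.trophic_subset,
                "temporal_variability": r.temporal_variability,
                "temporal_stability": r.temporal_stability,
                "synchrony": r.synchrony,
                "asynchrony": r.asynchrony,
                "dominance": r.dominance,
                "dominant_species": r.dominant_species,
                "dominant_species_variability": r.dominant_species_variability,
                "richness": r.richness,
                "flags": r.flags,
            }
        )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def write_metrics_csv(records: Sequence[StabilityRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.12g")


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"microcosm_id": str})
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics table missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# figure-level analysis
# ---------------------------------------------------------------------------


def _anova_block(df: pd.DataFrame, response: str, alpha: float, hc_type: str,
                 robust_posthoc: bool) -> dict:
    sub = df.dropna(subset=[response])
    values = sub[response].to_numpy(dtype=float)
    groups = sub["treatment"].to_numpy()
    try:
        res = inference.hc_anova(values, groups, hc_type=hc_type)
    except ValueError as e:
        return {"error": str(e)}
    if robust_posthoc:
        pw = inference.robust_pairwise(values, groups, alpha=alpha, hc_type=hc_type)
    else:
        pw = inference.tukey_hsd(values, groups, alpha=alpha)
    res.letters = pw.letters
    block = res.to_dict()
    block["pairwise"] = pw.table.to_dict(orient="records")
    block["posthoc_method"] = pw.method
    return block


def _correlation_block(df: pd.DataFrame, xcol: str, ycol: str) -> dict:
    sub = df.dropna(subset=[xcol, ycol])
    try:
        r, p = inference.pearson_correlation(sub[xcol].to_numpy(float), sub[ycol].to_numpy(float))
        return {"x": xcol, "y": ycol, "r": r, "p_value": p, "n": int(len(sub))}
    except ValueError as e:
        return {"x": xcol, "y": ycol, "error": str(e), "n": int(len(sub))}


def run_figures_analysis(table: pd.DataFrame, alpha: float = 0.05,
                         hc_type: str = "HC3", robust_posthoc: bool = False) -> dict:
    """Treatment effects and stabilising-mechanism correlations.

    Per trophic component: a robust (sandwich) one-way ANOVA with Tukey
    letters on temporal variability and on resident richness, then Pearson
    correlations of (asynchrony vs variability), (dominant-species
    stability vs community stability) and (dominance vs community
    stability), pooling all microcosms across treatments.
    """
    if isinstance(table, list):
        table = records_to_frame(table)
    if table["treatment"].nunique() < 2:
        raise ValueError("need at least 2 treatments for the analysis")

    report: dict = {"alpha": alpha, "hc_type": hc_type, "trophic_groups": {}}
    for subset, df in table.groupby("trophic_subset"):
        df = df.copy()
        df["dominant_species_stability"] = [
            (1.0 / v if v is not None and np.isfinite(v) and v > 0 else np.nan)
            for v in df["dominant_species_variability"]
        ]
        block = {
            "n_microcosms": int(df["microcosm_id"].nunique()),
            "anova": {
                "temporal_variability": _anova_block(
                    df, "temporal_variability", alpha, hc_type, robust_posthoc
                ),
                "richness": _anova_block(df, "richness", alpha, hc_type, robust_posthoc),
            },
            "correlations": {
                "asynchrony_vs_variability": _correlation_block(
                    df, "asynchrony", "temporal_variability"
                ),
                "dominant_stability_vs_community_stability": _correlation_block(
                    df, "dominant_species_stability", "temporal_stability"
                ),
                "dominance_vs_community_stability": _correlation_block(
                    df, "dominance", "temporal_stability"
                ),
            },
        }
        report["trophic_groups"][subset] = block
    return report


# ---------------------------------------------------------------------------
# report serialisation
# ---------------------------------------------------------------------------


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if not math.isfinite(x):
            return repr(x)
        return float(f"{x:.{sig}g}")
    return obj


def report_to_json(report: dict, path=None) -> str:
    text = json.dumps(_round_floats(report), indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


_ANOVA_KEYS = {"F", "df_num", "df_den", "p_value", "robust", "hc_type", "group_means",
               "F_classical", "p_classical", "degenerate", "letters", "pairwise",
               "posthoc_method"}
_CORR_KEYS = {"asynchrony_vs_variability", "dominant_stability_vs_community_stability",
              "dominance_vs_community_stability"}


def validate_report(report: dict) -> None:
    """Check a figures-analysis report against the shipped structure.

    Raises ValueError with the offending path on the first violation.
    """
    for key in ("alpha", "hc_type", "trophic_groups"):
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
    for name, block in report["trophic_groups"].items():
        for key in ("n_microcosms", "anova", "correlations"):
            if key not in block:
                raise ValueError(f"trophic_groups.{name} missing {key!r}")
        for resp, ab in block["anova"].items():
            if "error" in ab:
                continue
            missing = _ANOVA_KEYS - set(ab)
            if missing:
                raise ValueError(f"trophic_groups.{name}.anova.{resp} missing {sorted(missing)}")
        missing = _CORR_KEYS - set(block["correlations"])
        if missing:
            raise ValueError(f"trophic_groups.{name}.correlations missing {sorted(missing)}")
        for cname, cb in block["correlations"].items():
            if "error" not in cb and not (-1 - 1e-9 <= cb["r"] <= 1 + 1e-9):
                raise ValueError(f"trophic_groups.{name}.correlations.{cname}: r out of range")


def report_to_text(report: dict) -> str:
    """Human-readable summary mirroring the omnibus-F / letters / correlation layout."""
    lines = [f"Stability analysis report (alpha={report['alpha']}, sandwich={report['hc_type']})", ""]
    for name, block in sorted(report["trophic_groups"].items()):
        lines.append(f"== {name} component ({block['n_microcosms']} microcosms) ==")
        for resp, ab in block["anova"].items():
            if "error" in ab:
                lines.append(f"  {resp}: ANOVA unavailable ({ab['error']})")
                continue
            lines.append(
                f"  {resp}: robust F_{ab['df_num']},{ab['df_den']} = {ab['F']:.2f}"
                f" (p = {ab['p_value']:.4g}); classical F = {ab['F_classical']:.2f}"
                f" (p = {ab['p_classical']:.4g})"
            )
            letters = ab["letters"] or {}
            means = ab["group_means"]
            per_group = ", ".join(
                f"{g}: {means[g]:.3g} '{letters.get(g, '?')}'" for g in sorted(means)
            )
            lines.append(f"    means/letters: {per_group}")
        for cname, cb in block["correlations"].items():
            if "error" in cb:
                lines.append(f"  {cname}: unavailable ({cb['error']})")
            else:
                lines.append(
                    f"  {cname}: r = {cb['r']:.3f} (p = {cb['p_value']:.4g}, n = {cb['n']})"
                )
        lines.append("")
    return "\n".join(lines)
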