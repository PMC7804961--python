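"""End-to-end analyses: free-hand PRE/POST, tool-use FIRST/LAST, arm-length
estimation and gesture imitation, from extracted trial tables to reports.

Each analysis follows the same recipe: a PCA meta-parameter over the nine
kinematic parameters decides (by ML likelihood ratio) between the linear and
quadratic puberty basis; the selected basis is then used for every
per-parameter random-intercept mixed model, Type III Wald tables, and the
crossing-point / interval-of-equivalence procedure.  Component-wise global
p-values come from the Wald tests on each component's own first-PC
meta-parameter model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import reference
from .crossing import CrossingResult, aggregate_crossings, crossing_and_equivalence, \
    predict_condition_curves
from .lmm import ModelFit, fit_lmm, imitation_regression, lrt_poly_vs_linear, \
    pca_meta, wald_type3
from .simulate import pivot_trials

log = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_freehand_analysis",
    "run_tooluse_analysis",
    "run_armlength_analysis",
    "run_imitation_analysis",
    "reproduce_study",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable settings for one analysis run, echoed into every report."""

    alpha: float = 0.05
    grid_lo: float = 5.0
    grid_hi: float = 20.0
    grid_step: float = 0.01
    degree: str | int = "auto"   # "auto": LRT on the meta-parameter decides
    orientation_reference: str = "vel_amplitude"
    holm: bool = False           # Holm-adjust interaction p across parameters
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.grid_step <= 0 or self.grid_hi <= self.grid_lo:
            raise ValueError("invalid grid settings")
        if self.degree not in ("auto", 1, 2):
            raise ValueError("degree must be 'auto', 1 or 2")


def _crossing_entry(result: CrossingResult, interaction_p: float,
                    alpha: float) -> dict:
    return {
        "crossing_point": result.crossing_point,
        "equivalence_interval": result.equivalence_interval,
        "equivalence_interval_int": result.interval_as_integers(),
        "no_reversal": result.no_reversal,
        "reliable": bool(interaction_p < alpha) and not result.no_reversal,
        "interaction_p": float(interaction_p),
    }


@dataclass
class AnalysisReport:
    """Structured results of one analysis, serialisable to JSON."""

    variant: str
    degree_selected: int
    lrt: dict
    meta: dict
    per_parameter: dict
    components: dict
    aggregate: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None, indent: int = 1) -> str:
        text = json.dumps(self.to_dict(), indent=indent, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text

    def content_hash(self) -> str:
        """Hash of the report contents, excluding volatile provenance."""
        payload = self.to_dict()
        payload.get("provenance", {}).pop("timestamp", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=_jsonify).encode()
        ).hexdigest()

    def crossing_table(self) -> pd.DataFrame:
        """Table-style summary: one row per parameter plus overall rows."""
        rows = []
        for name, entry in self.per_parameter.items():
            cp = entry["crossing"]["crossing_point"]
            iv = entry["crossing"]["equivalence_interval_int"]
            rows.append((name, cp, iv[0] if iv else None, iv[1] if iv else None))
        agg = self.aggregate
        rows.append(("Average", agg.get("mean"), None, None))
        rows.append(("Median", agg.get("median"), None, None))
        iv = agg.get("meta_interval_int")
        rows.append(("Meta-parameter", agg.get("meta_crossing"),
                     iv[0] if iv else None, iv[1] if iv else None))
        return pd.DataFrame(
            rows, columns=["parameter", "crossing_point", "interval_lo", "interval_hi"]
        )


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _provenance(config: AnalysisConfig, data: pd.DataFrame, variant: str) -> dict:
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(data, index=False).to_numpy().tobytes()
    ).hexdigest()
    return {
        "variant": variant,
        "config": dataclasses.asdict(config),
        "software_version": _pkg_version,
        "input_checksum": digest,
        "n_rows": int(len(data)),
        "timestamp": pd.Timestamp.now().isoformat(),
    }


def _wald_records(fit: ModelFit) -> list[dict]:
    return wald_type3(fit).to_dict(orient="records")


def _interaction_p(fit: ModelFit) -> float:
    table = wald_type3(fit)
    return float(table.loc[table["term"] == "interaction", "p"].iloc[0])


def _condition_analysis(
    wide: pd.DataFrame,
    config: AnalysisConfig,
    variant: str,
    condition_col: str,
    condition_levels: tuple[str, str],
    parameters: tuple[str, ...] | None = None,
) -> AnalysisReport:
    """Shared engine for the free-hand and tool-use analyses."""
    if parameters is None:
        parameters = tuple(p for p in reference.PARAMETERS if p in wide.columns)
    if len(parameters) < 2:
        raise ValueError(
            f"need at least 2 kinematic parameter columns, found {list(parameters)}"
        )
    if len(parameters) < len(reference.PARAMETERS):
        log.info("analysing %d of the %d canonical parameters",
                 len(parameters), len(reference.PARAMETERS))
    meta_all = pca_meta(wide, list(parameters), config.orientation_reference)
    with_meta = wide.loc[meta_all.scores.index].copy()
    with_meta["meta"] = meta_all.scores

    lrt = lrt_poly_vs_linear(with_meta, "meta", condition_col, condition_levels,
                             alpha=config.alpha)
    degree = ({"linear": 1, "quadratic": 2}[lrt["selected"]]
              if config.degree == "auto" else int(config.degree))

    def analyse(outcome, frame):
        fit = fit_lmm(frame, outcome, condition_col, condition_levels,
                      degree=degree, reml=True)
        wald = wald_type3(fit)
        curves = predict_condition_curves(fit, config.grid_lo, config.grid_hi,
                                          config.grid_step)
        result = crossing_and_equivalence(curves, config.alpha)
        p_int = float(wald.loc[wald["term"] == "interaction", "p"].iloc[0])
        return fit, wald, result, p_int

    per_parameter = {}
    crossing_results = {}
    for name in parameters:
        fit, wald, result, p_int = analyse(name, wide)
        per_parameter[name] = {
            "wald": wald.to_dict(orient="records"),
            "coefficients": dict(zip(fit.column_names, fit.params.tolist())),
            "singular": fit.singular,
            "crossing": _crossing_entry(result, p_int, config.alpha),
        }
        crossing_results[name] = result

    if config.holm:
        # optional Holm adjustment of the interaction p-values across the
        # analysed parameters (raw p-values remain the default report)
        names_p = [(n, per_parameter[n]["crossing"]["interaction_p"])
                   for n in parameters]
        order = sorted(names_p, key=lambda kv: kv[1])
        m = len(order)
        running = 0.0
        for rank, (name, p) in enumerate(order):
            running = max(running, min(1.0, (m - rank) * p))
            per_parameter[name]["crossing"]["interaction_p_holm"] = running

    meta_fit, meta_wald, meta_cross, meta_p_int = analyse("meta", with_meta)
    meta_summary = {
        "loadings": meta_all.loadings.to_dict(),
        "explained_variance_pct": 100.0 * meta_all.explained_variance_fraction,
        "orientation_reference": meta_all.orientation_reference,
        "wald": meta_wald.to_dict(orient="records"),
        "crossing": _crossing_entry(meta_cross, meta_p_int, config.alpha),
    }

    components = {}
    for comp_name, comp_params, ref_param in (
        ("reaching", reference.REACHING_PARAMETERS, "vel_amplitude"),
        ("grasping", reference.GRASPING_PARAMETERS, "mga"),
    ):
        comp_params = tuple(p for p in comp_params if p in parameters)
        if len(comp_params) < 2:
            continue
        comp_meta = pca_meta(wide, list(comp_params), ref_param)
        comp_frame = wide.loc[comp_meta.scores.index].copy()
        comp_frame["component_meta"] = comp_meta.scores
        comp_fit = fit_lmm(comp_frame, "component_meta", condition_col,
                           condition_levels, degree=degree, reml=True)
        components[comp_name] = {
            "parameters": list(comp_params),
            "explained_variance_pct": 100.0 * comp_meta.explained_variance_fraction,
            "loadings": comp_meta.loadings.to_dict(),
            "wald": _wald_records(comp_fit),  # the component's global p-values
        }

    aggregate = aggregate_crossings(crossing_results, meta_cross)
    return AnalysisReport(
        variant=variant,
        degree_selected=degree,
        lrt=lrt,
        meta=meta_summary,
        per_parameter=per_parameter,
        components=components,
        aggregate=aggregate,
    )


def run_freehand_analysis(trials: pd.DataFrame,
                          config: AnalysisConfig | None = None) -> AnalysisReport:
    """Free-hand PRE/POST analysis of the nine kinematic parameters.

    ``trials`` is the long-format trial table (columns ``subject_id, puberty,
    session, trial, parameter, value``) or an already-pivoted wide table.
    """
    config = config or AnalysisConfig()
    wide = pivot_trials(trials) if "parameter" in trials.columns else trials
    sessions = set(wide["session"].astype(str).unique())
    if not {"PRE", "POST"} <= sessions:
        raise ValueError(f"free-hand analysis needs PRE and POST sessions, got {sessions}")
    report = _condition_analysis(wide, config, "freehand", "session", ("PRE", "POST"))
    report.provenance = _provenance(config, wide, "freehand")
    return report


def run_tooluse_analysis(trials: pd.DataFrame,
                         config: AnalysisConfig | None = None,
                         first_block: str = "1",
                         last_block: str = "4") -> AnalysisReport:
    """Tool-use analysis contrasting the first and last practice blocks.

    Intermediate blocks are dropped with a log entry; the condition factor is
    FIRST/LAST and the puberty covariate enters with the LRT-selected basis.
    """
    config = config or AnalysisConfig()
    wide = pivot_trials(trials, condition_col="block") if "parameter" in trials.columns \
        else trials
    blocks = set(wide["block"].astype(str).unique())
    if not {first_block, last_block} <= blocks:
        raise ValueError(f"tool-use analysis needs blocks {first_block} and "
                         f"{last_block}, got {blocks}")
    ignored = blocks - {first_block, last_block}
    if ignored:
        log.info("tool-use analysis: ignoring intermediate blocks %s", sorted(ignored))
    wide = wide[wide["block"].astype(str).isin({first_block, last_block})].copy()
    wide["block"] = wide["block"].astype(str).map(
        {first_block: "FIRST", last_block: "LAST"}
    )
    report = _condition_analysis(wide, config, "tooluse", "block", ("FIRST", "LAST"))
    report.provenance = _provenance(config, wide, "tooluse")
    return report


def run_armlength_analysis(estimates: pd.DataFrame,
                           config: AnalysisConfig | None = None) -> AnalysisReport:
    """Arm-length estimation analysis on the percent-of-veridical scale.

    ``estimates`` needs columns ``subject_id, puberty, session, trial,
    estimate, forearm_length``; the outcome is ``100 * estimate / forearm``,
    which makes the analysis invariant to the growth-driven differences in
    actual arm length.
    """
    config = config or AnalysisConfig()
    required = {"subject_id", "puberty", "session", "estimate", "forearm_length"}
    missing = required - set(estimates.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (estimates["forearm_length"] <= 0).any():
        raise ValueError("forearm_length must be positive")
    data = estimates.copy()
    data["estimate_pct"] = 100.0 * data["estimate"] / data["forearm_length"]

    if np.ptp(data["estimate_pct"].to_numpy(float)) < 1e-9:
        # degenerate case: estimates identical to the veridical arm length
        report = AnalysisReport(
            variant="armlength", degree_selected=0,
            lrt={"chi2": 0.0, "df": 2, "p": 1.0, "selected": "linear"},
            meta={},
            per_parameter={"estimate_pct": {
                "wald": [], "coefficients": {}, "singular": True,
                "crossing": {"crossing_point": None, "equivalence_interval": None,
                             "equivalence_interval_int": None, "no_reversal": True,
                             "reliable": False, "interaction_p": 1.0},
            }},
            components={},
            aggregate={"no_reversal_detected": True, "mean": None, "median": None},
        )
        report.provenance = _provenance(config, data, "armlength")
        return report

    lrt = lrt_poly_vs_linear(data, "estimate_pct", alpha=config.alpha)
    degree = ({"linear": 1, "quadratic": 2}[lrt["selected"]]
              if config.degree == "auto" else int(config.degree))
    fit = fit_lmm(data, "estimate_pct", degree=degree, reml=True)
    wald = wald_type3(fit)
    curves = predict_condition_curves(fit, config.grid_lo, config.grid_hi,
                                      config.grid_step)
    result = crossing_and_equivalence(curves, config.alpha)
    p_int = float(wald.loc[wald["term"] == "interaction", "p"].iloc[0])
    report = AnalysisReport(
        variant="armlength",
        degree_selected=degree,
        lrt=lrt,
        meta={},
        per_parameter={"estimate_pct": {
            "wald": wald.to_dict(orient="records"),
            "coefficients": dict(zip(fit.column_names, fit.params.tolist())),
            "singular": fit.singular,
            "crossing": _crossing_entry(result, p_int, config.alpha),
        }},
        components={},
        aggregate=aggregate_crossings({"estimate_pct": result}, result),
    )
    report.provenance = _provenance(config, data, "armlength")
    return report


def run_imitation_analysis(scores: pd.DataFrame,
                           config: AnalysisConfig | None = None) -> dict:
    """Linear-vs-quadratic regression of per-subject imitation totals."""
    config = config or AnalysisConfig()
    result = imitation_regression(scores["score"], scores["puberty"],
                                  alpha=config.alpha)
    result["n_subjects"] = int(len(scores))
    return result


# ---------------------------------------------------------------------------
# Reproduction of the archived study
# ---------------------------------------------------------------------------

def _compare(name: str, computed, published, tolerance) -> dict:
    ok = computed is not None and abs(float(computed) - float(published)) <= tolerance
    return {
        "quantity": name,
        "computed": None if computed is None else float(computed),
        "published": float(published),
        "tolerance": float(tolerance),
        "pass": bool(ok),
    }


def reproduce_study(data_dir: str | Path,
                    mapping: Mapping[str, Mapping] | None = None,
                    config: AnalysisConfig | None = None) -> dict:
    """Re-run all analyses on a local copy of the archived study data
    (OSF accession 3g9mz) and compare against the published values.

    ``mapping`` adapts the archive's file names and column headers: per
    analysis (``freehand``, ``tooluse``, ``armlength``, ``imitation``) it
    gives a ``path`` (relative to ``data_dir``) and an optional ``columns``
    rename map onto the canonical schema.  Missing files are listed and the
    remaining analyses still run.  Comparison tolerances follow
    :data:`toolplast.reference.REPRODUCE_TOLERANCES`.
    """
    config = config or AnalysisConfig()
    data_dir = Path(data_dir)
    mapping = mapping or {
        "freehand": {"path": "freehand_trials.csv"},
        "tooluse": {"path": "tooluse_trials.csv"},
        "armlength": {"path": "armlength_trials.csv"},
        "imitation": {"path": "imitation_scores.csv"},
        "cohort": {"path": "cohort.csv"},
    }
    tol = reference.REPRODUCE_TOLERANCES
    missing_files: list[str] = []
    reports: dict = {}
    comparisons: list[dict] = []

    def load(key):
        entry = mapping.get(key)
        if entry is None:
            return None
        path = data_dir / entry["path"]
        if not path.exists():
            missing_files.append(str(path))
            return None
        df = pd.read_csv(path)
        if entry.get("columns"):
            df = df.rename(columns=dict(entry["columns"]))
        return df

    freehand = load("freehand")
    if freehand is not None:
        report = run_freehand_analysis(freehand, config)
        reports["freehand"] = report
        agg = report.aggregate
        comparisons += [
            _compare("freehand_meta_crossing", agg.get("meta_crossing"),
                     reference.REPORTED_META_CROSSING[0], tol["crossing_point"]),
            _compare("freehand_mean_crossing", agg.get("mean"),
                     reference.REPORTED_MEAN_CROSSING, tol["crossing_point"]),
            _compare("freehand_median_crossing", agg.get("median"),
                     reference.REPORTED_MEDIAN_CROSSING, tol["crossing_point"]),
            _compare("freehand_lrt_chi2", report.lrt["chi2"],
                     reference.REPORTED_LRT_CHI2["freehand"], tol["lrt_chi2"]),
        ]
        for comp in ("reaching", "grasping"):
            if comp in report.components:
                comparisons.append(_compare(
                    f"freehand_{comp}_explained_variance_pct",
                    report.components[comp]["explained_variance_pct"],
                    reference.REPORTED_EXPLAINED_VARIANCE[("freehand", comp)],
                    tol["explained_variance_pct"],
                ))
        for name, (cp, _, _) in reference.REPORTED_CROSSINGS.items():
            entry = report.per_parameter.get(name)
            computed = entry["crossing"]["crossing_point"] if entry else None
            comparisons.append(_compare(f"freehand_{name}_crossing", computed, cp,
                                        tol["crossing_point"]))

    tooluse = load("tooluse")
    if tooluse is not None:
        report = run_tooluse_analysis(tooluse, config)
        reports["tooluse"] = report
        comparisons.append(_compare("tooluse_lrt_chi2", report.lrt["chi2"],
                                    reference.REPORTED_LRT_CHI2["tooluse"],
                                    tol["lrt_chi2"]))
        for comp in ("reaching", "grasping"):
            if comp in report.components:
                comparisons.append(_compare(
                    f"tooluse_{comp}_explained_variance_pct",
                    report.components[comp]["explained_variance_pct"],
                    reference.REPORTED_EXPLAINED_VARIANCE[("tooluse", comp)],
                    tol["explained_variance_pct"],
                ))

    armlength = load("armlength")
    if armlength is not None:
        report = run_armlength_analysis(armlength, config)
        reports["armlength"] = report
        cp = report.per_parameter["estimate_pct"]["crossing"]["crossing_point"]
        comparisons += [
            _compare("armlength_crossing", cp,
                     reference.REPORTED_ARMLENGTH_CROSSING[0], tol["crossing_point"]),
            _compare("armlength_lrt_chi2", report.lrt["chi2"],
                     reference.REPORTED_LRT_CHI2["armlength"], tol["lrt_chi2"]),
        ]

    imitation = load("imitation")
    if imitation is not None:
        reports["imitation"] = run_imitation_analysis(imitation, config)

    cohort = load("cohort")
    if cohort is not None and {"height", "forearm_length"} <= set(cohort.columns):
        r = float(np.corrcoef(cohort["height"], cohort["forearm_length"])[0, 1])
        comparisons.append(_compare("height_forearm_r", r,
                                    reference.HEIGHT_FOREARM_R, tol["correlation"]))

    return {
        "reports": reports,
        "comparisons": comparisons,
        "missing_files": missing_files,
        "n_pass": sum(c["pass"] for c in comparisons),
        "n_total": len(comparisons),
    }
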