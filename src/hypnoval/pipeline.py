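"""End-to-end orchestration: sync -> consensus -> align -> metrics ->
night measures -> subgroup tests -> survey, with report assembly.

Every number in the report is recomputable from the emitted
intermediate tables; the report itself only formats them. Outputs are
plain CSV/JSON plus a markdown report so diff-based regression testing
stays possible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import consensus as consensus_mod
from . import epoch_metrics as em
from . import night_measures as nm
from . import subgroup_stats as sg
from .errors import ConfigError, HypnovalError
from .hypnogram import (
    AlignedPair,
    Hypnogram,
    align_pair,
    read_hypnogram,
)
from .stages import HARMONIZED4
from .sync import apply_offset, estimate_offset, read_respiratory
from .synthetic import (
    CohortConfig,
    SubjectRecord,
    SyntheticBundle,
    config_from_manifest,
    simulate_cohort,
)

logger = logging.getLogger("hypnoval")

__all__ = ["PipelineConfig", "run_pipeline", "load_bundle_dir", "load_config"]

#: Measures the subgroup family tests, per the evaluation protocol.
SUBGROUP_MEASURES = (
    "tst_min",
    "ti_rem_min", "ti_light_min", "ti_deep_min",
    "pi_rem_pct", "pi_light_pct", "pi_deep_pct", "pi_wake_pct",
    "ne_rem", "ne_light", "ne_deep", "ne_wake",
)
SUBGROUP_GROUPINGS = (
    "sex", "age_group", "bmi_group", "bed_partner", "mattress_type",
    "mattress_thickness_group", "sleep_duration_group",
    "self_reported_quality", "woke_during_night",
)


@dataclass(frozen=True)
class PipelineConfig:
    """A full pipeline run: where data come from and how each stage behaves."""

    simulation: CohortConfig | None = None
    input_dir: str | None = None
    out_dir: str | None = None
    seed: int = 0
    absent_policy: str = "exclude"
    window_policy: str = "full_recording"  # or lights_window (start_s/end_s set)
    lights_window_s: tuple[float, float] | None = None
    sync_enabled: bool = True
    sync_max_lag_s: float = 120.0
    sync_step_s: float = 0.5
    ci_method: str = "normal"
    holm_family: str = "per_test"
    pi_denominator: str = "window"
    skip_bad_nights: bool = False

    def __post_init__(self) -> None:
        if self.simulation is None and self.input_dir is None:
            raise ConfigError("config needs either a simulation block or input_dir")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline config; the ``simulation`` block maps onto
    :class:`hypnoval.synthetic.CohortConfig` via its manifest schema."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    sim = raw.pop("simulation", None)
    if sim is not None:
        if "architecture" in sim:
            sim = config_from_manifest(sim)
        else:
            sim = CohortConfig(**sim)
    return PipelineConfig(simulation=sim, **raw)


def load_bundle_dir(path: str | Path) -> SyntheticBundle:
    """Load a written bundle directory back into memory."""
    path = Path(path)
    with open(path / "manifest.yaml", "r", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    metadata = pd.read_csv(path / "metadata.csv")
    subjects = []
    for sid in metadata["subject_id"]:
        def _h(name: str) -> Hypnogram:
            return read_hypnogram(path / f"{sid}_{name}.csv")

        b_ref = b_dev = None
        if (path / f"{sid}_breath_ref.csv").exists():
            b_ref = read_respiratory(path / f"{sid}_breath_ref.csv")
            b_dev = read_respiratory(path / f"{sid}_breath_dev.csv")
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                truth=_h("truth"),
                reviewer1=_h("reviewer1"),
                reviewer2=_h("reviewer2"),
                adjudicator=_h("adjudicator"),
                device=_h("device"),
                clock_offset_s=float("nan"),
                emission=np.array(manifest["device"]["emission"]),
                breathing_ref=b_ref,
                breathing_dev=b_dev,
            )
        )
    return SyntheticBundle(tuple(subjects), metadata, manifest)


@dataclass
class NightResult:
    subject_id: str
    pair: AlignedPair
    cm: em.ConfusionMatrix4
    metrics: em.NightClassificationMetrics
    agreement_pair: AlignedPair
    disagreement_pair: AlignedPair
    ref_measures: nm.SleepMeasures
    dev_measures: nm.SleepMeasures
    kappa_stages: float
    kappa_sw: float
    offset_s: float
    peak_r: float
    low_confidence: bool


def _pair_hypnograms(pair: AlignedPair) -> tuple[Hypnogram, Hypnogram]:
    """Reference and device hypnograms over the pair's valid span."""
    mask = np.asarray(pair.valid_mask, dtype=bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise HypnovalError(f"night {pair.subject_id}: no valid epochs")
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    origin = pair.window_origin_s + lo * pair.epoch_s
    ref = Hypnogram(pair.subject_id, "reference", origin, pair.epoch_s,
                    pair.reference[lo:hi], HARMONIZED4)
    dev = Hypnogram(pair.subject_id, "device", origin, pair.epoch_s,
                    pair.device[lo:hi], HARMONIZED4)
    return ref, dev


def _process_subject(rec: SubjectRecord, config: PipelineConfig) -> NightResult:
    t0 = time.perf_counter()
    offset_s, peak_r, low = 0.0, float("nan"), False
    if config.sync_enabled and rec.breathing_ref is not None:
        est = estimate_offset(
            rec.breathing_ref, rec.breathing_dev,
            max_lag_s=config.sync_max_lag_s, step_s=config.sync_step_s,
        )
        offset_s, peak_r, low = est.offset_s, est.peak_r, est.low_confidence
    device = apply_offset(rec.device, offset_s)

    cons = consensus_mod.build_consensus(rec.reviewer1, rec.reviewer2, rec.adjudicator)
    reference = cons.consensus
    if config.window_policy == "lights_window" and config.lights_window_s:
        from .hypnogram import restrict_window

        reference = restrict_window(reference, *config.lights_window_s)

    pair = align_pair(reference, device, absent_policy=config.absent_policy)
    cm = em.confusion(pair)
    metrics = em.night_metrics(cm)

    mask, covered = consensus_mod.crop_mask_to_pair(
        cons.agreement_mask, reference.onset_s, pair
    )
    in_span = pair.with_mask(np.asarray(pair.valid_mask, dtype=bool) & np.asarray(covered))
    agree_pair, disagree_pair = consensus_mod.stratify_epochs(in_span, mask)

    ref_h, dev_h = _pair_hypnograms(pair)
    ref_meas = nm.compute_measures(ref_h, pi_denominator=config.pi_denominator)
    dev_meas = nm.compute_measures(dev_h, pi_denominator=config.pi_denominator)

    logger.info(
        "night %s: %d valid epochs, offset %.1f s, %.0f ms",
        rec.subject_id, pair.n_valid, offset_s, 1e3 * (time.perf_counter() - t0),
    )
    return NightResult(
        subject_id=rec.subject_id,
        pair=pair,
        cm=cm,
        metrics=metrics,
        agreement_pair=agree_pair,
        disagreement_pair=disagree_pair,
        ref_measures=ref_meas,
        dev_measures=dev_meas,
        kappa_stages=cons.kappa_stages,
        kappa_sw=cons.kappa_sw,
        offset_s=offset_s,
        peak_r=peak_r,
        low_confidence=low,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full validation pipeline; returns the result tables.

    If ``config.out_dir`` is set, every table is written as CSV/JSON
    alongside a human-readable ``report.md``.
    """
    if config.simulation is not None:
        bundle = simulate_cohort(config.simulation, config.seed)
    else:
        bundle = load_bundle_dir(config.input_dir)

    nights: list[NightResult] = []
    excluded: list[tuple[str, str]] = []
    for rec in bundle.subjects:
        try:
            nights.append(_process_subject(rec, config))
        except HypnovalError as exc:
            if config.skip_bad_nights:
                logger.warning("excluding night %s: %s", rec.subject_id, exc)
                excluded.append((rec.subject_id, str(exc)))
            else:
                raise HypnovalError(f"subject {rec.subject_id}: {exc}") from exc
    if not nights:
        raise HypnovalError("no nights survived processing")

    # --- epoch-by-epoch agreement -------------------------------------
    night_table = pd.DataFrame(
        [{"subject_id": nr.subject_id, **nr.metrics.flat(),
          "kappa_reviewers_stages": nr.kappa_stages,
          "kappa_reviewers_sw": nr.kappa_sw} for nr in nights]
    )
    summary = em.aggregate_nights([nr.metrics for nr in nights],
                                  ci_method=config.ci_method, seed=config.seed)
    pooled, pooled_pct = em.pooled_confusion([nr.cm for nr in nights])
    try:
        strata = em.compare_strata(
            [nr.agreement_pair for nr in nights],
            [nr.disagreement_pair for nr in nights],
            ci_method=config.ci_method,
        )
    except HypnovalError as exc:  # e.g. perfect reviewers: no disagreements
        logger.warning("strata comparison skipped: %s", exc)
        strata = pd.DataFrame()

    # --- night-scale measures -----------------------------------------
    measures_rows = []
    for nr in nights:
        for src, meas in (("reference", nr.ref_measures), ("device", nr.dev_measures)):
            measures_rows.append({"subject_id": nr.subject_id, "source": src, **meas.flat()})
    measures = pd.DataFrame(measures_rows)

    agreement_rows = []
    ref_tab = measures[measures.source == "reference"].set_index("subject_id")
    dev_tab = measures[measures.source == "device"].set_index("subject_id")
    for name in nm.MEASURE_NAMES:
        ps = nm.paired_stats(dev_tab[name], ref_tab[name],
                             ci_method=config.ci_method, seed=config.seed)
        agreement_rows.append({
            "measure": name, "mae": ps.mae,
            "mae_ci95_low": ps.mae_ci95[0], "mae_ci95_high": ps.mae_ci95[1],
            "bias": ps.bias,
            "bias_ci95_low": ps.bias_ci95[0], "bias_ci95_high": ps.bias_ci95[1],
            "loa_low": ps.loa_low, "loa_high": ps.loa_high,
            "prop_bias_slope": ps.prop_bias_slope, "prop_bias_p": ps.prop_bias_p,
            "n_nights": ps.n_nights,
        })
    agreement = pd.DataFrame(agreement_rows).set_index("measure")

    if len(nights) >= 3 and np.ptp(ref_tab["tst_min"].to_numpy()) > 0:
        fit = nm.ransac_regression(dev_tab["tst_min"], ref_tab["tst_min"], seed=config.seed)
        ransac = {"measure": "tst_min", "slope": fit.slope, "intercept": fit.intercept,
                  "r2": fit.r2, "inlier_fraction": fit.inlier_fraction,
                  "slope_p": fit.slope_p, "seed": fit.seed}
    else:
        ransac = None

    # --- subgroup tests and survey ------------------------------------
    abs_err = (dev_tab[list(nm.MEASURE_NAMES)] - ref_tab[list(nm.MEASURE_NAMES)]).abs()
    metadata = sg.add_derived_groups(bundle.metadata)
    groupings = [g for g in SUBGROUP_GROUPINGS if g in metadata.columns]
    try:
        subgroup_table = sg.run_subgroup_family(
            abs_err.reset_index(), metadata,
            groupings=groupings, measures=list(SUBGROUP_MEASURES),
            family=config.holm_family,
        )
    except HypnovalError as exc:
        logger.warning("subgroup tests skipped: %s", exc)
        subgroup_table = pd.DataFrame()

    survey = None
    if {"quality_with_psg", "quality_without_psg"} <= set(metadata.columns):
        survey = sg.survey_summary(metadata)

    offsets = pd.DataFrame(
        [{"subject_id": nr.subject_id, "offset_s": nr.offset_s, "peak_r": nr.peak_r,
          "flag": "low_confidence" if nr.low_confidence else "ok"} for nr in nights]
    )

    results = {
        "night_metrics": night_table,
        "cohort_summary": summary,
        "confusion_pooled": pooled,
        "confusion_pooled_pct": pooled_pct,
        "strata_report": strata,
        "measures": measures,
        "agreement": agreement,
        "ransac": ransac,
        "subgroup_tests": subgroup_table,
        "survey": survey,
        "offsets": offsets,
        "excluded": excluded,
        "manifest": bundle.manifest,
    }
    if config.out_dir:
        _write_outputs(results, Path(config.out_dir))
    return results


def _write_outputs(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    results["night_metrics"].to_csv(outdir / "night_metrics.csv", index=False)
    results["cohort_summary"].to_csv(outdir / "cohort_summary.csv")
    with open(outdir / "confusion_pooled.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "counts": results["confusion_pooled"].counts.tolist(),
                "row_normalized_pct": results["confusion_pooled_pct"].values.tolist(),
                "stage_order": list(results["confusion_pooled_pct"].index),
            },
            fh, indent=2,
        )
    results["strata_report"].to_csv(outdir / "strata_report.csv")
    results["measures"].to_csv(outdir / "measures.csv", index=False)
    results["agreement"].to_csv(outdir / "agreement.csv")
    if results["ransac"] is not None:
        with open(outdir / "ransac.json", "w", encoding="utf-8") as fh:
            json.dump(results["ransac"], fh, indent=2)
    if not results["subgroup_tests"].empty:
        tab = results["subgroup_tests"].copy()
        tab["group_summaries"] = tab["group_summaries"].map(json.dumps)
        tab.to_csv(outdir / "subgroup_tests.csv", index=False)
    if results["survey"] is not None:
        pd.concat(
            {k: v for k, v in results["survey"].items()}, names=["table", "level"]
        ).to_csv(outdir / "survey_summary.csv")
    results["offsets"].to_csv(outdir / "offsets.csv", index=False)
    (outdir / "report.md").write_text(render_report(results), encoding="utf-8")


def render_report(results: dict) -> str:
    """Assemble the markdown report from the result tables."""
    s = results["cohort_summary"]

    def fmt(metric: str) -> str:
        if metric not in s.index:
            return "n/a"
        r = s.loc[metric]
        return f"{r['mean']:.2f} (95% CI {r['ci95_low']:.2f}-{r['ci95_high']:.2f}, n={int(r['n_nights_used'])})"

    lines = [
        "# Device-vs-reference validation report",
        "",
        f"Nights analysed: {results['night_metrics'].shape[0]}"
        + (f" (excluded: {len(results['excluded'])})" if results["excluded"] else ""),
        "",
        "## Epoch-by-epoch agreement (mean of per-night values)",
        "",
        f"- 4-stage kappa: {fmt('kappa4')}",
        f"- 4-stage accuracy: {fmt('accuracy4')}",
        f"- sleep-wake kappa: {fmt('kappa2')}",
        f"- sleep-wake accuracy: {fmt('accuracy2')}",
        f"- Se sleep: {fmt('se_sleep')}  /  Sp sleep: {fmt('sp_sleep')}",
        "",
        "## Pooled row-normalized confusion (%)",
        "",
        results["confusion_pooled_pct"].to_string(),
        "",
        "## Night-scale measures (device - reference)",
        "",
        results["agreement"][["mae", "bias", "loa_low", "loa_high", "n_nights"]]
        .round(2).to_string(),
        "",
    ]
    if results["ransac"] is not None:
        r = results["ransac"]
        lines += [
            "## Robust TST regression (RANSAC)",
            "",
            f"slope {r['slope']:.3f}, intercept {r['intercept']:.1f} min, "
            f"R2 {r['r2']:.3f}, inliers {100 * r['inlier_fraction']:.0f}%, "
            f"slope p {r['slope_p']:.2g}",
            "",
        ]
    if not results["subgroup_tests"].empty:
        rejected = results["subgroup_tests"][results["subgroup_tests"]["reject"]]
        lines += [
            "## Subgroup tests",
            "",
            f"{len(results['subgroup_tests'])} tests; "
            f"{len(rejected)} rejected after Holm correction.",
            "",
        ]
    return "\n".join(lines)
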