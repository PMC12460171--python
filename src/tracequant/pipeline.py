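"""End-to-end pipeline orchestration.

Runs are driven by a single declarative YAML config so that a run is
fully reproducible from the config artifact; every stage writes its
intermediate table to the output directory, making each reported number
traceable to a named file.  Stage failures surface as
:class:`StageError` carrying the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

import tracequant
from tracequant import body_water as bw
from tracequant import dnl as dnl_mod
from tracequant import fao as fao_mod
from tracequant import group_stats, peak_io
from tracequant.enrichment import deuterium_enrichment
from tracequant.na_correction import NaturalAbundanceModel, correct_mid

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the report."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    pipeline: str = "dnl"
    output_dir: str = "tracequant_run"
    seed: int = 0
    # DNL inputs
    peak_table: str | None = None
    metadata: str | None = None
    body_water_standards: str | None = None
    # FAO inputs
    traces: str | None = None
    substrate: str | None = None
    animal_groups: str | None = None
    # options
    na_correction: dict[str, Any] = field(default_factory=dict)
    statistics: dict[str, Any] = field(default_factory=dict)
    enrichment_floor: float = 0.001

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def na_model(self, tracer_element: str) -> NaturalAbundanceModel:
        opts = self.na_correction
        key = "heavy_fraction_c13" if tracer_element == "C" else "heavy_fraction_h2"
        return NaturalAbundanceModel(
            tracer_element=tracer_element,
            heavy_fraction=opts.get(key),
            tracer_purity=opts.get("tracer_purity", 1.0),
        )

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_log(config: RunConfig, outdir: Path, n_inputs: int) -> None:
    log = {
        "tool": "tracequant",
        "version": tracequant.__version__,
        "pipeline": config.pipeline,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_inputs": n_inputs,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")


def _group_tests(
    frame: pd.DataFrame, value_col: str, config: RunConfig, metric: str
) -> pd.DataFrame:
    method = config.statistics.get("method", "anova_tukey")
    alternative = config.statistics.get("alternative", "two-sided")
    by_group = {g: sub[value_col].to_numpy() for g, sub in frame.groupby("group", sort=False)}
    columns = ["metric", "group_1", "group_2", "statistic", "p_value", "adjusted_p", "method"]
    if len(by_group) < 2:
        logger.warning("only %d group(s) with data for %s; group tests skipped",
                       len(by_group), metric)
        return pd.DataFrame(columns=columns)
    comparisons = group_stats.compare_groups(
        by_group, method=method, metric=metric, alternative=alternative
    )
    rows = [
        {
            "metric": c.metric,
            "group_1": c.groups[0],
            "group_2": c.groups[1],
            "statistic": c.statistic,
            "p_value": c.p_value,
            "adjusted_p": c.adjusted_p,
            "method": c.method,
        }
        for c in comparisons
    ]
    out = pd.DataFrame(rows)
    if config.statistics.get("fdr", False) and not out.empty:
        out["fdr_adjusted_p"] = group_stats.adjust_fdr(out["p_value"].to_numpy())
    return out


def run_dnl_pipeline(config: RunConfig) -> pd.DataFrame:
    """2H2O lipogenesis pipeline: peak table -> per-sample DNL -> group stats.

    Returns the per-sample result table; all intermediates land in
    ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- read -------------------------------------------------------------
    try:
        records = peak_io.read_peak_table(config.peak_table)
        samples = peak_io.read_sample_metadata(config.metadata)
        dataset = peak_io.Dataset(records=records, samples=samples)
        dataset.validate()
    except (TypeError, ValueError, OSError) as exc:
        raise StageError("read", str(exc)) from exc
    peak_io.records_to_frame(records).to_csv(outdir / "01_records.csv", index=False)

    # --- assemble ---------------------------------------------------------
    try:
        mids = peak_io.assemble_mids(records)
    except ValueError as exc:
        raise StageError("assemble", str(exc)) from exc
    pd.DataFrame(
        [
            {"sample_id": m.sample_id, "metabolite": m.metabolite, "n_atoms": m.n_atoms,
             "total_intensity": m.intensities.sum()}
            for m in mids.values()
        ]
    ).to_csv(outdir / "02_raw_mids.csv", index=False)

    # --- natural-abundance correction ------------------------------------
    residual_warn = config.na_correction.get("residual_warn_threshold", 0.01)
    corrected = {}
    corr_rows = []
    for key, m in mids.items():
        try:
            result = correct_mid(m.intensities, m.n_atoms, config.na_model(m.tracer_element))
        except ValueError as exc:
            raise StageError("na_correct", f"{key}: {exc}") from exc
        if result.residual > residual_warn:
            logger.warning("%s: NA-correction residual %.3g above threshold", key, result.residual)
        corrected[key] = result
        for i, frac in enumerate(result.fractions):
            corr_rows.append(
                {"sample_id": key[0], "metabolite": key[1], "isotopologue": i,
                 "fraction": frac, "residual": result.residual}
            )
    pd.DataFrame(corr_rows).to_csv(outdir / "03_corrected_mids.csv", index=False)

    # --- deuterium enrichment ---------------------------------------------
    enr_rows = []
    for key, result in corrected.items():
        try:
            de = deuterium_enrichment(result.fractions)
        except ValueError as exc:
            raise StageError("enrichment", f"{key}: {exc}") from exc
        enr_rows.append(
            {"sample_id": key[0], "metabolite": key[1], "h1": de.h1, "h2": de.h2,
             "h3": de.h3, "h2_enrichment": de.enrichment, "untruncated": de.untruncated}
        )
    enr_frame = pd.DataFrame(enr_rows)
    enr_frame.to_csv(outdir / "04_enrichment.csv", index=False)

    # --- body water --------------------------------------------------------
    try:
        std_frame = pd.read_csv(config.body_water_standards)
        standards = [
            bw.BodyWaterStandard(row.known_fraction, row.acetone_h1_fraction)
            for row in std_frame.itertuples(index=False)
        ]
        curve = bw.fit_body_water_curve(standards)
    except (TypeError, ValueError, OSError, AttributeError) as exc:
        raise StageError("body_water", str(exc)) from exc
    bw_rows = []
    water_by_sample = {}
    for s in dataset.samples:
        if s.body_water_acetone_fraction is None:
            continue
        fraction = bw.body_water_enrichment(s.body_water_acetone_fraction, curve)
        water_by_sample[s.sample_id] = fraction
        bw_rows.append({"sample_id": s.sample_id, "body_water_fraction": fraction})
    pd.DataFrame(bw_rows, columns=["sample_id", "body_water_fraction"]).to_csv(
        outdir / "05_body_water.csv", index=False
    )
    pd.DataFrame(
        [{"slope": curve.slope, "intercept": curve.intercept,
          "r_squared": curve.r_squared, "n_points": curve.n_points}]
    ).to_csv(outdir / "05_body_water_curve.csv", index=False)

    # --- DNL ----------------------------------------------------------------
    dnl_rows = []
    excluded = []
    for key, result in corrected.items():
        sample = dataset.sample(key[0])
        if sample.sample_id not in water_by_sample:
            excluded.append({"sample_id": key[0], "reason": "no body-water measurement"})
            continue
        try:
            res = dnl_mod.dnl_from_mid(
                result.fractions,
                body_water=water_by_sample[sample.sample_id],
                elapsed_hours=sample.elapsed_hours,
                sample_id=sample.sample_id,
            )
        except dnl_mod.UndefinedIsotopomerRatio as exc:
            excluded.append({"sample_id": key[0], "reason": str(exc)})
            continue
        except ValueError as exc:
            raise StageError("dnl", f"{key}: {exc}") from exc
        dnl_rows.append(
            {
                "sample_id": res.sample_id,
                "group": sample.group,
                "h_enrichment": res.h_enrichment,
                "body_water": res.body_water,
                "n_exchangeable": res.n_exchangeable,
                "dnl_fraction": res.dnl_fraction,
                "dnl_rate_per_hour": res.dnl_rate_per_hour,
                "elapsed_hours": res.elapsed_hours,
                "qc_flags": ";".join(res.qc_flags),
            }
        )
    results = pd.DataFrame(dnl_rows)
    results.to_csv(outdir / "06_dnl_results.csv", index=False)
    pd.DataFrame(excluded, columns=["sample_id", "reason"]).to_csv(
        outdir / "06_excluded_samples.csv", index=False
    )
    if results.empty:
        raise StageError("dnl", "no samples with a defined DNL estimate")

    # --- outlier flagging ---------------------------------------------------
    results["outlier"] = False
    for _, idx in results.groupby("group", sort=False).groups.items():
        flags = group_stats.flag_outliers_iqr(results.loc[idx, "dnl_fraction"].to_numpy())
        results.loc[idx, "outlier"] = flags
    results.to_csv(outdir / "07_outlier_flags.csv", index=False)
    retained = results[~results["outlier"]]

    # --- group statistics -----------------------------------------------------
    try:
        tests = _group_tests(retained, "dnl_fraction", config, metric="dnl_fraction")
    except ValueError as exc:
        raise StageError("group_stats", str(exc)) from exc
    tests.to_csv(outdir / "08_group_stats.csv", index=False)

    _write_summary_dnl(outdir, retained, tests, excluded)
    _write_log(config, outdir, n_inputs=len(records))
    return results


def _write_summary_dnl(outdir, retained, tests, excluded):
    lines = ["tracequant DNL pipeline summary", "=" * 32, ""]
    means = retained.groupby("group", sort=False)["dnl_fraction"].agg(["mean", "std", "count"])
    lines.append("Per-group DNL fraction (outliers excluded):")
    for group, row in means.iterrows():
        lines.append(
            f"  {group}: mean {row['mean']:.4f}  sd {row['std']:.4f}  n {int(row['count'])}"
        )
    if excluded:
        lines.append("")
        lines.append(f"Excluded samples: {len(excluded)}")
    lines.append("")
    lines.append("Group comparisons:")
    for _, row in tests.iterrows():
        adj = f"  adj p {row['adjusted_p']:.4g}" if pd.notna(row.get("adjusted_p")) else ""
        lines.append(
            f"  {row['group_1']} vs {row['group_2']}: p {row['p_value']:.4g}{adj}"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")


def _read_traces(config: RunConfig):
    trace_frame = pd.read_csv(config.traces)
    sub_frame = pd.read_csv(config.substrate)
    for col in ("animal_id", "time_min", "co2_ratio"):
        if col not in trace_frame.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
    for col in ("animal_id", "time_min", "enrichment"):
        if col not in sub_frame.columns:
            raise ValueError(f"substrate CSV missing column {col!r}")
    baseline = config.na_correction.get("heavy_fraction_c13", fao_mod.NATURAL_13C_FRACTION)
    traces = [
        fao_mod.CO2Trace(
            animal_id=str(animal),
            times=sub.sort_values("time_min")["time_min"].to_numpy(),
            ratios=sub.sort_values("time_min")["co2_ratio"].to_numpy(),
            baseline_fraction=baseline,
        )
        for animal, sub in trace_frame.groupby("animal_id", sort=False)
    ]
    substrates = {
        str(animal): fao_mod.SubstrateEnrichmentTrace(
            animal_id=str(animal),
            times=sub.sort_values("time_min")["time_min"].to_numpy(),
            enrichments=sub.sort_values("time_min")["enrichment"].to_numpy(),
        )
        for animal, sub in sub_frame.groupby("animal_id", sort=False)
    }
    return traces, substrates


def _animal_group(config: RunConfig, animal_id: str, mapping: dict[str, str]) -> str:
    if mapping:
        return mapping[animal_id]
    return animal_id.rsplit("_", 1)[0]


def run_fao_pipeline(config: RunConfig) -> pd.DataFrame:
    """13CO2 oxidation pipeline: traces -> slopes + normalized oxidation -> stats."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        traces, substrates = _read_traces(config)
    except (TypeError, ValueError, OSError) as exc:
        raise StageError("read", str(exc)) from exc

    group_map: dict[str, str] = {}
    if config.animal_groups:
        gframe = pd.read_csv(config.animal_groups)
        group_map = dict(zip(gframe["animal_id"].astype(str), gframe["group"].astype(str)))

    excess_rows, slope_rows, norm_rows = [], [], []
    no_rise = []
    for trace in traces:
        excess = fao_mod.excess_co2(trace)
        for t, e in zip(trace.times, excess):
            excess_rows.append({"animal_id": trace.animal_id, "time_min": t, "excess": e})
        try:
            s = fao_mod.slope_to_max(trace)
        except ValueError as exc:
            no_rise.append((trace.animal_id, str(exc)))
            continue
        if trace.animal_id not in substrates:
            raise StageError("normalize", f"no substrate series for {trace.animal_id}")
        try:
            times, normalized = fao_mod.normalize_oxidation(
                trace, substrates[trace.animal_id], config.enrichment_floor
            )
        except ValueError as exc:
            raise StageError("normalize", str(exc)) from exc
        group = _animal_group(config, trace.animal_id, group_map)
        slope_rows.append(
            {"animal_id": trace.animal_id, "group": group, "slope_per_min": s.slope,
             "time_of_max_min": s.time_of_max, "n_points": s.n_points,
             "mean_normalized_oxidation": float(np.mean(normalized))}
        )
        for t, v in zip(times, normalized):
            norm_rows.append({"animal_id": trace.animal_id, "time_min": t, "normalized": v})
    pd.DataFrame(excess_rows).to_csv(outdir / "01_excess.csv", index=False)
    if not slope_rows:
        detail = "; ".join(f"{a}: {m}" for a, m in no_rise) or "no traces"
        raise StageError("slope", f"no rising traces ({detail})")
    slopes = pd.DataFrame(slope_rows)
    slopes.to_csv(outdir / "02_slopes.csv", index=False)
    pd.DataFrame(norm_rows).to_csv(outdir / "03_normalized.csv", index=False)

    try:
        tests = pd.concat(
            [
                _group_tests(slopes, "slope_per_min", config, metric="slope_per_min"),
                _group_tests(
                    slopes, "mean_normalized_oxidation", config,
                    metric="mean_normalized_oxidation",
                ),
            ],
            ignore_index=True,
        )
    except ValueError as exc:
        raise StageError("group_stats", str(exc)) from exc
    tests.to_csv(outdir / "04_group_stats.csv", index=False)

    lines = ["tracequant FAO pipeline summary", "=" * 32, ""]
    means = slopes.groupby("group", sort=False)[["slope_per_min", "mean_normalized_oxidation"]].mean()
    for group, row in means.iterrows():
        lines.append(
            f"  {group}: mean slope {row['slope_per_min']:.3e} min^-1, "
            f"mean normalized oxidation {row['mean_normalized_oxidation']:.4f}"
        )
    if no_rise:
        lines.append("")
        lines.append("Animals without a rising phase: " + ", ".join(a for a, _ in no_rise))
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    _write_log(config, outdir, n_inputs=len(traces))
    return slopes
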