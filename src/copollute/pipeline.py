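"""End-to-end orchestration: simulate/ingest -> QC -> aggregate -> type ->
trend -> risk -> spatial -> synergy -> report.

All scientific constants (typing thresholds, band edges, quotas, weights k,
permutation count) live in :class:`PipelineConfig` with the published values
as defaults; nothing is hard-coded inline. A fixed seed makes the whole run,
including the written report, byte-identical across invocations.
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

from . import exposure_risk, ingest_qc, pollution_typing, spatial_assoc, synergy, trend
from .synthetic_data import SyntheticConfig, generate_city_metadata, generate_daily_series, \
    generate_emissions

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _jsonify(obj):
    """Recursively convert numpy scalars so json.dump accepts the report."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


@dataclass
class PipelineConfig:
    outdir: str = "output"
    # input files; when series_csv is None the synthetic generator is used
    series_csv: str | None = None
    cities_csv: str | None = None
    emissions_csv: str | None = None
    synthetic: dict = field(default_factory=dict)
    seed: int = 0
    # scientific constants (defaults are the published values)
    pm_typing_threshold: float = 35.0
    o3_typing_threshold: float = 100.0
    pm_band_edges: tuple[float, float] = (25.0, 35.0)
    o3_band_edges: tuple[float, float] = (100.0, 120.0)
    monthly_quota: int = 27
    annual_quota: int = 360
    northern_calendar: bool = False
    trend_resolution: str = "month"  # month | year | day
    require_significance: int = 0  # 0 = sign-only direction; else 90/95/99
    classification_mode: str = "mean"  # mean | exceedance
    exceedance_fraction: float = 0.5
    weights_k: int = 5
    kernel_bandwidth: int = 15
    n_perm: int = 999

    def validate(self) -> None:
        if self.pm_band_edges[0] >= self.pm_band_edges[1]:
            raise PipelineError("PM2.5 band edges must be ordered")
        if self.o3_band_edges[0] >= self.o3_band_edges[1]:
            raise PipelineError("O3 band edges must be ordered")
        if self.trend_resolution not in ("month", "year", "day"):
            raise PipelineError(f"unknown trend_resolution {self.trend_resolution!r}")
        if self.classification_mode not in ("mean", "exceedance"):
            raise PipelineError(f"unknown classification_mode {self.classification_mode!r}")
        if self.n_perm < 1 or self.weights_k < 1:
            raise PipelineError("n_perm and weights_k must be >= 1")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    for key in ("pm_band_edges", "o3_band_edges"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                logger.info("stage %s: done", name)
                return out
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("inputs")
def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.series_csv is None:
        syn = SyntheticConfig(**{"seed": cfg.seed, **cfg.synthetic})
        metadata = generate_city_metadata(syn)
        series, truth = generate_daily_series(syn, metadata)
        emissions = generate_emissions(metadata, syn, truth)
        datadir = outdir / "data"
        datadir.mkdir(parents=True, exist_ok=True)
        out = series.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(datadir / "series.csv", index=False)
        metadata.to_csv(datadir / "cities.csv", index=False)
        emissions.to_csv(datadir / "emissions.csv", index=False)
        with open(datadir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
        raw = series
    else:
        raw = pd.read_csv(cfg.series_csv)
        metadata = pd.read_csv(cfg.cities_csv) if cfg.cities_csv else None
        emissions = pd.read_csv(cfg.emissions_csv) if cfg.emissions_csv else None
    if metadata is None or len(metadata) == 0:
        raise PipelineError("no cities: a metadata table with at least 2 cities is required")
    return raw, metadata, emissions


@_stage("trend")
def _trends(series: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.trend_resolution == "month":
        agg = ingest_qc.aggregate(series, "month", monthly_quota=cfg.monthly_quota,
                                  annual_quota=cfg.annual_quota)
        agg = agg[agg["is_valid"]]
        values = {key: grp.sort_values("period_key")["mean"].to_numpy()
                  for key, grp in agg.groupby(["city_id", "pollutant"])}
    elif cfg.trend_resolution == "year":
        agg = ingest_qc.aggregate(series, "year", monthly_quota=cfg.monthly_quota,
                                  annual_quota=cfg.annual_quota)
        agg = agg[agg["is_valid"]]
        values = {key: grp.sort_values("year")["mean"].to_numpy()
                  for key, grp in agg.groupby(["city_id", "pollutant"])}
    else:
        valid = series[series["valid"]]
        values = {key: grp.sort_values("date")["value"].to_numpy()
                  for key, grp in valid.groupby(["city_id", "pollutant"])}
    rows = []
    for (city, pol), x in sorted(values.items()):
        if x.size < 2:
            logger.info("trend skipped for %s/%s: %d points", city, pol, x.size)
            continue
        res = trend.mk_test(x)
        direction = res.direction
        if cfg.require_significance and res.sig_tier < cfg.require_significance:
            direction = "none"
        rows.append({"city_id": city, "pollutant": pol, "n": res.n, "S": res.s,
                     "var_S": res.var_s, "Z": res.z, "direction": direction,
                     "sig_tier": res.sig_tier})
    return pd.DataFrame(rows)


def _annual_panel(annual: pd.DataFrame, pollutant: str) -> pd.DataFrame:
    sub = annual[(annual["pollutant"] == pollutant) & annual["is_valid"]]
    return sub.pivot_table(index="city_id", columns="year", values="mean", aggfunc="first")


@_stage("spatial")
def _spatial(study: pd.DataFrame, annual: pd.DataFrame, metadata: pd.DataFrame,
             emissions: pd.DataFrame | None, cfg: PipelineConfig) -> dict:
    wide = (study[study["is_valid"]]
            .pivot_table(index="city_id", columns="pollutant", values="mean", aggfunc="first")
            .dropna())
    meta = metadata[metadata["city_id"].isin(wide.index)].sort_values("city_id")
    wide = wide.reindex(meta["city_id"])
    if len(meta) < cfg.weights_k + 1:
        logger.warning("spatial stage skipped: only %d dually valid cities", len(meta))
        return {"skipped": True, "n_cities": int(len(meta))}
    W = spatial_assoc.build_weights(meta, k=cfg.weights_k)
    moran = spatial_assoc.bimoran(wide["PM25"].to_numpy(), wide["O3"].to_numpy(), W,
                                  n_perm=cfg.n_perm, seed=cfg.seed)
    pm_panel = _annual_panel(annual, "PM25").reindex(meta["city_id"])
    o3_panel = _annual_panel(annual, "O3").reindex(meta["city_id"])
    local_corr = spatial_assoc.local_correlation(pm_panel, o3_panel, meta,
                                                 bandwidth=cfg.kernel_bandwidth)
    try:
        curvature = spatial_assoc.correlation_curvature(local_corr["local_r"].to_numpy(),
                                                        wide["PM25"].to_numpy())
    except ValueError as exc:
        logger.warning("curvature fit unavailable: %s", exc)
        curvature = None
    precursor = {}
    if emissions is not None:
        em = emissions.set_index("city_id").reindex(meta["city_id"])
        for col, pol in (("nox_tons", "PM25"), ("voc_tons", "O3")):
            if col in em.columns and em[col].notna().all():
                assoc = spatial_assoc.precursor_association(
                    em[col].to_numpy(), wide[pol].to_numpy(), W,
                    n_perm=cfg.n_perm, seed=cfg.seed)
                precursor[f"{col}_vs_{pol}"] = {
                    "global_i": assoc["bimoran"].global_i,
                    "global_pseudo_p": assoc["bimoran"].global_pseudo_p,
                    "pearson_r": assoc["pearson_r"],
                }
    return {"skipped": False, "weights": W, "moran": moran, "meta": meta,
            "local_corr": local_corr, "curvature": curvature, "precursor": precursor}


def run(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline and write all stage outputs plus report.json.

    Returns the report dict. Any stage failure aborts with the stage name.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    raw, metadata, emissions = _load_inputs(cfg, outdir)

    try:
        series, qc_report = ingest_qc.qc_filter(raw)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'qc' failed: {exc}") from exc
    (outdir / "qc_report.txt").write_text(qc_report.to_text())

    try:
        monthly = ingest_qc.aggregate(series, "month", metadata=metadata,
                                      northern_calendar=cfg.northern_calendar,
                                      monthly_quota=cfg.monthly_quota,
                                      annual_quota=cfg.annual_quota)
        seasonal = ingest_qc.aggregate(series, "season", metadata=metadata,
                                       northern_calendar=cfg.northern_calendar,
                                       monthly_quota=cfg.monthly_quota,
                                       annual_quota=cfg.annual_quota)
        annual = ingest_qc.aggregate(series, "year", metadata=metadata,
                                     monthly_quota=cfg.monthly_quota,
                                     annual_quota=cfg.annual_quota)
        study = ingest_qc.aggregate(series, "study-period", metadata=metadata,
                                    monthly_quota=cfg.monthly_quota,
                                    annual_quota=cfg.annual_quota)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'aggregate' failed: {exc}") from exc
    aggregates = pd.concat([monthly, seasonal, annual, study], ignore_index=True)
    aggregates.to_csv(outdir / "aggregates.csv", index=False)

    # pollution typing on annual and study-period means
    try:
        annual_types = pollution_typing.classify_table(
            annual.assign(period_key=annual["year"]),
            pm_threshold=cfg.pm_typing_threshold, o3_threshold=cfg.o3_typing_threshold)
        study_types = pollution_typing.classify_table(
            study, pm_threshold=cfg.pm_typing_threshold, o3_threshold=cfg.o3_typing_threshold)
        types = pd.concat([annual_types, study_types], ignore_index=True)
        types.to_csv(outdir / "pollution_types.csv", index=False)
        per_city, transitions = pollution_typing.type_transitions(annual_types)
        transitions.to_csv(outdir / "transitions.csv")
        per_city.to_csv(outdir / "transitions_per_city.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'typing' failed: {exc}") from exc

    mk = _trends(series, cfg)
    mk.to_csv(outdir / "mk_results.csv", index=False)

    try:
        edges = {"PM25": tuple(cfg.pm_band_edges), "O3": tuple(cfg.o3_band_edges)}
        risk = exposure_risk.label_cities(study, mk, edges=edges)
        risk.to_csv(outdir / "risk_labels.csv", index=False)
        pop = exposure_risk.population_by_risk(risk, metadata)
        pop.to_csv(outdir / "population_by_risk.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'risk' failed: {exc}") from exc

    spatial = _spatial(study, annual, metadata, emissions, cfg)
    if not spatial["skipped"]:
        moran: spatial_assoc.BiMoran = spatial["moran"]
        local_df = pd.DataFrame({
            "city_id": spatial["meta"]["city_id"].to_numpy(),
            "local_i": moran.local_i,
            "quadrant": list(moran.quadrant),
            "pseudo_p": moran.pseudo_p,
        })
        local_df.to_csv(outdir / "bimoran.csv", index=False)
        spatial["local_corr"].to_csv(outdir / "local_corr.csv", index=False)
        with open(outdir / "global_moran.json", "w") as fh:
            json.dump({"global_i": moran.global_i, "mean_local_i": float(moran.local_i.mean()),
                       "global_pseudo_p": moran.global_pseudo_p, "n_perm": moran.n_perm,
                       "seed": moran.seed}, fh, indent=2, sort_keys=True)

    try:
        years = sorted(annual.loc[annual["is_valid"], "year"].unique())
        syn_results = pd.DataFrame()
        syn_summary = None
        if len(years) >= 2:
            syn_results = synergy.classify_cities(annual, int(years[0]), int(years[-1]))
            if len(syn_results):
                syn_summary = synergy.synergy_summary(syn_results, metadata)
        syn_results.to_csv(outdir / "synergy.csv", index=False)
        if syn_summary is not None:
            with open(outdir / "synergy_summary.json", "w") as fh:
                json.dump(_jsonify(syn_summary), fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'synergy' failed: {exc}") from exc

    report = _build_report(cfg, qc_report, metadata, annual_types, study_types, transitions,
                           mk, risk, pop, spatial, syn_summary)
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
    return report


def _build_report(cfg, qc_report, metadata, annual_types, study_types, transitions,
                  mk, risk, pop, spatial, syn_summary) -> dict:
    shares_by_year = {}
    for year, grp in annual_types.groupby("period_key"):
        shares_by_year[str(year)] = pollution_typing.type_shares(grp).to_dict()
    study_shares = (pollution_typing.type_shares(study_types).to_dict()
                    if len(study_types) else {})
    risk_counts = {
        pol: risk[risk["pollutant"] == pol]["label"].value_counts().to_dict()
        for pol in ("PM25", "O3")
    }
    combined_counts = risk.dropna(subset=["combined"])["combined"].value_counts().to_dict()
    pop_totals = (pop.groupby("combined")["population_total"].sum().to_dict()
                  if len(pop) else {})
    spatial_summary: dict = {"skipped": spatial["skipped"]}
    if not spatial["skipped"]:
        moran = spatial["moran"]
        local_r = spatial["local_corr"]["local_r"].dropna()
        spatial_summary.update({
            "global_bimoran_i": moran.global_i,
            "global_pseudo_p": moran.global_pseudo_p,
            "quadrant_counts": pd.Series(moran.quadrant).value_counts().to_dict(),
            "local_correlation": {
                "n": int(local_r.size),
                "min": float(local_r.min()) if local_r.size else None,
                "median": float(local_r.median()) if local_r.size else None,
                "max": float(local_r.max()) if local_r.size else None,
            },
            "curvature": spatial["curvature"],
            "precursor": spatial["precursor"],
        })
    return {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "qc": {name: getattr(qc_report, name) for name in
               ("n_input", "n_dropped_unparseable", "n_flagged_above_max",
                "n_flagged_negative", "n_flagged_nonfinite",
                "n_duplicates_collapsed", "n_output")},
        "n_cities": int(len(metadata)),
        "type_shares_by_year": shares_by_year,
        "type_shares_study_period": study_shares,
        "transition_matrix": {r: transitions.loc[r].to_dict() for r in transitions.index},
        "trend_directions": mk.groupby(["pollutant", "direction"]).size()
                              .unstack(fill_value=0).to_dict() if len(mk) else {},
        "risk_label_counts": risk_counts,
        "combined_risk_counts": combined_counts,
        "population_by_combined_risk": pop_totals,
        "spatial": spatial_summary,
        "synergy": syn_summary,
    }
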