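"""Orchestration: seeded end-to-end runs and table I/O.

A run executes simulate -> observe -> quantify -> analyze and writes the
observation table, a statistics report (JSON) and a run manifest with
config hash and per-stage timings.  Identical (config, seed) pairs produce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import CohortConfig, default_config
from .quantify import classify_observations, cumulative_gfp, distance_zone_counts
from .simulate import Cohort, observe, simulate_cohort
from .stats import StatsError, binary_fit, group_compare, linear_fit, paired_compare

SCHEMA_VERSION = 1

OBSERVATION_COLUMNS = {
    "segment_id": "int64",
    "nephron_id": "int64",
    "mouse_id": "int64",
    "region": "object",
    "segment_class": "object",
    "day": "int64",
    "total_nuclei": "int64",
    "pi_pos": "int64",
    "gfp_pos": "int64",
    "gfp_near": "int64",
    "gfp_far": "int64",
    "pi_frac": "float64",
    "gfp_frac": "float64",
    "pi0_frac": "float64",
    "cast_fraction": "float64",
    "cross_section_um2": "float64",
    "morphology": "object",
    "mean_green": "float64",
    "mean_blue": "float64",
    "albumin_apical": "float64",
    "albumin_capillary": "float64",
    "fate": "object",
    "fate_day": "float64",
    "distance_to_target_um": "float64",
    "is_laser_target": "bool",
    "schema_version": "int64",
}


class SchemaError(ValueError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    software_version: str
    protocol: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


# ---------------------------------------------------------------------------
# table I/O


def write_observations(obs: pd.DataFrame, path: str | Path) -> Path:
    """Write the observation table (CSV or Parquet by extension).

    UTF-8, '.' decimal, days as ISO integers; a ``schema_version`` column
    makes the dialect self-describing.
    """
    path = Path(path)
    out = obs.copy()
    out["schema_version"] = SCHEMA_VERSION
    if path.suffix == ".parquet":
        out.to_parquet(path, index=False)
    elif path.suffix == ".csv":
        out.to_csv(path, index=False)
    else:
        raise SchemaError(f"unsupported table format: {path.suffix}")
    return path


def read_observations(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    elif path.suffix == ".csv":
        df = pd.read_csv(path)
    else:
        raise SchemaError(f"unsupported table format: {path.suffix}")
    validate_observations(df)
    version = int(df["schema_version"].iloc[0]) if len(df) else SCHEMA_VERSION
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unknown schema version {version} (supported: {SCHEMA_VERSION})")
    return df.drop(columns=["schema_version"])


def validate_observations(df: pd.DataFrame) -> None:
    """Fail fast with the name of the first offending column."""
    for col in OBSERVATION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing column: {col!r}")
    extra = set(df.columns) - set(OBSERVATION_COLUMNS)
    if extra:
        raise SchemaError(f"unknown column: {sorted(extra)[0]!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# statistics report


def necrosis_report(obs: pd.DataFrame) -> dict:
    """Day-0 necrosis means by region and class, with mixed-model contrasts."""
    d0 = obs[obs["day"] == 0]
    out: dict = {"mean_pi_pct_by_region": {}, "mean_pi_pct_by_class": {}}
    for region, grp in d0.groupby("region"):
        out["mean_pi_pct_by_region"][region] = float(100 * grp["pi_frac"].mean())
    ir = d0[d0["region"] == "IR"]
    for cls, grp in ir.groupby("segment_class"):
        out["mean_pi_pct_by_class"][cls] = float(100 * grp["pi_frac"].mean())
    try:
        sel = d0[d0["region"].isin(["IR", "Mid"])]
        cmp_ = group_compare(sel["pi_frac"], sel["region"], sel["mouse_id"])
        out["ir_vs_mid"] = cmp_.to_dict()
    except (StatsError, KeyError):
        pass
    try:
        pts = ir[ir["segment_class"].isin(["PT-S1", "PT-S2"])]
        cmp_ = group_compare(pts["pi_frac"], pts["segment_class"], pts["mouse_id"])
        out["s1_vs_s2"] = cmp_.to_dict()
    except (StatsError, KeyError):
        pass
    return out


def proximity_report(obs: pd.DataFrame, days=(1, 2, 3)) -> dict:
    """Near/far cumulative cycling and the necrosis->proliferation regression.

    The near/far analysis runs on segments with at least one day-0 PI+
    nucleus (the 25 um near zone is undefined otherwise).
    """
    cum = cumulative_gfp(obs, days=days)
    pi0 = obs[obs["day"] == 0].set_index("segment_id")["pi0_frac"]
    cum = cum.assign(pi0=pi0.reindex(cum["segment_id"]).to_numpy())
    nec = cum[cum["pi0"] > 0]
    out: dict = {
        "near_mean_pct": float(100 * nec["near_frac"].mean()),
        "far_mean_pct": float(100 * nec["far_frac"].mean()),
        "n_segments": int(len(nec)),
    }
    if len(nec) >= 2:
        out["paired_test"] = paired_compare(nec["near_frac"], nec["far_frac"]).to_dict()
    # cumulative cycling vs day-0 necrosis, per PT class
    meta = obs[obs["day"] == 0].set_index("segment_id")
    merged = cum.join(meta[["segment_class", "mouse_id"]], on="segment_id")
    pts = merged[merged["segment_class"].isin(["PT-S1", "PT-S2"])].dropna(
        subset=["pi0", "gfp_cum_frac"]
    )
    try:
        fit = linear_fit(
            100 * pts["pi0"],
            100 * pts["gfp_cum_frac"],
            groups=pts["segment_class"],
            cluster_ids=pts["mouse_id"],
        )
        out["necrosis_regression"] = fit.to_dict()
    except StatsError:
        pass
    return out


def cast_report(obs: pd.DataFrame) -> dict:
    """Cast accumulation by class/necrosis and the cast->cycling regression."""
    sel = obs[obs["day"].isin([1, 2, 3])]
    out: dict = {"cast_pct_days_1_3": {}}
    for cls in ("PT-S1", "PT-S2"):
        cdf = sel[sel["segment_class"] == cls]
        nn = cdf["pi0_frac"] <= 0.01
        out["cast_pct_days_1_3"][cls] = {
            "non_necrotic": float(100 * cdf.loc[nn, "cast_fraction"].mean()) if nn.any() else 0.0,
            "necrotic": float(100 * cdf.loc[~nn, "cast_fraction"].mean()) if (~nn).any() else 0.0,
        }
    # cast at day t vs far cycling at day t+1 in PT-S2
    days = sorted(obs["day"].unique())
    pairs = [(d, d + 1) for d in days if d + 1 in days and d >= 1]
    rows = []
    for d0_, d1_ in pairs:
        a = obs[(obs["day"] == d0_) & (obs["segment_class"] == "PT-S2")]
        b = obs[(obs["day"] == d1_)].set_index("segment_id")
        for _, r in a.iterrows():
            if r["segment_id"] in b.index:
                nxt = b.loc[r["segment_id"]]
                rows.append(
                    {
                        "cast_pct": 100 * r["cast_fraction"],
                        "gfp_far_next_pct": 100 * nxt["gfp_far"] / max(nxt["total_nuclei"], 1),
                        "mouse_id": r["mouse_id"],
                        "non_necrotic": r["pi0_frac"] <= 0.01,
                    }
                )
    if rows:
        df = pd.DataFrame(rows)
        try:
            fit = linear_fit(df["cast_pct"], df["gfp_far_next_pct"], cluster_ids=df["mouse_id"])
            out["cast_to_cycling_regression"] = fit.to_dict()
        except StatsError:
            pass
    return out


def fate_report(obs: pd.DataFrame, severe_cast_threshold: float = 0.25) -> dict:
    """Fate distribution, timing, and the cast->atrophy binary regression."""
    days = obs["day"].unique()
    if 21 not in days:
        return {}
    last = obs[obs["day"] == 21]
    d34 = obs[obs["day"] == 4]
    out: dict = {
        "fate_counts": last["fate"].value_counts().to_dict(),
        "fate_by_region": {
            r: g["fate"].value_counts(normalize=True).round(4).to_dict()
            for r, g in last.groupby("region")
        },
    }
    atro = last[last["fate"] == "atrophic"]
    rec = last[last["fate"] == "recovered"]
    if len(atro):
        out["atrophic_share_in_ir_pct"] = float(100 * (atro["region"] == "IR").mean())
        out["atrophic_zero_day0_necrosis_pct"] = float(100 * (atro["pi0_frac"] == 0).mean())
    if len(rec):
        out["recovered_determined_by_day7_pct"] = float(100 * (rec["fate_day"] <= 7).mean())
    if len(atro):
        out["atrophic_determined_by_day7_pct"] = float(100 * (atro["fate_day"] <= 7).mean())
    sev = d34[d34["cast_fraction"] >= severe_cast_threshold]
    if len(sev):
        out["severely_casted_atrophic_pct"] = float(100 * (sev["fate"] == "atrophic").mean())
    g34 = d34.set_index("segment_id")["gfp_frac"]
    if len(atro) and len(rec):
        out["gfp_day34_pct"] = {
            "atrophic": float(100 * g34.reindex(atro["segment_id"]).mean()),
            "recovered": float(100 * g34.reindex(rec["segment_id"]).mean()),
        }
    try:
        fit = binary_fit(
            100 * d34["cast_fraction"],
            (d34["fate"] == "atrophic").astype(int),
            cluster_ids=d34["mouse_id"],
        )
        out["cast_to_atrophy_regression"] = fit.to_dict()
    except StatsError:
        pass
    # PT-S1 albumin reuptake by fate over time
    alb = obs[(obs["segment_class"] == "PT-S1") & obs["albumin_apical"].notna()].copy()
    if len(alb):
        alb["ratio"] = alb["albumin_apical"] / alb["albumin_capillary"]
        out["albumin_reuptake_by_fate"] = {
            f: {int(d): float(g2["ratio"].mean()) for d, g2 in g.groupby("day")}
            for f, g in alb.groupby("fate")
        }
    return out


def laser_report(obs: pd.DataFrame, config: CohortConfig) -> dict:
    """Casted-vs-uncasted PT-S2 contrast and the distance-zone control."""
    day = 2 if 2 in set(obs["day"]) else int(obs["day"].max())
    d2 = obs[(obs["day"] == day) & (obs["segment_class"] == "PT-S2") & ~obs["is_laser_target"]]
    casted = d2["cast_fraction"] > config.casts.detect_min_fraction
    out: dict = {
        "day": day,
        "gfp_pct_casted": float(100 * d2.loc[casted, "gfp_frac"].mean()) if casted.any() else 0.0,
        "gfp_pct_uncasted": float(100 * d2.loc[~casted, "gfp_frac"].mean())
        if (~casted).any()
        else 0.0,
        "n_casted": int(casted.sum()),
        "n_uncasted": int((~casted).sum()),
    }
    try:
        cmp_ = group_compare(
            d2["gfp_frac"], np.where(casted, "casted", "uncasted"), d2["mouse_id"]
        )
        out["casted_vs_uncasted"] = cmp_.to_dict()
    except StatsError:
        pass
    edges = config.laser.zone_edges_um
    zones = tuple(zip(edges[:-1], edges[1:]))
    zdf = distance_zone_counts(
        obs[obs["day"] == day], zones=zones, target_radius_um=config.laser.target_radius_um
    )
    out["distance_zones"] = zdf.to_dict("records")
    return out


def build_report(obs: pd.DataFrame, config: CohortConfig) -> dict:
    report: dict = {
        "protocol": config.protocol,
        "seed": config.seed,
        "n_segments": int(obs["segment_id"].nunique()),
        "n_mice": int(obs["mouse_id"].nunique()),
    }
    if config.protocol == "laser":
        report["laser"] = laser_report(obs, config)
        return report
    report["necrosis"] = necrosis_report(obs)
    if set(config.schedule_days) >= {1, 2, 3}:
        report["proximity"] = proximity_report(obs)
        report["casts"] = cast_report(obs)
    if 21 in config.schedule_days:
        report["fates"] = fate_report(obs, config.fate.severe_cast_threshold)
        report["gfp_pct_by_day"] = {
            int(d): float(100 * g["gfp_frac"].mean()) for d, g in obs.groupby("day")
        }
    return report


# ---------------------------------------------------------------------------
# end-to-end run


def run_experiment(
    config: CohortConfig | str | Path | None = None,
    seed: int | None = None,
    output_dir: str | Path = "results",
    protocol: str | None = None,
    table_format: str = "csv",
) -> tuple[RunManifest, pd.DataFrame, dict]:
    """Execute a full seeded run and write tables, report and manifest."""
    if config is None:
        config = default_config(protocol or "partial_iri_long", seed=seed or 0)
    elif isinstance(config, (str, Path)):
        config = CohortConfig.from_yaml(config)
    if protocol is not None:
        config = config.replace(protocol=protocol)
    if seed is not None:
        config = config.replace(seed=seed)
    config.validate()

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        software_version=__version__,
        protocol=config.protocol,
    )

    t0 = time.perf_counter()
    cohort: Cohort = simulate_cohort(config)
    manifest.stage_seconds["simulate"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    obs = observe(cohort)
    manifest.stage_seconds["observe"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    report = build_report(obs, config)
    manifest.stage_seconds["analyze"] = round(time.perf_counter() - t0, 3)

    table_path = outdir / f"observations_{config.protocol}.{table_format}"
    write_observations(obs, table_path)
    report_path = outdir / f"report_{config.protocol}.json"
    report_path.write_text(json.dumps(report, indent=1, default=float))
    config_path = outdir / f"config_{config.protocol}.yaml"
    config.to_yaml(config_path)
    for p in (table_path, report_path, config_path):
        manifest.outputs[p.name] = _sha256(p)
    manifest.to_json(outdir / f"manifest_{config.protocol}.json")
    return manifest, obs, report
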