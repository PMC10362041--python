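"""Recompute the study-level summary statistics from scratch.

Each function simulates the relevant default cohort(s) from a root seed and
measures the quantity with the package's own operators.  Cohort-mean
quantities are averaged over a few replicate cohorts to reduce seed-level
Monte-Carlo error; fate-level quantities use a scaled cohort (~10^4
segments, mice scaled in proportion so the per-mouse load stays fixed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig, default_config
from .quantify import (
    classify_fates_table,
    classify_observations,
    count_nuclei_volumetric,
    proximity_split,
)
from .simulate import Cohort, build_cohort, observe, seed_necrosis, simulate_cohort
from .stats import binary_fit, paired_compare


def replicate_seeds(root_seed: int, n: int, stream: int = 0) -> list[int]:
    """Derive independent child seeds (< 2^31) from one root seed."""
    ss = np.random.SeedSequence([int(root_seed) % (2**31), stream])
    return [int(s % (2**31)) for s in ss.generate_state(n)]


def _scaled(cfg: CohortConfig, scale: int) -> CohortConfig:
    if scale == 1:
        return cfg
    return cfg.replace(
        cohort={
            "nephrons_per_region": {
                k: v * scale for k, v in cfg.cohort.nephrons_per_region.items()
            },
            "n_mice": cfg.cohort.n_mice * scale,
        }
    )


# ---------------------------------------------------------------------------
# day-0 necrosis (volumetric counting + autofluorescence classification)


def day0_necrosis_stats(root_seed: int, n_reps: int = 12, scale: int = 1) -> dict:
    """Mean day-0 PI+ percentages: IR, Mid, and classified PT-S1 within IR."""
    rows = []
    for seed in replicate_seeds(root_seed, n_reps, stream=1):
        cfg = _scaled(default_config("partial_iri_long", seed=seed), scale)
        cohort = seed_necrosis(build_cohort(cfg))
        from .model import ObservationSchedule

        obs0 = observe(cohort, schedule=ObservationSchedule((0,))).copy()
        counted = {
            s.segment_id: count_nuclei_volumetric(s, day=0) for s in cohort.segments
        }
        obs0["pi_pct"] = [
            100 * counted[sid][1] / counted[sid][0] for sid in obs0["segment_id"]
        ]
        obs0["classified"] = classify_observations(obs0, cfg.optics)
        rows.append(obs0)
    d0 = pd.concat(rows, ignore_index=True)
    ir = d0[d0["region"] == "IR"]
    return {
        "ir_mean_pi_pct": float(ir["pi_pct"].mean()),
        "mid_mean_pi_pct": float(d0.loc[d0["region"] == "Mid", "pi_pct"].mean()),
        "not_ir_mean_pi_pct": float(d0.loc[d0["region"] == "Not-IR", "pi_pct"].mean()),
        "pt_s1_classified_pi_pct": float(ir.loc[ir["classified"] == "PT-S1", "pi_pct"].mean()),
        "pt_s2_classified_pi_pct": float(ir.loc[ir["classified"] == "PT-S2", "pi_pct"].mean()),
        "mouse_se": {
            "ir": _mouse_se(ir, "pi_pct"),
            "mid": _mouse_se(d0[d0["region"] == "Mid"], "pi_pct"),
            "pt_s1": _mouse_se(ir[ir["classified"] == "PT-S1"], "pi_pct"),
        },
        "n_segments": int(len(d0)),
    }


def _mouse_se(df: pd.DataFrame, col: str) -> float:
    by_mouse = df.groupby("mouse_id")[col].mean()
    if len(by_mouse) < 2:
        return float("nan")
    return float(by_mouse.std(ddof=1) / np.sqrt(len(by_mouse)))


# ---------------------------------------------------------------------------
# proximity split (days 1-3 cumulative cycling near/far of day-0 necrosis)


def proximity_stats(root_seed: int, n_reps: int = 6) -> dict:
    """Near/far cumulative reporter fractions on necrotic segments.

    ``proximity_split`` runs per segment against the frozen day-0 PI+
    positions; the analysis set is segments with at least one day-0 PI+
    nucleus (the near zone is undefined otherwise).
    """
    near_fracs, far_fracs = [], []
    for seed in replicate_seeds(root_seed, n_reps, stream=2):
        cfg = default_config("partial_iri_short", seed=seed)
        cohort = simulate_cohort(cfg)
        for i, nephron in enumerate(cohort.nephrons):
            pi_pos = cohort._day0_pi_positions[i]
            for seg in nephron.segments:
                if not any(c.pi_positive for c in seg.cells):
                    continue
                gfp_pos = [
                    c.axial_pos
                    for c in seg.cells
                    if c.gfp_interval is not None and 1 <= c.gfp_interval[0] <= 3
                ]
                near, far = proximity_split(gfp_pos, pi_pos, cfg.proliferation.r_prox_um)
                total = len(seg.epithelial_cells())
                if total == 0:
                    continue
                near_fracs.append(100 * near / total)
                far_fracs.append(100 * far / total)
    test = paired_compare(near_fracs, far_fracs)
    return {
        "near_mean_pct": float(np.mean(near_fracs)),
        "far_mean_pct": float(np.mean(far_fracs)),
        "n_segments": len(near_fracs),
        "paired_t": float(test.t_statistic),
        "paired_p": float(test.p_value),
    }


# ---------------------------------------------------------------------------
# granular casts (days 1-3, by class and necrosis status)


def cast_stats(root_seed: int, n_reps: int = 16) -> dict:
    rows = []
    for seed in replicate_seeds(root_seed, n_reps, stream=3):
        cfg = default_config("partial_iri_short", seed=seed)
        obs = observe(simulate_cohort(cfg))
        rows.append(obs[obs["day"].isin([1, 2, 3])])
    d13 = pd.concat(rows, ignore_index=True)
    nn = d13["pi0_frac"] <= 0.01
    s2 = d13["segment_class"] == "PT-S2"
    s1 = d13["segment_class"] == "PT-S1"
    return {
        "pt_s2_non_necrotic_cast_pct": float(100 * d13.loc[s2 & nn, "cast_fraction"].mean()),
        "pt_s2_necrotic_cast_pct": float(100 * d13.loc[s2 & ~nn, "cast_fraction"].mean()),
        "pt_s1_non_necrotic_cast_pct": float(100 * d13.loc[s1 & nn, "cast_fraction"].mean()),
        "pt_s1_necrotic_cast_pct": float(100 * d13.loc[s1 & ~nn, "cast_fraction"].mean()),
    }


# ---------------------------------------------------------------------------
# fate layer (large-sample long-term cohort)


def fate_stats(root_seed: int, scale: int = 14, bootstrap: int = 0, n_reps: int = 1) -> dict:
    """Atrophy structure at ~10^4 segments.

    The binary regression uses the day-3/4 cast area percentage; fates and
    fate days come from morphology-trajectory classification at day 21.
    With ``bootstrap`` > 0, mouse-level bootstrap standard errors are
    attached for every statistic.  With ``n_reps`` > 1 the statistics are
    averaged over independent replicate cohorts.
    """
    if n_reps > 1:
        reps = [
            fate_stats(s, scale=scale, bootstrap=0, n_reps=1)
            for s in replicate_seeds(root_seed, n_reps, stream=7)
        ]
        out = {
            k: float(np.mean([r[k] for r in reps]))
            for k in reps[0]
            if isinstance(reps[0][k], float)
        }
        out["n_segments"] = int(sum(r["n_segments"] for r in reps))
        return out
    seed = replicate_seeds(root_seed, 1, stream=4)[0]
    cfg = _scaled(default_config("partial_iri_long", seed=seed), scale)
    cohort = simulate_cohort(cfg)
    obs = observe(cohort)
    fates = classify_fates_table(obs, cfg.fate.necrotic_flag_threshold).set_index("segment_id")
    d34 = obs[obs["day"] == 4].set_index("segment_id")
    d0 = obs[obs["day"] == 0].set_index("segment_id")
    df = pd.DataFrame(
        {
            "cast_pct": 100 * d34["cast_fraction"],
            "gfp34_pct": 100 * d34["gfp_frac"],
            "region": d34["region"],
            "mouse_id": d34["mouse_id"],
            "pi0": d0["pi0_frac"],
            "fate": fates["fate"],
            "fate_day": fates["fate_day"],
        }
    ).dropna(subset=["fate"])

    def compute(frame: pd.DataFrame) -> dict:
        atro = frame[frame["fate"] == "atrophic"]
        rec = frame[frame["fate"] == "recovered"]
        fit = binary_fit(frame["cast_pct"], (frame["fate"] == "atrophic").astype(int))
        sev = frame[frame["cast_pct"] >= 100 * cfg.fate.severe_cast_threshold]
        return {
            "binary_r2_response": float(fit.r_squared_response),
            "binary_odds_ratio": float(fit.odds_ratio),
            "severely_casted_atrophic_pct": float(100 * (sev["fate"] == "atrophic").mean()),
            "atrophic_share_in_ir_pct": float(100 * (atro["region"] == "IR").mean()),
            "recovered_determined_by_day7_pct": float(100 * (rec["fate_day"] <= 7).mean()),
            "gfp_day34_atrophic_pct": float(atro["gfp34_pct"].mean()),
            "gfp_day34_recovered_pct": float(rec["gfp34_pct"].mean()),
            "atrophic_zero_day0_necrosis_pct": float(100 * (atro["pi0"] == 0).mean()),
        }

    out = compute(df)
    out["n_segments"] = int(len(df))
    if bootstrap > 0:
        rng = np.random.default_rng(replicate_seeds(root_seed, 1, stream=5)[0])
        mice = df["mouse_id"].unique()
        groups = {m: g for m, g in df.groupby("mouse_id")}
        samples: dict[str, list[float]] = {k: [] for k in out if k != "n_segments"}
        for _ in range(bootstrap):
            pick = rng.choice(mice, size=len(mice), replace=True)
            frame = pd.concat([groups[m] for m in pick], ignore_index=True)
            try:
                stats = compute(frame)
            except Exception:
                continue
            for k, v in stats.items():
                samples[k].append(v)
        out["bootstrap_se"] = {
            k: float(np.nanstd(np.asarray(v), ddof=1)) if len(v) > 2 else float("nan")
            for k, v in samples.items()
        }
    return out


# ---------------------------------------------------------------------------
# laser injury


def laser_stats(root_seed: int, n_reps: int = 4) -> dict:
    frames = []
    zone_frames = []
    for seed in replicate_seeds(root_seed, n_reps, stream=6):
        cfg = default_config("laser", seed=seed)
        obs = observe(simulate_cohort(cfg))
        d2 = obs[(obs["day"] == 2) & (obs["segment_class"] == "PT-S2") & ~obs["is_laser_target"]]
        frames.append(d2.assign(casted=d2["cast_fraction"] > cfg.casts.detect_min_fraction))
        from .quantify import distance_zone_counts

        zone_frames.append(
            distance_zone_counts(
                obs[obs["day"] == 2], target_radius_um=cfg.laser.target_radius_um
            )
        )
    d2 = pd.concat(frames, ignore_index=True)
    zones = pd.concat(zone_frames).groupby(["zone_lo_um", "zone_hi_um"], as_index=False).sum()
    zones["gfp_per_1e4_um2"] = zones["gfp_per_1e4_um2"] / n_reps
    return {
        "casted_gfp_pct": float(100 * d2.loc[d2["casted"], "gfp_frac"].mean()),
        "uncasted_gfp_pct": float(100 * d2.loc[~d2["casted"], "gfp_frac"].mean()),
        "n_casted": int(d2["casted"].sum()),
        "zone_density": zones["gfp_per_1e4_um2"].tolist(),
    }


# ---------------------------------------------------------------------------
# one-call summary of every replicated quantity


def compute_summary(root_seed: int, fate_scale: int = 10) -> dict:
    """All replicated cohort statistics from one root seed."""
    return {
        "necrosis": day0_necrosis_stats(root_seed),
        "proximity": proximity_stats(root_seed),
        "casts": cast_stats(root_seed),
        "fates": fate_stats(root_seed, scale=fate_scale, n_reps=2),
        "laser": laser_stats(root_seed),
    }
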