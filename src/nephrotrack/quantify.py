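"""Measurement operators for per-segment quantification.

Every operator has a dual path: it accepts either simulator state / tables
(lossless "table path") or rendered image stacks (via :mod:`.imaging`).
Units follow the conventions of intravital quantification: fractions are
stored in [0, 1] and reported as percentages; distances in um.

Boundary conventions: a tubule is *necrotic* iff its day-0 PI+ fraction is
strictly > 1%; *severe* necrosis is strictly > 20% (20% itself is moderate);
a cycling cell is *near* a necrotic nucleus iff its distance is strictly
< 25 um.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .config import OpticsParams
from .model import TubuleSegment


class QuantificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# nuclei counting


def count_nuclei_volumetric(target, day: int | None = None, optics: OpticsParams | None = None):
    """(total, PI+, reporter+) nuclei of one segment, counted volumetrically.

    Table path: exact counts from the segment's cell states at ``day``.
    Image path (a :class:`~nephrotrack.imaging.ChannelStack`): nuclei are
    detected as negative-stain voids on five evenly spaced planes spanning
    the central 25 um and de-duplicated by xy-overlap across planes.
    """
    if isinstance(target, TubuleSegment):
        if day is None:
            raise QuantificationError("table path requires the observation day")
        return target.counts(day)
    from . import imaging

    return imaging.count_nuclei_stack(target, optics=optics)


# ---------------------------------------------------------------------------
# segment classification from autofluorescence


def classify_segment(
    mean_green: float, mean_blue: float, optics: OpticsParams | None = None
) -> str:
    """Assign PT-S1 / PT-S2 / DCT-CD from 750 nm channel means.

    Classification uses the green/blue emission ratio together with overall
    brightness (nearest class centre in a scaled (ratio, log-brightness)
    plane).  Severe necrosis collapses blue autofluorescence, which drives
    the segment dark and ratio-high: such segments are 'unclassifiable'.
    """
    optics = optics or OpticsParams()
    if mean_blue <= 0 or not np.isfinite(mean_blue) or not np.isfinite(mean_green):
        return "unclassifiable"
    if mean_blue < optics.min_blue:
        return "unclassifiable"
    ratio = mean_green / mean_blue
    if ratio > optics.max_ratio:
        return "unclassifiable"
    brightness = mean_green + mean_blue
    best, best_score = "unclassifiable", math.inf
    for cls in optics.blue_mean:
        r_c = optics.green_mean[cls] / optics.blue_mean[cls]
        b_c = optics.green_mean[cls] + optics.blue_mean[cls]
        score = ((ratio - r_c) / optics.ratio_scale) ** 2 + (
            math.log(brightness / b_c) / optics.log_brightness_scale
        ) ** 2
        if score < best_score:
            best, best_score = cls, score
    return best


def classify_observations(obs: pd.DataFrame, optics: OpticsParams | None = None) -> pd.Series:
    """Vectorised :func:`classify_segment` over an observation table."""
    return pd.Series(
        [classify_segment(g, b, optics) for g, b in zip(obs["mean_green"], obs["mean_blue"])],
        index=obs.index,
        name="classified_class",
    )


# ---------------------------------------------------------------------------
# spatial proximity


def proximity_split(
    gfp_positions: Sequence[float] | np.ndarray,
    day0_pi_positions: Sequence[float] | np.ndarray,
    r_prox_um: float = 25.0,
) -> tuple[int, int]:
    """Partition reporter+ nuclei into (<25 um, >=25 um) of day-0 necrosis.

    A reporter-positive nucleus is *near* iff its minimum distance to any
    day-0 PI+ nucleus is strictly below ``r_prox_um``.  The partition is
    exhaustive and exclusive; with no day-0 necrosis every nucleus is far.
    """
    gfp = np.atleast_1d(np.asarray(gfp_positions, dtype=float))
    pi = np.atleast_1d(np.asarray(day0_pi_positions, dtype=float))
    if gfp.size == 0:
        return (0, 0)
    if pi.size == 0:
        return (0, int(gfp.size))
    if gfp.ndim == 1:
        gfp = gfp[:, None]
    if pi.ndim == 1:
        pi = pi[:, None]
    d = np.sqrt(((gfp[:, None, :] - pi[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    near = int((d < r_prox_um).sum())
    return near, int(gfp.size) - near


# ---------------------------------------------------------------------------
# granular casts


def cast_area_fraction(target, optics: OpticsParams | None = None) -> tuple[float, bool]:
    """Luminal solid area as % of cross-sectional area at the widest plane.

    Returns ``(percentage, collapsed)``; ``collapsed`` flags atrophic
    tubules whose lumen is no longer patent, where the area normalisation
    is unreliable.
    """
    if isinstance(target, TubuleSegment):
        return 100.0 * target.cast_fraction, target.morphology == "atrophic"
    from . import imaging

    return imaging.cast_fraction_stack(target, optics=optics)


# ---------------------------------------------------------------------------
# necrosis severity classes


def necrosis_class(pi_fraction: float) -> tuple[str, bool]:
    """Severity class of day-0 necrosis and the >1% 'necrotic' flag.

    0 -> non-necrotic; (0, 0.20] -> moderate; > 0.20 -> severe.
    """
    if not 0.0 <= pi_fraction <= 1.0:
        raise QuantificationError(f"pi_fraction {pi_fraction} outside [0, 1]")
    if pi_fraction == 0.0:
        label = "non-necrotic"
    elif pi_fraction <= 0.20:
        label = "moderate"
    else:
        label = "severe"
    return label, pi_fraction > 0.01


# ---------------------------------------------------------------------------
# tubule fate


def classify_fate(trajectory: pd.DataFrame, necrotic_threshold: float = 0.01):
    """Terminal fate of one segment from its long-term morphology trajectory.

    Expects one row per observation day with columns ``day``, ``morphology``
    and ``pi0_frac``.  Atrophic: terminal morphology 'atrophic'.  Recovered:
    day-0 PI+ > 1% with regained normal epithelium.  Uninjured: PI-negative
    and preserved.  ``fate_day`` is the first observation day at which the
    terminal morphology is held through the end.  Trajectories truncated
    before day 14 are 'undetermined' (not an error).
    """
    traj = trajectory.sort_values("day")
    days = traj["day"].to_numpy()
    if days.size == 0 or days.max() < 14:
        return "undetermined", None
    morph = traj["morphology"].to_numpy()
    terminal = morph[-1]
    # first day of the final consecutive run of the terminal morphology
    idx = len(morph) - 1
    while idx > 0 and morph[idx - 1] == terminal:
        idx -= 1
    fate_day = int(days[idx])
    pi0 = float(traj["pi0_frac"].iloc[0])
    if terminal == "atrophic":
        return "atrophic", fate_day
    if terminal == "normal":
        if pi0 > necrotic_threshold:
            return "recovered", fate_day
        return "uninjured", fate_day
    return "undetermined", None


def classify_fates_table(obs: pd.DataFrame, necrotic_threshold: float = 0.01) -> pd.DataFrame:
    """Apply :func:`classify_fate` to every segment of an observation table."""
    out = []
    for seg_id, traj in obs.groupby("segment_id"):
        fate, fate_day = classify_fate(traj, necrotic_threshold)
        out.append(
            {
                "segment_id": seg_id,
                "fate": fate,
                "fate_day": fate_day if fate_day is not None else np.nan,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# albumin reuptake


def albumin_reuptake_ratio(apical_intensity: float, capillary_intensity: float) -> float:
    """Apical / peritubular-capillary Alexa-albumin intensity ratio.

    Returns NaN (undefined) when the capillary reference signal is zero.
    """
    if apical_intensity < 0 or capillary_intensity < 0:
        raise QuantificationError("intensities must be non-negative")
    if capillary_intensity == 0:
        return float("nan")
    return apical_intensity / capillary_intensity


# ---------------------------------------------------------------------------
# laser-injury distance zones


def distance_zone_counts(
    obs_day: pd.DataFrame,
    zones: Sequence[tuple[float, float]] = ((0.0, 35.0), (35.0, 85.0), (85.0, 135.0)),
    target_radius_um: float = 20.0,
) -> pd.DataFrame:
    """Area-normalised GFP+ nuclei per distance zone around a laser site.

    ``obs_day`` holds one observation day of a laser cohort; the injured
    segment itself is excluded.  Counts are normalised by the annulus area
    of each zone measured from the target's basolateral membrane.
    """
    prev_hi = -math.inf
    for lo, hi in zones:
        if hi <= lo or lo < prev_hi:
            raise QuantificationError(f"zones must be non-overlapping and increasing: {zones}")
        prev_hi = hi
    df = obs_day[~obs_day["is_laser_target"]]
    rows = []
    for lo, hi in zones:
        sel = df[(df["distance_to_target_um"] >= lo) & (df["distance_to_target_um"] < hi)]
        area = math.pi * ((hi + target_radius_um) ** 2 - (lo + target_radius_um) ** 2)
        rows.append(
            {
                "zone_lo_um": lo,
                "zone_hi_um": hi,
                "n_segments": len(sel),
                "gfp_count": int(sel["gfp_pos"].sum()),
                "gfp_per_1e4_um2": 1e4 * sel["gfp_pos"].sum() / area,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bolus arrival


def bolus_arrival(
    trace: Sequence[float] | np.ndarray,
    frame_rate_hz: float = 13.7,
    threshold: float | None = None,
    sustain_frames: int = 3,
) -> float | None:
    """First sustained threshold crossing of a luminal dye trace (seconds).

    The default threshold is half-maximum.  Returns None if the trace never
    crosses for ``sustain_frames`` consecutive frames.
    """
    y = np.asarray(trace, dtype=float)
    if y.size == 0:
        return None
    thr = threshold if threshold is not None else 0.5 * float(y.max())
    if thr <= 0:
        return None
    above = y >= thr
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= sustain_frames:
            return (i - sustain_frames + 1) / frame_rate_hz
    return None


# ---------------------------------------------------------------------------
# derived cohort summaries


def cumulative_gfp(obs: pd.DataFrame, days: Sequence[int] = (1, 2, 3)) -> pd.DataFrame:
    """Per-segment cumulative reporter+ fractions over the given days.

    With the transient (single-day-visible) reporter every visible cell is
    unique, so the cumulative unique count equals the sum of daily counts.
    Fractions are normalised by the nuclei count at the last included day.
    """
    sel = obs[obs["day"].isin(days)]
    agg = sel.groupby("segment_id").agg(
        gfp_cum=("gfp_pos", "sum"),
        gfp_near_cum=("gfp_near", "sum"),
        gfp_far_cum=("gfp_far", "sum"),
        last_total=("total_nuclei", "last"),
    )
    # a fully destroyed segment (all nuclei shed) has no reporter activity
    denom = agg["last_total"].where(agg["last_total"] > 0, 1)
    agg["gfp_cum_frac"] = agg["gfp_cum"] / denom
    agg["near_frac"] = agg["gfp_near_cum"] / denom
    agg["far_frac"] = agg["gfp_far_cum"] / denom
    return agg.reset_index()
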