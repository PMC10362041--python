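"""Configuration tree for the cohort simulator and pipeline.

All tunable parameters — cohort layout, injury severity, cast transport,
proliferation kinetics, fate model, optics — live in one YAML file so a run
is fully specified by (config, seed).  The calibrated defaults shipped in
``data/default_config.yaml`` reproduce the cohort-level statistics of a
partial ischemia-reperfusion injury (IRI) study cohort.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

SEGMENT_CLASSES = ("PT-S1", "PT-S2", "DCT-CD")
REGIONS = ("Not-IR", "Mid", "IR", "Sham")

SHORT_TERM_DAYS = (0, 1, 2, 3)
LONG_TERM_DAYS = (0, 3, 4, 7, 14, 21)


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its contract."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class CohortLayout:
    """Counts and geometry of the simulated cohort.

    ``nephrons_per_region`` are totals, distributed round-robin over mice;
    each nephron carries ``segments_per_nephron`` tubule segments in flow
    order PT-S1 -> PT-S2 -> DCT/CD.
    """

    n_mice: int = 7
    nephrons_per_region: dict[str, int] = field(
        default_factory=lambda: {"IR": 53, "Mid": 67, "Not-IR": 25}
    )
    segments_per_nephron: dict[str, int] = field(
        default_factory=lambda: {"PT-S1": 2, "PT-S2": 2, "DCT-CD": 1}
    )
    cells_per_segment: int = 40
    segment_length_um: float = 240.0
    cross_section_um2: dict[str, float] = field(
        default_factory=lambda: {"PT-S1": 1257.0, "PT-S2": 1257.0, "DCT-CD": 900.0}
    )
    lumen_fraction: dict[str, float] = field(
        default_factory=lambda: {"PT-S1": 0.40, "PT-S2": 0.40, "DCT-CD": 0.45}
    )
    # multiplicative log-normal mouse-level effect on injury severity
    mouse_sigma: float = 0.10

    def validate(self) -> None:
        _check(self.n_mice > 0, "n_mice must be positive")
        _check(self.cells_per_segment > 0, "cells_per_segment must be positive")
        _check(self.segment_length_um > 0, "segment_length_um must be positive")
        for region, n in self.nephrons_per_region.items():
            _check(n >= 0, f"nephron count for {region} must be >= 0")
        for cls, n in self.segments_per_nephron.items():
            _check(cls in SEGMENT_CLASSES, f"unknown segment class {cls!r}")
            _check(n >= 0, f"segments per nephron for {cls} must be >= 0")
        _check(
            sum(self.segments_per_nephron.values()) > 0,
            "a nephron needs at least one segment",
        )


@dataclass
class InjuryParams:
    """Initial necrosis (day 0, 2 h post reperfusion) per region and class.

    A nephron in region r is 'ischemic' with probability
    ``ischemic_fraction[r]``; within an ischemic nephron each segment is
    necrotic with class probability ``p_necrotic`` and draws a PI+ severity
    from a two-component Beta mixture (body + severe spike), scaled by
    ``severity_scale[r]``.  Non-ischemic nephrons carry only rare scattered
    single-cell necrosis.
    """

    ischemic_fraction: dict[str, float] = field(
        default_factory=lambda: {"IR": 1.0, "Mid": 0.5, "Not-IR": 0.0, "Sham": 0.0}
    )
    severity_scale: dict[str, float] = field(
        default_factory=lambda: {"IR": 1.0, "Mid": 0.575, "Not-IR": 1.0, "Sham": 1.0}
    )
    p_necrotic: dict[str, float] = field(
        default_factory=lambda: {"PT-S1": 0.85, "PT-S2": 0.78, "DCT-CD": 0.55}
    )
    body_mean: dict[str, float] = field(
        default_factory=lambda: {"PT-S1": 0.35, "PT-S2": 0.195, "DCT-CD": 0.053}
    )
    body_conc: dict[str, float] = field(
        default_factory=lambda: {"PT-S1": 12.0, "PT-S2": 20.0, "DCT-CD": 30.0}
    )
    severe_weight: dict[str, float] = field(
        default_factory=lambda: {"PT-S1": 0.085, "PT-S2": 0.15, "DCT-CD": 0.0}
    )
    severe_mean: dict[str, float] = field(
        default_factory=lambda: {"PT-S1": 0.78, "PT-S2": 0.64, "DCT-CD": 0.50}
    )
    severe_conc: float = 20.0
    # scattered background necrosis in non-ischemic nephrons
    scattered_prob: float = 0.0488
    scattered_two_cell_prob: float = 0.2
    shedding_delay_days: float = 0.25

    def validate(self) -> None:
        for name, d in (
            ("ischemic_fraction", self.ischemic_fraction),
            ("p_necrotic", self.p_necrotic),
            ("severe_weight", self.severe_weight),
        ):
            for key, p in d.items():
                _check(0.0 <= p <= 1.0, f"{name}[{key}] must lie in [0, 1]")
        for d in (self.body_mean, self.severe_mean):
            for key, m in d.items():
                _check(0.0 < m < 1.0, f"severity mean for {key} must lie in (0, 1)")
        _check(0.0 <= self.scattered_prob <= 1.0, "scattered_prob must lie in [0,1]")


@dataclass
class CastParams:
    """Granular cast production, downstream transport and deposition.

    Shed necrotic cells form luminal parcels (area units, um^2) that advect
    downstream at ``transport_um_per_day`` and deposit with a per-um rate
    that strongly prefers PT-S2 and DCT/CD over PT-S1.
    """

    area_per_shed_cell_um2: float = 97.0
    production_sigma: float = 0.35  # log-normal noise on parcel mass
    transport_um_per_day: float = 185.0
    deposition_per_um: dict[str, float] = field(
        default_factory=lambda: {"PT-S1": 2e-05, "PT-S2": 0.0052, "DCT-CD": 0.0012}
    )
    deposition_sigma: float = 1.2  # log-normal noise on per-segment deposition
    clearance_recovered_per_day: float = 0.35
    detect_min_fraction: float = 0.02  # casted/uncasted split threshold
    # ischemic necrosis casts off gradually over this many days (the laser
    # protocol overrides both values: acute ablation sheds at once into a
    # normally flowing healthy nephron)
    shed_over_days: int = 3

    def validate(self) -> None:
        _check(self.transport_um_per_day >= 0, "transport rate must be >= 0")
        _check(self.area_per_shed_cell_um2 >= 0, "cast area per cell must be >= 0")
        for cls, lam in self.deposition_per_um.items():
            _check(lam >= 0, f"deposition rate for {cls} must be >= 0")


@dataclass
class ProliferationParams:
    """Commitment of surviving epithelial cells to the cell cycle.

    Two triggers: proximity (< ``r_prox_um`` of a day-0 necrotic nucleus,
    active on days ``prox_window``) and a saturating luminal-cast dose
    response evaluated on the previous day's cast fraction.  Committed cells
    show the transient cycling reporter for ``visible_days``.
    """

    r_prox_um: float = 25.0
    p_commit_near_per_day: float = 0.055
    prox_window: tuple[int, int] = (1, 4)
    cast_p_max_per_day: float = 0.087
    cast_half_dose: float = 0.17  # cast fraction giving half-maximal commitment
    cast_hill: float = 4.0  # cooperativity of the luminal-obstruction response
    baseline_per_day: float = 0.0046
    latency_days: int = 1
    visible_days: int = 1
    # day -> multiplier on injury-triggered commitment hazards (step
    # function, last value carried forward): the repair program ramps up
    # over the first days after reperfusion and shuts down as the
    # epithelium re-differentiates
    response_ramp: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.35, 3: 0.6, 4: 1.36, 5: 0.7, 7: 0.15, 14: 0.02}
    )

    def ramp(self, day: int) -> float:
        val = 1.0
        for d in sorted(self.response_ramp):
            if day >= d:
                val = self.response_ramp[d]
            else:
                break
        return val

    def validate(self) -> None:
        _check(self.r_prox_um > 0, "r_prox_um must be positive")
        for p in (self.p_commit_near_per_day, self.cast_p_max_per_day, self.baseline_per_day):
            _check(0.0 <= p <= 1.0, "commitment probabilities must lie in [0, 1]")
        _check(self.visible_days >= 1, "visible_days must be >= 1")
        _check(self.cast_half_dose > 0, "cast_half_dose must be positive")
        _check(self.cast_hill > 0, "cast_hill must be positive")


@dataclass
class FateParams:
    """Terminal tubule fate (atrophy vs recovery vs uninjured).

    Atrophy probability is logistic in the day-3/4 cast fraction; the
    fate-decision day is drawn from an empirical timing distribution over
    observation days 7/14/21.
    """

    assignment_day: int = 4
    logistic_intercept: float = -5.7
    logistic_cast_coef: float = 21.0
    logistic_pi0_coef: float = 0.0
    timing_recovered: dict[int, float] = field(
        default_factory=lambda: {7: 0.77, 14: 0.21, 21: 0.02}
    )
    timing_atrophic: dict[int, float] = field(
        default_factory=lambda: {7: 0.55, 14: 0.34, 21: 0.11}
    )
    severe_cast_threshold: float = 0.25  # 'lumen-filling' classification
    cast_morphology_threshold: float = 0.04
    necrotic_flag_threshold: float = 0.01

    def validate(self) -> None:
        for name, dist in (
            ("timing_recovered", self.timing_recovered),
            ("timing_atrophic", self.timing_atrophic),
        ):
            total = sum(dist.values())
            _check(abs(total - 1.0) < 1e-9, f"{name} must sum to 1 (got {total})")
            for day, p in dist.items():
                _check(p >= 0, f"{name}[{day}] must be >= 0")


@dataclass
class AlbuminParams:
    """Albumin reuptake-ratio trajectories (apical / capillary) per fate."""

    capillary_intensity: float = 100.0
    noise_cv: float = 0.12
    # mean ratio by fate at each long-term observation day
    trajectories: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "sham": {0: 1.8, 3: 1.8, 4: 1.8, 7: 1.8, 14: 1.8, 21: 1.8},
            "uninjured": {0: 1.75, 3: 1.75, 4: 1.75, 7: 1.8, 14: 1.8, 21: 1.8},
            "recovered": {0: 0.50, 3: 0.65, 4: 0.75, 7: 1.75, 14: 1.8, 21: 1.8},
            "atrophic": {0: 0.40, 3: 0.35, 4: 0.35, 7: 0.30, 14: 0.25, 21: 0.25},
        }
    )

    def validate(self) -> None:
        for fate, traj in self.trajectories.items():
            for day, r in traj.items():
                _check(r >= 0, f"albumin ratio for {fate} day {day} must be >= 0")


@dataclass
class OpticsParams:
    """Autofluorescence model at 750 nm and classification decision regions.

    Class means carry the PT-S2 > PT-S1 > DCT/CD brightness ordering; necrosis
    attenuates blue (NADH depletion) much more than green, which both raises
    the green/blue ratio and darkens the segment — severely necrotic segments
    become unclassifiable.
    """

    blue_mean: dict[str, float] = field(
        default_factory=lambda: {"PT-S1": 120.0, "PT-S2": 200.0, "DCT-CD": 70.0}
    )
    green_mean: dict[str, float] = field(
        default_factory=lambda: {"PT-S1": 100.0, "PT-S2": 220.0, "DCT-CD": 45.0}
    )
    blue_attenuation: float = 0.95
    green_attenuation: float = 0.25
    channel_cv: float = 0.06
    # classification guards
    min_blue: float = 42.0
    max_ratio: float = 2.15
    ratio_scale: float = 0.15
    log_brightness_scale: float = 0.25
    # rendering
    nucleus_void_level: float = 0.15
    gfp_track_intensity: float = 180.0
    cast_intensity: float = 400.0
    pi_red_intensity: float = 300.0
    epithelium_940_level: float = 20.0
    noise_read_sd: float = 0.0
    noise_poisson_scale: float = 0.0

    def validate(self) -> None:
        for cls in SEGMENT_CLASSES:
            _check(self.blue_mean[cls] > 0, f"blue mean for {cls} must be positive")
            _check(self.green_mean[cls] > 0, f"green mean for {cls} must be positive")
        ratios = {c: self.green_mean[c] / self.blue_mean[c] for c in SEGMENT_CLASSES}
        _check(
            ratios["PT-S2"] > ratios["PT-S1"] > ratios["DCT-CD"],
            "green/blue ratio ordering PT-S2 > PT-S1 > DCT/CD must be strict",
        )
        _check(0 <= self.blue_attenuation <= 1, "blue_attenuation must lie in [0,1]")
        _check(0 <= self.green_attenuation <= 1, "green_attenuation must lie in [0,1]")


@dataclass
class LaserParams:
    """Selective focal PT-S1 laser-injury experiment layout."""

    n_mice: int = 7
    sites_per_mouse: int = 10
    n_target_cells: int = 35
    neighbor_segments_per_mouse: int = 65
    neighbor_class_mix: dict[str, float] = field(
        default_factory=lambda: {"PT-S1": 0.30, "PT-S2": 0.55, "DCT-CD": 0.15}
    )
    max_distance_um: float = 135.0
    zone_edges_um: tuple[float, ...] = (0.0, 35.0, 85.0, 135.0)
    target_radius_um: float = 20.0
    n_days: int = 3
    transport_um_per_day: float = 300.0
    shed_over_days: int = 1

    def validate(self) -> None:
        _check(self.n_target_cells >= 0, "n_target_cells must be >= 0")
        _check(
            list(self.zone_edges_um) == sorted(self.zone_edges_um),
            "zone edges must be increasing",
        )


@dataclass
class ObservationParams:
    dropout_rate: float = 0.0
    count_noise: float = 0.0  # kept 0 by default: manual counting treated as exact

    def validate(self) -> None:
        _check(0.0 <= self.dropout_rate < 1.0, "dropout_rate must lie in [0, 1)")


@dataclass
class CohortConfig:
    """Full parameter tree for one simulated experiment."""

    protocol: str = "partial_iri_long"  # sham | partial_iri_short | partial_iri_long | laser
    seed: int = 0
    cohort: CohortLayout = field(default_factory=CohortLayout)
    injury: InjuryParams = field(default_factory=InjuryParams)
    casts: CastParams = field(default_factory=CastParams)
    proliferation: ProliferationParams = field(default_factory=ProliferationParams)
    fate: FateParams = field(default_factory=FateParams)
    albumin: AlbuminParams = field(default_factory=AlbuminParams)
    optics: OpticsParams = field(default_factory=OpticsParams)
    laser: LaserParams = field(default_factory=LaserParams)
    observation: ObservationParams = field(default_factory=ObservationParams)

    def validate(self) -> "CohortConfig":
        _check(
            self.protocol in ("sham", "partial_iri_short", "partial_iri_long", "laser"),
            f"unknown protocol {self.protocol!r}",
        )
        for section in (
            self.cohort,
            self.injury,
            self.casts,
            self.proliferation,
            self.fate,
            self.albumin,
            self.optics,
            self.laser,
            self.observation,
        ):
            section.validate()
        return self

    @property
    def schedule_days(self) -> tuple[int, ...]:
        if self.protocol == "partial_iri_short":
            return SHORT_TERM_DAYS
        if self.protocol == "laser":
            return tuple(range(0, self.laser.n_days + 1))
        return LONG_TERM_DAYS

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return _stringify_keys(d)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "CohortConfig":
        base = cls()
        merged = _merge(base.to_dict(), data)
        return _build(cls, merged).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def replace(self, **overrides: Any) -> "CohortConfig":
        """Return a copy with nested overrides, e.g. replace(protocol='sham')."""
        d = self.to_dict()
        d = _merge(d, overrides)
        return CohortConfig.from_dict(d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stringify_keys(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_stringify_keys(v) for v in obj]
    if isinstance(obj, list):
        return [_stringify_keys(v) for v in obj]
    return obj


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        key = str(key)
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _build(cls: type, data: dict[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.type, str) and f.type in _SECTION_TYPES
        ):
            section_cls = _SECTION_TYPES[f.type if isinstance(f.type, str) else f.type.__name__]
            kwargs[f.name] = _build(section_cls, val)
        elif f.name in _INT_KEY_FIELDS and isinstance(val, dict):
            kwargs[f.name] = {int(k): float(v) for k, v in val.items()}
        elif f.name in _NESTED_INT_KEY_FIELDS and isinstance(val, dict):
            kwargs[f.name] = {
                str(k): {int(kk): float(vv) for kk, vv in v.items()} for k, v in val.items()
            }
        elif f.name in _TUPLE_FIELDS and isinstance(val, (list, tuple)):
            kwargs[f.name] = tuple(val)
        else:
            kwargs[f.name] = val
    return cls(**kwargs)


_SECTION_TYPES = {
    t.__name__: t
    for t in (
        CohortLayout,
        InjuryParams,
        CastParams,
        ProliferationParams,
        FateParams,
        AlbuminParams,
        OpticsParams,
        LaserParams,
        ObservationParams,
    )
}
_INT_KEY_FIELDS = {"timing_recovered", "timing_atrophic", "response_ramp"}
_NESTED_INT_KEY_FIELDS = {"trajectories"}
_TUPLE_FIELDS = {"prox_window", "zone_edges_um"}


def default_config(protocol: str = "partial_iri_long", seed: int = 0) -> CohortConfig:
    """Load the calibrated default configuration shipped with the package."""
    ref = resources.files("nephrotrack").joinpath("data/default_config.yaml")
    data = yaml.safe_load(ref.read_text())
    cfg = CohortConfig.from_dict(data)
    return cfg.replace(protocol=protocol, seed=seed)
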