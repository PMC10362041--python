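"""Stochastic forward simulator of partial-IRI injury propagation.

Daily time steps over a 1-D nephron cohort:

1. day 0 (2 h post reperfusion): necrotic cells are seeded per
   (region, class) as contiguous PI+ patches;
2. attached necrotic cells shed into the lumen (6 h event, executed on the
   first daily step) and form granular-cast parcels;
3. parcels advect downstream and deposit preferentially in PT-S2 and DCT/CD;
4. surviving cells commit to cycle via a proximity trigger (< 25 um from a
   day-0 necrotic nucleus) or a saturating luminal-cast dose response
   evaluated on the previous day's cast load, plus a small baseline rate;
5. terminal fate (atrophy / recovery) is drawn from a logistic model on the
   day-3/4 cast fraction and realised in the morphology trajectory at a
   sampled fate-decision day.

All randomness derives from a single root seed through named child streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CohortConfig, SEGMENT_CLASSES
from .model import (
    CYCLING,
    HEALTHY,
    NECROTIC_ATTACHED,
    POST_CYCLE,
    SHED,
    EpithelialCell,
    NephronPath,
    ObservationSchedule,
    TubuleSegment,
    build_cohort_skeleton,
)


class SimulationError(RuntimeError):
    pass


@dataclass
class CastParcel:
    nephron_index: int
    position_um: float
    mass_um2: float
    origin_segment_id: int = -1


@dataclass
class MassLedger:
    """Granular-cast mass accounting (um^2 of solid luminal area)."""

    produced: float = 0.0
    outflow: float = 0.0
    cleared: float = 0.0

    def balance(self, deposited: float, in_transit: float) -> float:
        return self.produced - (deposited + in_transit + self.outflow + self.cleared)


@dataclass
class Cohort:
    """A simulated cohort with full per-day history."""

    config: CohortConfig
    nephrons: list[NephronPath]
    day: int = -1
    parcels: list[CastParcel] = field(default_factory=list)
    ledger: MassLedger = field(default_factory=MassLedger)
    history: list[dict] = field(default_factory=list)
    _rng_cache: dict = field(default_factory=dict)
    _mouse_factor: dict[int, float] = field(default_factory=dict)
    _near_day0: dict[int, np.ndarray] = field(default_factory=dict)
    _day0_pi_positions: dict[int, np.ndarray] = field(default_factory=dict)

    # -- plumbing ---------------------------------------------------------

    def rng(self, name: str) -> np.random.Generator:
        if name not in self._rng_cache:
            digest = sum(ord(c) * 257**i for i, c in enumerate(name)) % (2**31)
            self._rng_cache[name] = np.random.default_rng(
                np.random.SeedSequence([int(self.config.seed) % (2**31), digest])
            )
        return self._rng_cache[name]

    @property
    def segments(self) -> list[TubuleSegment]:
        return [s for n in self.nephrons for s in n.segments]

    def segment_by_id(self, segment_id: int) -> TubuleSegment:
        for seg in self.segments:
            if seg.segment_id == segment_id:
                return seg
        raise KeyError(f"no segment with id {segment_id}")

    def deposited_mass(self) -> float:
        return sum(s.cast_area_um2 for s in self.segments)

    def in_transit_mass(self) -> float:
        return sum(p.mass_um2 for p in self.parcels)

    def mass_balance_error(self) -> float:
        return self.ledger.balance(self.deposited_mass(), self.in_transit_mass())

    def nuclei_accounting_ok(self) -> bool:
        """healthy + necrotic_attached + cycling + post_cycle == epithelial total."""
        for seg in self.segments:
            epithelial = seg.epithelial_cells()
            by_state = sum(
                1
                for c in epithelial
                if c.state in (HEALTHY, NECROTIC_ATTACHED, CYCLING, POST_CYCLE)
            )
            if by_state != len(epithelial):
                return False
            if len(epithelial) + sum(1 for c in seg.cells if c.state == SHED) != len(seg.cells):
                return False
        return True


# ---------------------------------------------------------------------------
# cohort construction and day-0 injury


def build_cohort(config: CohortConfig) -> Cohort:
    config.validate()
    if config.protocol == "laser":
        nephrons = _build_laser_skeleton(config)
    else:
        nephrons = build_cohort_skeleton(config)
        if config.protocol == "sham":
            for n in nephrons:
                n.region = "Sham"
                for s in n.segments:
                    s.region = "Sham"
    cohort = Cohort(config=config, nephrons=nephrons)
    mouse_rng = cohort.rng("mouse_effects")
    sigma = config.cohort.mouse_sigma
    n_mice = max(config.cohort.n_mice, config.laser.n_mice)
    for m in range(n_mice):
        z = mouse_rng.normal(0.0, sigma) if sigma > 0 else 0.0
        cohort._mouse_factor[m] = math.exp(z - 0.5 * sigma**2)
    return cohort


def _build_laser_skeleton(config: CohortConfig) -> list[NephronPath]:
    """Healthy FOV layouts for the focal laser-injury experiment.

    Each mouse contributes ``sites_per_mouse`` full nephrons (one PT-S1 ->
    PT-S2 -> DCT/CD path whose S1 will be laser-targeted) plus a population
    of bystander single-segment tubules at area-uniform radial distances
    from the injury site.
    """
    laser = config.laser
    layout = config.cohort
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), 0x1A5E]))
    nephrons: list[NephronPath] = []
    nid = 0
    sid = 0
    cid = 0
    classes = list(laser.neighbor_class_mix)
    probs = np.array([laser.neighbor_class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    def _radial() -> float:
        r0 = laser.target_radius_um
        rmax = laser.target_radius_um + laser.max_distance_um
        return float(np.sqrt(rng.uniform(r0**2, rmax**2)) - r0)

    for mouse in range(laser.n_mice):
        for _ in range(laser.sites_per_mouse):
            nephron = NephronPath(nephron_id=nid, mouse_id=mouse, region="Sham")
            x = 0.0
            for seg_class in SEGMENT_CLASSES:
                length = layout.segment_length_um * float(rng.uniform(0.9, 1.1))
                seg = TubuleSegment(
                    segment_id=sid,
                    nephron_id=nid,
                    mouse_id=mouse,
                    segment_class=seg_class,
                    region="Sham",
                    axial_start=x,
                    axial_end=x + length,
                    cross_section_um2=layout.cross_section_um2[seg_class],
                    lumen_fraction=layout.lumen_fraction[seg_class],
                )
                seg.cells = _cells_for(seg, layout.cells_per_segment, cid)
                cid += layout.cells_per_segment
                if seg_class == "PT-S1":
                    seg.is_laser_target = True
                    seg.distance_to_target_um = 0.0
                else:
                    seg.distance_to_target_um = _radial()
                nephron.segments.append(seg)
                x += length
                sid += 1
            nephron.validate_flow_order()
            nephrons.append(nephron)
            nid += 1
        for _ in range(laser.neighbor_segments_per_mouse):
            seg_class = classes[int(rng.choice(len(classes), p=probs))]
            nephron = NephronPath(nephron_id=nid, mouse_id=mouse, region="Sham")
            length = layout.segment_length_um * float(rng.uniform(0.9, 1.1))
            seg = TubuleSegment(
                segment_id=sid,
                nephron_id=nid,
                mouse_id=mouse,
                segment_class=seg_class,
                region="Sham",
                axial_start=0.0,
                axial_end=length,
                cross_section_um2=layout.cross_section_um2[seg_class],
                lumen_fraction=layout.lumen_fraction[seg_class],
                distance_to_target_um=_radial(),
            )
            seg.cells = _cells_for(seg, layout.cells_per_segment, cid)
            cid += layout.cells_per_segment
            nephron.segments.append(seg)
            nephrons.append(nephron)
            nid += 1
            sid += 1
    return nephrons


def _cells_for(seg: TubuleSegment, n: int, first_id: int) -> list[EpithelialCell]:
    spacing = seg.axial_length / n
    return [
        EpithelialCell(
            cell_id=first_id + i,
            segment_id=seg.segment_id,
            axial_pos=seg.axial_start + (i + 0.5) * spacing,
        )
        for i in range(n)
    ]


def seed_necrosis(cohort: Cohort) -> Cohort:
    """Seed day-0 (2 h) necrosis: contiguous PI+ patches per segment.

    Ischemic nephrons draw a per-segment severity from the configured Beta
    mixture; non-ischemic nephrons carry only rare scattered 1-2 cell
    necrosis.  Sham cohorts stay at exactly 0% PI+.
    """
    if cohort.day >= 0:
        raise SimulationError("necrosis already seeded")
    inj = cohort.config.injury
    rng = cohort.rng("necrosis")
    for nephron in cohort.nephrons:
        p_isch = inj.ischemic_fraction.get(nephron.region, 0.0)
        nephron.is_ischemic = bool(rng.random() < p_isch)
        scale = inj.severity_scale.get(nephron.region, 1.0) * cohort._mouse_factor.get(
            nephron.mouse_id, 1.0
        )
        for seg in nephron.segments:
            n = len(seg.cells)
            k = 0
            if nephron.is_ischemic:
                cls = seg.segment_class
                if rng.random() < inj.p_necrotic[cls]:
                    if rng.random() < inj.severe_weight[cls]:
                        mean, conc = inj.severe_mean[cls], inj.severe_conc
                    else:
                        mean, conc = inj.body_mean[cls], inj.body_conc[cls]
                    f = float(rng.beta(mean * conc, (1.0 - mean) * conc))
                    f = min(max(f * scale, 0.0), 1.0)
                    k = int(rng.binomial(n, f))
            elif nephron.region != "Sham":
                # scattered background necrosis exists in partial-IRI kidneys
                # (including Not-IR tissue) but not in sham controls
                if inj.scattered_prob > 0 and rng.random() < inj.scattered_prob:
                    k = 2 if rng.random() < inj.scattered_two_cell_prob else 1
            if k > 0:
                start = int(rng.integers(0, n - k + 1))
                for cell in seg.cells[start : start + k]:
                    cell.state = NECROTIC_ATTACHED
                    cell.pi_positive = True
    _index_day0_necrosis(cohort)
    cohort.day = 0
    _record_day(cohort)
    return cohort


def laser_injury(cohort: Cohort, target_segment_id: int, n_cells: int) -> Cohort:
    """Selective focal necrosis of ``n_cells`` contiguous cells in one PT-S1.

    The surrounding tissue is untouched; ``n_cells=0`` is the identity.
    """
    seg = cohort.segment_by_id(target_segment_id)
    if seg.segment_class != "PT-S1":
        raise SimulationError("laser injury is defined for PT-S1 segments only")
    if n_cells < 0 or n_cells > len(seg.cells):
        raise SimulationError(f"n_cells must lie in [0, {len(seg.cells)}]")
    if n_cells == 0:
        return cohort
    start = (len(seg.cells) - n_cells) // 2
    for cell in seg.cells[start : start + n_cells]:
        cell.state = NECROTIC_ATTACHED
        cell.pi_positive = True
    return cohort


def apply_laser_protocol(cohort: Cohort) -> Cohort:
    """Target every laser site in the cohort, then index day-0 necrosis."""
    if cohort.day >= 0:
        raise SimulationError("laser must be applied before day 0")
    n_cells = cohort.config.laser.n_target_cells
    for seg in cohort.segments:
        if seg.is_laser_target:
            laser_injury(cohort, seg.segment_id, n_cells)
    _index_day0_necrosis(cohort)
    cohort.day = 0
    _record_day(cohort)
    return cohort


def _index_day0_necrosis(cohort: Cohort) -> None:
    """Freeze day-0 PI+ positions and each cell's <25 um proximity flag."""
    r = cohort.config.proliferation.r_prox_um
    for i, nephron in enumerate(cohort.nephrons):
        pi_pos = np.array(
            [c.axial_pos for s in nephron.segments for c in s.cells if c.pi_positive],
            dtype=float,
        )
        cohort._day0_pi_positions[i] = pi_pos
        for seg in nephron.segments:
            xs = np.array([c.axial_pos for c in seg.cells])
            if pi_pos.size == 0:
                near = np.zeros(xs.size, dtype=bool)
            else:
                near = np.min(np.abs(xs[:, None] - pi_pos[None, :]), axis=1) < r
            cohort._near_day0[seg.segment_id] = near


# ---------------------------------------------------------------------------
# daily dynamics


def step_day(cohort: Cohort, t: int) -> Cohort:
    """Advance the cohort from day t-1 to day t."""
    if t != cohort.day + 1:
        raise SimulationError(f"non-monotone time step: at day {cohort.day}, requested {t}")
    cfg = cohort.config
    cast_prev = {s.segment_id: s.cast_fraction for s in cohort.segments}

    _shed_cells(cohort, t)
    _transport_casts(cohort)
    _clear_casts(cohort, t)
    _commit_cells(cohort, t, cast_prev)
    cohort.day = t
    if cfg.protocol in ("partial_iri_long", "sham") and t == cfg.fate.assignment_day:
        assign_fates(cohort)
    _update_morphology(cohort, t)
    _record_day(cohort)
    return cohort


def _shed_days(cohort: Cohort) -> int:
    if cohort.config.protocol == "laser":
        return cohort.config.laser.shed_over_days
    return cohort.config.casts.shed_over_days


def _transport_speed(cohort: Cohort) -> float:
    if cohort.config.protocol == "laser":
        return cohort.config.laser.transport_um_per_day
    return cohort.config.casts.transport_um_per_day


def _shed_cells(cohort: Cohort, t: int) -> None:
    """Attached necrotic cells cast off into the lumen, starting 6 h after
    reperfusion and spread uniformly over ``shed_over_days`` days."""
    if t < max(1, math.ceil(cohort.config.injury.shedding_delay_days)):
        return
    shed_days = _shed_days(cohort)
    remaining = max(shed_days - t + 1, 0)
    if remaining == 0:
        return
    p_shed = 1.0 / remaining
    casts = cohort.config.casts
    rng = cohort.rng("shedding")
    for i, nephron in enumerate(cohort.nephrons):
        for seg in nephron.segments:
            run: list[EpithelialCell] = []
            for cell in seg.cells + [None]:  # type: ignore[list-item]
                if cell is not None and cell.state == NECROTIC_ATTACHED:
                    run.append(cell)
                    continue
                if run:
                    # one parcel per shed cell: a long necrotic run sheds
                    # debris along its full axial extent
                    for c in run:
                        if p_shed < 1.0 and rng.random() >= p_shed:
                            continue
                        mass = casts.area_per_shed_cell_um2
                        if casts.production_sigma > 0:
                            mass *= float(
                                rng.lognormal(
                                    -0.5 * casts.production_sigma**2, casts.production_sigma
                                )
                            )
                        if mass > 0:
                            cohort.parcels.append(
                                CastParcel(i, c.axial_pos, mass, seg.segment_id)
                            )
                            cohort.ledger.produced += mass
                        c.state = SHED
                        c.shed_day = t
                    run = []


def _transport_casts(cohort: Cohort) -> None:
    """Advect parcels downstream; deposit per class-specific per-um rates."""
    casts = cohort.config.casts
    v = _transport_speed(cohort)
    rng = cohort.rng("deposition")
    # one stickiness multiplier per segment per day: luminal flow state is a
    # segment-level property shared by all debris passing through that day
    day_mult: dict[int, float] = {}

    def _mult(segment_id: int) -> float:
        if casts.deposition_sigma <= 0:
            return 1.0
        if segment_id not in day_mult:
            day_mult[segment_id] = float(
                rng.lognormal(-0.5 * casts.deposition_sigma**2, casts.deposition_sigma)
            )
        return day_mult[segment_id]

    surviving: list[CastParcel] = []
    for parcel in cohort.parcels:
        nephron = cohort.nephrons[parcel.nephron_index]
        x0, mass = parcel.position_um, parcel.mass_um2
        x1 = x0 + v
        for seg in nephron.segments:
            lo, hi = max(x0, seg.axial_start), min(x1, seg.axial_end)
            if hi <= lo or mass <= 0:
                continue
            # freshly shed debris is carried out of its segment of origin
            # before it can settle
            if seg.segment_id == parcel.origin_segment_id:
                continue
            lam = casts.deposition_per_um.get(seg.segment_class, 0.0)
            if lam > 0:
                lam *= _mult(seg.segment_id)
            dep = mass * (1.0 - math.exp(-lam * (hi - lo)))
            seg.cast_area_um2 += dep
            mass -= dep
        if x1 >= nephron.total_length:
            cohort.ledger.outflow += mass
        elif mass > 1e-12:
            surviving.append(
                CastParcel(parcel.nephron_index, x1, mass, parcel.origin_segment_id)
            )
        else:
            cohort.ledger.outflow += max(mass, 0.0)
    cohort.parcels = surviving


def _clear_casts(cohort: Cohort, t: int) -> None:
    """Slow exponential cast clearance in non-atrophic fated tubules."""
    rate = cohort.config.casts.clearance_recovered_per_day
    if rate <= 0:
        return
    keep = math.exp(-rate)
    for seg in cohort.segments:
        if seg.fate in ("recovered", "uninjured") and t > cohort.config.fate.assignment_day:
            removed = seg.cast_area_um2 * (1.0 - keep)
            seg.cast_area_um2 -= removed
            cohort.ledger.cleared += removed


def _commit_cells(cohort: Cohort, t: int, cast_prev: dict[int, float]) -> None:
    prolif = cohort.config.proliferation
    rng = cohort.rng("commitment")
    lo, hi = prolif.prox_window
    prox_active = lo <= t <= hi
    # the remodeling-capacity ramp describes post-ischemic kinetics of the
    # whole kidney; focal laser injury in otherwise healthy tissue responds
    # at full capacity immediately
    ramp = 1.0 if cohort.config.protocol == "laser" else prolif.ramp(t)
    for seg in cohort.segments:
        near = cohort._near_day0.get(seg.segment_id)
        c = cast_prev.get(seg.segment_id, 0.0)
        ch = c**prolif.cast_hill
        p_cast = (
            ramp
            * prolif.cast_p_max_per_day
            * ch
            / (ch + prolif.cast_half_dose**prolif.cast_hill)
        )
        for idx, cell in enumerate(seg.cells):
            if cell.state != HEALTHY:
                continue
            p = prolif.baseline_per_day + p_cast
            if prox_active and near is not None and near[idx]:
                p += ramp * prolif.p_commit_near_per_day
            if p > 0 and rng.random() < min(p, 1.0):
                cell.state = CYCLING
                cell.commit_day = t
                start = t  # trigger (day t-1) + 1 day latency to visible reporter
                cell.gfp_interval = (start, start + prolif.visible_days)
    # transient reporter: cells past their visibility window return to rest
    for seg in cohort.segments:
        for cell in seg.cells:
            if cell.state == CYCLING and cell.gfp_interval is not None:
                if t >= cell.gfp_interval[1]:
                    cell.state = POST_CYCLE


def assign_fates(cohort: Cohort) -> Cohort:
    """Draw terminal fates from the logistic cast model at day 3/4.

    Atrophy probability is logistic in the current (day-3/4) cast fraction
    (optionally plus day-0 PI+ fraction); non-atrophic necrotic segments
    (day-0 PI+ > 1%) become 'recovered', the rest 'uninjured'.  Fate-decision
    days are drawn from the configured timing distributions.
    """
    fate_cfg = cohort.config.fate
    if cohort.day < min(3, fate_cfg.assignment_day):
        raise SimulationError("fates require the day-3/4 cast predictor; simulate further first")
    rng = cohort.rng("fates")
    rec_days = sorted(fate_cfg.timing_recovered)
    rec_p = np.array([fate_cfg.timing_recovered[d] for d in rec_days])
    atr_days = sorted(fate_cfg.timing_atrophic)
    atr_p = np.array([fate_cfg.timing_atrophic[d] for d in atr_days])
    for seg in cohort.segments:
        if seg.fate != "undetermined":
            continue
        eta = (
            fate_cfg.logistic_intercept
            + fate_cfg.logistic_cast_coef * seg.cast_fraction
            + fate_cfg.logistic_pi0_coef * seg.pi0_fraction
        )
        p_atrophy = 1.0 / (1.0 + math.exp(-eta))
        if rng.random() < p_atrophy:
            seg.fate = "atrophic"
            seg.fate_day = int(atr_days[int(rng.choice(len(atr_days), p=atr_p))])
        elif seg.pi0_fraction > fate_cfg.necrotic_flag_threshold:
            seg.fate = "recovered"
            seg.fate_day = int(rec_days[int(rng.choice(len(rec_days), p=rec_p))])
        else:
            seg.fate = "uninjured"
            if seg.cast_fraction > fate_cfg.cast_morphology_threshold:
                seg.fate_day = int(rec_days[int(rng.choice(len(rec_days), p=rec_p))])
            else:
                seg.fate_day = 0
    return cohort


def _update_morphology(cohort: Cohort, t: int) -> None:
    for seg in cohort.segments:
        seg.morphology = _morphology_at(cohort.config, seg, t)


def _morphology_at(config: CohortConfig, seg: TubuleSegment, day: int) -> str:
    fate_cfg = config.fate
    if seg.fate != "undetermined" and seg.fate_day is not None and day >= seg.fate_day:
        return "atrophic" if seg.fate == "atrophic" else "normal"
    if seg.cast_fraction > fate_cfg.cast_morphology_threshold:
        return "granular"
    pi0 = seg.pi0_fraction
    if pi0 > 0.20:
        return "granular"
    if pi0 > fate_cfg.necrotic_flag_threshold:
        return "flattened"
    return "normal"


# ---------------------------------------------------------------------------
# recording and observation


def _record_day(cohort: Cohort) -> None:
    day = cohort.day
    for seg in cohort.segments:
        total, pi, gfp = seg.counts(day)
        near_mask = cohort._near_day0.get(seg.segment_id)
        gfp_near = 0
        if near_mask is not None:
            gfp_near = sum(
                1
                for idx, c in enumerate(seg.cells)
                if c.state != SHED and c.gfp_visible(day) and near_mask[idx]
            )
        cohort.history.append(
            {
                "day": day,
                "segment_id": seg.segment_id,
                "total_nuclei": total,
                "pi_pos": pi,
                "gfp_pos": gfp,
                "gfp_near": gfp_near,
                "gfp_far": gfp - gfp_near,
                "cast_fraction": seg.cast_fraction,
                "morphology": _morphology_at(cohort.config, seg, day),
            }
        )


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Build, injure and advance a cohort through its full protocol."""
    cohort = build_cohort(config)
    if config.protocol == "laser":
        apply_laser_protocol(cohort)
    else:
        seed_necrosis(cohort)
    for t in range(1, max(config.schedule_days) + 1):
        step_day(cohort, t)
    return cohort


def observe(cohort: Cohort, schedule: ObservationSchedule | None = None) -> pd.DataFrame:
    """Assemble the per-segment x observation-day table.

    Counts are taken from the recorded history (manual counting is treated
    as exact); channel means carry multiplicative log-normal measurement
    noise; optional field-of-view dropout removes whole nephron-days at
    random ("missing FOV").
    """
    cfg = cohort.config
    days = tuple(schedule) if schedule is not None else cfg.schedule_days
    if cohort.day < max(days):
        raise SimulationError(f"cohort simulated to day {cohort.day} < requested {max(days)}")
    optics = cfg.optics
    # fresh stream per call so repeated observation of the same cohort is
    # bit-identical
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) % (2**31), 0x0B5E])
    )
    hist = pd.DataFrame(cohort.history)
    hist = hist[hist["day"].isin(days)]

    seg_info = {}
    for nephron in cohort.nephrons:
        for seg in nephron.segments:
            seg_info[seg.segment_id] = (nephron, seg)

    dropout: set[tuple[int, int]] = set()
    if cfg.observation.dropout_rate > 0:
        for nephron in cohort.nephrons:
            for day in days:
                if day > 0 and rng.random() < cfg.observation.dropout_rate:
                    dropout.add((nephron.nephron_id, day))

    rows = []
    for rec in hist.to_dict("records"):
        nephron, seg = seg_info[rec["segment_id"]]
        if (nephron.nephron_id, rec["day"]) in dropout:
            continue
        pi0 = seg.pi0_fraction
        noise_b = float(rng.lognormal(-0.5 * optics.channel_cv**2, optics.channel_cv))
        noise_g = float(rng.lognormal(-0.5 * optics.channel_cv**2, optics.channel_cv))
        blue = optics.blue_mean[seg.segment_class] * (1 - optics.blue_attenuation * pi0) * noise_b
        green = (
            optics.green_mean[seg.segment_class] * (1 - optics.green_attenuation * pi0) * noise_g
        )
        alb_ap, alb_cap = _albumin_intensities(cfg, seg, rec["day"], rng)
        rows.append(
            {
                "segment_id": seg.segment_id,
                "nephron_id": seg.nephron_id,
                "mouse_id": seg.mouse_id,
                "region": seg.region,
                "segment_class": seg.segment_class,
                "day": rec["day"],
                "total_nuclei": rec["total_nuclei"],
                "pi_pos": rec["pi_pos"],
                "gfp_pos": rec["gfp_pos"],
                "gfp_near": rec["gfp_near"],
                "gfp_far": rec["gfp_far"],
                "pi_frac": rec["pi_pos"] / rec["total_nuclei"] if rec["total_nuclei"] else 0.0,
                "gfp_frac": rec["gfp_pos"] / rec["total_nuclei"] if rec["total_nuclei"] else 0.0,
                "pi0_frac": pi0,
                "cast_fraction": rec["cast_fraction"],
                "cross_section_um2": seg.cross_section_um2,
                "morphology": rec["morphology"],
                "mean_green": green,
                "mean_blue": blue,
                "albumin_apical": alb_ap,
                "albumin_capillary": alb_cap,
                "fate": seg.fate,
                "fate_day": seg.fate_day if seg.fate_day is not None else np.nan,
                "distance_to_target_um": seg.distance_to_target_um,
                "is_laser_target": seg.is_laser_target,
            }
        )
    return pd.DataFrame(rows)


def _albumin_intensities(cfg: CohortConfig, seg: TubuleSegment, day: int, rng) -> tuple[float, float]:
    """Alexa-albumin intensities; the reuptake readout exists for PT-S1 only."""
    if seg.segment_class != "PT-S1" or cfg.protocol not in ("sham", "partial_iri_long"):
        return (np.nan, np.nan)
    alb = cfg.albumin
    fate = "sham" if cfg.protocol == "sham" else seg.fate
    if fate == "undetermined":
        fate = "recovered" if seg.pi0_fraction > cfg.fate.necrotic_flag_threshold else "uninjured"
    traj = alb.trajectories.get(fate)
    if traj is None or day not in traj:
        return (np.nan, np.nan)
    cap = alb.capillary_intensity
    ratio = traj[day] * float(rng.lognormal(-0.5 * alb.noise_cv**2, alb.noise_cv))
    return (ratio * cap, cap)
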