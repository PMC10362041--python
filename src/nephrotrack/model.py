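"""Domain types: nephron topology, tubule segments, epithelial cells.

The geometry is one-dimensional: every nephron has a single axial coordinate
(um) increasing in flow direction PT-S1 -> PT-S2 -> DCT/CD, and every cell a
scalar axial position.  Cross sections are treated as discs whose area enters
only through the cast-area normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .config import CohortConfig, ConfigurationError, SEGMENT_CLASSES

# epithelial cell states
HEALTHY = "healthy"
NECROTIC_ATTACHED = "necrotic_attached"
SHED = "shed"
CYCLING = "cycling"
POST_CYCLE = "post_cycle"

MORPHOLOGIES = ("normal", "flattened", "granular", "atrophic")
FATES = ("undetermined", "uninjured", "recovered", "atrophic")

FLOW_ORDER = {cls: i for i, cls in enumerate(SEGMENT_CLASSES)}


@dataclass
class EpithelialCell:
    """One tubule epithelial cell with its state trajectory.

    ``axial_pos`` is in the nephron frame (um from the nephron inlet).
    ``gfp_interval`` is the half-open [start, end) day window during which
    the transient cycling reporter is visible; it exists only for cells that
    committed to cycle.
    """

    cell_id: int
    segment_id: int
    axial_pos: float
    state: str = HEALTHY
    pi_positive: bool = False
    commit_day: int | None = None
    gfp_interval: tuple[int, int] | None = None
    shed_day: int | None = None

    def gfp_visible(self, day: int) -> bool:
        return self.gfp_interval is not None and self.gfp_interval[0] <= day < self.gfp_interval[1]


@dataclass
class TubuleSegment:
    segment_id: int
    nephron_id: int
    mouse_id: int
    segment_class: str
    region: str
    axial_start: float
    axial_end: float
    cross_section_um2: float
    lumen_fraction: float
    cells: list[EpithelialCell] = field(default_factory=list)
    cast_area_um2: float = 0.0
    morphology: str = "normal"
    fate: str = "undetermined"
    fate_day: int | None = None
    # laser-experiment bookkeeping
    distance_to_target_um: float = np.nan
    is_laser_target: bool = False

    @property
    def axial_length(self) -> float:
        return self.axial_end - self.axial_start

    @property
    def cast_fraction(self) -> float:
        """Solid luminal area over cross-sectional area, capped by the lumen."""
        if self.cross_section_um2 <= 0:
            return 0.0
        return float(min(self.cast_area_um2 / self.cross_section_um2, self.lumen_fraction))

    @property
    def n_cells_initial(self) -> int:
        return len(self.cells)

    @property
    def pi0_fraction(self) -> float:
        """Day-0 PI+ fraction of total nuclei (severity of initial necrosis)."""
        if not self.cells:
            return 0.0
        return sum(c.pi_positive for c in self.cells) / len(self.cells)

    def epithelial_cells(self) -> list[EpithelialCell]:
        """Cells still counted among epithelial nuclei (shed cells excluded)."""
        return [c for c in self.cells if c.state != SHED]

    def counts(self, day: int) -> tuple[int, int, int]:
        """(total nuclei, PI+ attached, reporter-visible) at the given day."""
        epithelial = self.epithelial_cells()
        total = len(epithelial)
        pi = sum(1 for c in epithelial if c.pi_positive and c.state == NECROTIC_ATTACHED)
        gfp = sum(1 for c in epithelial if c.gfp_visible(day))
        return total, pi, gfp


@dataclass
class NephronPath:
    """Flow-ordered segments of one nephron with cumulative axial coordinates."""

    nephron_id: int
    mouse_id: int
    region: str
    segments: list[TubuleSegment] = field(default_factory=list)
    is_ischemic: bool = False

    def validate_flow_order(self) -> None:
        order = [FLOW_ORDER[s.segment_class] for s in self.segments]
        if order != sorted(order):
            raise ValueError(f"nephron {self.nephron_id} violates PT-S1 < PT-S2 < DCT/CD flow order")
        coords = [s.axial_start for s in self.segments] + [self.segments[-1].axial_end]
        if not all(a < b for a, b in zip(coords, coords[1:])):
            raise ValueError(f"nephron {self.nephron_id} axial coordinates are not strictly increasing")

    @property
    def total_length(self) -> float:
        return self.segments[-1].axial_end if self.segments else 0.0

    def segment_at(self, x: float) -> TubuleSegment | None:
        for seg in self.segments:
            if seg.axial_start <= x < seg.axial_end:
                return seg
        return None


@dataclass
class ObservationSchedule:
    days: tuple[int, ...]

    def __post_init__(self) -> None:
        days = tuple(self.days)
        if list(days) != sorted(set(days)) or (days and days[0] < 0):
            raise ValueError("observation days must be sorted, unique and >= 0")
        self.days = days

    def __iter__(self) -> Iterator[int]:
        return iter(self.days)


def build_cohort_skeleton(config: CohortConfig, rng_seed: int | None = None) -> list[NephronPath]:
    """Construct the healthy cohort skeleton: nephrons, segments, cells.

    Deterministic given the seed.  Segment counts per (region, class) equal
    the configured values exactly; every segment starts healthy with zero
    cast load and undetermined fate.  Nephrons are distributed round-robin
    over mice so each mouse carries every region.
    """
    layout = config.cohort
    layout.validate()
    seed = config.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0F0]))

    nephrons: list[NephronPath] = []
    nephron_id = 0
    segment_id = 0
    cell_id = 0
    for region, n_nephrons in layout.nephrons_per_region.items():
        if n_nephrons <= 0 and n_nephrons != 0:
            raise ConfigurationError(f"negative nephron count for region {region}")
        for k in range(n_nephrons):
            mouse_id = k % layout.n_mice
            nephron = NephronPath(nephron_id=nephron_id, mouse_id=mouse_id, region=region)
            x = 0.0
            for seg_class in SEGMENT_CLASSES:
                for _ in range(layout.segments_per_nephron.get(seg_class, 0)):
                    # mild geometric variability; strictly positive lengths
                    length = layout.segment_length_um * float(rng.uniform(0.9, 1.1))
                    seg = TubuleSegment(
                        segment_id=segment_id,
                        nephron_id=nephron_id,
                        mouse_id=mouse_id,
                        segment_class=seg_class,
                        region=region,
                        axial_start=x,
                        axial_end=x + length,
                        cross_section_um2=layout.cross_section_um2[seg_class],
                        lumen_fraction=layout.lumen_fraction[seg_class],
                    )
                    seg.cells = _place_cells(seg, layout.cells_per_segment, cell_id)
                    cell_id += layout.cells_per_segment
                    x += length
                    segment_id += 1
                    nephron.segments.append(seg)
            nephron.validate_flow_order()
            nephrons.append(nephron)
            nephron_id += 1
    return nephrons


def _place_cells(seg: TubuleSegment, n_cells: int, first_id: int) -> list[EpithelialCell]:
    """Evenly spaced cells along the segment axis (single-file 1-D layout)."""
    if n_cells <= 0:
        raise ConfigurationError("cells per segment must be positive")
    spacing = seg.axial_length / n_cells
    return [
        EpithelialCell(
            cell_id=first_id + i,
            segment_id=seg.segment_id,
            axial_pos=seg.axial_start + (i + 0.5) * spacing,
        )
        for i in range(n_cells)
    ]


def segments_table(nephrons: list[NephronPath]):
    """Serialize a skeleton to one row per segment (ids, class, region, geometry)."""
    import pandas as pd

    rows = []
    for nephron in nephrons:
        for seg in nephron.segments:
            rows.append(
                {
                    "segment_id": seg.segment_id,
                    "nephron_id": seg.nephron_id,
                    "mouse_id": seg.mouse_id,
                    "segment_class": seg.segment_class,
                    "region": seg.region,
                    "axial_start_um": seg.axial_start,
                    "axial_end_um": seg.axial_end,
                    "cross_section_um2": seg.cross_section_um2,
                    "lumen_fraction": seg.lumen_fraction,
                    "n_cells": seg.n_cells_initial,
                }
            )
    return pd.DataFrame(rows)
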