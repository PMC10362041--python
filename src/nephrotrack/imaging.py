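"""Synthetic two-photon stack rendering and image-level measurement.

Renders per-segment multichannel z-stacks that mimic the acquisition
protocol: two excitation tracks (750 nm, 940 nm) x three emission channels
(red ~595/50, green ~525/50, blue ~460/50), 1 um z-step over 60 um.  The
tubule is a cylinder along x; nuclei appear as negative-stain voids in the
cytoplasmic autofluorescence, PI+ nuclei add nuclear red with attenuated
blue, the cycling reporter is green on the 940 nm track, and granular casts
are bright luminal granules on the 750 nm track only (which is what makes
cast and reporter signal separable).

The renderer is 2-D cross-section per z-plane rather than a full 3-D tube
mesh: sufficient for every measurement defined on these stacks.  Denoising
and registration hooks are deliberate no-ops (published external tools sat
there in the original workflow).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage import measure as skmeasure

from .config import OpticsParams
from .model import TubuleSegment
from .quantify import QuantificationError

TRACKS = (750, 940)
CHANNELS = ("red_595_50", "green_525_50", "blue_460_50")
RED, GREEN, BLUE = 0, 1, 2

# nuclei are ellipsoids with these semi-axes (um); cells sit in the central
# 25 um band so that five counting planes see every nucleus
NUCLEUS_SEMI = (3.5, 3.0, 4.5)  # (x, y, z)
CELL_Z_BAND = 12.0


@dataclass
class ChannelStack:
    """Calibrated multichannel z-stack: data[track, z, channel, y, x]."""

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float = 1.0
    metadata: dict = field(default_factory=dict)
    masks: dict = field(default_factory=dict)  # 'tubule'/'lumen'/'epithelium': [z, y, x]

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise QuantificationError("stack data must be 5-D (track, z, channel, y, x)")
        if self.z_step_um != 1.0:
            raise QuantificationError("z-step must be 1 um")
        if np.any(self.data < 0):
            raise QuantificationError("intensities must be >= 0")

    @property
    def n_tracks(self) -> int:
        return self.data.shape[0]

    @property
    def nz(self) -> int:
        return self.data.shape[1]

    def track(self, wavelength_nm: int) -> np.ndarray:
        return self.data[TRACKS.index(wavelength_nm)]


def _cell_geometry(i: int) -> tuple[int, float]:
    """Deterministic (side, z-offset) for cell index i.

    Alternating walls and a fixed pseudo-uniform z in the central band keep
    nuclei non-overlapping in xy, which makes zero-noise counting exact.
    """
    side = 1 if i % 2 == 0 else -1
    z = ((i * 37) % 25) - CELL_Z_BAND
    return side, float(z)


def render_segment(
    segment: TubuleSegment,
    optics: OpticsParams,
    rng: np.random.Generator | None = None,
    pixel_size_um: float = 1.0,
    nz: int = 60,
    day: int | None = None,
) -> ChannelStack:
    """Render one segment's state into a two-track z-stack.

    ``day`` selects which cells are reporter-visible (defaults to counting
    any cell with an open reporter interval).
    """
    if pixel_size_um > min(NUCLEUS_SEMI[:2]):
        raise QuantificationError(
            f"pixel size {pixel_size_um} um cannot resolve {2 * NUCLEUS_SEMI[0]} um nuclei"
        )
    rng = rng or np.random.default_rng(0)
    radius = float(np.sqrt(segment.cross_section_um2 / np.pi))
    lumen_half = segment.lumen_fraction * radius  # linear half-width of the lumen band
    length = segment.axial_length
    nx = int(round(length / pixel_size_um))
    ny = int(round((2 * radius + 8) / pixel_size_um))
    yc = ny / 2.0

    data = np.zeros((2, nz, 3, ny, nx), dtype=np.float32)
    tub_mask = np.zeros((nz, ny, nx), dtype=bool)
    lum_mask = np.zeros((nz, ny, nx), dtype=bool)

    yy = (np.arange(ny) + 0.5 - yc) * pixel_size_um
    xx = (np.arange(nx) + 0.5) * pixel_size_um
    zmid = (nz - 1) / 2.0

    blue0 = optics.blue_mean[segment.segment_class]
    green0 = optics.green_mean[segment.segment_class]

    cells = segment.cells
    local_x = np.array([c.axial_pos - segment.axial_start for c in cells])
    geo = [_cell_geometry(i) for i in range(len(cells))]

    # per-cell cytoplasm attenuation (NADH depletion in necrotic cells)
    att_b = np.array([1.0 - optics.blue_attenuation if c.pi_positive else 1.0 for c in cells])
    att_g = np.array([1.0 - optics.green_attenuation if c.pi_positive else 1.0 for c in cells])

    for iz in range(nz):
        zm = (iz - zmid) * 1.0
        if abs(zm) >= radius:
            continue
        w = float(np.sqrt(radius**2 - zm**2))
        wl = float(np.sqrt(max(lumen_half**2 - zm**2, 0.0)))
        tub = np.abs(yy) < w
        lum = np.abs(yy) < wl
        epi_rows = tub & ~lum
        tub_mask[iz, tub, :] = True
        lum_mask[iz, lum, :] = True
        if not epi_rows.any():
            continue
        # partition each wall into nearest-cell territories
        for side in (+1, -1):
            rows = epi_rows & ((yy > 0) if side > 0 else (yy < 0))
            if not rows.any():
                continue
            side_idx = [i for i in range(len(cells)) if geo[i][0] == side]
            if side_idx:
                owner = np.array(side_idx)[
                    np.argmin(np.abs(xx[None, :] - local_x[side_idx][:, None]), axis=0)
                ]
                data[0, iz, BLUE][np.ix_(rows, np.arange(nx))] = blue0 * att_b[owner]
                data[0, iz, GREEN][np.ix_(rows, np.arange(nx))] = green0 * att_g[owner]
            else:
                data[0, iz, BLUE][rows, :] = blue0
                data[0, iz, GREEN][rows, :] = green0
            data[1, iz, GREEN][rows, :] = optics.epithelium_940_level

    # nuclei: negative-stain voids; PI+ red; reporter green on the 940 track
    zz = np.arange(nz) - zmid
    for i, cell in enumerate(cells):
        if cell.state == "shed":
            continue  # shed nuclei are luminal debris, not epithelial voids
        side, zoff = geo[i]
        wz = np.sqrt(max(radius**2 - zoff**2, 0.0))
        wlz = np.sqrt(max(lumen_half**2 - zoff**2, 0.0))
        y0 = side * (wlz + (wz - wlz) / 2.0)
        x0 = local_x[i]
        dz2 = ((zz - zoff) / NUCLEUS_SEMI[2]) ** 2
        for iz in np.nonzero(dz2 < 1.0)[0]:
            rem = 1.0 - dz2[iz]
            ex = NUCLEUS_SEMI[0] * np.sqrt(rem)
            ey = NUCLEUS_SEMI[1] * np.sqrt(rem)
            blob = ((yy[:, None] - y0) / ey) ** 2 + ((xx[None, :] - x0) / ex) ** 2 < 1.0
            if not blob.any():
                continue
            data[0, iz, BLUE][blob] *= optics.nucleus_void_level
            data[0, iz, GREEN][blob] *= optics.nucleus_void_level
            if cell.pi_positive:
                data[0, iz, RED][blob] = optics.pi_red_intensity
            visible = (
                cell.gfp_visible(day) if day is not None else cell.gfp_interval is not None
            )
            if visible:
                data[1, iz, GREEN][blob] = optics.gfp_track_intensity

    _render_casts(data, tub_mask, lum_mask, segment, optics, rng, pixel_size_um)

    if optics.noise_poisson_scale > 0:
        data = rng.poisson(data * optics.noise_poisson_scale).astype(np.float32)
        data /= optics.noise_poisson_scale
    if optics.noise_read_sd > 0:
        data = np.clip(data + rng.normal(0, optics.noise_read_sd, data.shape), 0, None).astype(
            np.float32
        )

    masks = {
        "tubule": tub_mask,
        "lumen": lum_mask,
        "epithelium": tub_mask & ~lum_mask,
    }
    meta = {
        "segment_id": segment.segment_id,
        "segment_class": segment.segment_class,
        "region": segment.region,
        "tracks_nm": list(TRACKS),
        "channels": list(CHANNELS),
        "pixel_size_um": pixel_size_um,
        "z_step_um": 1.0,
        "cast_fraction": segment.cast_fraction,
        "morphology": segment.morphology,
    }
    return ChannelStack(
        data=data, pixel_size_um=pixel_size_um, metadata=meta, masks=masks
    )


def _render_casts(data, tub_mask, lum_mask, segment, optics, rng, px) -> None:
    """Luminal granules covering the configured solid-area fraction at the
    widest plane (bright on the 750 nm track only)."""
    frac = segment.cast_fraction
    if frac <= 0:
        return
    nz = data.shape[1]
    widest = widest_plane(tub_mask)
    lum = lum_mask[widest]
    target = int(round(frac * tub_mask[widest].sum()))
    if target <= 0 or not lum.any():
        return
    granule = np.zeros_like(lum)
    ys, xs = np.nonzero(lum)
    order = rng.permutation(len(ys))
    r_px = max(int(round(2.5 / px)), 1)
    yy, xx = np.ogrid[: lum.shape[0], : lum.shape[1]]
    k = 0
    while granule.sum() < target and k < len(order):
        cy, cx = ys[order[k]], xs[order[k]]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        granule |= disk & lum
        k += 1
    excess = int(granule.sum()) - target
    if excess > 0:
        gy, gx = np.nonzero(granule)
        drop = rng.choice(len(gy), size=excess, replace=False)
        granule[gy[drop], gx[drop]] = False
    for iz in range(nz):
        g = granule & lum_mask[iz]
        data[0, iz, GREEN][g] = optics.cast_intensity
        data[0, iz, BLUE][g] = optics.cast_intensity


# ---------------------------------------------------------------------------
# measurement on stacks


def widest_plane(tubule_mask: np.ndarray) -> int:
    """Index of the z-plane with the largest tubule diameter.

    Ties (the discrete grid flattens the profile near the equator) break
    toward the stack middle.
    """
    widths = tubule_mask.any(axis=2).sum(axis=1)
    best = np.flatnonzero(widths == widths.max())
    zmid = (len(widths) - 1) / 2.0
    return int(best[np.argmin(np.abs(best - zmid))])


def measure_channels(stack: ChannelStack, mask: np.ndarray | None = None):
    """Raw channel means over the epithelial mask, plus the widest plane.

    Returns (mean_green, mean_blue, cross_section_um2, widest_plane_index).
    Quantification happens on unprocessed intensities.
    """
    if mask is None:
        mask = stack.masks.get("epithelium")
    if mask is None or not np.any(mask):
        raise QuantificationError("empty epithelial mask")
    t750 = stack.track(750)
    mean_green = float(t750[:, GREEN][mask].mean())
    mean_blue = float(t750[:, BLUE][mask].mean())
    tub = stack.masks.get("tubule", mask)
    widest = widest_plane(tub)
    area = float(tub[widest].sum()) * stack.pixel_size_um**2
    return mean_green, mean_blue, area, widest


def _detect_blobs(plane: np.ndarray, mask: np.ndarray, threshold: float, min_area: int = 5):
    lab = skmeasure.label(mask & (plane > threshold) if threshold > 0 else mask)
    out = []
    for region in skmeasure.regionprops(lab):
        if region.area >= min_area:
            out.append(region.centroid)  # (y, x)
    return out


def count_nuclei_stack(stack: ChannelStack, optics: OpticsParams | None = None):
    """Volumetric nuclei counting on five planes spanning the central 25 um.

    Nuclei are negative-stain voids on the 750 nm blue channel; PI+ nuclei
    carry nuclear red; reporter+ nuclei are green on the 940 nm track.  A
    nucleus spanning several planes is linked by xy overlap and counted
    once.  Returns (total, pi_pos, gfp_pos); ``gfp_pos`` is None (flagged)
    when the 940 nm track is missing.
    """
    optics = optics or OpticsParams()
    nz = stack.nz
    if nz * stack.z_step_um < 25.0:
        raise QuantificationError("usable depth below the 25 um counting volume")
    zmid = (nz - 1) / 2.0
    planes = [int(round(zmid + off)) for off in (-12.5, -6.25, 0.0, 6.25, 12.5)]
    epi = stack.masks.get("epithelium")
    if epi is None:
        raise QuantificationError("stack lacks an epithelium mask")
    t750 = stack.track(750)
    has_940 = stack.n_tracks > 1
    t940 = stack.track(940) if has_940 else None

    px = stack.pixel_size_um
    # nucleus-sized blob area bounds (um^2 -> px); necrotic cells attenuate
    # their whole cytoplasmic territory, so bare voids are only trusted at
    # nucleus size and PI+ nuclei are detected by their nuclear red signal
    min_area = max(int(3 / px**2), 3)
    max_area = int(48 / px**2)
    found: list[tuple[float, float, bool, bool, int]] = []  # (y_um, x_um, pi, gfp, area)
    for iz in planes:
        mask = epi[iz]
        if not mask.any():
            continue
        # 3x3 median: suppresses detector speckle without moving edges
        blue = ndimage.median_filter(t750[iz, BLUE], size=3)
        red = ndimage.median_filter(t750[iz, RED], size=3)
        red_hot = red > 0.5 * optics.pi_red_intensity
        for region in skmeasure.regionprops(skmeasure.label(mask & red_hot)):
            if region.area < min_area:
                continue
            cy, cx = region.centroid
            gfp = False
            if has_940:
                coords = tuple(region.coords.T)
                gfp = bool(t940[iz, GREEN][coords].mean() > 0.5 * optics.gfp_track_intensity)
            found.append((cy * px, cx * px, True, gfp, int(region.area)))
        vals = blue[mask & (blue > 0)]
        if vals.size == 0:
            continue
        # bright (unattenuated) cytoplasm level; robust to segments whose
        # necrotic-cell territories darken a majority of the epithelium
        bright = float(np.percentile(vals, 90))
        if bright <= 0:
            continue
        # two void bands: nuclei inside healthy cytoplasm sit well below the
        # bright level but above darkened (NADH-depleted) cytoplasm; nuclei
        # inside darkened cytoplasm are darker still
        band_a = mask & (blue < 0.5 * bright) & (blue > 0.10 * bright) & ~red_hot
        band_b = mask & (blue < 0.025 * bright) & ~red_hot
        for voids in (band_a, band_b):
            for region in skmeasure.regionprops(skmeasure.label(voids)):
                if not min_area <= region.area <= max_area:
                    continue
                coords = tuple(region.coords.T)
                if red[coords].max() > 0.5 * optics.pi_red_intensity:
                    continue  # PI+ nucleus already counted through red
                cy, cx = region.centroid
                gfp = False
                if has_940:
                    gfp = bool(
                        t940[iz, GREEN][coords].mean() > 0.5 * optics.gfp_track_intensity
                    )
                found.append((cy * px, cx * px, False, gfp, int(region.area)))


    # xy-overlap linking: centroids within one nucleus diameter are the same
    # nucleus seen on different planes
    clusters: list[list[int]] = []
    assigned = [-1] * len(found)
    for i, (y, x, *_rest) in enumerate(found):
        for ci, members in enumerate(clusters):
            my, mx = np.mean([[found[m][0], found[m][1]] for m in members], axis=0)
            if (y - my) ** 2 + (x - mx) ** 2 < (2 * NUCLEUS_SEMI[0]) ** 2:
                members.append(i)
                assigned[i] = ci
                break
        if assigned[i] < 0:
            clusters.append([i])
    # a true nucleus shows a solid blob on its best plane; clusters made
    # only of marginal slices are noise artefacts
    solid_area = max(int(6 / px**2), 4)
    clusters = [c for c in clusters if max(found[m][4] for m in c) >= solid_area]
    total = len(clusters)
    pi_pos = sum(1 for c in clusters if any(found[m][2] for m in c))
    gfp_pos = sum(1 for c in clusters if any(found[m][3] for m in c)) if has_940 else None
    return total, pi_pos, gfp_pos


def cast_fraction_stack(stack: ChannelStack, optics: OpticsParams | None = None):
    """Cast area over cross-sectional area (%) at the widest plane.

    Returns (percentage, collapsed_flag); the flag marks stacks whose lumen
    is not patent at the widest plane (atrophic collapse), where the
    normalisation is unreliable.
    """
    optics = optics or OpticsParams()
    tub = stack.masks.get("tubule")
    lum = stack.masks.get("lumen")
    if tub is None or lum is None or not tub.any():
        raise QuantificationError("stack lacks tubule/lumen masks")
    widest = widest_plane(tub)
    collapsed = not lum[widest].any() or stack.metadata.get("morphology") == "atrophic"
    t750 = stack.track(750)
    solid = lum[widest] & (t750[widest, BLUE] > 0.5 * optics.cast_intensity)
    denom = tub[widest].sum()
    pct = 100.0 * float(solid.sum()) / float(denom) if denom else 0.0
    return pct, collapsed


# ---------------------------------------------------------------------------
# bolus tracking


def render_bolus_trace(
    segment_class: str,
    frame_rate_hz: float = 13.7,
    duration_s: float = 15.0,
    arrival_s1_s: float = 3.0,
    transit_delay_s: float = 2.0,
    rise_tau_s: float = 0.6,
    amplitude: float = 100.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Luminal dye-intensity time series during an i.v. dextran bolus.

    Filtered dextran reaches PT-S1 first and PT-S2 after the configured
    tubular transit delay.
    """
    if segment_class not in ("PT-S1", "PT-S2"):
        raise QuantificationError("bolus tracking is defined for PT-S1 and PT-S2")
    rng = rng or np.random.default_rng(0)
    n = int(round(duration_s * frame_rate_hz))
    t = np.arange(n) / frame_rate_hz
    arrival = arrival_s1_s + (transit_delay_s if segment_class == "PT-S2" else 0.0)
    trace = amplitude * (1.0 - np.exp(-np.clip(t - arrival, 0, None) / rise_tau_s))
    trace[t < arrival] = 0.0
    if noise_sd > 0:
        trace = np.clip(trace + rng.normal(0, noise_sd, n), 0, None)
    return trace


# ---------------------------------------------------------------------------
# TIFF + JSON sidecar I/O


def save_stack(stack: ChannelStack, path: str | Path) -> Path:
    """Write a multi-page TIFF (axes TZCYX) with a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, metadata={"axes": "TZCYX"})
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size_um": stack.pixel_size_um,
                "z_step_um": stack.z_step_um,
                **{k: v for k, v in stack.metadata.items()},
            },
            default=float,
            indent=1,
        )
    )
    return path


def load_stack(path: str | Path) -> ChannelStack:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ChannelStack(
        data=np.asarray(data, dtype=np.float32),
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        z_step_um=float(meta.get("z_step_um", 1.0)),
        metadata=meta,
    )


def denoise_hook(stack: ChannelStack) -> ChannelStack:
    """No-op placeholder where VST+BM4D denoising sat in the original
    acquisition workflow; quantification runs on unprocessed images."""
    return stack


def register_hook(stacks: list[ChannelStack]) -> list[ChannelStack]:
    """No-op placeholder for serial-session registration (BigWarp slot)."""
    return stacks
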