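"""Rendering and image-level measurement: closed loops and degradation."""

import numpy as np
import pytest

from nephrotrack import imaging
from nephrotrack.config import default_config
from nephrotrack.quantify import QuantificationError, bolus_arrival
from nephrotrack.simulate import build_cohort, seed_necrosis, step_day


@pytest.fixture(scope="module")
def stepped_cohort():
    cfg = default_config("partial_iri_long", seed=3)
    cohort = seed_necrosis(build_cohort(cfg))
    for t in range(1, 5):
        step_day(cohort, t)
    return cfg, cohort


def _segment_where(cohort, pred):
    return next(s for s in cohort.segments if pred(s))


def test_noiseless_render_reproduces_class_channel_ratio(stepped_cohort):
    cfg, cohort = stepped_cohort
    seg = _segment_where(
        cohort, lambda s: s.segment_class == "PT-S2" and s.pi0_fraction == 0 and s.cast_fraction == 0
    )
    stack = imaging.render_segment(seg, cfg.optics, day=4)
    g, b, area, widest = imaging.measure_channels(stack)
    expect = cfg.optics.green_mean["PT-S2"] / cfg.optics.blue_mean["PT-S2"]
    assert g / b == pytest.approx(expect, rel=1e-6)
    assert area > 0


def test_pt_s2_renders_brighter_than_pt_s1_in_both_channels(stepped_cohort):
    cfg, cohort = stepped_cohort
    s1 = _segment_where(cohort, lambda s: s.segment_class == "PT-S1" and s.pi0_fraction == 0)
    s2 = _segment_where(cohort, lambda s: s.segment_class == "PT-S2" and s.pi0_fraction == 0)
    g1, b1, _, _ = imaging.measure_channels(imaging.render_segment(s1, cfg.optics, day=4))
    g2, b2, _, _ = imaging.measure_channels(imaging.render_segment(s2, cfg.optics, day=4))
    assert g2 > g1 and b2 > b1


def test_pi_positive_nuclei_appear_as_exactly_that_many_red_blobs(stepped_cohort):
    cfg, _ = stepped_cohort
    cohort = seed_necrosis(build_cohort(cfg.replace(seed=21)))
    seg = _segment_where(cohort, lambda s: 8 <= sum(c.pi_positive for c in s.cells) <= 12)
    truth = seg.counts(0)
    stack = imaging.render_segment(seg, cfg.optics, day=0)
    total, pi, gfp = imaging.count_nuclei_stack(stack, cfg.optics)
    assert pi == truth[1]
    assert total == truth[0]


def test_render_count_closed_loop_is_exact_at_zero_noise(stepped_cohort):
    cfg, cohort = stepped_cohort
    rng = np.random.default_rng(0)
    idx = rng.choice(len(cohort.segments), size=25, replace=False)
    for i in idx:
        seg = cohort.segments[i]
        stack = imaging.render_segment(seg, cfg.optics, day=4)
        assert imaging.count_nuclei_stack(stack, cfg.optics) == seg.counts(4)


def test_render_measure_cast_loop_within_one_percent(stepped_cohort):
    cfg, cohort = stepped_cohort
    segs = sorted(cohort.segments, key=lambda s: -s.cast_fraction)[:10]
    for seg in segs:
        stack = imaging.render_segment(seg, cfg.optics, day=4)
        pct, _ = imaging.cast_fraction_stack(stack, cfg.optics)
        assert pct == pytest.approx(100 * seg.cast_fraction, abs=1.0)


def test_counting_error_degrades_monotonically_with_noise(stepped_cohort):
    cfg, cohort = stepped_cohort
    segs = [s for s in cohort.segments if 0.05 < s.pi0_fraction < 0.3][:6]
    errors = []
    for read_sd in (0.0, 8.0, 40.0):
        optics = cfg.optics.__class__(**{**cfg.optics.__dict__, "noise_read_sd": read_sd})
        errs = []
        for seg in segs:
            for rep in range(2):
                stack = imaging.render_segment(
                    seg, optics, rng=np.random.default_rng(rep), day=4
                )
                total, pi, gfp = imaging.count_nuclei_stack(stack, optics)
                truth = seg.counts(4)
                errs.append(abs(total - truth[0]) + abs(pi - truth[1]))
        errors.append(np.mean(errs))
    assert errors[0] <= errors[1] <= errors[2]


def test_moderate_noise_keeps_error_within_one_nucleus(stepped_cohort):
    cfg, cohort = stepped_cohort
    optics = cfg.optics.__class__(**{**cfg.optics.__dict__, "noise_read_sd": 2.0})
    rng = np.random.default_rng(1)
    idx = rng.choice(len(cohort.segments), size=20, replace=False)
    within = 0
    for i in idx:
        seg = cohort.segments[i]
        stack = imaging.render_segment(seg, optics, rng=np.random.default_rng(i), day=4)
        total, _, _ = imaging.count_nuclei_stack(stack, optics)
        within += abs(total - seg.counts(4)[0]) <= 1
    assert within / len(idx) >= 0.95


def test_uniform_channel_mean_is_exact():
    data = np.zeros((2, 60, 3, 10, 10), dtype=np.float32)
    data[0, :, 1] = 7.5
    data[0, :, 2] = 2.5
    mask = np.ones((60, 10, 10), dtype=bool)
    stack = imaging.ChannelStack(data=data, pixel_size_um=1.0, masks={"epithelium": mask, "tubule": mask})
    g, b, _, _ = imaging.measure_channels(stack)
    assert g == 7.5 and b == 2.5


def test_largest_diameter_plane_is_the_widest():
    data = np.zeros((2, 60, 3, 20, 10), dtype=np.float32)
    tub = np.zeros((60, 20, 10), dtype=bool)
    tub[10, 5:11, :] = True   # 30 um wide
    tub[40, 0:10, :] = True   # 50 um wide
    stack = imaging.ChannelStack(data=data, pixel_size_um=1.0, masks={"epithelium": tub, "tubule": tub})
    assert imaging.measure_channels(stack)[3] == 40


def test_empty_mask_raises():
    data = np.zeros((2, 60, 3, 5, 5), dtype=np.float32)
    stack = imaging.ChannelStack(data=data, pixel_size_um=1.0)
    with pytest.raises(QuantificationError):
        imaging.measure_channels(stack)


def test_depth_below_25um_raises(stepped_cohort):
    cfg, cohort = stepped_cohort
    stack = imaging.render_segment(cohort.segments[0], cfg.optics, nz=20, day=4)
    with pytest.raises(QuantificationError):
        imaging.count_nuclei_stack(stack, cfg.optics)


def test_coarse_pixels_cannot_resolve_nuclei(stepped_cohort):
    cfg, cohort = stepped_cohort
    with pytest.raises(QuantificationError):
        imaging.render_segment(cohort.segments[0], cfg.optics, pixel_size_um=4.0)


def test_missing_940_track_flags_gfp_as_undefined(stepped_cohort):
    cfg, cohort = stepped_cohort
    seg = cohort.segments[0]
    stack = imaging.render_segment(seg, cfg.optics, day=4)
    single = imaging.ChannelStack(
        data=stack.data[:1], pixel_size_um=1.0, masks=stack.masks, metadata=stack.metadata
    )
    total, pi, gfp = imaging.count_nuclei_stack(single, cfg.optics)
    assert gfp is None
    assert total == seg.counts(4)[0]


def test_tiff_round_trip_is_bit_exact(tmp_path, stepped_cohort):
    cfg, cohort = stepped_cohort
    stack = imaging.render_segment(cohort.segments[3], cfg.optics, day=4)
    path = imaging.save_stack(stack, tmp_path / "seg.tiff")
    back = imaging.load_stack(path)
    assert np.array_equal(back.data, stack.data)
    assert back.pixel_size_um == stack.pixel_size_um
    assert back.metadata["segment_class"] == stack.metadata["segment_class"]


# ---------------------------------------------------------------------------
# bolus tracking


def test_zero_transit_delay_gives_identical_arrivals():
    a = imaging.render_bolus_trace("PT-S1", transit_delay_s=0.0)
    b = imaging.render_bolus_trace("PT-S2", transit_delay_s=0.0)
    assert bolus_arrival(a) == bolus_arrival(b)


def test_transit_delay_is_recovered_by_threshold_crossing():
    delay = 2.0
    rate = 13.7
    a = imaging.render_bolus_trace("PT-S1", transit_delay_s=delay, frame_rate_hz=rate)
    b = imaging.render_bolus_trace("PT-S2", transit_delay_s=delay, frame_rate_hz=rate)
    ta, tb = bolus_arrival(a, rate), bolus_arrival(b, rate)
    assert tb - ta == pytest.approx(delay, abs=1.5 / rate)


def test_filtered_dye_reaches_s1_before_s2():
    a = imaging.render_bolus_trace("PT-S1")
    b = imaging.render_bolus_trace("PT-S2")
    assert bolus_arrival(a) < bolus_arrival(b)


def test_bolus_trace_rejects_distal_classes():
    with pytest.raises(QuantificationError):
        imaging.render_bolus_trace("DCT-CD")
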