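"""Pattern planning, proximity dose maps, conversion maps, FWHM metrology."""

import numpy as np
import pytest

from febic.beam_dose import BeamSettings, areal_dose
from febic.kinetics import KineticParams, max_cellulose_fraction, optimal_dose
from febic.patterning import (
    ExposurePlan,
    PatternBitmap,
    ProximityPSF,
    convert_map,
    dose_map,
    line_space_bitmap,
    measure_fwhm,
    plan_from_bitmap,
)

SETTINGS = BeamSettings(2.0, 53.0, 1200.0, 1, beam_diameter_nm=20.8)
PARAMS = KineticParams(1.0, 2.5, 0.8)


def _sorted_points(plan):
    return plan.points_nm[np.lexsort((plan.points_nm[:, 0], plan.points_nm[:, 1]))]


def test_plan_point_count_on_full_field():
    """A fully exposed 1x1 um field at 10.4 nm pitch holds 97^2 points."""
    bitmap = PatternBitmap(np.ones((100, 100), bool), pixel_size_nm=10.0)
    plan = plan_from_bitmap(bitmap, SETTINGS)
    per_axis = int(np.floor(1000.0 / 10.4)) + 1
    assert len(plan) == per_axis**2 == 9409
    assert np.all(plan.dwells_ns == 1200.0)


def test_empty_bitmap_gives_empty_plan():
    bitmap = PatternBitmap(np.zeros((50, 50), bool), pixel_size_nm=10.0)
    plan = plan_from_bitmap(bitmap, SETTINGS)
    assert len(plan) == 0


def test_orderings_expose_identical_point_sets():
    bitmap = line_space_bitmap(100.0, 150.0, 3, 400.0, pixel_size_nm=5.0)
    serp = plan_from_bitmap(bitmap, SETTINGS, ordering="serpentine")
    inter = plan_from_bitmap(bitmap, SETTINGS, ordering="interlaced")
    np.testing.assert_array_equal(_sorted_points(serp), _sorted_points(inter))
    assert not np.array_equal(serp.points_nm, inter.points_nm)  # order differs


def test_stream_file_round_trip(tmp_path):
    bitmap = line_space_bitmap(60.0, 120.0, 2, 200.0, pixel_size_nm=5.0)
    plan = plan_from_bitmap(bitmap, SETTINGS)
    path = tmp_path / "pattern.str"
    plan.write_stream(path)
    back = ExposurePlan.read_stream(path, SETTINGS.beam_current_pA)
    assert back.n_passes == plan.n_passes
    assert len(back) == len(plan)
    np.testing.assert_allclose(back.points_nm, np.round(plan.points_nm), atol=0.5)
    header = path.read_text().splitlines()[0]
    assert header == "s16"


def test_flat_field_interior_dose_matches_areal_dose():
    """Deep inside a large uniformly exposed field the delivered dose is the
    nominal areal dose times (1 + eta)."""
    bitmap = PatternBitmap(np.ones((100, 100), bool), pixel_size_nm=10.0)
    plan = plan_from_bitmap(bitmap, SETTINGS)
    eta = 0.15
    psf = ProximityPSF(8.0, 60.0, eta)
    dm = dose_map(plan, psf, grid_nm=2.0)
    xc, yc = dm.x_centers_nm, 0.5 * (dm.y_edges_nm[:-1] + dm.y_edges_nm[1:])
    interior = dm.dose[np.ix_(
        (yc > 300) & (yc < 700), (xc > 300) & (xc < 700)
    )]
    assert interior.mean() == pytest.approx(areal_dose(SETTINGS) * (1 + eta), rel=0.02)
    assert dm.charge_loss_fraction <= 0.005


def test_single_point_spot_fwhm_is_gaussian():
    plan = ExposurePlan(np.array([[0.0, 0.0]]), np.array([1200.0]), 1, 53.0)
    sigma = 30.0
    dm = dose_map(plan, ProximityPSF(sigma, 60.0, 0.0), grid_nm=1.0, pad_nm=6 * sigma)
    iy = np.argmax(dm.dose.max(axis=1))
    width = measure_fwhm(dm.dose[iy], dm.x_centers_nm)
    assert width.width_nm == pytest.approx(2.355 * sigma, abs=1.0)


def test_symmetric_plan_gives_symmetric_dose_map():
    xs = np.array([-90.0, -60.0, -30.0, 0.0, 30.0, 60.0, 90.0])
    pts = np.column_stack([xs, np.zeros_like(xs)])
    plan = ExposurePlan(pts, np.full(xs.size, 500.0), 1, 53.0)
    dm = dose_map(plan, ProximityPSF(10.0, 40.0, 0.1), grid_nm=2.0, pad_nm=160.0)
    profile = dm.dose.sum(axis=0)
    # mirror the profile about the charge centre: must coincide
    com = np.average(dm.x_centers_nm, weights=profile)
    interp = np.interp(2 * com - dm.x_centers_nm, dm.x_centers_nm, profile)
    # half-bin lattice offset and FFT roundoff allow tiny deviations
    np.testing.assert_allclose(
        profile[2:-2], interp[2:-2], rtol=1e-2, atol=1e-5 * profile.max()
    )


def test_convert_map_limits():
    plan = ExposurePlan(np.array([[0.0, 0.0]]), np.array([1200.0]), 1, 53.0)
    dm = dose_map(plan, ProximityPSF(10.0, 40.0, 0.0), grid_nm=2.0, pad_nm=150.0)
    cm = convert_map(dm, PARAMS)
    # far corners got essentially no dose: still TMSC
    assert cm.fractions.f_tmsc[0, 0] == pytest.approx(1.0, abs=1e-6)
    cm.fractions.validate()


def test_overdosed_line_develops_cellulose_halo():
    """When the line centre is pushed deep into the over-exposure regime,
    the cellulose maximum sits off-centre (non-monotone dose response)."""
    d_star = optimal_dose(PARAMS)
    # dwell chosen so the line-centre dose lands ~8x past the optimum
    hot = SETTINGS.with_(dwell_time_ns=1200.0 * 8)
    bitmap = line_space_bitmap(40.0, 400.0, 1, 300.0, pixel_size_nm=4.0)
    plan = plan_from_bitmap(bitmap, hot)
    dm = dose_map(plan, ProximityPSF(15.0, 60.0, 0.05), grid_nm=2.0)
    cm = convert_map(dm, PARAMS)
    iy = dm.dose.shape[0] // 2
    dose_prof = dm.dose[iy]
    cell_prof = cm.f_cellulose[iy]
    i_hot = int(np.argmax(dose_prof))
    assert dose_prof[i_hot] > 3 * d_star
    assert cell_prof[np.argmax(cell_prof)] > cell_prof[i_hot]  # off-centre maxima
    assert abs(int(np.argmax(cell_prof)) - i_hot) >= 2


def test_delta_kernel_limit_reproduces_thresholded_bitmap():
    """With eta = 0 and a PSF much narrower than the pitch, interior pixels
    of exposed regions convert as the nominal dose prescribes and
    unexposed regions stay TMSC."""
    bitmap = PatternBitmap(np.ones((60, 60), bool), pixel_size_nm=10.0)
    plan = plan_from_bitmap(bitmap, SETTINGS)
    dm = dose_map(plan, ProximityPSF(4.0, 40.0, 0.0), grid_nm=10.4 / 2)
    nominal = areal_dose(SETTINGS)
    xc = dm.x_centers_nm
    yc = 0.5 * (dm.y_edges_nm[:-1] + dm.y_edges_nm[1:])
    interior = dm.dose[np.ix_((yc > 150) & (yc < 450), (xc > 150) & (xc < 450))]
    assert interior.mean() == pytest.approx(nominal, rel=0.02)


def test_fwhm_rectangular_pulse():
    x = np.arange(0.0, 200.0, 1.0)
    v = ((x >= 50) & (x < 130)).astype(float)
    w = measure_fwhm(v, x)
    assert w.width_nm == pytest.approx(80.0, abs=1.0)


def test_fwhm_open_ended_flagging():
    x = np.arange(0.0, 100.0, 1.0)
    v = np.exp(-((x - 95.0) ** 2) / (2 * 20.0**2))  # peak at the right edge
    w = measure_fwhm(v, x)
    assert w.open_right and not w.open_left


def test_fwhm_rejects_flat_profile():
    with pytest.raises(ValueError):
        measure_fwhm(np.ones(10), np.arange(10.0))


def test_line_fwhm_non_decreasing_in_bse_width_and_eta():
    """Proximity broadening: the converted line FWHM never shrinks when the
    BSE amplitude grows, nor when the BSE kernel widens while its halo
    still overlaps the line (sigma_bse up to the line width — the regime
    the Monte Carlo predicts at low keV). A much wider kernel dilutes the
    BSE dose over a large area, so the width relaxes back toward the
    primary-only value but never below it."""
    # under-dosed line so conversion is monotone in dose
    cool = SETTINGS.with_(dwell_time_ns=300.0)
    bitmap = line_space_bitmap(60.0, 500.0, 1, 240.0, pixel_size_nm=4.0)
    plan = plan_from_bitmap(bitmap, cool)

    def line_width(sigma_bse, eta):
        dm = dose_map(plan, ProximityPSF(10.0, sigma_bse, eta), grid_nm=2.0)
        cm = convert_map(dm, PARAMS)
        iy = dm.dose.shape[0] // 2
        return measure_fwhm(cm.f_cellulose[iy], dm.x_centers_nm).width_nm

    w0 = line_width(60.0, 0.0)
    widths_sigma = [line_width(s, 0.2) for s in (12.0, 20.0, 30.0)]
    assert np.all(np.diff(widths_sigma) >= -1e-9)
    # any BSE contribution broadens relative to the primary-only line
    assert all(line_width(s, 0.2) >= w0 for s in (12.0, 60.0, 200.0))
    widths_eta = [line_width(45.0, e) for e in (0.0, 0.15, 0.4)]
    assert np.all(np.diff(widths_eta) >= -1e-9)


def test_bitmap_validation_and_image_io(tmp_path):
    with pytest.raises(ValueError):
        PatternBitmap(np.ones((4, 4), bool), pixel_size_nm=-1.0)
    from PIL import Image

    arr = np.zeros((20, 20), dtype=np.uint8)
    arr[5:15, 5:15] = 255
    path = tmp_path / "pattern.png"
    Image.fromarray(arr).save(path)
    bm = PatternBitmap.from_image(path, pixel_size_nm=5.0)
    assert bm.pixels.sum() == 100
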