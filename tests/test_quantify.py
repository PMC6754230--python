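"""Measurement conventions: alignment, binning, normalization, indices, speeds."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kip2traffic.constants import PIXEL_SIZE_NM
from kip2traffic.quantify import (
    AlignedProfile,
    AlignmentError,
    CellRecord,
    KymographTrack,
    LengthSeries,
    LineScan,
    ProfileBin,
    ProfileBins,
    align_line_scan,
    asymmetry_index,
    bin_profiles,
    microtubule_length_3d,
    plus_end_regression,
    qq_normalize,
    relative_fluorescence,
    speckle_speed,
    summarize_dynamics,
)

PX = PIXEL_SIZE_NM


def _scan(gfp_peak_idx, mch_peak_idx, n=30, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    positions = np.arange(n) * PX
    x = np.arange(n)
    gfp = 10.0 + 100.0 * np.exp(-0.5 * ((x - gfp_peak_idx) / 1.5) ** 2)
    mch = 10.0 + 100.0 * np.exp(-0.5 * ((x - mch_peak_idx) / 1.5) ** 2)
    if noise:
        gfp = gfp + rng.normal(0, noise, n)
        mch = mch + rng.normal(0, noise, n)
    return LineScan(positions, gfp, mch, cell_id="c", date="d")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def test_profile_length_is_peak_to_peak_distance():
    aligned = align_line_scan(_scan(gfp_peak_idx=12, mch_peak_idx=3))
    assert aligned.profile_length == pytest.approx(9 * PX)
    assert aligned.positions[3] == pytest.approx(0.0)
    assert not aligned.degenerate


def test_coincident_peaks_flagged_degenerate():
    aligned = align_line_scan(_scan(gfp_peak_idx=5, mch_peak_idx=5))
    assert aligned.profile_length == 0.0
    assert aligned.degenerate


def test_flat_channel_rejected_with_reason():
    positions = np.arange(30) * PX
    flat = np.full(30, 10.0)
    peaked = 10.0 + 100.0 * np.exp(-0.5 * ((np.arange(30) - 5) / 1.5) ** 2)
    with pytest.raises(AlignmentError, match="flat-channel"):
        align_line_scan(LineScan(positions, flat, peaked))


def test_gfp_peak_before_spb_rejected():
    with pytest.raises(AlignmentError, match="negative-length"):
        align_line_scan(_scan(gfp_peak_idx=2, mch_peak_idx=10))


def test_alignment_recovers_known_offsets_within_one_pixel():
    """Noisy two-channel scans with known peak geometry."""
    for seed in range(5):
        scan = _scan(gfp_peak_idx=14, mch_peak_idx=4, noise=3.0, seed=seed)
        aligned = align_line_scan(scan)
        assert abs(aligned.profile_length - 10 * PX) <= PX


def test_generator_scans_align_end_to_end():
    """Low-noise synthetic scans align to the SPB with the plus end in-lattice.

    The generated wild-type profile is a plateau with a mild tip maximum, so
    peak-to-peak alignment places the plus end inside the represented lattice
    (within pixel tolerance) rather than at an exact offset.
    """
    from kip2traffic.synthetic import generate_profile_dataset, preset

    truth = preset("wt", seed=3, cells_per_bin=3, noise_sd_au=2.0)
    bins, scans, _ = generate_profile_dataset(truth)
    n_checked = 0
    for scan in scans:
        aligned = align_line_scan(scan, min_snr=1.0)
        bin_idx = int(scan.cell_id.split("_")[0].removeprefix("bin"))
        b = bins.bins[bin_idx]
        assert aligned.profile_length <= b.hi + 2 * PX
        assert aligned.profile_length >= 0.0
        n_checked += 1
    assert n_checked == len(scans)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def _aligned(length_nm, values, lead=3):
    n = int(np.ceil(length_nm / PX)) + lead + 4
    positions = (np.arange(n) - lead) * PX
    gfp = np.asarray(values, dtype=float)[: n] if np.ndim(values) else np.full(n, float(values))
    return AlignedProfile(positions, gfp, float(length_nm))


def test_single_profile_bin_is_degenerate_with_zero_sem():
    bins = bin_profiles([_aligned(500.0, 5.0)], bin_size=266.7)
    assert len(bins) == 1
    b = bins.bins[0]
    assert b.degenerate and b.n == 1
    assert np.all(b.sem == 0.0)
    assert np.allclose(b.mean, 5.0)


def test_identical_profiles_have_zero_sem():
    bins = bin_profiles([_aligned(500.0, 7.0), _aligned(500.0, 7.0)], bin_size=266.7)
    b = bins.bins[0]
    assert b.n == 2 and not b.degenerate
    assert np.all(b.sem == 0.0)


def test_binning_is_a_partition():
    """Every profile lands in exactly one bin; counts are conserved."""
    rng = np.random.default_rng(4)
    lengths = rng.uniform(300, 2200, size=60)
    profiles = [_aligned(L, 3.0) for L in lengths]
    bins = bin_profiles(profiles, bin_size=266.7)
    assert sum(b.n for b in bins) == len(profiles)
    for L in lengths:
        k = int(np.floor(L / 266.7))
        assert any(b.lo == pytest.approx(k * 266.7) for b in bins)


def test_sem_matches_sampling_law():
    """SEM of n i.i.d.-noise profiles approximates sigma/sqrt(n)."""
    rng = np.random.default_rng(5)
    n, sigma = 100, 4.0
    profiles = []
    for _ in range(n):
        p = _aligned(500.0, 10.0)
        p.gfp = p.gfp + rng.normal(0, sigma, p.gfp.size)
        profiles.append(p)
    bins = bin_profiles(profiles, bin_size=266.7)
    expected = sigma / np.sqrt(n)
    assert np.mean(bins.bins[0].sem) == pytest.approx(expected, rel=0.2)


def test_low_count_bins_dropped_with_warning():
    profiles = [_aligned(500.0, 1.0)] * 3 + [_aligned(1200.0, 1.0)]
    with pytest.warns(UserWarning, match="dropping length bin"):
        bins = bin_profiles(profiles, bin_size=266.7, min_count=2)
    assert len(bins) == 1
    assert bins.bins[0].n == 3


def test_profile_bins_csv_roundtrip(tmp_path):
    profiles = [_aligned(500.0, v) for v in (3.0, 5.0, 7.0)]
    bins = bin_profiles(profiles, bin_size=266.7)
    path = tmp_path / "bins.csv"
    bins.write_csv(path)
    back = ProfileBins.read_csv(path)
    assert len(back) == len(bins)
    assert np.allclose(back.bins[0].mean, bins.bins[0].mean)
    assert np.allclose(back.bins[0].sem, bins.bins[0].sem)
    assert back.bins[0].n == bins.bins[0].n


# ---------------------------------------------------------------------------
# Q-Q normalization
# ---------------------------------------------------------------------------


def test_qq_identity_recovers_unit_map():
    rng = np.random.default_rng(6)
    x = rng.normal(100, 20, 5000)
    fit = qq_normalize(x, x)
    assert fit.alpha == pytest.approx(1.0, abs=1e-10)
    assert fit.beta == pytest.approx(0.0, abs=1e-8)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    alpha=st.floats(0.1, 10.0),
    beta=st.floats(-100.0, 100.0),
)
def test_qq_recovers_any_affine_relation_exactly(alpha, beta):
    rng = np.random.default_rng(7)
    other = rng.gamma(3.0, 50.0, 2000)
    reference = alpha * other + beta
    fit = qq_normalize(reference, other)
    assert fit.alpha == pytest.approx(alpha, rel=1e-9)
    assert fit.beta == pytest.approx(beta, abs=1e-6 * max(1, abs(beta)) + 1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
    assert np.allclose(fit.mapped, reference)


def test_qq_same_distribution_slope_near_unity():
    rng = np.random.default_rng(8)
    a = rng.normal(1000, 150, 10_000)
    b = rng.normal(1000, 150, 10_000)
    fit = qq_normalize(a, b)
    assert abs(fit.alpha - 1.0) < 0.05


def test_qq_zero_variance_errors():
    with pytest.raises(ValueError, match="zero variance"):
        qq_normalize(np.arange(300.0), np.full(300, 5.0))


def test_qq_small_samples_warn():
    rng = np.random.default_rng(9)
    with pytest.warns(UserWarning, match="fewer than 199"):
        qq_normalize(rng.normal(size=50), rng.normal(size=50))


# ---------------------------------------------------------------------------
# plus-end regression
# ---------------------------------------------------------------------------


def _peak_bins(midpoints, peaks, sems):
    bins = []
    for mid, pk, s in zip(midpoints, peaks, sems):
        positions = np.array([mid - PX, mid, mid + PX])
        mean = np.array([pk - 1.0, pk, pk - 1.0])
        sem = np.full(3, s)
        bins.append(ProfileBin(mid - 133.35, mid + 133.35, positions, mean, sem, 10))
    return ProfileBins(bins, 266.7)


def test_equal_peaks_give_zero_slope():
    bins = _peak_bins([400.0, 700.0, 1000.0], [50.0, 50.0, 50.0], [2.0, 2.0, 2.0])
    slope, intercept = plus_end_regression(bins)
    assert slope == pytest.approx(0.0, abs=1e-12)
    assert intercept == pytest.approx(50.0)


def test_proportional_peaks_recover_proportionality():
    mids = [400.0, 700.0, 1000.0, 1300.0]
    bins = _peak_bins(mids, [0.05 * m for m in mids], [1.0] * 4)
    slope, intercept = plus_end_regression(bins)
    assert slope == pytest.approx(0.05, rel=1e-9)
    assert intercept == pytest.approx(0.0, abs=1e-6)


def test_weighted_fit_matches_normal_equations():
    """Heteroscedastic peaks: WLS agrees with a hand-rolled solve to 1e-10."""
    rng = np.random.default_rng(10)
    mids = np.array([400.0, 700.0, 1000.0, 1300.0, 1600.0])
    peaks = 20.0 + 0.01 * mids + rng.normal(0, 3, 5)
    sems = np.array([1.0, 0.5, 2.0, 0.8, 1.5])
    bins = _peak_bins(mids, peaks, sems)
    slope, intercept = plus_end_regression(bins)
    w = 1.0 / sems**2
    X = np.column_stack([np.ones(5), mids])
    beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * peaks))
    assert intercept == pytest.approx(beta[0], abs=1e-10 * max(1, abs(beta[0])))
    assert slope == pytest.approx(beta[1], rel=1e-10)


def test_zero_sem_falls_back_to_unweighted():
    bins = _peak_bins([400.0, 700.0], [10.0, 20.0], [0.0, 1.0])
    with pytest.warns(UserWarning, match="unweighted"):
        slope, _ = plus_end_regression(bins)
    assert slope == pytest.approx(10.0 / 300.0)


# ---------------------------------------------------------------------------
# asymmetry and relative fluorescence
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "fi_b, fi_m, expected",
    [(5.0, 5.0, 0.0), (5.0, 0.0, 1.0), (0.0, 5.0, -1.0), (85.0, 15.0, 0.7)],
)
def test_asymmetry_index_values(fi_b, fi_m, expected):
    assert asymmetry_index(CellRecord(fi_b, fi_m)) == pytest.approx(expected)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    fi_b=st.floats(0, 1e6),
    fi_m=st.floats(0, 1e6),
)
def test_asymmetry_index_antisymmetric(fi_b, fi_m):
    if fi_b + fi_m == 0:
        return
    a = asymmetry_index(CellRecord(fi_b, fi_m))
    b = asymmetry_index(CellRecord(fi_m, fi_b))
    assert a == -b
    assert -1.0 <= a <= 1.0


def test_asymmetry_undefined_for_double_zero():
    with pytest.raises(ValueError, match="both intensities"):
        asymmetry_index(CellRecord(0.0, 0.0))


def test_relative_fluorescence_percentages():
    values = np.array([10.0, 10.0, 10.0, 25.0])
    groups = np.array(["ref", "ref", "q", "q"])
    out = relative_fluorescence(values, groups, "ref")
    assert out == pytest.approx([100.0, 100.0, 100.0, 250.0])


def test_relative_fluorescence_four_to_one_ratio():
    """Generated 4:1 b:m cohort: mother-side mean lands at ~25%."""
    from kip2traffic.synthetic import generate_spb_dataset, preset

    truth = preset(
        "wt", seed=11, spb_ratio_median=4.0, spb_ratio_log_sd=0.0, spb_noise=0.0,
        orientation_p_correct=1.0,
    )
    records, _ = generate_spb_dataset(truth, 500)
    values = np.array([r.fi_b for r in records] + [r.fi_m for r in records])
    groups = np.array(["b"] * 500 + ["m"] * 500)
    out = relative_fluorescence(values, groups, "b")
    assert np.mean(out[groups == "m"]) == pytest.approx(25.0, rel=1e-9)


def test_relative_fluorescence_empty_or_zero_reference():
    with pytest.raises(ValueError, match="empty"):
        relative_fluorescence([1.0], ["a"], "b")
    with pytest.raises(ValueError, match="positive"):
        relative_fluorescence([0.0, 1.0], ["a", "b"], "a")


# ---------------------------------------------------------------------------
# speckle speeds
# ---------------------------------------------------------------------------


def test_stationary_speckle_has_zero_speed():
    t = KymographTrack(0, 5.0, 10, 5.0)
    assert speckle_speed(t) == 0.0


def test_speckle_speed_unit_conversion():
    """10 px over 10 frames: 1.3335 µm in 10.7 s is 7.48 µm/min."""
    t = KymographTrack(0, 0.0, 10, 10.0)
    assert speckle_speed(t) == pytest.approx(1333.5 / 10.7 * 60 / 1000, rel=1e-12)
    assert round(speckle_speed(t), 2) == 7.48


def test_speckle_speed_invariant_under_frame_shift():
    a = KymographTrack(0, 2.0, 8, 12.0)
    b = KymographTrack(40, 2.0, 48, 12.0)
    assert speckle_speed(a) == speckle_speed(b)


def test_speckle_cohort_mean_matches_generator():
    from kip2traffic.quantify import speckle_speed as speed
    from kip2traffic.synthetic import generate_speckle_tracks, preset

    truth = preset("wt", seed=12)
    tracks, _ = generate_speckle_tracks(truth, 192)
    speeds = np.array([speed(t) for t in tracks])
    se = truth.speckle_speed_sd / np.sqrt(192)
    assert abs(speeds.mean() - truth.speckle_speed_mean) <= 2 * se + 0.1


def test_zero_frame_span_rejected():
    with pytest.raises(ValueError):
        KymographTrack(5, 0.0, 5, 3.0)


# ---------------------------------------------------------------------------
# 3D lengths and dynamics
# ---------------------------------------------------------------------------


def _series(lengths_um, spindle=1.5, phases=()):
    lengths = np.asarray(lengths_um, dtype=float)
    n = lengths.size
    plus = np.zeros((n, 3))
    plus[:, 0] = lengths
    return LengthSeries(
        plus_end_um=plus,
        spb_um=np.zeros((n, 3)),
        spindle_um=np.full(n, spindle),
        phases=list(phases),
    )


def test_three_four_five_triangle_is_undetectable():
    series = LengthSeries(
        plus_end_um=np.array([[0.3, 0.4, 0.0]]),
        spb_um=np.zeros((1, 3)),
        spindle_um=np.array([1.0]),
    )
    out = microtubule_length_3d(series)
    assert out["length_um"].iloc[0] == pytest.approx(0.5)
    assert not out["detectable"].iloc[0]


def test_one_micron_microtubule_is_detectable():
    series = LengthSeries(
        plus_end_um=np.array([[0.6, 0.8, 0.0]]),
        spb_um=np.zeros((1, 3)),
        spindle_um=np.array([1.0]),
    )
    out = microtubule_length_3d(series)
    assert out["length_um"].iloc[0] == pytest.approx(1.0)
    assert out["detectable"].iloc[0]


def test_lengths_match_bruteforce_distance():
    rng = np.random.default_rng(13)
    plus = rng.uniform(-2, 2, (50, 3))
    spb = rng.uniform(-2, 2, (50, 3))
    series = LengthSeries(plus, spb, np.full(50, 1.0))
    out = microtubule_length_3d(series)
    brute = np.sqrt(((plus - spb) ** 2).sum(axis=1))
    assert np.max(np.abs(out["length_um"].to_numpy() - brute)) < 1e-12


def test_long_spindle_frames_excluded_and_filter_idempotent():
    series = _series([1.0, 1.0, 1.0])
    series.spindle_um = np.array([1.5, 2.5, 1.9])
    out = microtubule_length_3d(series)
    assert out["excluded_spindle"].tolist() == [False, True, False]
    # pure predicate: re-applying the threshold to the kept frames is a no-op
    kept = out[~out["excluded_spindle"]]
    assert (series.spindle_um[kept["frame"]] > 2.0).sum() == 0


def test_growth_phase_speed_arithmetic():
    lengths = np.linspace(0.7, 1.4, 31)
    series = _series(lengths, phases=[(0, 30, "growth")])
    out = summarize_dynamics(series)
    assert out["phase_speeds"][0]["speed_um_min"] == pytest.approx(0.7 / 32.1 * 60)
    assert out["max_length_um"] == pytest.approx(1.4)


def test_constant_series_has_zero_speeds_and_full_lifetime():
    series = _series(np.full(20, 1.0), phases=[(0, 19, "growth")])
    out = summarize_dynamics(series)
    assert out["phase_speeds"][0]["speed_um_min"] == 0.0
    assert out["lifetime_s"] == pytest.approx(20 * 1.07)


def test_short_phase_skipped_with_warning():
    series = _series(np.full(10, 1.0), phases=[(0, 1, "growth")])
    with pytest.warns(UserWarning, match="shorter than 2 frames"):
        out = summarize_dynamics(series)
    assert out["phase_speeds"] == []


def test_generator_dynamics_speeds_recovered_exactly():
    """Zero-spread generator: annotated phase speeds match the truth."""
    from kip2traffic.synthetic import generate_dynamics_dataset, preset

    truth = preset(
        "wt", seed=14, growth_speed_mean=0.8, growth_speed_sd=0.0,
        shrink_speed_mean=0.5, shrink_speed_sd=0.0, spindle_gt2_fraction=0.0,
    )
    series_list, truths = generate_dynamics_dataset(truth, 5)
    for series, t in zip(series_list, truths):
        out = summarize_dynamics(series)
        recovered = {(p["start"], p["end"]): p["speed_um_min"] for p in out["phase_speeds"]}
        for ph in t["phases"]:
            if ph["end"] - ph["start"] < 2:
                continue
            assert recovered[(ph["start"], ph["end"])] == pytest.approx(
                ph["speed_um_min"], abs=1e-9
            )


def test_tabular_io_roundtrips(tmp_path):
    """Record, track and coordinate tables survive a CSV roundtrip."""
    from kip2traffic.quantify import (
        cell_records_from_frame,
        cell_records_to_frame,
        length_series_from_frame,
        length_series_to_frame,
        tracks_from_frame,
        tracks_to_frame,
    )

    records = [CellRecord(10.0, 2.5, "correct", "wt"), CellRecord(4.0, 4.0, "inverted", "wt")]
    frame = cell_records_to_frame(records)
    back = cell_records_from_frame(pd.read_csv(_roundtrip(tmp_path, frame, "cells.csv")))
    assert [(r.fi_b, r.fi_m, r.orientation) for r in back] == [
        (r.fi_b, r.fi_m, r.orientation) for r in records
    ]

    tracks = [KymographTrack(0, 1.0, 8, 11.0), KymographTrack(3, 0.0, 13, 7.0)]
    back = tracks_from_frame(pd.read_csv(_roundtrip(tmp_path, tracks_to_frame(tracks), "t.csv")))
    assert [speckle_speed(t) for t in back] == [speckle_speed(t) for t in tracks]

    rng = np.random.default_rng(0)
    series = LengthSeries(rng.uniform(0, 2, (5, 3)), rng.uniform(0, 1, (5, 3)),
                          np.full(5, 1.4))
    back = length_series_from_frame(
        pd.read_csv(_roundtrip(tmp_path, length_series_to_frame(series), "s.csv"))
    )
    assert np.allclose(back.plus_end_um, series.plus_end_um)
    assert np.allclose(back.spb_um, series.spb_um)
    assert np.allclose(back.spindle_um, series.spindle_um)


def _roundtrip(tmp_path, frame, name):
    path = tmp_path / name
    frame.to_csv(path, index=False)
    return path


def test_predicted_profile_table_schema(tmp_path):
    from kip2traffic.lattice import MotorKinetics
    from kip2traffic.optics import OpticalModel, predict_binned_profiles, write_predicted_profiles

    kin = MotorKinetics(0.02, 0, 0, 13.125, 4.0, 35.0)
    optical = OpticalModel(135.0, 133.35, 10.0, 1.0)
    bins = [(533.4, 800.1), (800.1, 1066.8)]
    profiles = predict_binned_profiles(kin, optical, bins)
    path = tmp_path / "pred.csv"
    write_predicted_profiles(profiles, bins, path)
    frame = pd.read_csv(path)
    assert list(frame.columns) == ["bin_lo_nm", "bin_hi_nm", "position_nm", "intensity_au"]
    assert set(frame["bin_lo_nm"]) == {533.4, 800.1}
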