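"""Quantification statistics for microscopy-derived tables.

Implements the measurement conventions used for astral-microtubule line
scans and tracking tables: SPB alignment of dual-channel line scans,
length-binned mean +/- SEM profiles, inter-day quantile (Q-Q) intensity
normalization, weighted plus-end regressions, SPB asymmetry indices,
kymograph speckle speeds, and 3D microtubule length/dynamics with the
spindle-length and detectability filters.

All inputs are plain tables (CSV-friendly); no image processing happens
here -- peaks and coordinates are computed from 1-D scans and coordinate
tables only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import (
    BIN_NM,
    DETECT_LIMIT_NM,
    FRAME_INTERVAL_S,
    PIXEL_SIZE_NM,
    SPINDLE_MAX_UM,
)

__all__ = [
    "LineScan",
    "AlignedProfile",
    "ProfileBin",
    "ProfileBins",
    "NormalizationFit",
    "CellRecord",
    "KymographTrack",
    "LengthSeries",
    "AlignmentError",
    "align_line_scan",
    "bin_profiles",
    "qq_normalize",
    "plus_end_regression",
    "asymmetry_index",
    "relative_fluorescence",
    "speckle_speed",
    "microtubule_length_3d",
    "summarize_dynamics",
]

_METADATA_HEADER = (
    f"# pixel_size_nm={PIXEL_SIZE_NM}, frame_interval_s={FRAME_INTERVAL_S}, bin_nm={BIN_NM}"
)


class AlignmentError(ValueError):
    """A line scan could not be aligned; carries a reason code."""

    def __init__(self, reason: str, message: str):
        self.reason = reason
        super().__init__(f"{reason}: {message}")


@dataclass
class LineScan:
    """Dual-channel intensity scan along one astral microtubule.

    Positions run along the scan (nm) at uniform pixel spacing; the scan is
    oriented so that lower positions are SPB-proximal.
    """

    positions: np.ndarray
    gfp: np.ndarray
    mcherry: np.ndarray
    cell_id: str = ""
    date: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        self.mcherry = np.asarray(self.mcherry, dtype=float)
        if not (self.positions.size == self.gfp.size == self.mcherry.size):
            raise ValueError("positions, gfp and mcherry must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_nm": self.positions,
                "gfp_au": self.gfp,
                "mcherry_au": self.mcherry,
                "cell_id": self.cell_id,
                "date": self.date,
            }
        )


def write_line_scans(scans: list[LineScan], path) -> None:
    """Write scans as one tidy CSV with a constants metadata header line."""
    frame = pd.concat([s.to_frame() for s in scans], ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_METADATA_HEADER + "\n")
        frame.to_csv(fh, index=False)


def read_line_scans(path) -> list[LineScan]:
    frame = pd.read_csv(path, comment="#", dtype={"cell_id": str, "date": str})
    scans = []
    for (cell, date), grp in frame.groupby(["cell_id", "date"], sort=False):
        scans.append(
            LineScan(
                grp["position_nm"].to_numpy(),
                grp["gfp_au"].to_numpy(),
                grp["mcherry_au"].to_numpy(),
                cell_id=str(cell),
                date=str(date),
            )
        )
    return scans


@dataclass
class AlignedProfile:
    """A GFP profile re-referenced to the SPB (mCherry) peak.

    ``profile_length`` is the SPB-peak-to-GFP-peak distance and locates the
    plus end.
    """

    positions: np.ndarray  # nm relative to the SPB peak
    gfp: np.ndarray
    plus_end_position: float
    cell_id: str = ""
    date: str = ""
    degenerate: bool = False

    @property
    def profile_length(self) -> float:
        return self.plus_end_position


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-pixel centered moving average with shrinking edge windows."""
    return (
        pd.Series(y).rolling(3, center=True, min_periods=1).mean().to_numpy()
    )


def _peak_index(y: np.ndarray, min_snr: float) -> int:
    smoothed = _smooth3(y)
    # robust noise floor from first differences (insensitive to plateaus/steps)
    sigma = 1.4826 * np.median(np.abs(np.diff(smoothed))) / np.sqrt(2.0)
    peak = int(np.argmax(smoothed))  # ties break toward the scan start (SPB-proximal)
    prominence = smoothed[peak] - np.median(smoothed)
    if prominence <= 0 or (sigma > 0 and prominence < min_snr * sigma):
        raise AlignmentError("flat-channel", "no peak above the noise floor")
    return peak


def align_line_scan(scan: LineScan, *, min_snr: float = 3.0) -> AlignedProfile:
    """Align a scan to the SPB and measure the profile length.

    Peaks are global maxima after 3-pixel moving-average smoothing; the
    origin is placed at the mCherry (SPB) peak and the plus end at the GFP
    peak.  A channel without a peak above ``min_snr`` robust noise floors
    raises :class:`AlignmentError`; coincident peaks yield a zero-length
    profile flagged degenerate; a GFP peak on the SPB-proximal side of the
    mCherry peak is rejected.
    """
    i_spb = _peak_index(scan.mcherry, min_snr)
    i_plus = _peak_index(scan.gfp, min_snr)
    origin = scan.positions[i_spb]
    plus = scan.positions[i_plus] - origin
    if plus < 0:
        raise AlignmentError("negative-length", "GFP peak lies before the SPB peak")
    return AlignedProfile(
        positions=scan.positions - origin,
        gfp=scan.gfp,
        plus_end_position=float(plus),
        cell_id=scan.cell_id,
        date=scan.date,
        degenerate=(i_spb == i_plus),
    )


@dataclass
class ProfileBin:
    """Mean +/- SEM fluorescence vs position for one microtubule-length bin."""

    lo: float  # nm, inclusive
    hi: float  # nm, exclusive
    positions: np.ndarray  # nm relative to the SPB
    mean: np.ndarray
    sem: np.ndarray
    n: int
    degenerate: bool = False  # n == 1: SEM is 0 by convention

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass
class ProfileBins:
    """SPB-aligned mean +/- SEM profiles grouped by microtubule length."""

    bins: list[ProfileBin]
    bin_size: float = BIN_NM

    def __iter__(self):
        return iter(self.bins)

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def length_bins(self) -> list[tuple[float, float]]:
        return [(b.lo, b.hi) for b in self.bins]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.bins:
            rows.append(
                pd.DataFrame(
                    {
                        "bin_lo_nm": b.lo,
                        "bin_hi_nm": b.hi,
                        "position_nm": b.positions,
                        "mean_au": b.mean,
                        "sem_au": b.sem,
                        "n": b.n,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(_METADATA_HEADER + "\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, bin_size: float = BIN_NM) -> "ProfileBins":
        bins = []
        for (lo, hi), grp in frame.groupby(["bin_lo_nm", "bin_hi_nm"], sort=True):
            n = int(grp["n"].iloc[0])
            bins.append(
                ProfileBin(
                    float(lo),
                    float(hi),
                    grp["position_nm"].to_numpy(),
                    grp["mean_au"].to_numpy(),
                    grp["sem_au"].to_numpy(),
                    n,
                    degenerate=(n == 1),
                )
            )
        return cls(bins, bin_size)

    @classmethod
    def read_csv(cls, path, bin_size: float = BIN_NM) -> "ProfileBins":
        return cls.from_frame(pd.read_csv(path, comment="#"), bin_size)


def bin_profiles(
    profiles: list[AlignedProfile],
    bin_size: float = BIN_NM,
    *,
    min_count: int = 1,
    pixel_size: float = PIXEL_SIZE_NM,
    tail_pixels: int = 3,
    lead_pixels: int = 3,
) -> ProfileBins:
    """Group aligned profiles into half-open length bins and average per position.

    Each profile contributes to exactly one bin ``[k*bin_size, (k+1)*bin_size)``
    determined by its length.  Within a bin, profiles are truncated at their
    plus-end peak plus ``tail_pixels`` and at ``lead_pixels`` before the SPB,
    and the mean and SEM are taken per position over the positions common to
    all members.  Bins with fewer than ``min_count`` profiles are dropped
    (with a warning); a single-profile bin has SEM 0 and is flagged degenerate.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if not profiles:
        return ProfileBins([], bin_size)

    groups: dict[int, list[AlignedProfile]] = {}
    for p in profiles:
        groups.setdefault(int(np.floor(p.profile_length / bin_size)), []).append(p)

    bins = []
    for k in sorted(groups):
        members = groups[k]
        if len(members) < min_count:
            warnings.warn(
                f"dropping length bin [{k * bin_size:.1f}, {(k + 1) * bin_size:.1f}) nm "
                f"with only {len(members)} profile(s)",
                stacklevel=2,
            )
            continue
        lo_lim = -lead_pixels * pixel_size - 1e-9
        hi_lims = [p.plus_end_position + tail_pixels * pixel_size + 1e-9 for p in members]
        grids = []
        for p, hi_lim in zip(members, hi_lims):
            keep = (p.positions >= lo_lim) & (p.positions <= hi_lim)
            grids.append((np.round(p.positions[keep], 6), p.gfp[keep]))
        common = grids[0][0]
        for pos, _ in grids[1:]:
            common = np.intersect1d(common, pos)
        stack = np.vstack(
            [vals[np.isin(pos, common)] for pos, vals in grids]
        )
        mean = stack.mean(axis=0)
        if stack.shape[0] > 1:
            sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        else:
            sem = np.zeros_like(mean)
        bins.append(
            ProfileBin(
                k * bin_size,
                (k + 1) * bin_size,
                common,
                mean,
                sem,
                stack.shape[0],
                degenerate=(stack.shape[0] == 1),
            )
        )
    return ProfileBins(bins, bin_size)


@dataclass
class NormalizationFit:
    """Affine inter-day intensity calibration estimated from Q-Q quantiles."""

    alpha: float
    beta: float
    r_squared: float
    mapped: np.ndarray | None = None


def qq_normalize(reference: np.ndarray, other: np.ndarray) -> NormalizationFit:
    """Affine map aligning ``other``'s intensity distribution to ``reference``.

    Computes the 0.5% .. 99.5% quantiles (0.5% steps, 199 points, linear
    interpolation between order statistics) of both datasets and fits
    ``ref_q = alpha * other_q + beta`` by ordinary least squares.  Returns
    the fit and ``other`` mapped through it.
    """
    reference = np.asarray(reference, dtype=float)
    other = np.asarray(other, dtype=float)
    q = np.arange(0.005, 0.9951, 0.005)
    if reference.size < 199 or other.size < 199:
        warnings.warn(
            "fewer than 199 values; quantiles are interpolated between order statistics",
            stacklevel=2,
        )
    ref_q = np.quantile(reference, q)
    oth_q = np.quantile(other, q)
    if np.ptp(oth_q) == 0:
        raise ValueError("zero variance in the quantiles of `other`")
    x = sm.add_constant(oth_q)
    fit = sm.OLS(ref_q, x).fit()
    beta, alpha = fit.params
    return NormalizationFit(float(alpha), float(beta), float(fit.rsquared), alpha * other + beta)


def _peak_value(bin_: ProfileBin, window_pixels: int, pixel_size: float):
    """Mean-profile maximum within +/- window_pixels of the bin's plus end."""
    target = bin_.midpoint
    mask = np.abs(bin_.positions - target) <= window_pixels * pixel_size + 1e-9
    if not mask.any():
        return None
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(bin_.mean[idx])]
    return bin_.mean[best], bin_.sem[best]


def plus_end_regression(
    bins: ProfileBins,
    *,
    window_pixels: int = 2,
    pixel_size: float = PIXEL_SIZE_NM,
) -> tuple[float, float]:
    """Weighted linear regression of plus-end peak intensity on bin length.

    The plus-end peak of each bin is the maximum of the mean profile within
    ``window_pixels`` of the aligned plus end; weights are 1/SEM^2 at the
    peak position.  Falls back to an unweighted fit (with a warning) when
    any peak SEM is zero.  Returns ``(slope, intercept)`` in a.u. per nm and
    a.u.
    """
    xs, ys, sems = [], [], []
    for b in bins:
        pv = _peak_value(b, window_pixels, pixel_size)
        if pv is None:
            continue
        xs.append(b.midpoint)
        ys.append(pv[0])
        sems.append(pv[1])
    if len(xs) < 2:
        raise ValueError("need at least 2 bins with defined plus-end peaks")
    x = sm.add_constant(np.asarray(xs))
    y = np.asarray(ys)
    sems = np.asarray(sems)
    if np.any(sems <= 0):
        warnings.warn("zero SEM at a peak; falling back to unweighted regression", stacklevel=2)
        fit = sm.OLS(y, x).fit()
    else:
        fit = sm.WLS(y, x, weights=1.0 / sems**2).fit()
    intercept, slope = fit.params
    return float(slope), float(intercept)


@dataclass
class CellRecord:
    """Per-cell fluorescence pair for the bud- and mother-facing sides."""

    fi_b: float
    fi_m: float
    orientation: str = "correct"  # or "inverted"
    genotype: str = "wt"

    def __post_init__(self) -> None:
        if self.fi_b < 0 or self.fi_m < 0:
            raise ValueError("fluorescence intensities must be >= 0")


def asymmetry_index(record: CellRecord) -> float:
    """Bounded bud-vs-mother intensity bias: (FI_b - FI_m) / (FI_b + FI_m).

    Reaches +1 for fully bud-biased and -1 for fully mother-biased signal;
    undefined (raises) when both sides are zero.
    """
    total = record.fi_b + record.fi_m
    if total <= 0:
        raise ValueError("asymmetry index undefined: both intensities are zero")
    return (record.fi_b - record.fi_m) / total


def relative_fluorescence(
    values: np.ndarray, groups: np.ndarray, reference_group
) -> np.ndarray:
    """Normalize intensities to the mean of a reference group, in percent."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ref = values[groups == reference_group]
    if ref.size == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")
    mean = ref.mean()
    if mean <= 0:
        raise ValueError("reference-group mean must be positive")
    return values / mean * 100.0


def records_relative_fluorescence(
    records: list[CellRecord], reference_side: str = "b"
) -> pd.DataFrame:
    """Per-record b/m intensities as percentages of the mean reference side."""
    frame = pd.DataFrame(
        {
            "fi_b": [r.fi_b for r in records],
            "fi_m": [r.fi_m for r in records],
            "orientation": [r.orientation for r in records],
            "genotype": [r.genotype for r in records],
        }
    )
    ref_mean = frame[f"fi_{reference_side}"].mean()
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    frame["fi_b_pct"] = frame["fi_b"] / ref_mean * 100.0
    frame["fi_m_pct"] = frame["fi_m"] / ref_mean * 100.0
    return frame


@dataclass
class KymographTrack:
    """Start/end coordinates of one fluorescent speckle on a kymograph."""

    start_frame: int
    start_pixel: float
    end_frame: int
    end_pixel: float
    frame_interval: float = FRAME_INTERVAL_S  # s
    pixel_size: float = PIXEL_SIZE_NM  # nm

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end frame must be after start frame")


def speckle_speed(track: KymographTrack) -> float:
    """Speckle speed from its kymograph endpoints, in µm per minute."""
    dpx = abs(track.end_pixel - track.start_pixel)
    dt = (track.end_frame - track.start_frame) * track.frame_interval
    if dt <= 0:
        raise ValueError("zero frame span")
    nm_per_s = dpx * track.pixel_size / dt
    return nm_per_s * 60.0 / 1000.0


@dataclass
class LengthSeries:
    """Tracked 3D plus-end / SPB coordinates over one recording window."""

    plus_end_um: np.ndarray  # (n_frames, 3)
    spb_um: np.ndarray  # (n_frames, 3)
    spindle_um: np.ndarray  # (n_frames,)
    frame_interval: float = FRAME_INTERVAL_S
    phases: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.plus_end_um = np.asarray(self.plus_end_um, dtype=float)
        self.spb_um = np.asarray(self.spb_um, dtype=float)
        self.spindle_um = np.asarray(self.spindle_um, dtype=float)
        if self.plus_end_um.shape != self.spb_um.shape:
            raise ValueError("plus-end and SPB coordinate tables differ in shape")
        if self.plus_end_um.shape[0] != self.spindle_um.size:
            raise ValueError("spindle lengths do not match the number of frames")

    @property
    def n_frames(self) -> int:
        return self.spindle_um.size


def microtubule_length_3d(
    series: LengthSeries,
    *,
    spindle_max_um: float = SPINDLE_MAX_UM,
    detect_limit_nm: float = DETECT_LIMIT_NM,
) -> pd.DataFrame:
    """Per-frame 3D microtubule length with the standard filters.

    Length is the Euclidean plus-end-to-SPB distance.  Frames with spindles
    longer than ``spindle_max_um`` are excluded; lengths at or below the
    5-pixel resolution limit are flagged undetectable.  An absent microtubule
    is recorded as length 0 (the 2-D no-microtubule convention).
    """
    if not (np.isfinite(series.plus_end_um).all() and np.isfinite(series.spb_um).all()):
        raise ValueError("coordinates must be finite")
    length_um = np.linalg.norm(series.plus_end_um - series.spb_um, axis=1)
    excluded = series.spindle_um > spindle_max_um
    detectable = length_um > detect_limit_nm / 1000.0
    return pd.DataFrame(
        {
            "frame": np.arange(series.n_frames),
            "length_um": length_um,
            "excluded_spindle": excluded,
            "detectable": detectable,
        }
    )


def summarize_dynamics(
    series: LengthSeries,
    *,
    spindle_max_um: float = SPINDLE_MAX_UM,
    detect_limit_nm: float = DETECT_LIMIT_NM,
) -> dict:
    """Maximum length, lifetime and per-phase growth/shrinkage speeds.

    The maximum is over detectable, non-excluded frames; lifetime is the
    total time with a detectable microtubule.  Each annotated phase yields a
    signed speed (µm/min) from its endpoint lengths; phases shorter than two
    frames are skipped with a warning.
    """
    table = microtubule_length_3d(
        series, spindle_max_um=spindle_max_um, detect_limit_nm=detect_limit_nm
    )
    usable = table[~table["excluded_spindle"]]
    detected = usable[usable["detectable"]]
    max_length = float(detected["length_um"].max()) if len(detected) else 0.0
    lifetime = len(detected) * series.frame_interval

    speeds = []
    lengths = table["length_um"].to_numpy()
    for start, end, label in series.phases:
        if not (0 <= start < end < series.n_frames):
            raise ValueError(f"phase ({start}, {end}) outside the frame range")
        if end - start < 2:
            warnings.warn(f"skipping {label} phase shorter than 2 frames", stacklevel=2)
            continue
        dt = (end - start) * series.frame_interval
        speed = (lengths[end] - lengths[start]) / dt * 60.0
        speeds.append({"phase": label, "start": start, "end": end, "speed_um_min": speed})

    return {
        "max_length_um": max_length,
        "lifetime_s": lifetime,
        "phase_speeds": speeds,
    }


# ---------------------------------------------------------------------------
# tabular IO for records, tracks and coordinate series
# ---------------------------------------------------------------------------


def cell_records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fi_b": [r.fi_b for r in records],
            "fi_m": [r.fi_m for r in records],
            "orientation": [r.orientation for r in records],
            "genotype": [r.genotype for r in records],
        }
    )


def cell_records_from_frame(frame: pd.DataFrame) -> list[CellRecord]:
    return [
        CellRecord(row.fi_b, row.fi_m, row.orientation, row.genotype)
        for row in frame.itertuples()
    ]


def tracks_to_frame(tracks: list[KymographTrack]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_frame": [t.start_frame for t in tracks],
            "start_pixel": [t.start_pixel for t in tracks],
            "end_frame": [t.end_frame for t in tracks],
            "end_pixel": [t.end_pixel for t in tracks],
            "frame_interval_s": [t.frame_interval for t in tracks],
            "pixel_size_nm": [t.pixel_size for t in tracks],
        }
    )


def tracks_from_frame(frame: pd.DataFrame) -> list[KymographTrack]:
    return [
        KymographTrack(
            int(r.start_frame), float(r.start_pixel), int(r.end_frame),
            float(r.end_pixel), float(r.frame_interval_s), float(r.pixel_size_nm),
        )
        for r in frame.itertuples()
    ]


def length_series_to_frame(series: LengthSeries) -> pd.DataFrame:
    """Tidy coordinate table: frame, marker, x_um, y_um, z_um (+ spindle)."""
    frames = np.arange(series.n_frames)
    rows = []
    for marker, coords in (("plus_end", series.plus_end_um), ("spb", series.spb_um)):
        rows.append(
            pd.DataFrame(
                {
                    "frame": frames,
                    "marker": marker,
                    "x_um": coords[:, 0],
                    "y_um": coords[:, 1],
                    "z_um": coords[:, 2],
                    "spindle_um": series.spindle_um,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def length_series_from_frame(
    frame: pd.DataFrame,
    frame_interval: float = FRAME_INTERVAL_S,
    phases: list | None = None,
) -> LengthSeries:
    plus = frame[frame["marker"] == "plus_end"].sort_values("frame")
    spb = frame[frame["marker"] == "spb"].sort_values("frame")
    return LengthSeries(
        plus_end_um=plus[["x_um", "y_um", "z_um"]].to_numpy(),
        spb_um=spb[["x_um", "y_um", "z_um"]].to_numpy(),
        spindle_um=plus["spindle_um"].to_numpy(),
        frame_interval=frame_interval,
        phases=phases or [],
    )
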