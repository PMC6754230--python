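"""Synthetic datasets emulating the microscopy-derived tables.

Every generator is a pure function of its configuration and seed, and each
one emits a ground-truth sidecar so downstream recovery tests never
re-derive the truth from the generated data.

The preset truth configurations encode the strain differences as reported
fold-changes on an otherwise identical wild-type parameter set:

* ``wt`` -- minus-end loading dominates lattice landing 500-fold
  (k_in / k_on = 500), no lattice detachment (k_off = 0), stepping rate
  from the measured speckle speed (6.3 µm/min at 8 nm per step).
* ``bfa1_bub2`` (bfa1Δ bub2Δ) -- identical except k_in reduced 12-fold.
* ``s63a`` (KIP2-S63A) -- identical except k_on raised 6-fold.

Absolute rate values are not printed for the experimental system; the
defaults here set a low shaft density (r_in / k_step = 0.05) with a
plus-end exit rate of the same order as the loading rate, which reproduces
the qualitative profile anatomy (flat shaft, plus-end peak).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .constants import (
    BIN_NM,
    CELL_VOLUME_FL,
    FRAME_INTERVAL_S,
    PIXEL_SIZE_NM,
    PSF_SIGMA_NM,
    SITE_NM,
)
from .lattice import LatticeSpec, MotorKinetics, ReservoirSpec, solve_meanfield_steady_state
from .optics import OpticalModel, intensity_at
from .quantify import (
    CellRecord,
    KymographTrack,
    LengthSeries,
    LineScan,
    ProfileBin,
    ProfileBins,
)

__all__ = [
    "TruthConfig",
    "preset",
    "PRESET_NAMES",
    "generate_profile_dataset",
    "generate_spb_dataset",
    "generate_speckle_tracks",
    "generate_dynamics_dataset",
    "apply_day_effect",
]

#: default microtubule-length bin edges: six 266.7 nm bins from 2 to 8 pixels
_DEFAULT_EDGES = tuple(BIN_NM * k for k in range(2, 9))


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth configuration for all synthetic generators."""

    kinetics: MotorKinetics
    optical: OpticalModel
    length_bin_edges: tuple = _DEFAULT_EDGES
    cells_per_bin: int = 100
    noise_sd_au: float = 25.0
    orientation_p_correct: float = 0.94
    spb_ratio_median: float = 17.0 / 3.0
    spb_ratio_log_sd: float = 0.5
    spb_ratio_median_inverted: float = 2.0 / 3.0
    spb_noise: float = 0.2
    speckle_speed_mean: float = 6.3  # µm/min
    speckle_speed_sd: float = 2.1
    growth_speed_mean: float = 1.4  # µm/min
    growth_speed_sd: float = 1.1
    shrink_speed_mean: float = 2.8  # µm/min (magnitude)
    shrink_speed_sd: float = 1.4
    spindle_gt2_fraction: float = 0.1
    reservoir: ReservoirSpec = field(default_factory=lambda: ReservoirSpec(CELL_VOLUME_FL))
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.orientation_p_correct, self.spindle_gt2_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for s in (
            self.noise_sd_au,
            self.spb_ratio_log_sd,
            self.spb_noise,
            self.speckle_speed_sd,
            self.growth_speed_sd,
            self.shrink_speed_sd,
        ):
            if s < 0:
                raise ValueError("standard deviations must be >= 0")

    def sidecar(self) -> dict:
        """JSON-serializable ground-truth record."""
        out = asdict(self)
        return json.loads(json.dumps(out, default=str))


#: wild-type kinetic truth (rate ratios from the reported fold-relations)
_WT_KINETICS = MotorKinetics(
    k_in=0.01875,  # /nM/s -> r_in = 0.656 /s at 35 nM; r_in/k_step = 0.05
    k_on=0.01875 / 500.0,  # k_in / k_on = 500
    k_off=0.0,
    k_step=6.3 * 1000.0 / 60.0 / SITE_NM,  # 13.125 /s from the speckle speed
    # plus-end exit: high enough that the landing-derepressed strain (6x
    # k_on) stays below the tip-jamming threshold on the longest measured
    # microtubules, while still slow enough to leave a plus-end accumulation
    k_out=4.0,  # /s
    c_total=35.0,  # nM
)

_WT_OPTICAL = OpticalModel(
    psf_sigma=PSF_SIGMA_NM, pixel_size=PIXEL_SIZE_NM, scale=60.0, background=100.0
)

PRESET_NAMES = ("wt", "bfa1_bub2", "s63a")

_ALIASES = {
    "wt": "wt",
    "bfa1_bub2": "bfa1_bub2",
    "bfa1bub2": "bfa1_bub2",
    "bfa1Δbub2Δ": "bfa1_bub2",
    "s63a": "s63a",
    "S63A": "s63a",
}


def preset(name: str, **overrides) -> TruthConfig:
    """Named truth configurations; strains differ only in the reported changes."""
    key = _ALIASES.get(name, _ALIASES.get(name.lower()))
    if key is None:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    kin = _WT_KINETICS
    if key == "bfa1_bub2":
        kin = kin.replace(k_in=kin.k_in / 12.0)  # k_in 12-fold down
    elif key == "s63a":
        kin = kin.replace(k_on=kin.k_on * 6.0)  # k_on 6-fold up
    return TruthConfig(kinetics=kin, optical=_WT_OPTICAL, **overrides)


# ---------------------------------------------------------------------------
# profile datasets
# ---------------------------------------------------------------------------


def generate_profile_dataset(
    truth: TruthConfig, seed: int | None = None
) -> tuple[ProfileBins, list[LineScan], dict]:
    """Binned mean +/- SEM profiles plus the raw per-cell line scans.

    For each length bin the mean-field forward profile is rendered at the
    bin-midpoint length, i.i.d. Gaussian pixel noise is added per simulated
    cell, and the cells are aggregated to mean +/- SEM.  The raw scans carry
    an mCherry (SPB) peak so that the alignment/binning stages can be
    exercised end-to-end.  Returns (bins, scans, truth sidecar).
    """
    if truth.cells_per_bin < 1:
        raise ValueError("cells_per_bin must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    edges = np.asarray(truth.length_bin_edges, dtype=float)
    optical = truth.optical
    px = optical.pixel_size
    lead_px = 5
    tail_px = 3

    bins: list[ProfileBin] = []
    scans: list[LineScan] = []
    for b in range(edges.size - 1):
        lo, hi = edges[b], edges[b + 1]
        mid = 0.5 * (lo + hi)
        n_sites = int(round(mid / SITE_NM))
        lattice = LatticeSpec(n_sites, SITE_NM)
        occ = solve_meanfield_steady_state(truth.kinetics, lattice, truth.reservoir)
        n_px = lead_px + int(np.ceil(mid / px)) + tail_px + 1
        positions = (np.arange(n_px) - lead_px) * px  # SPB peak at position 0
        pred = intensity_at(occ, optical, positions)

        cells = pred[None, :] + rng.normal(0.0, truth.noise_sd_au, size=(truth.cells_per_bin, n_px))
        mean = cells.mean(axis=0)
        if truth.cells_per_bin > 1:
            sem = cells.std(axis=0, ddof=1) / np.sqrt(truth.cells_per_bin)
        else:
            sem = np.zeros_like(mean)
        bins.append(
            ProfileBin(lo, hi, positions, mean, sem, truth.cells_per_bin,
                       degenerate=(truth.cells_per_bin == 1))
        )

        # raw scans: mCherry SPB peak at position 0, scan coordinates from 0
        mch_peak = 500.0 * np.exp(-0.5 * (positions / optical.psf_sigma) ** 2) + 50.0
        for c in range(truth.cells_per_bin):
            mch = mch_peak + rng.normal(0.0, truth.noise_sd_au / 2.0, size=n_px)
            scans.append(
                LineScan(
                    positions - positions[0],
                    cells[c],
                    mch,
                    cell_id=f"bin{b}_cell{c}",
                    date="synthetic",
                )
            )
    sidecar = truth.sidecar()
    sidecar["generator"] = "generate_profile_dataset"
    return ProfileBins(bins, float(np.diff(edges).mean())), scans, sidecar


def apply_day_effect(values: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Impose an inter-day intensity distortion that Q-Q normalization undoes.

    Returns ``(values - beta) / alpha`` so that regressing the original
    values on the distorted ones recovers ``(alpha, beta)``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return (np.asarray(values, dtype=float) - beta) / alpha


# ---------------------------------------------------------------------------
# SPB intensity pairs
# ---------------------------------------------------------------------------


def generate_spb_dataset(
    truth: TruthConfig, n_cells: int, seed: int | None = None
) -> tuple[list[CellRecord], dict]:
    """Per-cell bud-/mother-side fluorescence pairs with orientation labels.

    Orientation is Bernoulli(``orientation_p_correct``).  The per-cell true
    b:m ratio is lognormal with the configured median (a weaker, inverted
    bias for mis-oriented cells), brightness varies lognormally between
    cells, and each side carries multiplicative lognormal measurement noise
    of the configured magnitude.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    records = []
    for _ in range(n_cells):
        correct = rng.random() < truth.orientation_p_correct
        median = truth.spb_ratio_median if correct else truth.spb_ratio_median_inverted
        ratio = median * np.exp(rng.normal(0.0, truth.spb_ratio_log_sd))
        base = 100.0 * np.exp(rng.normal(0.0, 0.3))
        fi_m = base * np.exp(rng.normal(0.0, truth.spb_noise)) if truth.spb_noise > 0 else base
        fi_b = base * ratio * (
            np.exp(rng.normal(0.0, truth.spb_noise)) if truth.spb_noise > 0 else 1.0
        )
        records.append(
            CellRecord(fi_b=fi_b, fi_m=fi_m,
                       orientation="correct" if correct else "inverted")
        )
    sidecar = truth.sidecar()
    sidecar["generator"] = "generate_spb_dataset"
    sidecar["n_cells"] = n_cells
    return records, sidecar


# ---------------------------------------------------------------------------
# kymograph speckle tracks
# ---------------------------------------------------------------------------


def generate_speckle_tracks(
    truth: TruthConfig, n_tracks: int, seed: int | None = None
) -> tuple[list[KymographTrack], dict]:
    """Kymograph endpoint tracks with speeds from the configured distribution.

    Speeds are drawn from a normal truncated at zero (rejection sampling),
    converted to an integer pixel displacement over an integer frame span at
    the acquisition constants; the quantization error is below one pixel per
    track.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    tracks = []
    for _ in range(n_tracks):
        while True:
            speed = rng.normal(truth.speckle_speed_mean, truth.speckle_speed_sd)
            if speed >= 0:
                break
        span = int(rng.integers(5, 21))  # frames
        nm = speed * 1000.0 / 60.0 * span * FRAME_INTERVAL_S
        dpx = int(round(nm / PIXEL_SIZE_NM))
        start_frame = int(rng.integers(0, 80 - span))
        start_px = float(rng.integers(0, 10))
        tracks.append(
            KymographTrack(
                start_frame=start_frame,
                start_pixel=start_px,
                end_frame=start_frame + span,
                end_pixel=start_px + dpx,
            )
        )
    sidecar = truth.sidecar()
    sidecar["generator"] = "generate_speckle_tracks"
    sidecar["n_tracks"] = n_tracks
    return tracks, sidecar


# ---------------------------------------------------------------------------
# microtubule dynamics
# ---------------------------------------------------------------------------


def generate_dynamics_dataset(
    truth: TruthConfig, n_microtubules: int, seed: int | None = None
) -> tuple[list[LengthSeries], list[dict]]:
    """3D length time series with alternating growth/shrinkage phases.

    Each microtubule is sampled over 80 frames at the stack interval.  Phase
    speeds are drawn per phase from the configured normals (growth truncated
    positive); the SPB sits at the origin and the plus end moves along a
    random fixed direction, so the 3D distance equals the scalar length.
    A configurable fraction of cells carries a spindle longer than 2 µm so
    the spindle filter stays testable.  Phase annotations are emitted as
    ground truth per series.
    """
    if n_microtubules < 1:
        raise ValueError("n_microtubules must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_frames = 80
    dt = FRAME_INTERVAL_S
    series_list, truths = [], []
    for _ in range(n_microtubules):
        if rng.random() < truth.spindle_gt2_fraction:
            spindle = rng.uniform(2.05, 2.6)
        else:
            spindle = rng.uniform(1.0, 1.9)

        length = rng.uniform(0.8, 1.2)
        lengths = np.empty(n_frames)
        lengths[0] = length
        phases = []
        truth_speeds = []
        frame = 0
        growing = bool(rng.random() < 0.5)
        while frame < n_frames - 1:
            span = int(rng.integers(8, 31))
            end = min(frame + span, n_frames - 1)
            if growing:
                while True:
                    speed = rng.normal(truth.growth_speed_mean, truth.growth_speed_sd)
                    if speed > 0:
                        break
            else:
                while True:
                    mag = rng.normal(truth.shrink_speed_mean, truth.shrink_speed_sd)
                    if mag > 0:
                        break
                speed = -mag
            for f in range(frame, end):
                lengths[f + 1] = max(lengths[f] + speed * dt / 60.0, 0.05)
            phases.append((frame, end, "growth" if growing else "shrinkage"))
            truth_speeds.append(speed)
            frame = end
            growing = not growing

        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        plus = lengths[:, None] * direction[None, :]
        series_list.append(
            LengthSeries(
                plus_end_um=plus,
                spb_um=np.zeros((n_frames, 3)),
                spindle_um=np.full(n_frames, spindle),
                frame_interval=dt,
                phases=phases,
            )
        )
        truths.append(
            {
                "spindle_um": spindle,
                "phases": [
                    {"start": s, "end": e, "label": l, "speed_um_min": v}
                    for (s, e, l), v in zip(phases, truth_speeds)
                ],
            }
        )
    return series_list, truths
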