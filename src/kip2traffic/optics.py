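"""Forward model from lattice occupancy to SPB-aligned fluorescence profiles.

Bound motors are point emitters at their site centers; the microscope blurs
each emitter with a Gaussian point-spread function and the camera integrates
the blurred signal over finite pixels.  Intensity is linear in occupancy
(``scale`` a.u. per bound motor) on top of an additive ``background``.
Because profile data are in arbitrary units, ``scale`` and ``background``
are nuisance parameters estimated jointly with the kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .constants import PIXEL_SIZE_NM, PSF_SIGMA_NM
from .lattice import (
    LatticeSpec,
    MotorKinetics,
    OccupancyProfile,
    ReservoirSpec,
    solve_meanfield_steady_state,
)

__all__ = [
    "OpticalModel",
    "PredictedProfile",
    "render_profile",
    "intensity_at",
    "predict_binned_profiles",
    "write_predicted_profiles",
]


@dataclass(frozen=True)
class OpticalModel:
    """Gaussian-PSF camera model and arbitrary-unit intensity conversion."""

    psf_sigma: float = PSF_SIGMA_NM  # nm
    pixel_size: float = PIXEL_SIZE_NM  # nm per pixel
    scale: float = 1.0  # a.u. per bound motor
    background: float = 0.0  # a.u.

    def __post_init__(self) -> None:
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")


@dataclass
class PredictedProfile:
    """Predicted fluorescence at uniformly spaced pixel centers.

    Positions are distances from the SPB-aligned origin (the minus end) and
    may be negative where the blur extends the signal past the SPB.
    """

    positions: np.ndarray  # nm, pixel centers
    intensities: np.ndarray  # a.u.
    mt_length: float  # nm of lattice represented

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position_nm": self.positions, "intensity_au": self.intensities}
        )


def _pixel_mass(site_positions: np.ndarray, positions: np.ndarray, sigma: float, pixel: float) -> np.ndarray:
    """Fraction of each site's unit emission captured in each pixel.

    Returns a matrix of shape (n_positions, n_sites).  For ``sigma == 0`` the
    emission is a delta captured entirely by the containing pixel.
    """
    x = positions[:, None]
    s = site_positions[None, :]
    half = pixel / 2.0
    if sigma == 0.0:
        return ((s > x - half) & (s <= x + half)).astype(float)
    return ndtr((x + half - s) / sigma) - ndtr((x - half - s) / sigma)


def intensity_at(
    occupancy: OccupancyProfile, optical: OpticalModel, positions: np.ndarray
) -> np.ndarray:
    """Predicted intensity at arbitrary pixel-center positions (nm)."""
    positions = np.asarray(positions, dtype=float)
    mass = _pixel_mass(
        occupancy.site_positions, positions, optical.psf_sigma, optical.pixel_size
    )
    return optical.background + optical.scale * mass @ occupancy.occupancy


def render_profile(
    occupancy: OccupancyProfile,
    optical: OpticalModel,
    window: tuple[float, float],
) -> PredictedProfile:
    """Render an occupancy profile onto a uniform pixel grid covering ``window``.

    The window must cover the whole lattice (silent truncation is forbidden).
    Summed over an all-covering window, the background-subtracted intensity
    equals ``scale * sum(occupancy)`` because the pixel-integrated Gaussian
    kernel has unit mass per site.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must be a non-empty (lo, hi) range")
    spacing = (
        occupancy.site_positions[1] - occupancy.site_positions[0]
        if occupancy.n_sites > 1
        else 2.0 * occupancy.site_positions[0]
    )
    lattice_lo = occupancy.site_positions[0] - spacing / 2.0
    lattice_hi = occupancy.site_positions[-1] + spacing / 2.0
    if lo > lattice_lo + 1e-9 or hi < lattice_hi - 1e-9:
        raise ValueError(
            f"window ({lo}, {hi}) nm does not cover the lattice "
            f"({lattice_lo}, {lattice_hi}) nm"
        )
    n_px = int(np.ceil((hi - lo) / optical.pixel_size - 1e-9))
    positions = lo + (np.arange(n_px) + 0.5) * optical.pixel_size
    mt_length = lattice_hi - max(lattice_lo, 0.0)
    return PredictedProfile(positions, intensity_at(occupancy, optical, positions), mt_length)


def predict_binned_profiles(
    kinetics: MotorKinetics,
    optical: OpticalModel,
    length_bins: list[tuple[float, float]],
    lattice_defaults: LatticeSpec | None = None,
    reservoir: ReservoirSpec | None = None,
    *,
    margin_pixels: int = 5,
) -> list[PredictedProfile]:
    """One predicted profile per microtubule-length bin.

    Each bin is represented by a lattice whose length is the bin midpoint
    rounded to whole sites; the profile is the mean-field steady state of
    that lattice rendered through the optical model, with ``margin_pixels``
    of extra window on either side.  Deterministic.
    """
    from .lattice import CLAMPED

    site_length = lattice_defaults.site_length if lattice_defaults is not None else 8.0
    if reservoir is None:
        reservoir = CLAMPED
    lo_prev = -np.inf
    profiles = []
    for lo, hi in length_bins:
        if hi <= lo:
            raise ValueError(f"bin ({lo}, {hi}) is not increasing")
        if lo < lo_prev:
            raise ValueError("bins must be non-overlapping and increasing")
        lo_prev = hi
        mid = 0.5 * (lo + hi)
        n_sites = int(round(mid / site_length))
        if n_sites < 1:
            raise ValueError(
                f"bin midpoint {mid} nm is shorter than one {site_length} nm site"
            )
        lattice = LatticeSpec(n_sites, site_length)
        occ = solve_meanfield_steady_state(kinetics, lattice, reservoir)
        margin = margin_pixels * optical.pixel_size
        prof = render_profile(occ, optical, (-margin, lattice.length_nm + margin))
        profiles.append(prof)
    return profiles


def write_predicted_profiles(
    profiles: list[PredictedProfile],
    length_bins: list[tuple[float, float]],
    path,
) -> None:
    """Write binned predictions as one tidy CSV.

    Columns: bin_lo_nm, bin_hi_nm, position_nm, intensity_au.
    """
    if len(profiles) != len(length_bins):
        raise ValueError("one length bin per profile required")
    rows = []
    for prof, (lo, hi) in zip(profiles, length_bins):
        frame = prof.to_frame()
        frame.insert(0, "bin_lo_nm", lo)
        frame.insert(1, "bin_hi_nm", hi)
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
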