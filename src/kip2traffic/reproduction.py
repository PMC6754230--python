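"""Scaled-down synthetic reproduction of the headline model-derived numbers.

Each function regenerates its inputs from the preset truth configurations,
runs the corresponding pipeline stage, and returns the measured quantity:

* the wild-type loading-to-landing ratio (median k_in / median k_on) from a
  single-strain likelihood fit,
* the cross-strain fold-change of the loading rate constant (wild type vs
  the bfa1Δ bub2Δ double mutant) from a joint two-strain fit,
* the cross-strain fold-change of the landing rate constant and the
  in-strain loading-to-landing ratio for the KIP2-S63A mutant,
* the mean kymograph speckle speed over a generated cohort,
* the median SPB asymmetry index over a generated cohort.

All randomness derives from the single ``seed`` argument; derived child
seeds stay below 2**31.
"""

from __future__ import annotations

import warnings

import numpy as np

from .constants import CONDITIONING_NM
from .inference import compare_strains_paired, joint_fit_strains, sample_likelihood
from .quantify import asymmetry_index, speckle_speed
from .synthetic import (
    generate_profile_dataset,
    generate_spb_dataset,
    generate_speckle_tracks,
    preset,
)

__all__ = [
    "wt_loading_to_landing_ratio",
    "kin_fold_wt_vs_bfa1_bub2",
    "s63a_kon_fold_and_ratio",
    "speckle_speed_mean",
    "spb_asymmetry_median",
]

_CONDITION = f"c_total >= {CONDITIONING_NM}"


def _child(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def wt_loading_to_landing_ratio(
    seed: int, n_draws: int = 2048, cells_per_bin: int = 100
) -> dict:
    """Median k_in over median k_on from a wild-type single-strain fit."""
    truth = preset("wt", seed=_child(seed, 0), cells_per_bin=cells_per_bin)
    bins, _, _ = generate_profile_dataset(truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples = sample_likelihood(bins, n_draws=n_draws, seed=_child(seed, 1))
    med = samples.draws.median()
    return {
        "ratio": float(med["k_in"] / med["k_on"]),
        "n_draws": samples.n_draws,
        "samples": samples,
    }


def _joint(seed: int, mutant: str, n_draws: int, cells_per_bin: int) -> dict:
    wt_bins, _, _ = generate_profile_dataset(
        preset("wt", seed=_child(seed, 2), cells_per_bin=cells_per_bin)
    )
    mut_bins, _, _ = generate_profile_dataset(
        preset(mutant, seed=_child(seed, 3), cells_per_bin=cells_per_bin)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return joint_fit_strains(
            {"wt": wt_bins, mutant: mut_bins},
            n_draws=n_draws,
            seed=_child(seed, 4),
        )


def kin_fold_wt_vs_bfa1_bub2(
    seed: int, n_draws: int = 2048, cells_per_bin: int = 100
) -> dict:
    """Fold-reduction of the loading rate constant in bfa1Δ bub2Δ vs wild type.

    Joint two-strain fit with shared plus-end/lattice rates and optics;
    the fold is the ratio of conditional medians of k_in (wt over mutant)
    for draws with total concentration at or above the conditioning bound.
    """
    joint = _joint(seed, "bfa1_bub2", n_draws, cells_per_bin)
    cmp = compare_strains_paired(
        joint["wt"], joint["bfa1_bub2"], "k_in",
        alternative="greater", conditioning=_CONDITION,
    )
    return {"fold": cmp.fold_difference, "p_value": cmp.p_value, "joint": joint,
            "comparison": cmp}


def s63a_kon_fold_and_ratio(
    seed: int, n_draws: int = 2048, cells_per_bin: int = 100
) -> dict:
    """Landing-rate fold-increase in KIP2-S63A vs wild type, and the mutant's
    in-strain loading-to-landing ratio, from one joint fit."""
    joint = _joint(seed, "s63a", n_draws, cells_per_bin)
    cmp = compare_strains_paired(
        joint["s63a"], joint["wt"], "k_on",
        alternative="greater", conditioning=_CONDITION,
    )
    mut = joint["s63a"].draws
    cond = mut[mut.eval(_CONDITION)]
    ratio = float(cond["k_in"].median() / cond["k_on"].median())
    return {
        "kon_fold": cmp.fold_difference,
        "p_value": cmp.p_value,
        "kin_over_kon_s63a": ratio,
        "joint": joint,
        "comparison": cmp,
    }


def speckle_speed_mean(seed: int, n_tracks: int = 192) -> dict:
    """Mean speed over a generated kymograph speckle cohort (µm/min)."""
    truth = preset("wt", seed=_child(seed, 7))
    tracks, _ = generate_speckle_tracks(truth, n_tracks)
    speeds = np.array([speckle_speed(t) for t in tracks])
    return {
        "mean": float(speeds.mean()),
        "sd": float(speeds.std(ddof=1)),
        "n": n_tracks,
    }


def spb_asymmetry_median(seed: int, n_cells: int = 1407) -> dict:
    """Median asymmetry index over a correctly-oriented SPB-intensity cohort."""
    truth = preset("wt", seed=_child(seed, 8), orientation_p_correct=1.0)
    records, _ = generate_spb_dataset(truth, n_cells)
    indices = np.array([asymmetry_index(r) for r in records])
    return {"median": float(np.median(indices)), "n": n_cells}
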