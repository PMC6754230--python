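"""Minus-end-loading exclusion-process transport model on a microtubule lattice.

The model describes a plus-end-directed motor (kinesin Kip2) on a discrete
one-dimensional lattice of tubulin-dimer sites anchored at the spindle pole
body (SPB).  Free motor at concentration ``c_free`` enters the lattice in two
ways: it is loaded onto the minus-end site (rate ``r_in = k_in * c_free`` if
that site is empty) and it lands on any free lattice site (rate
``r_on = k_on * c_free`` per site).  A bound motor detaches from the lattice
with rate ``k_off``, steps toward the plus end with rate ``k_step`` when the
next site is free, and leaves the terminal (plus-end) site with its own rate
``k_out``.  At most one motor occupies a site (exclusion).  The free pool may
be a finite, conserved reservoir, in which case ``c_free`` is depleted by the
bound motors.

The module provides

* an exact stationary solution of the underlying continuous-time Markov chain
  for small lattices (:func:`solve_master_equation`, the oracle),
* a mean-field steady-state solver for arbitrary lattice sizes
  (:func:`solve_meanfield_steady_state`),
* an exact stochastic simulator (:func:`simulate_gillespie`) and its
  growing-lattice variant (:func:`simulate_growing_lattice`),
* the analytic classification of parameter regimes that produce a flat
  occupancy profile (:func:`classify_flat_profile`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse
import scipy.sparse.linalg
from scipy.linalg.lapack import dgtsv

from .constants import CELL_VOLUME_FL, COPIES_PER_NM_FL, SITE_NM

__all__ = [
    "MotorKinetics",
    "LatticeSpec",
    "ReservoirSpec",
    "OccupancyProfile",
    "LatticeTrajectory",
    "FlatnessVerdict",
    "ConvergenceError",
    "solve_meanfield_steady_state",
    "solve_master_equation",
    "simulate_gillespie",
    "simulate_growing_lattice",
    "time_averaged_occupancy",
    "classify_flat_profile",
]


class ConvergenceError(RuntimeError):
    """Raised when the mean-field solver fails to reach its tolerance."""


@dataclass(frozen=True)
class MotorKinetics:
    """Kinetic rate constants of the motor and its total concentration.

    Parameters
    ----------
    k_in
        Minus-end loading rate constant (per nM per s).
    k_on
        Lattice landing rate constant, per site (per nM per s).
    k_off
        Lattice detachment rate (per s); does not apply to the plus-end site.
    k_step
        Stepping rate toward the plus end (per s).
    k_out
        Detachment rate from the plus-end site (per s).
    c_total
        Total motor concentration (nM).
    """

    k_in: float
    k_on: float
    k_off: float
    k_step: float
    k_out: float
    c_total: float

    def __post_init__(self) -> None:
        for name in ("k_in", "k_on", "k_off", "k_step", "k_out", "c_total"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        if (self.k_in > 0 or self.k_on > 0) and self.c_total <= 0:
            raise ValueError("c_total must be > 0 when a binding rate constant is > 0")

    def replace(self, **changes) -> "MotorKinetics":
        from dataclasses import replace

        return replace(self, **changes)


@dataclass(frozen=True)
class LatticeSpec:
    """Discretization of the microtubule: number of sites and site length (nm)."""

    n_sites: int
    site_length: float = SITE_NM

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.site_length <= 0:
            raise ValueError("site_length must be > 0")

    @property
    def length_nm(self) -> float:
        return self.n_sites * self.site_length

    def site_positions(self) -> np.ndarray:
        """Site-center distances from the minus end (nm)."""
        return (np.arange(self.n_sites) + 0.5) * self.site_length


@dataclass(frozen=True)
class ReservoirSpec:
    """Cytoplasmic motor pool shared by ``n_filaments`` lattices.

    With ``closed=True`` the pool is finite: the free concentration is
    ``c_total`` minus the concentration equivalent of all bound motors in the
    volume.  With ``closed=False`` the free concentration is clamped at
    ``c_total``.
    """

    volume: float = CELL_VOLUME_FL
    n_filaments: int = 1
    closed: bool = True

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be > 0")
        if self.n_filaments < 1:
            raise ValueError("n_filaments must be >= 1")

    @property
    def copies_per_nm(self) -> float:
        """Motor copies in the volume per nM of concentration."""
        return COPIES_PER_NM_FL * self.volume


CLAMPED = ReservoirSpec(closed=False)


@dataclass
class OccupancyProfile:
    """Per-site expected occupancy, minus-end first, plus the plus-end flux."""

    occupancy: np.ndarray
    site_positions: np.ndarray
    flux: float

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        self.site_positions = np.asarray(self.site_positions, dtype=float)
        if self.occupancy.shape != self.site_positions.shape:
            raise ValueError("occupancy and site_positions must have equal length")

    @property
    def n_sites(self) -> int:
        return self.occupancy.size

    @property
    def total_bound(self) -> float:
        return float(self.occupancy.sum())


@dataclass
class FlatnessVerdict:
    """Analytic classification of whether the steady-state profile is flat."""

    is_flat: bool
    regime_label: str  # no-lattice-motors | zero-speed | minus-end-only | non-flat
    bulk_density: float | None = None


@dataclass
class LatticeTrajectory:
    """A stochastic realization of the lattice model.

    ``states[k]`` is the site-occupancy vector after the k-th event
    (``states[0]`` is the initial state); the state holds on
    ``[event_times[k], event_times[k+1])`` with ``event_times[0] = 0`` and the
    final state holding until ``duration``.  For growing lattices the state
    matrix is padded to the final width and ``n_sites_over_time`` records the
    instantaneous lattice length.
    """

    event_times: np.ndarray
    states: np.ndarray
    event_types: list[str]
    event_sites: np.ndarray
    n_sites_over_time: np.ndarray
    rng_seed: int
    duration: float
    quiescent: bool = False
    free_copies: np.ndarray | None = None
    total_copies: int | None = None
    site_length: float = SITE_NM

    @property
    def n_events(self) -> int:
        return self.event_times.size

    def to_frame(self) -> pd.DataFrame:
        """Tidy event table: time_s, event_type, site_index, n_sites."""
        return pd.DataFrame(
            {
                "time_s": self.event_times,
                "event_type": self.event_types,
                "site_index": self.event_sites,
                "n_sites": self.n_sites_over_time[1:],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# mean-field steady state
# ---------------------------------------------------------------------------


def _meanfield_residual(rho, r_in, r_on, k_off, k_step, k_out):
    """d(rho)/dt of the mean-field rate equations (vectorized, any N >= 1)."""
    n = rho.size
    res = np.empty(n)
    if n == 1:
        res[0] = (r_in + r_on) * (1.0 - rho[0]) - k_out * rho[0]
        return res
    res[0] = (r_in + r_on) * (1.0 - rho[0]) - k_off * rho[0] - k_step * rho[0] * (1.0 - rho[1])
    if n > 2:
        mid = rho[1:-1]
        res[1:-1] = (
            r_on * (1.0 - mid)
            + k_step * rho[:-2] * (1.0 - mid)
            - k_off * mid
            - k_step * mid * (1.0 - rho[2:])
        )
    res[-1] = r_on * (1.0 - rho[-1]) + k_step * rho[-2] * (1.0 - rho[-1]) - k_out * rho[-1]
    return res


def _meanfield_jacobian_tridiag(rho, r_in, r_on, k_off, k_step, k_out):
    """Tridiagonal Jacobian of the residual as (sub, diag, super) bands."""
    n = rho.size
    d = np.empty(n)
    if n == 1:
        d[0] = -(r_in + r_on) - k_out
        return np.empty(0), d, np.empty(0)
    d[0] = -(r_in + r_on) - k_off - k_step * (1.0 - rho[1])
    if n > 2:
        d[1:-1] = -r_on - k_step * rho[:-2] - k_off - k_step * (1.0 - rho[2:])
    d[-1] = -r_on - k_step * rho[-2] - k_out
    du = k_step * rho[:-1]  # d res_i / d rho_{i+1}
    dl = k_step * (1.0 - rho[1:])  # d res_i / d rho_{i-1}
    return dl, d, du


def _solve_meanfield_fixed_cfree(
    kinetics: MotorKinetics,
    n: int,
    c_free: float,
    tol: float,
    rho0: np.ndarray | None = None,
    deep_fallback: bool = True,
) -> np.ndarray:
    """Newton iteration (tridiagonal) with damped fixed-point fallback."""
    r_in = kinetics.k_in * c_free
    r_on = kinetics.k_on * c_free
    k_off, k_step, k_out = kinetics.k_off, kinetics.k_step, kinetics.k_out
    args = (r_in, r_on, k_off, k_step, k_out)

    if r_in == 0.0 and r_on == 0.0:
        return np.zeros(n)

    if rho0 is None:
        if k_step > 0:
            # low-density branch from cumulative-influx integration, with the
            # exit-limited tip value; puts Newton in the right basin even
            # close to the tip-jamming threshold
            cum = np.minimum((r_in + r_on * np.arange(1, n + 1)) / k_step, 0.249)
            rho0 = 0.5 * (1.0 - np.sqrt(1.0 - 4.0 * cum))
            if k_out > 0:
                rho0[-1] = min((r_in + n * r_on) / k_out, 0.97)
        else:
            tot = r_on + k_off
            rho0 = np.full(n, max(r_on / tot if tot > 0 else 0.0, 1e-6))
    rho = np.clip(rho0, 1e-9, 1.0 - 1e-9)

    def fixed_point(rho, n_iter, damp=0.4):
        # damped self-consistency map rho_i <- A_i / (A_i + B_i)
        for _ in range(n_iter):
            gain = np.full(n, r_on)
            gain[0] += r_in
            loss = np.full(n, k_off)
            loss[-1] += k_out - k_off  # plus-end site detaches only at k_out
            if n > 1:
                gain[1:] += k_step * rho[:-1]
                loss[:-1] += k_step * (1.0 - rho[1:])
            tot = np.maximum(gain + loss, 1e-300)
            rho = (1.0 - damp) * rho + damp * (gain / tot)
        return rho

    def newton(rho, n_iter=60):
        res = _meanfield_residual(rho, *args)
        fnorm = np.max(np.abs(res))
        for _ in range(n_iter):
            if fnorm <= tol:
                return rho, fnorm
            dl, d, du = _meanfield_jacobian_tridiag(rho, *args)
            if rho.size == 1:
                step = -res / d
            else:
                _, _, _, step, info = dgtsv(dl, d, du, -res)
                if info != 0:
                    return rho, fnorm
            lam = 1.0
            improved = False
            for _ in range(25):
                cand = np.clip(rho + lam * step, 0.0, 1.0)
                cres = _meanfield_residual(cand, *args)
                cnorm = np.max(np.abs(cres))
                if cnorm < fnorm or cnorm <= tol:
                    rho, res, fnorm = cand, cres, cnorm
                    improved = True
                    break
                lam *= 0.5
            if not improved:
                return rho, fnorm
        return rho, fnorm

    # Newton converges in a handful of iterations from a good guess; when it
    # stalls (jammed high-density corners), pull the iterate into the right
    # basin with short damped fixed-point bursts and retry.
    rho, fnorm = newton(rho)
    bursts = ((400, 0.4), (3000, 0.2)) if deep_fallback else ((400, 0.4),)
    for burst, damp in bursts:
        if fnorm <= tol:
            return rho
        rho = fixed_point(rho, burst, damp)
        rho, fnorm = newton(rho)
    if fnorm <= tol:
        return rho

    # Shock regimes (tip jamming when the landing flux exceeds the exit
    # capacity) lie outside Newton's basin from smooth guesses.  The mean-
    # field fixed point is the attractor of the rate equations, so integrate
    # them in pseudo-time with a stiff method and polish with Newton.
    import scipy.integrate

    def rhs(_t, y):
        return _meanfield_residual(np.clip(y, 0.0, 1.0), *args)

    def jac(_t, y):
        dl, d, du = _meanfield_jacobian_tridiag(np.clip(y, 0.0, 1.0), *args)
        m = np.diag(d)
        if n > 1:
            m += np.diag(du, 1) + np.diag(dl, -1)
        return m

    if not deep_fallback:
        # likelihood-loop mode: no integration budget; the caller treats the
        # failure as +inf (such points fit unjammed data catastrophically)
        raise ConvergenceError(
            f"mean-field Newton failed at n_sites={n}, c_free={c_free:.6g}, "
            f"kinetics={kinetics} (fast mode)"
        )

    slow = min(x for x in (k_step, k_out, k_off, r_in + n * r_on) if x > 0)
    horizon = 200.0 / slow
    for _ in range(3):
        ivp = scipy.integrate.solve_ivp(
            rhs, (0.0, horizon), rho, method="BDF", jac=jac, rtol=1e-8, atol=1e-10
        )
        rho = np.clip(ivp.y[:, -1], 0.0, 1.0)
        rho, fnorm = newton(rho)
        if fnorm <= tol:
            return rho
        horizon *= 10.0

    raise ConvergenceError(
        f"mean-field solver failed at n_sites={n}, c_free={c_free:.6g}, "
        f"kinetics={kinetics}"
    )


def solve_meanfield_steady_state(
    kinetics: MotorKinetics,
    lattice: LatticeSpec,
    reservoir: ReservoirSpec = CLAMPED,
    *,
    tol: float = 1e-10,
    deep_fallback: bool = True,
) -> OccupancyProfile:
    """Fixed point of the mean-field rate equations of the transport model.

    With a closed reservoir the free concentration is determined
    self-consistently: ``c_free = c_total - n_filaments * sum(rho) / copies_per_nM``.
    The residual of every site-balance equation is at most ``tol``.
    ``deep_fallback=False`` caps the pseudo-time integration budget used in
    shock (tip-jamming) regimes and raises early instead -- appropriate
    inside likelihood loops, where such points fit unjammed data
    catastrophically anyway.
    """
    n = lattice.n_sites
    c_free = kinetics.c_total
    rho = None
    if not reservoir.closed:
        rho = _solve_meanfield_fixed_cfree(kinetics, n, c_free, tol,
                                           deep_fallback=deep_fallback)
    else:
        # the map c -> c_total - bound(c)/copies is strongly contracting for
        # realistic volumes (tens of copies per nM); iterate directly and
        # fall back to damping only if it fails to settle
        per_nm = reservoir.copies_per_nm
        damping = 1.0
        converged = False
        for it in range(300):
            rho = _solve_meanfield_fixed_cfree(kinetics, n, c_free, tol, rho0=rho,
                                               deep_fallback=deep_fallback)
            bound_nm = reservoir.n_filaments * rho.sum() / per_nm
            new_c = max(kinetics.c_total - bound_nm, 0.0)
            if abs(new_c - c_free) <= 1e-9 * max(kinetics.c_total, 1.0):
                c_free = new_c
                converged = True
                break
            if it >= 20:
                damping = 0.5
            c_free = (1.0 - damping) * c_free + damping * new_c
        if not converged:
            raise ConvergenceError(
                f"closed-reservoir self-consistency failed for {kinetics}"
            )
        rho = _solve_meanfield_fixed_cfree(kinetics, n, c_free, tol, rho0=rho,
                                           deep_fallback=deep_fallback)
    flux = kinetics.k_out * rho[-1]
    return OccupancyProfile(rho, lattice.site_positions(), flux)


# ---------------------------------------------------------------------------
# exact master equation (oracle, N <= 12)
# ---------------------------------------------------------------------------


def solve_master_equation(
    kinetics: MotorKinetics,
    lattice: LatticeSpec,
    free_concentration: float,
) -> OccupancyProfile:
    """Exact stationary per-site occupancy of the lattice CTMC.

    The free motor concentration is clamped at ``free_concentration`` (nM).
    Enumerates all ``2**n_sites`` occupancy states; refuses ``n_sites > 12``.
    """
    n = lattice.n_sites
    if n > 12:
        raise ValueError(
            f"solve_master_equation is limited to n_sites <= 12 (got {n}); "
            "use the mean-field solver or the stochastic simulator instead"
        )
    if free_concentration < 0:
        raise ValueError("free_concentration must be >= 0")
    r_in = kinetics.k_in * free_concentration
    r_on = kinetics.k_on * free_concentration
    if r_in == 0.0 and r_on == 0.0:
        # no entry: the empty lattice is absorbing
        return OccupancyProfile(np.zeros(n), lattice.site_positions(), 0.0)

    n_states = 1 << n
    rows, cols, vals = [], [], []

    def add(src: int, dst: int, rate: float) -> None:
        if rate > 0:
            rows.append(src)
            cols.append(dst)
            vals.append(rate)

    for s in range(n_states):
        # entry at the minus-end site (loading + landing)
        if not s & 1:
            add(s, s | 1, r_in + r_on)
        for i in range(n):
            bit = 1 << i
            if s & bit:
                if i < n - 1:
                    if kinetics.k_off > 0:
                        add(s, s ^ bit, kinetics.k_off)
                    nxt = 1 << (i + 1)
                    if not s & nxt:
                        add(s, (s ^ bit) | nxt, kinetics.k_step)
                else:
                    add(s, s ^ bit, kinetics.k_out)
            elif i > 0:
                add(s, s | bit, r_on)

    q = scipy.sparse.coo_matrix((vals, (rows, cols)), shape=(n_states, n_states)).tocsr()
    diag = np.asarray(q.sum(axis=1)).ravel()
    gen = q - scipy.sparse.diags(diag)
    # stationary distribution: pi @ gen = 0, sum(pi) = 1
    a = gen.T.tolil()
    a[-1, :] = 1.0
    b = np.zeros(n_states)
    b[-1] = 1.0
    pi = scipy.sparse.linalg.spsolve(a.tocsr(), b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()

    states = np.arange(n_states)
    occ = np.array(
        [pi[(states >> i) & 1 == 1].sum() for i in range(n)], dtype=float
    )
    flux = kinetics.k_out * occ[-1]
    return OccupancyProfile(occ, lattice.site_positions(), flux)


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------


def _simulate(
    kinetics: MotorKinetics,
    initial_n: int,
    reservoir: ReservoirSpec,
    duration: float,
    seed: int,
    growth_rate: float,
    site_length: float,
) -> LatticeTrajectory:
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if growth_rate < 0:
        raise ValueError("growth_rate must be >= 0")
    rng = np.random.default_rng(seed)

    per_nm = reservoir.copies_per_nm
    if reservoir.closed:
        total_copies = int(round(kinetics.c_total * per_nm))
        n_free = total_copies
    else:
        total_copies = None
        n_free = None

    occ = np.zeros(initial_n, dtype=np.uint8)
    t = 0.0
    times: list[float] = []
    states: list[np.ndarray] = [occ.copy()]
    etypes: list[str] = []
    esites: list[int] = []
    nsites: list[int] = [initial_n]
    free_hist: list[int] = [n_free] if n_free is not None else []
    quiescent = False

    while True:
        n = occ.size
        c_free = (n_free / per_nm) if reservoir.closed else kinetics.c_total
        r_in = kinetics.k_in * c_free
        r_on = kinetics.k_on * c_free

        empty = occ == 0
        a_load = r_in if occ[0] == 0 else 0.0
        land = np.where(empty, r_on, 0.0)
        detach = np.zeros(n)
        if n > 1:
            detach[:-1] = np.where(occ[:-1] == 1, kinetics.k_off, 0.0)
        step = np.zeros(n)
        if n > 1:
            step[:-1] = np.where((occ[:-1] == 1) & (occ[1:] == 0), kinetics.k_step, 0.0)
        a_exit = kinetics.k_out if occ[-1] == 1 else 0.0
        a_grow = growth_rate

        land_sum = land.sum()
        detach_sum = detach.sum()
        step_sum = step.sum()
        total = a_load + land_sum + detach_sum + step_sum + a_exit + a_grow
        if total <= 0.0:
            quiescent = True
            break

        t += rng.exponential(1.0 / total)
        if t > duration:
            break
        u = rng.random() * total

        if u < a_load:
            occ[0] = 1
            if reservoir.closed:
                n_free -= 1
            etypes.append("load")
            esites.append(0)
        elif u < a_load + land_sum:
            u -= a_load
            i = int(np.searchsorted(np.cumsum(land), u, side="right"))
            occ[i] = 1
            if reservoir.closed:
                n_free -= 1
            etypes.append("land")
            esites.append(i)
        elif u < a_load + land_sum + detach_sum:
            u -= a_load + land_sum
            i = int(np.searchsorted(np.cumsum(detach), u, side="right"))
            occ[i] = 0
            if reservoir.closed:
                n_free += 1
            etypes.append("detach")
            esites.append(i)
        elif u < a_load + land_sum + detach_sum + step_sum:
            u -= a_load + land_sum + detach_sum
            i = int(np.searchsorted(np.cumsum(step), u, side="right"))
            occ[i] = 0
            occ[i + 1] = 1
            etypes.append("step")
            esites.append(i)
        elif u < a_load + land_sum + detach_sum + step_sum + a_exit:
            occ[-1] = 0
            if reservoir.closed:
                n_free += 1
            etypes.append("exit")
            esites.append(n - 1)
        else:
            occ = np.append(occ, np.uint8(0))
            etypes.append("grow")
            esites.append(occ.size - 1)

        times.append(t)
        states.append(occ.copy())
        nsites.append(occ.size)
        if reservoir.closed:
            free_hist.append(n_free)

    width = occ.size
    mat = np.zeros((len(states), width), dtype=np.uint8)
    for k, s in enumerate(states):
        mat[k, : s.size] = s
    return LatticeTrajectory(
        event_times=np.asarray(times, dtype=float),
        states=mat,
        event_types=etypes,
        event_sites=np.asarray(esites, dtype=int),
        n_sites_over_time=np.asarray(nsites, dtype=int),
        rng_seed=seed,
        duration=duration,
        quiescent=quiescent,
        free_copies=np.asarray(free_hist, dtype=int) if reservoir.closed else None,
        total_copies=total_copies,
        site_length=site_length,
    )


def simulate_gillespie(
    kinetics: MotorKinetics,
    lattice: LatticeSpec,
    reservoir: ReservoirSpec = CLAMPED,
    duration: float = 1000.0,
    seed: int = 0,
) -> LatticeTrajectory:
    """Exact stochastic simulation of the transport model on a fixed lattice.

    Identical seed and inputs reproduce the identical event sequence.  With a
    closed reservoir the free pool is decremented/incremented as integer
    copies on every binding/unbinding event (single simulated filament).
    """
    return _simulate(
        kinetics, lattice.n_sites, reservoir, duration, seed, 0.0, lattice.site_length
    )


def simulate_growing_lattice(
    kinetics: MotorKinetics,
    growth_rate: float,
    initial_n: int,
    duration: float,
    seed: int,
    reservoir: ReservoirSpec = CLAMPED,
    site_length: float = SITE_NM,
) -> LatticeTrajectory:
    """Stochastic simulation with the plus end growing as a Poisson process.

    Empty sites are appended at the plus end with rate ``growth_rate`` (sites
    per second), interleaved with the motor events.  ``growth_rate = 0``
    reduces event-for-event to :func:`simulate_gillespie`.
    """
    if initial_n < 1:
        raise ValueError("initial_n must be >= 1")
    return _simulate(kinetics, initial_n, reservoir, duration, seed, growth_rate, site_length)


def time_averaged_occupancy(
    trajectory: LatticeTrajectory, burn_in: float = 0.0
) -> OccupancyProfile:
    """Time-weighted mean occupancy per site after ``burn_in``.

    For growing lattices, sites are counted as unoccupied before they exist
    and the average is taken over the full post-burn-in window.  The flux is
    the empirical plus-end exit rate over the same window.
    """
    if burn_in >= trajectory.duration:
        raise ValueError("burn_in must be smaller than the trajectory duration")
    edges = np.concatenate(([0.0], trajectory.event_times, [trajectory.duration]))
    starts = np.maximum(edges[:-1], burn_in)
    ends = np.minimum(edges[1:], trajectory.duration)
    w = np.clip(ends - starts, 0.0, None)
    window = trajectory.duration - burn_in
    if window <= 0 or w.sum() <= 0:
        raise ValueError("empty post-burn-in window")
    occ = (w[:, None] * trajectory.states).sum(axis=0) / window

    n_exit = sum(
        1
        for t, e in zip(trajectory.event_times, trajectory.event_types)
        if e == "exit" and t >= burn_in
    )
    flux = n_exit / window
    positions = (np.arange(occ.size) + 0.5) * trajectory.site_length
    return OccupancyProfile(occ, positions, flux)


# ---------------------------------------------------------------------------
# analytic flat-profile classification
# ---------------------------------------------------------------------------


def classify_flat_profile(kinetics: MotorKinetics) -> FlatnessVerdict:
    """Classify whether the steady-state shaft profile is flat, and why.

    A flat profile arises in exactly three regimes: no entry pathway at all
    (``no-lattice-motors``), immobile motors exchanging with the pool
    everywhere (``zero-speed``), or pure minus-end loading with no lattice
    detachment (``minus-end-only``) -- the regime in which all motor is
    recruited at the minus end and ``k_off = 0``, producing a uniform
    low-density interior at ``r_in / k_step``.
    """
    k = kinetics
    c = k.c_total
    if k.k_in == 0 and k.k_on == 0:
        return FlatnessVerdict(True, "no-lattice-motors", 0.0)
    if k.k_step == 0 and k.k_on > 0:
        r_on = k.k_on * c
        return FlatnessVerdict(True, "zero-speed", r_on / (r_on + k.k_off))
    if k.k_on == 0 and k.k_off == 0 and k.k_in > 0 and k.k_step > 0:
        # uniform interior density on the low-density branch
        return FlatnessVerdict(True, "minus-end-only", min(k.k_in * c / k.k_step, 0.5))
    return FlatnessVerdict(False, "non-flat", None)
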