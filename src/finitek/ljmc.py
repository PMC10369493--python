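"""Canonical Monte Carlo sampling of associating Lennard-Jones particles.

The model system: N identical single-site particles in a periodic cubic box
at fixed temperature, interacting through a truncated (unshifted)
Lennard-Jones potential.  Two particles are bonded when their minimum-image
distance is below ``r_bond``; clusters are the connected components of the
bond graph.  Sampling is by Metropolis Monte Carlo with a mixed symmetric
move set — local single-particle displacements plus occasional uniform
reinsertions anywhere in the box — which targets the canonical distribution
at T while keeping bond-breaking and bond-forming moves frequent even at
well depths of many k_B T.  Ensemble averages of the cluster counts are the
only quantities consumed downstream, and those are independent of the
dynamics used to generate them.

A one-dimensional quadrature over the pair Boltzmann factor provides an
independent equilibrium constant for the two-particle system, used to
validate the sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit
from scipy.integrate import quad

from .series import CompositionState, CountsSeries
from .units import DEFAULT_C_STD, GAS_CONSTANT

__all__ = [
    "SimulationSpec",
    "Configuration",
    "pair_energy",
    "total_energy",
    "cluster_counts",
    "metropolis_chain",
    "two_particle_K_quadrature",
    "write_xyz",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the Lennard-Jones model system.

    Defaults follow the model definition: particle diameter
    ``sigma = 0.20 nm``, ``T = 300 K``, interaction cutoff ``2.0 nm`` and
    bonding criterion ``r < 0.35 nm`` (the first minimum of the pair
    distribution function).  ``epsilon`` is the well depth in kJ/mol.
    """

    n_total: int
    box_length: float
    epsilon: float
    sigma: float = 0.20
    temperature: float = 300.0
    r_cut: float = 2.0
    r_bond: float = 0.35
    max_disp: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError(f"n_total must be >= 1, got {self.n_total}")
        for name in ("box_length", "sigma", "temperature", "r_cut", "r_bond"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.box_length < 2.0 * self.r_cut:
            raise ValueError(
                f"box_length {self.box_length} must be >= 2*r_cut "
                f"= {2 * self.r_cut} for minimum-image validity"
            )
        if self.r_bond >= self.r_cut:
            raise ValueError("r_bond must be smaller than r_cut")
        if self.max_disp is not None and self.max_disp <= 0:
            raise ValueError("max_disp must be positive")

    @property
    def volume(self) -> float:
        return self.box_length**3

    @property
    def beta(self) -> float:
        return 1.0 / (GAS_CONSTANT * self.temperature)

    def initial_max_disp(self) -> float:
        # half-box displacements are, under wrapping, uniform reinsertions
        return self.max_disp if self.max_disp is not None else 0.5 * self.box_length


@dataclass
class Configuration:
    """Particle positions (nm), wrapped into the primary box [0, L)^3."""

    positions: np.ndarray
    box_length: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        self.positions = np.mod(self.positions, self.box_length)


def pair_energy(r: float, spec: SimulationSpec) -> float:
    """Truncated, unshifted Lennard-Jones pair energy at distance r (nm).

    ``4 eps [(sigma/r)^12 - (sigma/r)^6]`` for ``r <= r_cut``, zero beyond.
    """
    if r <= 0:
        raise ValueError(f"distance must be positive, got {r}")
    if r > spec.r_cut:
        return 0.0
    x6 = (spec.sigma / r) ** 6
    return 4.0 * spec.epsilon * (x6 * x6 - x6)


def _min_image_dist2(dx: np.ndarray, L: float) -> np.ndarray:
    dx = dx - L * np.round(dx / L)
    return np.sum(dx * dx, axis=-1)


def total_energy(config: Configuration, spec: SimulationSpec) -> float:
    """Sum of pair energies over minimum-image pairs."""
    pos = config.positions
    n = pos.shape[0]
    u = 0.0
    for i in range(n - 1):
        d2 = _min_image_dist2(pos[i + 1:] - pos[i], config.box_length)
        for r2 in d2:
            r = math.sqrt(r2)
            if 0 < r <= spec.r_cut:
                u += pair_energy(r, spec)
    return u


def cluster_counts(config: Configuration, spec: SimulationSpec) -> CompositionState:
    """Cluster-size histogram of one configuration.

    Bonds join pairs with minimum-image distance strictly below ``r_bond``;
    clusters are connected components of the bond graph, so bonding is
    transitive through shared neighbours.
    """
    pos = config.positions
    n = pos.shape[0]
    L = config.box_length
    adj = [[] for _ in range(n)]
    rb2 = spec.r_bond**2
    for i in range(n - 1):
        d2 = _min_image_dist2(pos[i + 1:] - pos[i], L)
        for off, r2 in enumerate(d2):
            if r2 < rb2:
                j = i + 1 + off
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    counts: dict[int, int] = {}
    for i in range(n):
        if seen[i]:
            continue
        stack, size = [i], 0
        seen[i] = True
        while stack:
            v = stack.pop()
            size += 1
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        counts[size] = counts.get(size, 0) + 1
    return CompositionState(counts)


# ---------------------------------------------------------------------------
# Metropolis kernel (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _particle_energy(pos, i, xi, yi, zi, L, eps, sig2, rcut2):
    u = 0.0
    n = pos.shape[0]
    for j in range(n):
        if j == i:
            continue
        dx = pos[j, 0] - xi
        dy = pos[j, 1] - yi
        dz = pos[j, 2] - zi
        dx -= L * round(dx / L)
        dy -= L * round(dy / L)
        dz -= L * round(dz / L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 <= rcut2 and r2 > 0.0:
            s6 = (sig2 / r2) ** 3
            u += 4.0 * eps * (s6 * s6 - s6)
    return u


@njit(cache=True)
def _frame_counts(pos, L, rbond2, out):
    n = pos.shape[0]
    parent = np.arange(n)
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            if dx * dx + dy * dy + dz * dz < rbond2:
                # union by root walk
                ri = i
                while parent[ri] != ri:
                    ri = parent[ri]
                rj = j
                while parent[rj] != rj:
                    rj = parent[rj]
                if ri != rj:
                    parent[rj] = ri
    sizes = np.zeros(n, dtype=np.int64)
    for i in range(n):
        r = i
        while parent[r] != r:
            r = parent[r]
        sizes[r] += 1
    for i in range(n):
        out[i] = 0
    for i in range(n):
        if sizes[i] > 0:
            out[sizes[i] - 1] += 1


@njit(cache=True)
def _attempt_move(pos, i, L, eps, sig2, rcut2, rbond, beta, max_disp, p_jump, p_avb):
    """One trial move for particle i.

    Returns (accepted, was_local).  Move mix:
    - uniform reinsertion anywhere in the box (prob p_jump);
    - aggregation-volume-bias swap between the bonded shell of a random
      partner and the bulk (prob p_avb, only for n >= 2): the trial position
      is drawn, with probability 1/2 each, uniformly inside the sphere of
      radius r_bond around the partner or uniformly in the remaining volume;
      the generation-probability ratio V_in/V_out enters the acceptance,
      preserving detailed balance while making association/dissociation
      events O(1)-probable even at deep wells;
    - local cubic displacement of half-width max_disp (remainder).
    All kernels are symmetric or explicitly bias-corrected.
    """
    n = pos.shape[0]
    xo, yo, zo = pos[i, 0], pos[i, 1], pos[i, 2]
    u = np.random.random()
    bias = 1.0
    was_local = False
    if u < p_jump:
        xn = np.random.random() * L
        yn = np.random.random() * L
        zn = np.random.random() * L
    elif u < p_jump + p_avb and n >= 2:
        j = np.random.randint(0, n - 1)
        if j >= i:
            j += 1
        v_in = 4.0 / 3.0 * math.pi * rbond**3
        v_out = L * L * L - v_in
        # is i currently inside the shell of j?
        dx = xo - pos[j, 0]
        dy = yo - pos[j, 1]
        dz = zo - pos[j, 2]
        dx -= L * round(dx / L)
        dy -= L * round(dy / L)
        dz -= L * round(dz / L)
        old_in = dx * dx + dy * dy + dz * dz < rbond * rbond
        if np.random.random() < 0.5:
            # propose uniformly inside the shell of j
            r = rbond * np.random.random() ** (1.0 / 3.0)
            gx = np.random.normal()
            gy = np.random.normal()
            gz = np.random.normal()
            norm = math.sqrt(gx * gx + gy * gy + gz * gz)
            while norm < 1e-12:
                gx = np.random.normal()
                gy = np.random.normal()
                gz = np.random.normal()
                norm = math.sqrt(gx * gx + gy * gy + gz * gz)
            xn = (pos[j, 0] + r * gx / norm) % L
            yn = (pos[j, 1] + r * gy / norm) % L
            zn = (pos[j, 2] + r * gz / norm) % L
            if not old_in:
                bias = v_in / v_out
        else:
            # propose uniformly in the bulk (outside the shell of j)
            while True:
                xn = np.random.random() * L
                yn = np.random.random() * L
                zn = np.random.random() * L
                dx = xn - pos[j, 0]
                dy = yn - pos[j, 1]
                dz = zn - pos[j, 2]
                dx -= L * round(dx / L)
                dy -= L * round(dy / L)
                dz -= L * round(dz / L)
                if dx * dx + dy * dy + dz * dz >= rbond * rbond:
                    break
            if old_in:
                bias = v_out / v_in
    else:
        xn = (xo + (np.random.random() - 0.5) * 2.0 * max_disp) % L
        yn = (yo + (np.random.random() - 0.5) * 2.0 * max_disp) % L
        zn = (zo + (np.random.random() - 0.5) * 2.0 * max_disp) % L
        was_local = True
    du = _particle_energy(pos, i, xn, yn, zn, L, eps, sig2, rcut2) - \
        _particle_energy(pos, i, xo, yo, zo, L, eps, sig2, rcut2)
    ratio = bias * math.exp(-min(beta * du, 700.0))
    if ratio >= 1.0 or np.random.random() < ratio:
        pos[i, 0], pos[i, 1], pos[i, 2] = xn, yn, zn
        return True, was_local
    return False, was_local


@njit(cache=True)
def _run_chain(
    n,
    L,
    eps,
    sig,
    rcut,
    rbond,
    beta,
    n_equil,
    n_prod,
    thin,
    max_disp0,
    p_jump,
    p_avb,
    tune,
    seed,
    counts_out,
):
    np.random.seed(seed)
    sig2 = sig * sig
    rcut2 = rcut * rcut
    rbond2 = rbond * rbond
    pos = np.random.random((n, 3)) * L
    max_disp = max_disp0
    tmp = np.zeros(n, dtype=np.int64)

    # equilibration (optionally with step-size tuning on local moves)
    loc_try = 0
    loc_acc = 0
    for sweep in range(n_equil):
        for _ in range(n):
            i = np.random.randint(0, n)
            ok, was_local = _attempt_move(
                pos, i, L, eps, sig2, rcut2, rbond, beta, max_disp, p_jump, p_avb
            )
            if was_local:
                loc_try += 1
                if ok:
                    loc_acc += 1
        if tune and loc_try >= 200:
            acc = loc_acc / loc_try
            if acc > 0.45:
                max_disp *= 1.1
            elif acc < 0.35:
                max_disp *= 0.9
            if max_disp > 0.5 * L:
                max_disp = 0.5 * L
            if max_disp < 1e-3 * L:
                max_disp = 1e-3 * L
            loc_try = 0
            loc_acc = 0

    # production: fixed move parameters (detailed balance)
    n_acc = 0
    n_try = 0
    frame = 0
    for sweep in range(n_prod):
        for _ in range(n):
            i = np.random.randint(0, n)
            ok, _was_local = _attempt_move(
                pos, i, L, eps, sig2, rcut2, rbond, beta, max_disp, p_jump, p_avb
            )
            n_try += 1
            if ok:
                n_acc += 1
        if (sweep + 1) % thin == 0:
            _frame_counts(pos, L, rbond2, tmp)
            for m in range(n):
                counts_out[frame, m] = tmp[m]
            frame += 1
    acc_rate = n_acc / n_try if n_try > 0 else 0.0
    return pos, acc_rate, max_disp


def metropolis_chain(
    spec: SimulationSpec,
    n_sweeps: int,
    thin: int = 1,
    equilibration_fraction: float = 0.1,
    tune: bool = True,
    p_jump: float = 0.2,
    p_avb: float = 0.5,
    return_configuration: bool = False,
):
    """Sample cluster-count series by Metropolis Monte Carlo.

    One sweep is ``n_total`` attempted single-particle moves.  The move mix
    combines uniform reinsertions (prob ``p_jump``), aggregation-volume-bias
    shell/bulk swaps (prob ``p_avb``; these keep association and
    dissociation events frequent even at well depths of many k_B T) and
    local displacements uniform in a cube of half-width ``max_disp``.  All
    kernels are symmetric or bias-corrected in the acceptance rule, so the
    chain satisfies detailed balance with respect to the canonical
    distribution at ``spec.temperature``.  The local step size is tuned
    toward ~40% acceptance during the equilibration segment only (the first
    ``equilibration_fraction`` of ``n_sweeps``, discarded); production runs
    with fixed move parameters.  Cluster counts are recorded every ``thin``
    production sweeps.

    Returns a :class:`CountsSeries` (with acceptance-rate diagnostics in
    ``provenance``); with ``return_configuration=True``, also the final
    :class:`Configuration`.
    """
    if n_sweeps < 1:
        raise ValueError(f"n_sweeps must be >= 1, got {n_sweeps}")
    if thin < 1:
        raise ValueError(f"thin must be >= 1, got {thin}")
    if not 0.0 <= equilibration_fraction < 1.0:
        raise ValueError("equilibration_fraction must be in [0, 1)")
    if not 0.0 <= p_jump <= 1.0 or not 0.0 <= p_avb <= 1.0 or p_jump + p_avb > 1.0:
        raise ValueError("p_jump and p_avb must be in [0, 1] with sum <= 1")
    n_equil = int(round(equilibration_fraction * n_sweeps))
    n_prod = n_sweeps - n_equil
    n_frames = n_prod // thin
    if n_frames < 1:
        raise ValueError(
            f"no production frames: {n_prod} production sweeps with thin={thin}"
        )
    counts = np.zeros((n_frames, spec.n_total), dtype=np.int64)
    pos, acc, tuned_disp = _run_chain(
        spec.n_total,
        spec.box_length,
        spec.epsilon,
        spec.sigma,
        spec.r_cut,
        spec.r_bond,
        spec.beta,
        n_equil,
        n_prod,
        thin,
        spec.initial_max_disp(),
        p_jump,
        p_avb,
        tune,
        spec.seed % 2**32,
        counts,
    )
    series = CountsSeries(
        counts=counts,
        volume=spec.volume,
        n_total=spec.n_total,
        c_std=DEFAULT_C_STD,
        provenance={
            "sampler": "lj_metropolis_mc",
            "seed": int(spec.seed),
            "n_sweeps": int(n_sweeps),
            "n_equilibration_sweeps": int(n_equil),
            "thin": int(thin),
            "p_jump": float(p_jump),
            "p_avb": float(p_avb),
            "acceptance_rate": float(acc),
            "tuned_max_disp": float(tuned_disp),
            "spec": {
                "n_total": spec.n_total,
                "box_length": spec.box_length,
                "epsilon": spec.epsilon,
                "sigma": spec.sigma,
                "temperature": spec.temperature,
                "r_cut": spec.r_cut,
                "r_bond": spec.r_bond,
            },
        },
    )
    if return_configuration:
        return series, Configuration(pos, spec.box_length)
    return series


# ---------------------------------------------------------------------------
# two-particle quadrature oracle
# ---------------------------------------------------------------------------


def two_particle_K_quadrature(
    spec: SimulationSpec, c_std: float = DEFAULT_C_STD
) -> float:
    """Exact dimerization constant of the two-particle system by quadrature.

    For N = 2 the relative-coordinate configuration integral factorizes
    into a bonded part ``I_b = int_0^{r_bond} exp(-u(r)/RT) 4 pi r^2 dr``
    and an unbonded part
    ``I_u = V - (4/3) pi r_bond^3 + int_{r_bond}^{r_cut} (exp(-u/RT) - 1) 4 pi r^2 dr``
    (beyond the cutoff the Boltzmann factor is 1), giving

        K = c_std * V * I_b / (2 * I_u)

    where the factor 2 is the monomer self-correlation combinatorics of the
    homo-dimerization constant.  Requires ``box_length >= 2 r_cut`` so the
    cutoff sphere fits the minimum-image cell.
    """
    beta = spec.beta

    def boltz(r: float) -> float:
        return math.exp(-beta * pair_energy(r, spec)) * 4.0 * math.pi * r * r

    def mayer(r: float) -> float:
        return (math.exp(-beta * pair_energy(r, spec)) - 1.0) * 4.0 * math.pi * r * r

    i_b, err_b = quad(boltz, 0.0, spec.r_bond, epsabs=0.0, epsrel=1e-11, limit=400)
    i_m, err_m = quad(
        mayer, spec.r_bond, spec.r_cut, epsabs=1e-13, epsrel=1e-11, limit=400
    )
    if i_b <= 0:
        raise ArithmeticError("bonded configuration integral vanished")
    if err_b / i_b > 1e-8 or err_m > max(1e-8 * abs(i_m), 1e-10):
        raise ArithmeticError(
            f"quadrature did not converge (errors {err_b}, {err_m})"
        )
    v = spec.volume
    i_u = v - (4.0 / 3.0) * math.pi * spec.r_bond**3 + i_m
    return c_std * v * i_b / (2.0 * i_u)


def write_xyz(config: Configuration, path, comment: str = "") -> None:
    """Write a configuration as XYZ (element tag ``A``, coordinates in nm)."""
    with open(path, "w") as fh:
        fh.write(f"{config.positions.shape[0]}\n{comment}\n")
        for x, y, z in config.positions:
            fh.write(f"A {x:.6f} {y:.6f} {z:.6f}\n")
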