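"""Equilibrium-constant expressions and fluctuation identities for finite systems.

In a closed system with a small number of associating particles, the law of
mass action in terms of *mean* concentrations fails: the equilibrium
constant of an elementary reaction must be written with correlated
concentration averages, and repeated species of the same kind acquire
successive self-correlation subtractions.  In count space those subtractions
are exactly falling factorials, so every expression here is built from one
kernel, the falling-factorial moment

    M[{m: k_m}] = < prod_m N_m (N_m - 1) ... (N_m - k_m + 1) > / V^(sum k_m)

For a two-body association of an i-mer and a j-mer,

    K_{i+j} = <c_{i+j}> c_std / < c_i (c_j - delta_ij / V) >

and its m-body (concerted) and transfer-reaction generalizations follow by
adding falling-factorial orders.  Products of elementary constants along a
reaction path give the multimerization constant K_m; all paths share one
value (free energy is a state function), which the exact ensemble in
:mod:`finitek.ensemble` certifies to machine precision.

Every estimator accepts either a :class:`~finitek.series.CountsSeries`
(sample moments; standard errors by block averaging) or a
:class:`~finitek.ensemble.ClusterModel` (exact moments; zero error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .ensemble import ClusterModel
from .series import CountsSeries
from .units import GAS_CONSTANT

__all__ = [
    "ReactionSpec",
    "Estimate",
    "KEstimate",
    "series_moment",
    "elementary_K",
    "path_K",
    "uncorrelated_K",
    "transfer_K_direct",
    "transfer_K_ratio",
    "transfer_K_uncorrelated",
    "prob_ratio_K",
    "relative_fluctuation",
    "fluctuation_relation_check",
    "partition_fluctuation_equality",
    "delta_G",
    "cycle_closure",
    "block_error",
    "enumerate_mechanisms",
]

DEFAULT_N_BLOCKS = 20


@dataclass(frozen=True)
class ReactionSpec:
    """A reaction between cluster species, as multisets of sizes.

    ``reactants`` and ``products`` are stored sorted.  Associations have a
    single product equal to the sum of the reactant sizes; transfer
    reactions have association and dissociation on both sides and conserve
    both the particle total and the species count.
    """

    reactants: tuple[int, ...]
    products: tuple[int, ...]

    def __init__(self, reactants: Sequence[int], products: Sequence[int] | None = None):
        reactants = tuple(sorted(int(x) for x in reactants))
        if any(x < 1 for x in reactants):
            raise ValueError("cluster sizes must be >= 1")
        if products is None:
            products = (sum(reactants),)
        products = tuple(sorted(int(x) for x in products))
        if any(x < 1 for x in products):
            raise ValueError("cluster sizes must be >= 1")
        if sum(reactants) != sum(products):
            raise ValueError(
                f"reaction does not conserve particles: "
                f"{reactants} -> {products}"
            )
        object.__setattr__(self, "reactants", reactants)
        object.__setattr__(self, "products", products)

    @property
    def is_association(self) -> bool:
        return len(self.products) == 1

    def label(self) -> str:
        lhs = "+".join(map(str, self.reactants))
        rhs = "+".join(map(str, self.products))
        return f"{lhs}={rhs}" if not self.is_association else lhs


@dataclass(frozen=True)
class Estimate:
    """A scalar estimate with a standard error.

    ``defined`` is False when the statistic could not be formed (e.g. a
    denominator species never observed); the value is then NaN rather than
    raising, so scans can report gaps.
    """

    value: float
    stderr: float
    defined: bool = True

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class KEstimate(Estimate):
    """Dimensionless equilibrium constant with the expression that made it."""

    label: str = ""
    n_blocks: int = 0


# ---------------------------------------------------------------------------
# data access: one uniform view over sampled series and the exact ensemble
# ---------------------------------------------------------------------------


def _unpack(data):
    """Return (counts (K,M), weights (K,), V, c_std, n_total, is_series)."""
    if isinstance(data, ClusterModel):
        return (
            data._matrix.astype(np.float64),
            data._probs,
            data.volume,
            data.c_std,
            data.n_total,
            False,
        )
    if isinstance(data, CountsSeries):
        counts = data.counts.astype(np.float64)
        w = np.full(len(data), 1.0 / len(data))
        return counts, w, data.volume, data.c_std, data.n_total, True
    raise TypeError(
        f"expected CountsSeries or ClusterModel, got {type(data).__name__}"
    )


def _ff(x: np.ndarray, k: int) -> np.ndarray:
    out = np.ones_like(x)
    for t in range(k):
        out = out * (x - t)
    return out


def _ff_rows(counts: np.ndarray, spec: Mapping[int, int]) -> np.ndarray:
    """Per-row falling-factorial product for a {size: order} spec."""
    vals = np.ones(counts.shape[0])
    for m, k in spec.items():
        m, k = int(m), int(k)
        if m < 1 or k < 0:
            raise ValueError(f"invalid moment spec entry {m}: {k}")
        if k == 0:
            continue
        if m > counts.shape[1]:
            vals = vals * 0.0
        else:
            vals = vals * _ff(counts[:, m - 1], k)
    return vals


def _expr_rows(counts: np.ndarray, expr) -> np.ndarray:
    """Per-row values for a count expression.

    ``expr`` may be a {size: order} falling-factorial spec or a callable
    mapping the (K, M) counts matrix to a length-K array.
    """
    if callable(expr):
        return np.asarray(expr(counts), dtype=np.float64)
    return _ff_rows(counts, expr)


def _evaluate(
    data,
    fn: Callable[[np.ndarray, np.ndarray, float, float], float],
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> Estimate:
    """Evaluate a statistic; block-average stderr on series, 0 on oracle."""
    counts, weights, V, c_std, _, is_series = _unpack(data)
    value = fn(counts, weights, V, c_std)
    if not np.isfinite(value):
        return Estimate(float("nan"), float("nan"), defined=False)
    if not is_series:
        return Estimate(float(value), 0.0)
    stderr = _block_stderr(counts, V, c_std, fn, n_blocks)
    return Estimate(float(value), stderr)


def _block_stderr(counts, V, c_std, fn, n_blocks: int) -> float:
    n = counts.shape[0]
    if n_blocks < 2 or n < 2 * n_blocks:
        return float("nan")
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    vals = []
    for a, b in zip(edges[:-1], edges[1:]):
        block = counts[a:b]
        w = np.full(block.shape[0], 1.0 / block.shape[0])
        vals.append(fn(block, w, V, c_std))
    vals = np.asarray(vals, dtype=np.float64)
    good = vals[np.isfinite(vals)]
    if good.size < 2:
        return float("nan")
    return float(np.std(good, ddof=1) / math.sqrt(good.size))


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------


def series_moment(
    data, spec: Mapping[int, int], n_blocks: int = DEFAULT_N_BLOCKS
) -> Estimate:
    """Concentration-space falling-factorial moment of a series (or oracle).

    ``E[prod_m N_m^(k_m)] / V^(sum k_m)`` — the correlated concentration
    average with one -1/V self-correlation subtraction per repeated order.
    The empty spec returns exactly 1 with zero error.
    """
    if not spec:
        return Estimate(1.0, 0.0)
    total_order = sum(int(k) for k in spec.values())

    def fn(counts, weights, V, c_std):
        return float(weights @ _ff_rows(counts, spec)) / V**total_order

    return _evaluate(data, fn, n_blocks)


# ---------------------------------------------------------------------------
# equilibrium-constant expressions
# ---------------------------------------------------------------------------


def _multiset_spec(sizes: Sequence[int]) -> dict[int, int]:
    spec: dict[int, int] = {}
    for m in sizes:
        spec[int(m)] = spec.get(int(m), 0) + 1
    return spec


def _elementary_fn(reactants: tuple[int, ...]):
    den_spec = _multiset_spec(reactants)
    s = sum(reactants)
    n = len(reactants)
    num_spec = {s: 1}

    def fn(counts, weights, V, c_std):
        num = float(weights @ _ff_rows(counts, num_spec)) / V
        den = float(weights @ _ff_rows(counts, den_spec)) / V**n
        if den <= 0:
            return float("nan")
        return num * c_std ** (n - 1) / den

    return fn


def elementary_K(
    data, reactants: Sequence[int], n_blocks: int = DEFAULT_N_BLOCKS
) -> KEstimate:
    """Equilibrium constant of one elementary association.

    ``reactants`` is the multiset of cluster sizes reacting in a single
    concerted step to form one cluster of the summed size.  Two reactants
    give the two-body binding constant; m monomers give the concerted
    m-body constant; mixed multisets such as ``(1, 1, 2)`` give the
    corresponding higher-order-body constants.  A repeated size of
    multiplicity k contributes the k-th falling factorial of its count
    (the successive self-correlation subtractions).
    """
    rxn = ReactionSpec(reactants)
    _, _, _, _, n_total, _ = _unpack(data)
    if sum(rxn.reactants) > n_total:
        raise ValueError(
            f"product size {sum(rxn.reactants)} exceeds n_total {n_total}"
        )
    est = _evaluate(data, _elementary_fn(rxn.reactants), n_blocks)
    return KEstimate(est.value, est.stderr, est.defined, f"K[{rxn.label()}]", n_blocks)


def _net_species(path: Sequence[ReactionSpec]) -> dict[int, int]:
    net: dict[int, int] = {}
    for rxn in path:
        for m in rxn.reactants:
            net[m] = net.get(m, 0) - 1
        for m in rxn.products:
            net[m] = net.get(m, 0) + 1
    return {m: v for m, v in net.items() if v != 0}


def path_K(
    data, path: Sequence, n_blocks: int = DEFAULT_N_BLOCKS
) -> KEstimate:
    """Multimerization constant via a reaction mechanism (path).

    ``path`` is a sequence of association steps, each a :class:`ReactionSpec`
    or a bare reactant multiset; the net reaction must telescope to
    ``m A -> A_m``.  The value is the product of the elementary constants
    along the path; by path independence it equals the constant of any
    other mechanism for the same net reaction.
    """
    steps = [r if isinstance(r, ReactionSpec) else ReactionSpec(r) for r in path]
    if not steps:
        raise ValueError("path must contain at least one reaction")
    for r in steps:
        if not r.is_association:
            raise ValueError(f"path steps must be associations, got {r.label()}")
    net = _net_species(steps)
    sizes = sorted(net)
    if not (
        len(sizes) == 2
        and sizes[0] == 1
        and net[sizes[1]] == 1
        and net[1] == -sizes[1]
    ):
        raise ValueError(
            f"path does not telescope to m monomers -> one m-mer (net {net})"
        )
    fns = [_elementary_fn(r.reactants) for r in steps]

    def fn(counts, weights, V, c_std):
        out = 1.0
        for f in fns:
            out *= f(counts, weights, V, c_std)
        return out

    est = _evaluate(data, fn, n_blocks)
    label = "*".join(f"K[{r.label()}]" for r in steps)
    return KEstimate(est.value, est.stderr, est.defined, label, n_blocks)


def uncorrelated_K(data, m: int, n_blocks: int = DEFAULT_N_BLOCKS) -> KEstimate:
    """Mass-action constant from mean concentrations, ignoring correlations.

    ``K'_m = <c_m> c_std^(m-1) / <c_1>^m`` — the expression valid only in
    the thermodynamic limit.  Kept as the comparison (bias) witness; it is
    not constant across volume or system size in small systems.
    """
    m = int(m)
    _, _, _, _, n_total, _ = _unpack(data)
    if not 2 <= m <= n_total:
        raise ValueError(f"m must be in [2, n_total={n_total}], got {m}")

    def fn(counts, weights, V, c_std):
        num = float(weights @ counts[:, m - 1]) / V
        c1 = float(weights @ counts[:, 0]) / V
        if c1 <= 0:
            return float("nan")
        return num * c_std ** (m - 1) / c1**m

    est = _evaluate(data, fn, n_blocks)
    return KEstimate(est.value, est.stderr, est.defined, f"Kprime[{m}]", n_blocks)


def transfer_K_direct(
    data, rxn: ReactionSpec, n_blocks: int = DEFAULT_N_BLOCKS
) -> KEstimate:
    """Transfer-reaction constant from correlated averages on both sides.

    For a reaction with association and dissociation on both sides (equal
    particle totals and equal species counts), ``K = M[products]/M[reactants]``
    with the falling-factorial moment kernel; the standard concentration
    cancels because both sides carry the same total order.
    """
    if len(rxn.reactants) != len(rxn.products):
        raise ValueError(
            "transfer reaction needs equal species counts on both sides"
        )
    num_spec = _multiset_spec(rxn.products)
    den_spec = _multiset_spec(rxn.reactants)
    n = len(rxn.reactants)

    def fn(counts, weights, V, c_std):
        num = float(weights @ _ff_rows(counts, num_spec)) / V**n
        den = float(weights @ _ff_rows(counts, den_spec)) / V**n
        if den <= 0:
            return float("nan")
        return num / den

    est = _evaluate(data, fn, n_blocks)
    return KEstimate(
        est.value, est.stderr, est.defined, f"Ktrans[{rxn.label()}]", n_blocks
    )


def _ratio_decomposition(rxn: ReactionSpec) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Decompose a transfer reaction as a difference of monomer additions.

    ``A + A_b = A_2 + A_{b-1}`` is ``(A + A = A_2) - (A + A_{b-1} = A_b)``,
    so K equals ``K[1+1] / K[1+(b-1)]``.  Reactions outside this family are
    rejected.
    """
    if len(rxn.reactants) != 2 or len(rxn.products) != 2:
        raise ValueError("ratio form needs a two-species transfer reaction")
    a, b = rxn.reactants
    if a != 1 or b < 3:
        raise ValueError(
            f"{rxn.label()} is not of the monomer-transfer family A + A_b = A_2 + A_(b-1)"
        )
    if rxn.products != tuple(sorted((2, b - 1))):
        raise ValueError(
            f"{rxn.label()} is not of the monomer-transfer family A + A_b = A_2 + A_(b-1)"
        )
    return (1, 1), (1, b - 1)


def transfer_K_ratio(
    data, rxn: ReactionSpec, n_blocks: int = DEFAULT_N_BLOCKS
) -> KEstimate:
    """Transfer constant as a ratio of two two-body binding constants.

    Writes the transfer as the difference of two monomer-addition reactions
    and returns the ratio of their elementary constants; equals
    :func:`transfer_K_direct` exactly on oracle moments and within joint
    error on sampled series.
    """
    num_r, den_r = _ratio_decomposition(rxn)
    f_num = _elementary_fn(num_r)
    f_den = _elementary_fn(den_r)

    def fn(counts, weights, V, c_std):
        den = f_den(counts, weights, V, c_std)
        if not np.isfinite(den) or den == 0:
            return float("nan")
        return f_num(counts, weights, V, c_std) / den

    est = _evaluate(data, fn, n_blocks)
    return KEstimate(
        est.value, est.stderr, est.defined, f"KtransRatio[{rxn.label()}]", n_blocks
    )


def transfer_K_uncorrelated(
    data, rxn: ReactionSpec, n_blocks: int = DEFAULT_N_BLOCKS
) -> KEstimate:
    """Transfer constant from products of mean concentrations (no correlations)."""
    if len(rxn.reactants) != len(rxn.products):
        raise ValueError(
            "transfer reaction needs equal species counts on both sides"
        )

    def fn(counts, weights, V, c_std):
        num = 1.0
        for m in rxn.products:
            num *= float(weights @ counts[:, m - 1]) / V
        den = 1.0
        for m in rxn.reactants:
            den *= float(weights @ counts[:, m - 1]) / V
        if den <= 0:
            return float("nan")
        return num / den

    est = _evaluate(data, fn, n_blocks)
    return KEstimate(
        est.value, est.stderr, est.defined, f"KtransPrime[{rxn.label()}]", n_blocks
    )


def prob_ratio_K(data, n_blocks: int = DEFAULT_N_BLOCKS) -> KEstimate:
    """K_m from occurrence probabilities, valid when ``n_total == m``.

    With ``f_clustered`` the fraction of frames in which all particles form
    one m-mer and ``f_monomeric`` the fraction in which all are monomers,

        K_m = (f_clustered / f_monomeric) * (c_std V)^(m-1) / m!

    which is frame-by-frame identical to the concerted m-body expression:
    the m-fold falling factorial of the monomer count is nonzero (= m!)
    only on all-monomer frames, and the m-mer count only on all-clustered
    frames.
    """
    _, _, _, _, n_total, _ = _unpack(data)
    m = n_total

    def fn(counts, weights, V, c_std):
        f_clu = float(weights @ (counts[:, m - 1] >= 1))
        f_mono = float(weights @ (counts[:, 0] == m))
        if f_mono <= 0:
            return float("nan")
        return (f_clu / f_mono) * (c_std * V) ** (m - 1) / math.factorial(m)

    est = _evaluate(data, fn, n_blocks)
    if est.defined and est.value == 0.0:
        # all-clustered state never observed: the point value is an exact
        # zero but no meaningful error can be attached
        return KEstimate(0.0, float("nan"), False, f"Kprob[{m}]", n_blocks)
    return KEstimate(est.value, est.stderr, est.defined, f"Kprob[{m}]", n_blocks)


# ---------------------------------------------------------------------------
# fluctuation identities
# ---------------------------------------------------------------------------


def relative_fluctuation(
    data, zeta, eta, n_blocks: int = DEFAULT_N_BLOCKS
) -> Estimate:
    """Relative fluctuation ``l(zeta, eta) = <zeta eta>/(<zeta><eta>) - 1``.

    ``zeta``/``eta`` are count expressions: either ``{size: order}``
    falling-factorial specs or callables on the counts matrix.  Symmetric
    in its arguments; undefined when either mean vanishes.
    """

    def fn(counts, weights, V, c_std):
        zv = _expr_rows(counts, zeta)
        ev = _expr_rows(counts, eta)
        mz = float(weights @ zv)
        me = float(weights @ ev)
        if mz == 0 or me == 0:
            return float("nan")
        return float(weights @ (zv * ev)) / (mz * me) - 1.0

    return _evaluate(data, fn, n_blocks)


def _pair_expr(i: int, j: int):
    """Per-frame value of N_i (N_j - delta_ij)."""
    if i == j:
        return {i: 2}
    return {i: 1, j: 1}


def fluctuation_relation_check(data, i: int, j: int, K) -> tuple[float, float]:
    """Mean (i+j)-mer count versus its fluctuation reconstruction.

    Returns ``(<N_{i+j}>, K <N_i><N_j - delta_ij>(1 + l)/ (c_std V))`` with
    ``l = l(N_i, N_j - delta_ij)``; the two sides agree identically when K
    is the two-body constant of the i+j association evaluated on the same
    moments, and within joint sampling error on simulated series.
    """
    counts, weights, V, c_std, n_total, _ = _unpack(data)
    i, j = int(i), int(j)
    if i + j > n_total:
        raise ValueError(f"i + j = {i + j} exceeds n_total {n_total}")
    k_val = K.value if isinstance(K, Estimate) else float(K)
    lhs = float(weights @ counts[:, i + j - 1])
    zi = counts[:, i - 1]
    ej = counts[:, j - 1] - (1.0 if i == j else 0.0)
    mz, me = float(weights @ zi), float(weights @ ej)
    if mz == 0 or me == 0:
        return lhs, float("nan")
    ell = float(weights @ (zi * ej)) / (mz * me) - 1.0
    rhs = k_val * mz * me * (1.0 + ell) / (c_std * V)
    return lhs, rhs


def partition_fluctuation_equality(
    data, i: int, j: int, k: int, s: int, n_blocks: int = DEFAULT_N_BLOCKS
) -> tuple[Estimate, Estimate]:
    """The two relative fluctuations tied to one cluster-size partition.

    For ``i + j == k + s``, returns
    ``l[N_{i+j}, N_i (N_j - delta_ij)]`` and
    ``l[N_{k+s}, N_k (N_s - delta_ks)]``; the pair is equal exactly on
    oracle moments and within sampling error on simulated series.
    """
    if i + j != k + s:
        raise ValueError(f"partitions must match: {i}+{j} != {k}+{s}")
    _, _, _, _, n_total, _ = _unpack(data)
    if i + j > n_total:
        raise ValueError(f"i + j = {i + j} exceeds n_total {n_total}")
    l1 = relative_fluctuation(data, {i + j: 1}, _pair_expr(i, j), n_blocks)
    l2 = relative_fluctuation(data, {k + s: 1}, _pair_expr(k, s), n_blocks)
    return l1, l2


# ---------------------------------------------------------------------------
# free energies and cycles
# ---------------------------------------------------------------------------


def delta_G(K, T: float) -> Estimate:
    """Standard free energy change ``-R T ln K`` in kJ/mol.

    The error is propagated linearly, ``R T * stderr / value``.
    """
    k_val = K.value if isinstance(K, Estimate) else float(K)
    k_err = K.stderr if isinstance(K, Estimate) else 0.0
    if not (k_val > 0):
        raise ValueError(f"K must be positive to take a log, got {k_val}")
    rt = GAS_CONSTANT * T
    err = rt * k_err / k_val if np.isfinite(k_err) else float("nan")
    return Estimate(-rt * math.log(k_val), err)


def cycle_closure(
    data,
    cycle: Sequence[tuple[int, Sequence[int]]],
    T: float,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> Estimate:
    """Signed sum of association free energies around a closed cycle, kJ/mol.

    ``cycle`` is a sequence of ``(sign, reactant multiset)`` entries, each
    denoting ``sign * deltaG`` of the association of those reactants.  The
    signed reactions must sum to the null reaction.  On exact moments the
    closure is identically zero (free energy is a state function); on a
    sampled series its magnitude is a convergence diagnostic.
    """
    steps = [(int(sgn), ReactionSpec(r)) for sgn, r in cycle]
    if not steps:
        raise ValueError("cycle must contain at least one reaction")
    net: dict[int, int] = {}
    for sgn, rxn in steps:
        for m in rxn.reactants:
            net[m] = net.get(m, 0) - sgn
        for m in rxn.products:
            net[m] = net.get(m, 0) + sgn
    if any(v != 0 for v in net.values()):
        raise ValueError(f"cycle does not close (net species change {net})")
    rt = GAS_CONSTANT * T
    fns = [(sgn, _elementary_fn(rxn.reactants)) for sgn, rxn in steps]

    def fn(counts, weights, V, c_std):
        total = 0.0
        for sgn, f in fns:
            k = f(counts, weights, V, c_std)
            if not np.isfinite(k) or k <= 0:
                return float("nan")
            total += sgn * (-rt * math.log(k))
        return total

    return _evaluate(data, fn, n_blocks)


# ---------------------------------------------------------------------------
# error analysis
# ---------------------------------------------------------------------------


def block_error(
    series: CountsSeries,
    statistic: Callable[[CountsSeries], float],
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> float:
    """Block-averaging standard error of an arbitrary series statistic.

    The series is split into ``n_blocks`` contiguous blocks, the statistic
    is evaluated on each, and the stderr is the sample standard deviation of
    the block values divided by ``sqrt(n_blocks)``.  Contiguity preserves
    (and thereby accounts for) autocorrelation within blocks.
    """
    if not isinstance(series, CountsSeries):
        raise TypeError("block_error requires a CountsSeries")
    if n_blocks < 2:
        raise ValueError(f"n_blocks must be >= 2, got {n_blocks}")
    n = len(series)
    if n < 2 * n_blocks:
        raise ValueError(
            f"series of length {n} too short for {n_blocks} blocks "
            f"(need >= {2 * n_blocks} frames)"
        )
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    vals = []
    for a, b in zip(edges[:-1], edges[1:]):
        sub = CountsSeries(
            counts=series.counts[a:b],
            volume=series.volume,
            n_total=series.n_total,
            c_std=series.c_std,
        )
        vals.append(statistic(sub))
    vals = np.asarray(vals, dtype=np.float64)
    good = vals[np.isfinite(vals)]
    if good.size < 2:
        return float("nan")
    return float(np.std(good, ddof=1) / math.sqrt(good.size))


# ---------------------------------------------------------------------------
# mechanism inventory
# ---------------------------------------------------------------------------


def enumerate_mechanisms(m: int, max_order: int | None = None) -> list[tuple[ReactionSpec, ...]]:
    """All association mechanisms building one m-mer from m monomers.

    A mechanism is a sequence of elementary merges; each merge combines two
    or more currently present clusters (a merge of k clusters is a k-body
    elementary reaction).  ``max_order = 2`` restricts to two-body paths.
    Paths are canonicalized (merges applied to sorted cluster pools,
    duplicate expression sequences removed), so the result enumerates the
    distinct K-expressions, matching the mechanism inventories used for
    path-independence scans.
    """
    if m < 2:
        raise ValueError(f"m must be >= 2, got {m}")
    out: set[tuple[ReactionSpec, ...]] = set()

    def recurse(pool: tuple[int, ...], path: tuple[ReactionSpec, ...]):
        if len(pool) == 1:
            # K is a product over steps, so mechanisms differing only in
            # merge order share one expression: canonicalize by sorting
            out.add(tuple(sorted(path, key=lambda r: r.reactants)))
            return
        n = len(pool)
        limit = n if max_order is None else min(n, max_order)
        # choose a sub-multiset of >= 2 clusters to merge
        from itertools import combinations

        seen = set()
        for k in range(2, limit + 1):
            for idx in combinations(range(n), k):
                merged = tuple(sorted(pool[i] for i in idx))
                if merged in seen:
                    continue
                seen.add(merged)
                rest = [pool[i] for i in range(n) if i not in idx]
                new_pool = tuple(sorted(rest + [sum(merged)]))
                recurse(new_pool, path + (ReactionSpec(merged),))

    recurse(tuple([1] * m), ())
    return sorted(out, key=lambda p: (len(p), [r.reactants for r in p]))
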