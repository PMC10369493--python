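"""Exact canonical ensemble of an ideal associating system.

``N_total`` labelled particles partition themselves into clusters; apart
from the association events themselves the particles are ideal (no
inter-cluster interactions).  Each cluster of size m carries a
configuration-integral parameter ``b_m`` (units nm^{3(m-1)}, with
``b_1 = 1``), so the canonical weight of a composition ``{m: n_m}`` is

    W = N_total! / prod_m [(m!)^{n_m} * n_m!] * prod_m (V * b_m)^{n_m}

— the number of ways to partition labelled particles into that cluster-size
multiset, times one translational volume V and one internal integral b_m per
cluster.  Because the composition space is just the integer partitions of
``N_total`` (p(12) = 77), every moment of the cluster counts is computed
exactly, which makes this ensemble the certification oracle for the
equilibrium-constant estimators: every reaction-path expression evaluated on
its exact moments must equal the closed form

    K_m = c_std^{m-1} * b_m / m!

independently of V and N_total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from typing import Mapping, Sequence

import numpy as np
from sympy.utilities.iterables import partitions as _int_partitions

from .series import CompositionState, CountsSeries
from .units import DEFAULT_C_STD

__all__ = [
    "ClusterModel",
    "enumerate_compositions",
    "state_weight",
    "exact_moment",
    "closed_form_K",
    "sample_states",
]


def enumerate_compositions(n_total: int) -> list[CompositionState]:
    """All cluster compositions of ``n_total`` particles.

    These are exactly the integer partitions of ``n_total``; the returned
    list has length p(n_total) (e.g. p(4) = 5, p(12) = 77).
    """
    if n_total < 1:
        raise ValueError(f"n_total must be >= 1, got {n_total}")
    return [CompositionState(dict(p)) for p in _int_partitions(n_total)]


@dataclass
class ClusterModel:
    """Exact ensemble parameterization.

    Parameters
    ----------
    n_total : int
        Particle count (enumeration is practical up to ~40).
    volume : float
        Box volume V in nm^3.
    b : sequence of float
        Configuration integrals ``(b_1, b_2, ..., b_M)`` with ``b_1 == 1``;
        sizes beyond ``len(b)`` take ``b_m = 0`` only if ``n_total > len(b)``
        is requested, which is rejected — supply all sizes up to ``n_total``.
    c_std : float
        Standard concentration in molecules/nm^3 (default 1 M).
    """

    n_total: int
    volume: float
    b: Sequence[float]
    c_std: float = DEFAULT_C_STD

    _states: list[CompositionState] = field(init=False, repr=False)
    _probs: np.ndarray = field(init=False, repr=False)
    _matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError(f"n_total must be >= 1, got {self.n_total}")
        if self.volume <= 0:
            raise ValueError(f"volume must be positive, got {self.volume}")
        if self.c_std <= 0:
            raise ValueError(f"c_std must be positive, got {self.c_std}")
        self.b = tuple(float(x) for x in self.b)
        if len(self.b) < self.n_total:
            raise ValueError(
                f"need b_m for every size up to n_total={self.n_total}, "
                f"got {len(self.b)} values"
            )
        if abs(self.b[0] - 1.0) > 1e-15:
            raise ValueError(f"b_1 must equal 1, got {self.b[0]}")
        if any(x < 0 for x in self.b):
            raise ValueError("all b_m must be >= 0")
        self._states = enumerate_compositions(self.n_total)
        w = np.array([state_weight(s, self) for s in self._states])
        total = w.sum()
        if total <= 0:
            raise ValueError("all state weights are zero; check b values")
        self._probs = w / total
        self._matrix = np.stack(
            [s.as_vector(self.n_total) for s in self._states]
        )

    # -- accessors ---------------------------------------------------------

    @property
    def states(self) -> list[CompositionState]:
        """Enumerated compositions (integer partitions of ``n_total``)."""
        return list(self._states)

    @property
    def probabilities(self) -> np.ndarray:
        """Exact state probabilities, aligned with :attr:`states`."""
        return self._probs.copy()

    @property
    def counts_matrix(self) -> np.ndarray:
        """(n_states, n_total) matrix of counts ``n_m`` per state."""
        return self._matrix.copy()

    def probability(self, state: CompositionState) -> float:
        """Exact probability of one composition."""
        for s, p in zip(self._states, self._probs):
            if s.counts == state.counts:
                return float(p)
        raise ValueError(f"state {state} is not a composition of {self.n_total}")


def state_weight(state: CompositionState, model: ClusterModel) -> float:
    """Unnormalized canonical weight of a composition.

    ``W = N!/prod_m[(m!)^n_m n_m!] * prod_m (V b_m)^n_m``; the probability of
    the state is ``W / sum_states W``.
    """
    if state.n_particles != model.n_total:
        raise ValueError(
            f"state holds {state.n_particles} particles, model has {model.n_total}"
        )
    w = float(factorial(model.n_total))
    for m, n in state.counts.items():
        w /= float(factorial(m)) ** n * float(factorial(n))
        w *= (model.volume * model.b[m - 1]) ** n
    return w


def _falling_factorial(x: np.ndarray, k: int) -> np.ndarray:
    """Elementwise falling factorial x(x-1)...(x-k+1); k=0 gives 1."""
    out = np.ones_like(x, dtype=np.float64)
    for t in range(k):
        out *= x - t
    return out


def exact_moment(model: ClusterModel, spec: Mapping[int, int]) -> float:
    """Exact concentration-space falling-factorial moment.

    ``E[prod_m n_m^(k_m)] / V^(sum k_m)`` where ``n^(k)`` is the falling
    factorial — the count-space form of the correlated concentration
    products ``<c (c - 1/V) (c - 2/V) ...>`` with one ``-1/V`` subtraction
    per repeated factor of the same species.

    ``spec`` maps cluster size to falling-factorial order; the empty spec
    gives 1.
    """
    total_order = 0
    vals = np.ones(len(model._states))
    for m, k in spec.items():
        m, k = int(m), int(k)
        if m < 1:
            raise ValueError(f"cluster size must be >= 1, got {m}")
        if k < 0:
            raise ValueError(f"order must be >= 0, got {k}")
        if k == 0:
            continue
        total_order += k
        if m > model.n_total:
            vals *= 0.0
        else:
            vals *= _falling_factorial(
                model._matrix[:, m - 1].astype(np.float64), k
            )
    return float(model._probs @ vals) / model.volume**total_order


def closed_form_K(model: ClusterModel, m: int) -> float:
    """Analytic equilibrium constant of m-mer formation for this ensemble.

    Every reaction-path expression for K_m evaluates, on the exact moments
    of this ensemble, to ``c_std^{m-1} b_m / m!`` — independent of V and of
    ``n_total``.  Used as the reference value in path-independence checks.
    """
    if not 2 <= m <= model.n_total:
        raise ValueError(f"m must be in [2, n_total={model.n_total}], got {m}")
    return model.c_std ** (m - 1) * model.b[m - 1] / float(factorial(m))


def sample_states(
    model: ClusterModel, n_frames: int, seed: int
) -> CountsSeries:
    """Draw i.i.d. frames from the exact composition distribution.

    Reproducible for a given ``seed``; empirical state frequencies converge
    to the exact probabilities, which makes this the synthetic-data
    generator for estimator consistency tests.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(model._states), size=n_frames, p=model._probs)
    return CountsSeries(
        counts=model._matrix[idx],
        volume=model.volume,
        n_total=model.n_total,
        c_std=model.c_std,
        provenance={
            "sampler": "ideal_cluster_ensemble",
            "seed": int(seed),
            "b": list(model.b),
        },
    )
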