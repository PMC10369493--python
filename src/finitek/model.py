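"""Model/results interface for finite-system multimerization equilibria.

:class:`MultimerEquilibrium` is constructed from observed data — a
cluster-count time series (from the Monte Carlo sampler, a CSV file or any
DataFrame of counts) or the exact ideal-cluster ensemble — and ``fit()``
evaluates a set of equilibrium-constant expressions on it, returning an
:class:`EquilibriumResults` carrying the estimates, their block-averaging
standard errors, diagnostics and a ``summary()`` table.

Example
-------
>>> from finitek import SimulationSpec, metropolis_chain, MultimerEquilibrium
>>> spec = SimulationSpec(n_total=4, box_length=6.0, epsilon=16.0, seed=1)
>>> series = metropolis_chain(spec, 1_000_000, thin=10)
>>> res = MultimerEquilibrium(series).fit(["K[1+1]", "K[1+2]", "Kprime[2]"])
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from .ensemble import ClusterModel
from .expressions import default_expressions, evaluate_expression
from .series import CountsSeries, read_counts_csv
from .units import DEFAULT_C_STD

__all__ = ["MultimerEquilibrium", "EquilibriumResults"]


class MultimerEquilibrium:
    """Equilibrium-constant model over cluster-count data.

    Parameters
    ----------
    data : CountsSeries or ClusterModel
        Sampled series (estimates carry block-averaging errors) or the
        exact ideal-cluster ensemble (estimates are exact, zero error).
    """

    def __init__(self, data):
        if not isinstance(data, (CountsSeries, ClusterModel)):
            raise TypeError(
                "data must be a CountsSeries or ClusterModel, got "
                f"{type(data).__name__}"
            )
        self.data = data

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        volume: float,
        n_total: Optional[int] = None,
        c_std: float = DEFAULT_C_STD,
    ) -> "MultimerEquilibrium":
        """Build from a DataFrame with columns ``n_1, n_2, ...``.

        ``n_total`` defaults to the per-row particle total, which must be
        constant across rows.
        """
        cols = sorted(
            (c for c in df.columns if str(c).startswith("n_")),
            key=lambda c: int(str(c)[2:]),
        )
        if not cols:
            raise ValueError("DataFrame needs n_1, n_2, ... columns")
        sizes = [int(str(c)[2:]) for c in cols]
        if sizes != list(range(1, len(sizes) + 1)):
            raise ValueError(f"size columns must be contiguous n_1..n_M, got {cols}")
        counts = df[cols].to_numpy(dtype=np.int64)
        totals = counts @ np.arange(1, len(sizes) + 1)
        inferred = int(totals[0]) if len(totals) else 0
        n_total = inferred if n_total is None else int(n_total)
        series = CountsSeries(counts, volume=volume, n_total=n_total, c_std=c_std)
        return cls(series)

    @classmethod
    def from_csv(cls, path) -> "MultimerEquilibrium":
        """Build from a counts CSV in the package dialect."""
        return cls(read_counts_csv(path))

    # -- properties --------------------------------------------------------

    @property
    def n_total(self) -> int:
        return self.data.n_total

    @property
    def volume(self) -> float:
        return self.data.volume

    @property
    def is_exact(self) -> bool:
        """True when backed by the exact ensemble rather than samples."""
        return isinstance(self.data, ClusterModel)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        expressions: Optional[Sequence[str]] = None,
        n_blocks: int = est.DEFAULT_N_BLOCKS,
    ) -> "EquilibriumResults":
        """Evaluate equilibrium-constant expressions on the data.

        Parameters
        ----------
        expressions : sequence of str, optional
            Expression strings (see :mod:`finitek.expressions`); defaults
            to the standard inventory for this system size.
        n_blocks : int
            Number of contiguous blocks for standard errors (series only).
        """
        if expressions is None:
            expressions = default_expressions(self.n_total)
        estimates: list[est.KEstimate] = []
        for expr in expressions:
            try:
                k = evaluate_expression(self.data, expr, n_blocks)
            except ValueError:
                # infeasible for this system size (e.g. Kprob mismatch)
                k = est.KEstimate(
                    float("nan"), float("nan"), False, expr.replace(" ", ""), n_blocks
                )
            estimates.append(k)
        return EquilibriumResults(self, list(expressions), estimates, n_blocks)


class EquilibriumResults:
    """Fitted equilibrium constants with uncertainties and diagnostics."""

    def __init__(self, model, expressions, estimates, n_blocks):
        self.model = model
        self.expressions = list(expressions)
        self.estimates = list(estimates)
        self.n_blocks = n_blocks
        self._by_expr = dict(zip(self.expressions, self.estimates))

    @property
    def table(self) -> pd.DataFrame:
        """One row per expression: label, value, stderr, defined."""
        return pd.DataFrame(
            {
                "expression": self.expressions,
                "label": [k.label for k in self.estimates],
                "value": [k.value for k in self.estimates],
                "stderr": [k.stderr for k in self.estimates],
                "defined": [k.defined for k in self.estimates],
            }
        )

    def k(self, expression: str) -> est.KEstimate:
        """Estimate for one expression string (as passed to fit)."""
        try:
            return self._by_expr[expression]
        except KeyError:
            raise KeyError(
                f"{expression!r} was not fitted; available: {self.expressions}"
            ) from None

    def delta_G(self, expression: str, T: Optional[float] = None) -> est.Estimate:
        """Free energy -RT ln K of a fitted expression, kJ/mol."""
        return est.delta_G(self.k(expression), self._temperature(T))

    def cycle_closure(
        self, cycle: Sequence[tuple[int, Sequence[int]]], T: Optional[float] = None
    ) -> est.Estimate:
        """Signed free-energy sum around a reaction cycle, kJ/mol."""
        return est.cycle_closure(
            self.model.data, cycle, self._temperature(T), self.n_blocks
        )

    def _temperature(self, T: Optional[float]) -> float:
        if T is not None:
            return float(T)
        prov = getattr(self.model.data, "provenance", {}) or {}
        spec = prov.get("spec", {})
        if "temperature" in spec:
            return float(spec["temperature"])
        raise ValueError(
            "temperature not recorded in the data provenance; pass T explicitly"
        )

    def summary(self) -> str:
        """Human-readable results table."""
        data = self.model.data
        kind = "exact ensemble" if self.model.is_exact else "sampled series"
        lines = [
            "Multimerization equilibrium constants",
            "=" * 64,
            f"data:      {kind}",
            f"N_total:   {data.n_total}",
            f"V:         {data.volume:.6g} nm^3",
            f"c_std:     {data.c_std:.9g} molecules/nm^3",
        ]
        if not self.model.is_exact:
            lines.append(f"frames:    {len(data)}   (blocks: {self.n_blocks})")
        lines += [
            "-" * 64,
            f"{'expression':<32}{'K':>14}{'stderr':>12}",
            "-" * 64,
        ]
        for expr, k in zip(self.expressions, self.estimates):
            if not k.defined and not np.isfinite(k.value):
                lines.append(f"{expr:<32}{'undefined':>14}{'':>12}")
            else:
                err = f"{k.stderr:.3g}" if np.isfinite(k.stderr) else "n/a"
                lines.append(f"{expr:<32}{k.value:>14.6g}{err:>12}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_constants(self, ax=None, log: bool = True):
        """Bar plot of the fitted constants with error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 + 0.6 * len(self.estimates), 4))
        tab = self.table[self.table.defined]
        x = np.arange(len(tab))
        ax.bar(x, tab.value, yerr=tab.stderr, capsize=3)
        ax.set_xticks(x)
        ax.set_xticklabels(tab.expression, rotation=60, ha="right")
        ax.set_ylabel("K")
        if log:
            ax.set_yscale("log")
        return ax

    def __repr__(self) -> str:
        return (
            f"<EquilibriumResults: {len(self.estimates)} expressions, "
            f"N_total={self.model.n_total}>"
        )
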