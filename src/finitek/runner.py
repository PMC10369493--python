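"""Scripted scans over volume and system size.

Two experiment families are supported, mirroring the two simulation designs
of the model system, plus their exact-ensemble analogues:

- R1 (volume scan): fixed particle number, grid of box lengths — how each
  K expression behaves as the concentration changes.
- R2 (size scan): grid of particle numbers at fixed total concentration
  (the box length is derived per grid point) — invariance of K with system
  size.
- oracle-volume / oracle-size: the same grids evaluated on the exact
  ideal-cluster ensemble, where correlated expressions are constant to
  machine precision and the uncorrelated ones are provably not.

``run_scan`` returns a long-form table (one row per grid point per
expression) and is deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .ensemble import ClusterModel, sample_states
from .expressions import evaluate_expression
from .ljmc import SimulationSpec, metropolis_chain
from .units import DEFAULT_C_STD, derive_box_length

__all__ = ["ScanConfig", "run_scan"]

_MODES = ("r1-volume", "r2-size", "oracle-volume", "oracle-size")


@dataclass
class ScanConfig:
    """Configuration of a scan.

    Parameters
    ----------
    mode : str
        One of ``r1-volume``, ``r2-size``, ``oracle-volume``, ``oracle-size``.
    expressions : sequence of str
        Expression strings to evaluate at every grid point.
    box_lengths : sequence of float
        Grid for the volume-scan modes (nm).
    n_totals : sequence of int
        Grid for the size-scan modes.
    n_total : int
        Particle number for volume-scan modes.
    concentration : float
        Number density (molecules/nm^3) held fixed in size-scan modes; the
        box length at each grid point is ``(N/concentration)^(1/3)``.
    epsilon, sigma, temperature, r_cut, r_bond : float
        Lennard-Jones sampler parameters (MC modes).
    n_sweeps, thin : int
        Sampling length per grid point (MC modes).
    b : sequence of float
        Configuration integrals (oracle modes); ``n_frames = 0`` evaluates
        exact moments, ``n_frames > 0`` samples that many i.i.d. frames.
    seed : int
        Base seed; grid point g uses ``seed + g``.
    """

    mode: str
    expressions: Sequence[str]
    seed: int = 0
    # volume-scan grids
    n_total: Optional[int] = None
    box_lengths: Optional[Sequence[float]] = None
    # size-scan grids
    n_totals: Optional[Sequence[int]] = None
    concentration: Optional[float] = None
    # LJ sampler parameters
    epsilon: float = 10.0
    sigma: float = 0.20
    temperature: float = 300.0
    r_cut: float = 2.0
    r_bond: float = 0.35
    n_sweeps: int = 1_000_000
    thin: int = 10
    # oracle parameters
    b: Optional[Sequence[float]] = None
    n_frames: int = 0
    c_std: float = DEFAULT_C_STD
    n_blocks: int = 20

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode.endswith("volume"):
            if not self.box_lengths:
                raise ValueError(f"{self.mode} needs a non-empty box_lengths grid")
            if not self.n_total:
                raise ValueError(f"{self.mode} needs n_total")
        else:
            if not self.n_totals:
                raise ValueError(f"{self.mode} needs a non-empty n_totals grid")
            if not self.concentration or self.concentration <= 0:
                raise ValueError(f"{self.mode} needs a positive concentration")
        if self.mode.startswith("oracle") and self.b is None:
            raise ValueError("oracle modes need the b configuration integrals")

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping at top level")
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, tuple):
                v = list(v)
            out[k] = v
        return out


def _grid(config: ScanConfig):
    """Yield (index, n_total, box_length) per grid point."""
    if config.mode.endswith("volume"):
        for g, L in enumerate(config.box_lengths):
            yield g, int(config.n_total), float(L)
    else:
        for g, n in enumerate(config.n_totals):
            yield g, int(n), derive_box_length(int(n), config.concentration)


def run_scan(config: ScanConfig) -> pd.DataFrame:
    """Run a scan; one row per grid point per expression.

    Grid points where an expression is undefined (species never observed)
    or infeasible (e.g. product size exceeding the particle number) are
    reported as flagged rows, never raised.  Deterministic for a given
    config and seed.
    """
    rows = []
    for g, n_total, L in _grid(config):
        point_seed = int(config.seed) + g
        diag: dict = {}
        if config.mode.startswith("oracle"):
            b = list(config.b)
            if len(b) < n_total:
                # extend with zero association strength for unlisted sizes
                b = b + [0.0] * (n_total - len(b))
            data = ClusterModel(n_total, L**3, b[:n_total], c_std=config.c_std)
            if config.n_frames > 0:
                data = sample_states(data, config.n_frames, seed=point_seed)
        else:
            spec = SimulationSpec(
                n_total=n_total,
                box_length=L,
                epsilon=config.epsilon,
                sigma=config.sigma,
                temperature=config.temperature,
                r_cut=config.r_cut,
                r_bond=config.r_bond,
                seed=point_seed,
            )
            data = metropolis_chain(spec, config.n_sweeps, thin=config.thin)
            diag = {
                "acceptance_rate": data.provenance.get("acceptance_rate"),
                "n_equilibration_sweeps": data.provenance.get(
                    "n_equilibration_sweeps"
                ),
            }
        for expr in config.expressions:
            base = {
                "mode": config.mode,
                "grid_index": g,
                "N_total": n_total,
                "L_box": L,
                "V": L**3,
                "expression": expr,
                "seed": point_seed,
            }
            try:
                k = evaluate_expression(data, expr, config.n_blocks)
                base.update(
                    value=k.value, stderr=k.stderr, defined=bool(k.defined)
                )
            except ValueError as exc:
                base.update(
                    value=float("nan"),
                    stderr=float("nan"),
                    defined=False,
                    error=str(exc),
                )
            base.update(diag)
            rows.append(base)
    cols = [
        "mode",
        "grid_index",
        "N_total",
        "L_box",
        "V",
        "expression",
        "value",
        "stderr",
        "defined",
        "seed",
    ]
    df = pd.DataFrame(rows, columns=cols if not rows else None)
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]
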