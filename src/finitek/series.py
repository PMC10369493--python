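"""Cluster-count compositions and time series.

A *composition* records how many clusters of each size are present in one
frame of a system of ``n_total`` identical associating particles: ``n_m``
clusters of size ``m`` with the particle-conservation constraint
``sum(m * n_m) == n_total``.  A :class:`CountsSeries` is an ordered sequence
of such compositions together with the box volume and the standard
concentration — the common currency between samplers (exact-ensemble or
Monte Carlo) and the equilibrium-constant estimators.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .units import DEFAULT_C_STD

__all__ = ["CompositionState", "CountsSeries", "read_counts_csv", "write_counts_csv"]


@dataclass(frozen=True)
class CompositionState:
    """Counts of m-mers in a single frame.

    ``counts`` maps cluster size m (positive int) to the number of clusters
    of that size; sizes with zero count may be omitted.
    """

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        cleaned = {}
        for m, n in self.counts.items():
            m = int(m)
            n = int(n)
            if m < 1:
                raise ValueError(f"cluster size must be >= 1, got {m}")
            if n < 0:
                raise ValueError(f"count for size {m} must be >= 0, got {n}")
            if n > 0:
                cleaned[m] = n
        object.__setattr__(self, "counts", dict(sorted(cleaned.items())))

    @property
    def n_particles(self) -> int:
        """Total number of particles in the frame, ``sum(m * n_m)``."""
        return sum(m * n for m, n in self.counts.items())

    def count(self, m: int) -> int:
        """Number of m-mers (0 if the size is absent)."""
        return self.counts.get(m, 0)

    def as_vector(self, max_size: int) -> np.ndarray:
        """Counts as a dense vector ``[n_1, ..., n_max_size]``."""
        v = np.zeros(max_size, dtype=np.int64)
        for m, n in self.counts.items():
            if m > max_size:
                raise ValueError(f"size {m} exceeds max_size {max_size}")
            v[m - 1] = n
        return v

    @classmethod
    def from_sizes(cls, sizes) -> "CompositionState":
        """Build from a list of cluster sizes, e.g. ``[1, 1, 2]``."""
        counts: dict[int, int] = {}
        for m in sizes:
            counts[m] = counts.get(m, 0) + 1
        return cls(counts)

    def __iter__(self):
        return iter(self.counts.items())

    def __str__(self) -> str:
        return "+".join(
            "+".join([str(m)] * n) for m, n in sorted(self.counts.items())
        )


@dataclass
class CountsSeries:
    """Time series of cluster-count compositions with system metadata.

    Parameters
    ----------
    counts : ndarray of shape (n_frames, n_total)
        ``counts[t, m-1]`` is the number of m-mers in frame ``t``.
    volume : float
        Box volume in nm^3.
    n_total : int
        Total particle number; every frame must satisfy
        ``sum(m * counts[t, m-1]) == n_total``.
    c_std : float
        Standard concentration c⌀ in molecules/nm^3 (default 1 M).
    provenance : dict
        Free-form metadata (sampler, seed, spec, ...).
    """

    counts: np.ndarray
    volume: float
    n_total: int
    c_std: float = DEFAULT_C_STD
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array (frames x sizes)")
        if self.counts.shape[0] < 1:
            raise ValueError("series must contain at least one frame")
        if self.volume <= 0:
            raise ValueError(f"volume must be positive, got {self.volume}")
        if self.c_std <= 0:
            raise ValueError(f"c_std must be positive, got {self.c_std}")
        if self.counts.shape[1] != self.n_total:
            # pad or reject: fixed width n_1..n_N keeps the CSV dialect stable
            if self.counts.shape[1] < self.n_total:
                pad = np.zeros(
                    (self.counts.shape[0], self.n_total - self.counts.shape[1]),
                    dtype=np.int64,
                )
                self.counts = np.hstack([self.counts, pad])
            else:
                raise ValueError(
                    f"counts has {self.counts.shape[1]} size columns but "
                    f"n_total is {self.n_total}"
                )
        sizes = np.arange(1, self.n_total + 1)
        totals = self.counts @ sizes
        bad = np.nonzero(totals != self.n_total)[0]
        if bad.size:
            raise ValueError(
                f"frame {bad[0]} violates particle conservation: "
                f"sum(m*n_m) = {totals[bad[0]]} != {self.n_total}"
            )

    def __len__(self) -> int:
        return self.counts.shape[0]

    def frames(self) -> Iterator[CompositionState]:
        for row in self.counts:
            yield CompositionState(
                {m + 1: int(n) for m, n in enumerate(row) if n > 0}
            )

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"n_{m}" for m in range(1, self.n_total + 1)]
        df = pd.DataFrame(self.counts, columns=cols)
        df.insert(0, "frame", np.arange(len(self)))
        return df


# ---------------------------------------------------------------------------
# CSV dialect:
#   # finitek-counts v1
#   # meta: {"N_total": 4, "V": 216.0, "c_std": 0.602214076, ...}
#   frame,n_1,n_2,n_3,n_4
#   0,4,0,0,0
# ---------------------------------------------------------------------------

_MAGIC = "# finitek-counts v1"


def write_counts_csv(series: CountsSeries, path) -> None:
    """Write a :class:`CountsSeries` to the package CSV dialect."""
    meta = {
        "N_total": int(series.n_total),
        "V": float(series.volume),
        "c_std": float(series.c_std),
        "provenance": series.provenance,
    }
    buf = io.StringIO()
    buf.write(_MAGIC + "\n")
    buf.write("# meta: " + json.dumps(meta) + "\n")
    series.to_dataframe().to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


class CountsFormatError(ValueError):
    """Malformed counts CSV (bad header, bad row, conservation violation)."""


def read_counts_csv(path) -> CountsSeries:
    """Read a counts CSV written by :func:`write_counts_csv`.

    Raises
    ------
    CountsFormatError
        If the header is missing/invalid or any row fails particle
        conservation; the error message names the offending line.
    """
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    if not lines:
        raise CountsFormatError(f"{path}: empty file")
    if lines[0].strip() != _MAGIC:
        raise CountsFormatError(f"{path}: line 1: missing '{_MAGIC}' header")
    if len(lines) < 2 or not lines[1].startswith("# meta:"):
        raise CountsFormatError(f"{path}: line 2: missing '# meta:' header")
    try:
        meta = json.loads(lines[1][len("# meta:"):])
        n_total = int(meta["N_total"])
        volume = float(meta["V"])
        c_std = float(meta["c_std"])
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise CountsFormatError(f"{path}: line 2: bad metadata ({exc})") from exc
    body = "\n".join(lines[2:])
    if not body.strip():
        raise CountsFormatError(f"{path}: no data rows")
    df = pd.read_csv(io.StringIO(body))
    expected = ["frame"] + [f"n_{m}" for m in range(1, n_total + 1)]
    if list(df.columns) != expected:
        raise CountsFormatError(
            f"{path}: line 3: expected columns {expected}, got {list(df.columns)}"
        )
    counts = df[expected[1:]].to_numpy(dtype=np.int64)
    sizes = np.arange(1, n_total + 1)
    totals = counts @ sizes
    bad = np.nonzero(totals != n_total)[0]
    if bad.size:
        # +4: magic, meta, header lines then 1-based data rows
        raise CountsFormatError(
            f"{path}: line {int(bad[0]) + 4}: row {int(bad[0])} violates "
            f"particle conservation (sum m*n_m = {int(totals[bad[0]])}, "
            f"expected {n_total})"
        )
    return CountsSeries(
        counts=counts,
        volume=volume,
        n_total=n_total,
        c_std=c_std,
        provenance=meta.get("provenance", {}),
    )
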