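"""Binary spike rasters: time bins x neurons, entries in {0, 1}.

A :class:`SpikeRaster` is the in-memory form of a binned population
recording: row ``t`` is the population pattern in time bin ``t`` (default
bin width 20 ms), column ``j`` is neuron ``j``. Both empirical recordings
and sampler output use this container.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ShapeError

__all__ = ["SpikeRaster", "split_train_test"]


@dataclass
class SpikeRaster:
    """Binary population activity matrix with bin-width metadata.

    Parameters
    ----------
    data : array-like of {0, 1}, shape (n_samples, n_neurons)
        Rows are time bins, columns are neurons.
    bin_width_ms : float, default 20.0
        Duration of one time bin in milliseconds. Metadata only; no
        operation in the package depends on it.
    """

    data: np.ndarray
    bin_width_ms: float = field(default=20.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ShapeError(f"raster must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ShapeError("raster needs at least one time bin and one neuron")
        if not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise ParameterError(
                f"raster entries must be 0/1; found {arr[tuple(bad)]!r} at "
                f"(row {bad[0]}, column {bad[1]})"
            )
        self.data = np.ascontiguousarray(arr, dtype=np.uint8)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.data.shape[1]

    def neuron_marginals(self) -> np.ndarray:
        """Per-neuron firing probability per bin, shape (n_neurons,)."""
        return self.data.mean(axis=0)

    def unique_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct population patterns and their counts."""
        pats, counts = np.unique(self.data, axis=0, return_counts=True)
        return pats, counts

    def __getitem__(self, rows) -> "SpikeRaster":
        return SpikeRaster(np.atleast_2d(self.data[rows]), self.bin_width_ms)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SpikeRaster(n_samples={self.n_samples}, n_neurons={self.n_neurons}, "
            f"bin_width_ms={self.bin_width_ms})"
        )


def split_train_test(
    X: SpikeRaster, fraction_test: float = 0.2, seed: int | None = None
) -> tuple[SpikeRaster, SpikeRaster]:
    """Random disjoint row partition into training and held-out test sets.

    The default ``fraction_test=0.2`` mirrors the conventional 4:1
    train:test proportion (e.g. 160k/40k samples). The partition is a
    permutation split, so every row lands in exactly one of the two sets.
    """
    if not 0.0 < fraction_test < 1.0:
        raise ParameterError(f"fraction_test must be in (0, 1), got {fraction_test}")
    rng = np.random.default_rng(seed)
    T = X.n_samples
    n_test = int(round(T * fraction_test))
    if n_test == 0 or n_test == T:
        raise ParameterError(
            f"fraction_test={fraction_test} leaves an empty split for {T} rows"
        )
    perm = rng.permutation(T)
    test_rows = np.sort(perm[:n_test])
    train_rows = np.sort(perm[n_test:])
    return (
        SpikeRaster(X.data[train_rows], X.bin_width_ms),
        SpikeRaster(X.data[test_rows], X.bin_width_ms),
    )
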