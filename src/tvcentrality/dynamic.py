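"""Sliding-window time-varying centralities (tEC, tPC).

Each window's samples are correlated, proportionally thresholded, and
the resulting per-window network is scored with eigenvector centrality
(tEC) or with per-window Louvain communities plus participation
coefficient (tPC).  The default window is 50 s, stepped one sample at a
time, so the first and last 25 s of the run carry no window centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .centrality import (
    eigenvector_centrality,
    louvain_partition,
    participation_coefficient,
)
from .connectome import (
    ParcelTimeSeries,
    ValidationError,
    _degenerate_rows,
    correlation_matrix,
    proportional_threshold,
)

__all__ = [
    "WindowSpec",
    "TimeVaryingCentrality",
    "enumerate_windows",
    "time_varying_centrality",
]

logger = logging.getLogger(__name__)

#: Louvain restarts per window; fewer than the static default because a
#: windowed run solves hundreds of community problems per participant.
WINDOW_LOUVAIN_RESTARTS = 10


@dataclass
class WindowSpec:
    """Sliding-window geometry.

    ``length_seconds`` is the full window span (default 50 s, i.e. 25 s
    each side of the centre); ``step`` is in samples.  Windows are
    half-open sample ranges [t - L/2, t - L/2 + L).
    """

    tr_seconds: float
    length_seconds: float = 50.0
    step: int = 1

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if self.step < 1:
            raise ValidationError("step must be >= 1 sample")
        if self.length_samples < 3:
            raise ValidationError(
                "window must span at least 3 samples "
                f"(got {self.length_samples})")

    @property
    def length_samples(self) -> int:
        return int(round(self.length_seconds / self.tr_seconds))


@dataclass
class TimeVaryingCentrality:
    """Parcels x windows centrality matrix with window-centre indices."""

    values: np.ndarray  # (n_parcels, n_windows); NaN for flagged windows
    centers: np.ndarray  # sample index of each window centre
    kind: str
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.centers = np.asarray(self.centers, dtype=int)
        if self.values.shape[1] != self.centers.shape[0]:
            raise ValidationError("one centre per window required")

    @property
    def center_times(self) -> np.ndarray:
        """Window-centre timestamps in seconds."""
        return self.centers * self.tr_seconds


def enumerate_windows(
    T: int, spec: WindowSpec
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Half-open sample windows and their centre indices.

    Returns every window [s, s + L) with s stepped by ``spec.step``
    from 0 while it fits in T samples; the centre of window [s, s+L) is
    s + L//2, so the first and last half-window of the run are excluded
    by construction.
    """
    L = spec.length_samples
    if T < L:
        raise ValidationError(
            f"run of {T} samples shorter than one {L}-sample window")
    starts = np.arange(0, T - L + 1, spec.step)
    windows = [(int(s), int(s + L)) for s in starts]
    centers = starts + L // 2
    return windows, centers


def _window_seed(seed: int, window_index: int) -> int:
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, window_index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def time_varying_centrality(
    ts: ParcelTimeSeries,
    spec: WindowSpec,
    density: float,
    kind: str,
    seed: int = 0,
    gamma: float = 1.0,
    restarts: int = WINDOW_LOUVAIN_RESTARTS,
) -> TimeVaryingCentrality:
    """Per-window centrality time course (tEC or tPC).

    For every window: Pearson correlation on the windowed samples,
    proportional threshold at ``density``, then EC, or Louvain (with a
    per-window seed derived from ``(seed, window index)``) followed by
    PC.  A window containing a zero-variance parcel is flagged: its
    column is NaN and a warning is logged.
    """
    if kind not in ("ec", "pc"):
        raise ValidationError("kind must be 'ec' or 'pc'")
    windows, centers = enumerate_windows(ts.n_timepoints, spec)
    n = ts.n_parcels
    out = np.full((n, len(windows)), np.nan)
    for wi, (s, e) in enumerate(windows):
        sub = ts.values[:, s:e]
        if _degenerate_rows(sub).size:
            logger.warning(
                "window %d [%d, %d) has a zero-variance parcel; "
                "column filled with NaN", wi, s, e)
            continue
        sub_ts = ParcelTimeSeries(
            values=sub, parcel_ids=ts.parcel_ids, tr_seconds=ts.tr_seconds)
        A = proportional_threshold(correlation_matrix(sub_ts), density)
        if kind == "ec":
            out[:, wi] = eigenvector_centrality(A).values
        else:
            P = louvain_partition(
                A, gamma=gamma, seed=_window_seed(seed, wi),
                n_restarts=restarts)
            out[:, wi] = participation_coefficient(A, P).values
    return TimeVaryingCentrality(
        values=out, centers=centers, kind=kind, tr_seconds=ts.tr_seconds)
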