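"""Static functional-connectome construction.

Parcel-averaged fMRI time series are z-scored per run, concatenated,
correlated (Pearson), and proportionally thresholded into a binary
undirected network whose edge density is either fixed (7.5% by default)
or selected by maximising the mean flow coefficient over a candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParcelTimeSeries",
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "standardize_and_concatenate",
    "correlation_matrix",
    "proportional_threshold",
    "select_density_by_flow",
    "DEFAULT_DENSITY",
    "DEFAULT_DENSITY_CANDIDATES",
]

#: Edge density retained by the proportional threshold (fraction of all
#: unordered parcel pairs).
DEFAULT_DENSITY = 0.075

#: Candidate densities scanned when selecting the threshold by flow
#: coefficient.
DEFAULT_DENSITY_CANDIDATES = (0.025, 0.05, 0.075, 0.10, 0.125, 0.15)


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


@dataclass
class ParcelTimeSeries:
    """Parcel-by-time signal matrix with its sampling interval.

    Parameters
    ----------
    values : ndarray, shape (n_parcels, n_timepoints)
        One row per parcel, one column per sample (TR).
    parcel_ids : list of str
        Unique node labels, one per row.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    run_boundaries : list of int
        Sample indices at which concatenated runs join (empty for a
        single run).  A boundary ``b`` means run k ends at sample b-1
        and run k+1 starts at sample b.
    """

    values: np.ndarray
    parcel_ids: list[str]
    tr_seconds: float
    run_boundaries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D parcels x time matrix")
        n, t = self.values.shape
        if t < 2:
            raise ValidationError("need at least 2 timepoints")
        if len(self.parcel_ids) != n:
            raise ValidationError(
                f"{len(self.parcel_ids)} parcel_ids for {n} rows"
            )
        if len(set(self.parcel_ids)) != n:
            raise ValidationError("duplicate parcel_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain non-finite entries")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        bounds = list(self.run_boundaries)
        if bounds != sorted(bounds) or any(b < 0 or b > t for b in bounds):
            raise ValidationError("run_boundaries must be sorted and in [0, T]")
        self.run_boundaries = bounds

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over parcels."""

    values: np.ndarray
    parcel_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValidationError("correlation matrix must be square")
        if len(self.parcel_ids) != n:
            raise ValidationError("parcel_ids length mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValidationError("correlation matrix must have unit diagonal")
        if np.nanmax(np.abs(self.values)) > 1 + 1e-10:
            raise ValidationError("correlation entries must lie in [-1, 1]")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class AdjacencyMatrix:
    """Binary undirected network at a stated edge density.

    ``density`` is the fraction of the N(N-1)/2 unordered parcel pairs
    retained as edges; the realised edge count is exactly
    ``round_half_up(density * N(N-1)/2)``.
    """

    values: np.ndarray
    density: float
    parcel_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValidationError("adjacency matrix must be square")
        if not np.array_equal(self.values, self.values.T):
            raise ValidationError("adjacency matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("adjacency matrix must have zero diagonal")
        vals = np.unique(self.values)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("adjacency matrix must be binary")
        self.values = self.values.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.values.sum()) // 2


def _degenerate_rows(x: np.ndarray) -> np.ndarray:
    """Rows whose variance is zero up to floating-point cancellation."""
    sd = x.std(axis=1, ddof=1)
    scale = np.maximum(1.0, np.abs(x).max(axis=1))
    return np.flatnonzero(sd <= 1e-12 * scale)


def _zscore_rows(x: np.ndarray, label: str, parcel_ids: list[str]) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    zero = _degenerate_rows(x)
    if zero.size:
        bad = ", ".join(parcel_ids[i] for i in zero[:5])
        raise ValidationError(
            f"zero-variance parcel(s) [{bad}] in {label}; cannot z-score"
        )
    return (x - mu) / sd


def standardize_and_concatenate(
    runs: list[ParcelTimeSeries],
) -> ParcelTimeSeries:
    """Z-score each run's each parcel, then concatenate runs along time.

    Every parcel series is normalised to mean 0 and (sample) standard
    deviation 1 within each run before concatenation, so that no single
    run dominates the correlation structure.  Run boundaries are
    recorded on the output.
    """
    if not runs:
        raise ValidationError("need at least one run")
    ids = runs[0].parcel_ids
    tr = runs[0].tr_seconds
    for k, r in enumerate(runs):
        if r.parcel_ids != ids:
            raise ValidationError(f"run {k} has a different parcel set")
        if r.tr_seconds != tr:
            raise ValidationError(f"run {k} has a different tr_seconds")
    blocks = [
        _zscore_rows(r.values, f"run {k}", ids) for k, r in enumerate(runs)
    ]
    boundaries = list(np.cumsum([b.shape[1] for b in blocks[:-1]]).astype(int))
    return ParcelTimeSeries(
        values=np.concatenate(blocks, axis=1),
        parcel_ids=list(ids),
        tr_seconds=tr,
        run_boundaries=boundaries,
    )


def correlation_matrix(ts: ParcelTimeSeries) -> CorrelationMatrix:
    """Pearson product-moment correlation for every parcel pair."""
    if ts.n_timepoints < 3:
        raise ValidationError("need at least 3 timepoints for correlation")
    zero = _degenerate_rows(ts.values)
    if zero.size:
        bad = ", ".join(ts.parcel_ids[i] for i in zero[:5])
        raise ValidationError(f"zero-variance parcel(s) [{bad}]")
    c = np.corrcoef(ts.values)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(values=c, parcel_ids=list(ts.parcel_ids))


def _edge_count(density: float, n: int) -> int:
    # round-half-up of density * N(N-1)/2
    return int(np.floor(density * n * (n - 1) / 2.0 + 0.5))


def proportional_threshold(
    C: CorrelationMatrix, density: float
) -> AdjacencyMatrix:
    """Binarise a correlation matrix at a proportional edge density.

    Keeps the ``round_half_up(density * N(N-1)/2)`` largest *signed*
    off-diagonal correlations (upper triangle; ties at the cutoff broken
    by ascending (row, column) index) and symmetrises.  Density is
    defined over unordered pairs.
    """
    if not (0 < density <= 1):
        raise ValidationError("density must lie in (0, 1]")
    n = C.n_parcels
    if n < 2:
        raise ValidationError("need at least 2 nodes")
    k = _edge_count(density, n)
    iu, ju = np.triu_indices(n, k=1)
    vals = C.values[iu, ju]
    # sort by descending value; ties by ascending (row, col)
    order = np.lexsort((ju, iu, -vals))
    keep = order[:k]
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[keep], ju[keep]] = 1
    a |= a.T
    return AdjacencyMatrix(values=a, density=density, parcel_ids=C.parcel_ids)


def select_density_by_flow(
    C: CorrelationMatrix,
    candidates: list[float] | tuple[float, ...] = DEFAULT_DENSITY_CANDIDATES,
) -> tuple[float, dict[float, float]]:
    """Pick the candidate density maximising the mean flow coefficient.

    Thresholds ``C`` at each candidate density, computes the mean flow
    coefficient across nodes, and returns the argmax candidate together
    with the full density -> mean-flow profile.  Ties go to the first
    (smallest) candidate.
    """
    from .centrality import flow_coefficient

    cands = list(candidates)
    if not cands:
        raise ValidationError("candidate list must be non-empty")
    for c in cands:
        if not (0 < c <= 1):
            raise ValidationError(f"candidate density {c} outside (0, 1]")
    profile: dict[float, float] = {}
    for c in cands:
        A = proportional_threshold(C, c)
        profile[c] = float(flow_coefficient(A).values.mean())
    best = cands[int(np.argmax([profile[c] for c in cands]))]
    return best, profile
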