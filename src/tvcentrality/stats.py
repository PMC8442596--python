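"""Group statistics linking centralities to the saliency signal.

Per-parcel Pearson correlations are Fisher-z transformed and taken to
one-sample or paired t tests across participants, Bonferroni-corrected
over the number of parcels; results are reported on a signed
standard-normal (Z) scale with a family-wise-error-derived cutoff
(Z > 4.3 at FWE 0.01 over 360 parcels).  Spatial map correlations, the
Fisher comparison of two map correlations, group-average r maps and
motion-confound correlations live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .connectome import ValidationError
from .dynamic import TimeVaryingCentrality
from .saliency import SaliencySignal

__all__ = [
    "GroupResult",
    "fisher_z",
    "fisher_z_inverse",
    "parcel_signal_correlation",
    "group_test",
    "group_average_r_map",
    "spatial_map_correlation",
    "compare_map_correlations",
    "covariate_correlation",
    "z_threshold",
    "DEFAULT_FWE_LEVEL",
]

DEFAULT_FWE_LEVEL = 0.01


def fisher_z(r):
    """Variance-stabilising Fisher z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValidationError("|r| must be < 1 for the Fisher transform")
    return np.arctanh(r)


def fisher_z_inverse(z):
    """Inverse Fisher transform, r = tanh(z)."""
    return np.tanh(np.asarray(z, dtype=float))


def z_threshold(fwe_level: float = DEFAULT_FWE_LEVEL,
                n_tests: int = 360) -> float:
    """Signed-Z cutoff equivalent to two-tailed Bonferroni at fwe_level."""
    return float(scipy.stats.norm.isf(fwe_level / n_tests / 2.0))


@dataclass
class GroupResult:
    """Per-parcel group statistics for one contrast."""

    contrast: str
    n_participants: int
    n_tests: int
    fwe_level: float
    table: pd.DataFrame  # columns: r?, z?, t, df, p, p_corrected, Z, significant

    @property
    def threshold_z(self) -> float:
        return z_threshold(self.fwe_level, self.n_tests)


def _align(values, signal, lag_s: float):
    """Common (n_parcels, T) matrix and signal vector after alignment."""
    if isinstance(signal, SaliencySignal):
        sig = signal.values
        tr = signal.tr_seconds
    else:
        sig = np.asarray(signal, dtype=float).ravel()
        tr = None
    if isinstance(values, TimeVaryingCentrality):
        mat = values.values
        tr = tr if tr is not None else values.tr_seconds
        # trim the signal to the window centres
        centers = values.centers
        if centers[-1] >= sig.size:
            raise ValidationError(
                f"signal of {sig.size} samples does not cover window "
                f"centres up to {centers[-1]}")
        sig = sig[centers]
    else:
        mat = np.asarray(values, dtype=float)
        if mat.ndim == 1:
            mat = mat[None, :]
    k = int(round(lag_s / tr)) if (lag_s and tr) else 0
    if k > 0:       # centrality at t compared with signal at t - k
        mat, sig = mat[:, k:], sig[:-k]
    elif k < 0:
        mat, sig = mat[:, :k], sig[-k:]
    if mat.shape[1] != sig.size:
        raise ValidationError(
            f"length mismatch after alignment: series {mat.shape[1]} "
            f"vs signal {sig.size}")
    if sig.size < 10:
        raise ValidationError("need at least 10 aligned samples")
    return mat, sig


def parcel_signal_correlation(
    values,
    signal,
    lag_s: float = 0.0,
) -> np.ndarray:
    """Pearson r between each parcel's series and the saliency signal.

    ``values`` may be a raw (n_parcels, T) matrix or a
    :class:`TimeVaryingCentrality`, in which case the signal is first
    trimmed to the window centres.  ``lag_s`` shifts the signal by
    round(lag_s / TR) samples (positive lag: centrality lags signal).
    Windows flagged NaN are excluded pairwise.
    """
    mat, sig = _align(values, signal, lag_s)
    out = np.empty(mat.shape[0])
    for i, row in enumerate(mat):
        ok = np.isfinite(row)
        x, y = row[ok], sig[ok]
        if x.size < 10 or x.std() == 0 or y.std() == 0:
            out[i] = np.nan
            continue
        out[i] = np.corrcoef(x, y)[0, 1]
    return out


def group_test(
    values,
    mode: str = "one_sample",
    values_b=None,
    n_tests: int | None = None,
    fwe_level: float = DEFAULT_FWE_LEVEL,
    contrast: str = "",
    is_correlation: bool = True,
) -> GroupResult:
    """Across-participant t test per parcel, Bonferroni FWE corrected.

    ``values`` is (n_participants, n_parcels); correlations
    (``is_correlation``) are Fisher-z transformed before testing.  Mode
    ``"one_sample"`` tests the mean against 0; ``"paired"`` tests the
    participant-wise difference ``values - values_b``.  Each parcel's
    two-tailed p is multiplied by ``n_tests`` (capped at 1) and
    converted to a signed standard-normal Z; the significance flag is
    Z > z_threshold(fwe_level, n_tests).  A parcel with zero variance
    across participants is flagged NaN rather than failing the run.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n_part, n_parcels = x.shape
    if n_part < 3:
        raise ValidationError("need at least 3 participants")
    if mode not in ("one_sample", "paired"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "paired":
        if values_b is None:
            raise ValidationError("paired mode requires values_b")
        y = np.asarray(values_b, dtype=float)
        if y.shape != x.shape:
            raise ValidationError(
                f"paired sets misaligned: {x.shape} vs {y.shape}")
    if is_correlation:
        x = fisher_z(x)
        if mode == "paired":
            y = fisher_z(y)
    d = x - y if mode == "paired" else x
    n_tests = n_parcels if n_tests is None else n_tests
    df = n_part - 1
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.full(n_parcels, np.nan)
    p = np.full(n_parcels, np.nan)
    ok = sd > 0
    with np.errstate(invalid="ignore"):
        t[ok] = mean[ok] / (sd[ok] / np.sqrt(n_part))
    p[ok] = 2.0 * scipy.stats.t.sf(np.abs(t[ok]), df)
    p_corr = np.minimum(1.0, p * n_tests)
    # signed standard-normal equivalent of the two-tailed p
    Z = np.sign(t) * scipy.stats.norm.isf(np.clip(p / 2.0, 1e-300, 1.0))
    thr = z_threshold(fwe_level, n_tests)
    sig = np.where(np.isnan(Z), False, Z > thr)
    table = pd.DataFrame({
        "mean": mean, "t": t, "df": df, "p": p,
        "p_corrected": p_corr, "Z": Z, "significant": sig,
    })
    if is_correlation and mode == "one_sample":
        table.insert(0, "z", mean)
        table.insert(0, "r", fisher_z_inverse(mean))
    return GroupResult(contrast=contrast or mode, n_participants=n_part,
                       n_tests=n_tests, fwe_level=fwe_level, table=table)


def group_average_r_map(r_per_participant) -> np.ndarray:
    """Group-average correlation map, tanh(mean(atanh(r))) per parcel."""
    r = np.asarray(r_per_participant, dtype=float)
    if r.ndim == 1:
        r = r[None, :]
    return fisher_z_inverse(fisher_z(r).mean(axis=0))


def spatial_map_correlation(map_a, map_b) -> float:
    """Pearson correlation of two per-parcel maps across parcels."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValidationError(f"map sizes differ: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValidationError("need at least 3 parcels")
    return float(np.corrcoef(a, b)[0, 1])


def compare_map_correlations(r1: float, r2: float, n: int):
    """Fisher independent-samples comparison of two map correlations.

    Z = (atanh r1 - atanh r2) / sqrt(2 / (n - 3)), two-tailed p.
    """
    if n <= 3:
        raise ValidationError("need n > 3 parcels")
    if max(abs(r1), abs(r2)) >= 1:
        raise ValidationError("|r| must be < 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(2.0 / (n - 3))
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(z), float(p)


def covariate_correlation(centrality, covariate) -> np.ndarray:
    """Per-parcel correlation with a participant-level covariate.

    ``centrality`` is (n_participants, n_parcels) — e.g. static EC per
    participant — and ``covariate`` a per-participant scalar such as
    mean head motion; returns Pearson r across participants per parcel.
    """
    c = np.asarray(centrality, dtype=float)
    v = np.asarray(covariate, dtype=float).ravel()
    if c.shape[0] != v.size:
        raise ValidationError(
            f"{c.shape[0]} participants vs covariate of {v.size}")
    if v.size < 4:
        raise ValidationError("need at least 4 participants")
    if v.std() == 0:
        raise ValidationError("covariate is constant")
    vz = (v - v.mean()) / v.std()
    cz = c - c.mean(axis=0)
    sd = c.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (cz * vz[:, None]).mean(axis=0) / sd
    r[sd == 0] = np.nan
    return r
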