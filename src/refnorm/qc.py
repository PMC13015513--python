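"""Reference-site quality control.

Paired per-site signals from the control and target samples are mapped to
M-A space (M = log2 ratio, A = mean log2 signal); reference sites that are
multivariate outliers there — sites whose signal did NOT stay stable
between samples — are removed by squared Mahalanobis distance against a
chi-square(2 df) quantile, so they cannot distort the normalization fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError, EstimationError
from .tracks import SignalMatrix, aggregate_profile

__all__ = ["MAPoints", "QCReport", "ma_transform", "mahalanobis_filter", "compute_qc"]

logger = logging.getLogger(__name__)


@dataclass
class MAPoints:
    """Vectorized M-A coordinates for a set of reference sites.

    M_i = log2(y_i + c) - log2(x_i + c); A_i = mean of the two log2 terms,
    with x the control per-site means, y the target per-site means, and c
    the pseudocount (keeps both finite at zero-coverage sites).
    """

    M: np.ndarray
    A: np.ndarray
    pseudocount: float

    def as_array(self) -> np.ndarray:
        """(n, 2) array with columns (M, A)."""
        return np.column_stack([self.M, self.A])

    def __len__(self) -> int:
        return len(self.M)


@dataclass
class QCReport:
    """Summary metrics for a control/target reference-site comparison."""

    n_references_input: int
    n_outliers_removed: int
    background_scaling: float  # control bg mean / target bg mean
    snr_control: float
    snr_target: float
    # mean/sd of log2(per-site signal means + c) and log2(bg + c) per sample
    summary: dict[str, float] = field(default_factory=dict)

    def to_rows(self) -> list[tuple[str, float]]:
        rows = [
            ("n_references_input", self.n_references_input),
            ("n_outliers_removed", self.n_outliers_removed),
            ("background_scaling", self.background_scaling),
            ("snr_control", self.snr_control),
            ("snr_target", self.snr_target),
        ]
        rows.extend(sorted(self.summary.items()))
        return rows


def ma_transform(x: np.ndarray, y: np.ndarray, pseudocount: float = 1.0) -> MAPoints:
    """Map paired non-negative per-site means to (M, A) log2 coordinates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError(f"x and y must have equal length, got {x.shape} vs {y.shape}")
    if pseudocount <= 0:
        raise DataError("pseudocount must be > 0")
    if np.any(x < 0) or np.any(y < 0):
        raise DataError("per-site means must be >= 0")
    lx = np.log2(x + pseudocount)
    ly = np.log2(y + pseudocount)
    return MAPoints(M=ly - lx, A=0.5 * (lx + ly), pseudocount=pseudocount)


def _robust_axis_z(v: np.ndarray) -> np.ndarray:
    """Robust per-axis z-scores (median/MAD); a zero-spread axis flags only
    points that differ from the common value."""
    med = np.median(v)
    scale = 1.4826 * np.median(np.abs(v - med))
    if scale < 1e-12:
        z = np.where(np.isclose(v, med, rtol=0.0, atol=1e-12), 0.0, np.inf)
    else:
        z = (v - med) / scale
    return z


def mahalanobis_filter(points: MAPoints, chi2_quantile: float = 0.99
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flag outlier reference sites in M-A space.

    Squared Mahalanobis distances use the single-pass sample mean and
    covariance of all points; a point is removed when its distance exceeds
    the chi-square(2 df) quantile. A singular covariance (e.g. perfectly
    collinear or constant coordinates) falls back to independent robust
    per-axis z-scores at the matching chi-square(1 df) cutoff; the fallback
    is logged.

    Returns ``(kept_indices, removed_indices, squared_distances)``.
    """
    pts = points.as_array()
    n = len(pts)
    if n < 3:
        raise DataError(f"Mahalanobis filtering needs >= 3 points, got {n}")
    if not 0.0 < chi2_quantile < 1.0:
        raise DataError("chi2_quantile must be in (0, 1)")
    mu = pts.mean(axis=0)
    cov = np.cov(pts.T, ddof=1)
    centered = pts - mu
    use_fallback = False
    try:
        cov_inv = np.linalg.inv(cov)
        if not np.all(np.isfinite(cov_inv)) or np.linalg.cond(cov) > 1e12:
            use_fallback = True
    except np.linalg.LinAlgError:
        use_fallback = True
    if not use_fallback:
        d2 = np.einsum("ij,jk,ik->i", centered, cov_inv, centered)
        cutoff = stats.chi2.ppf(chi2_quantile, df=2)
        removed_mask = d2 > cutoff
    else:
        logger.warning(
            "singular/ill-conditioned (M, A) covariance; falling back to "
            "per-axis robust z-score filtering at the chi2(1 df) %.3g quantile",
            chi2_quantile,
        )
        z_m = _robust_axis_z(pts[:, 0])
        z_a = _robust_axis_z(pts[:, 1])
        cutoff1 = stats.chi2.ppf(chi2_quantile, df=1)
        with np.errstate(invalid="ignore"):
            removed_mask = (z_m ** 2 > cutoff1) | (z_a ** 2 > cutoff1)
        d2 = np.where(np.isinf(z_m) | np.isinf(z_a), np.inf, z_m ** 2 + z_a ** 2)
    idx = np.arange(n)
    return idx[~removed_mask], idx[removed_mask], d2


def compute_qc(control_matrix: SignalMatrix, target_matrix: SignalMatrix,
               signal_window: np.ndarray, background_window: np.ndarray,
               n_outliers_removed: int = 0, n_references_input: int | None = None,
               pseudocount: float = 1.0) -> QCReport:
    """Background scaling and per-sample signal-to-noise from paired matrices.

    ``signal_window`` and ``background_window`` are disjoint column-index
    arrays into the shared profile window. SNR is the ratio of the aggregate
    profile's signal-window mean to its background-window mean; background
    scaling is control background mean over target background mean.
    """
    if control_matrix.values.shape != target_matrix.values.shape:
        raise DataError("control and target matrices must share regions and bin count")
    sig = np.asarray(signal_window, dtype=int)
    bg = np.asarray(background_window, dtype=int)
    if sig.size == 0 or bg.size == 0:
        raise DataError("signal and background windows must be non-empty")
    if np.intersect1d(sig, bg).size:
        raise DataError("signal and background windows must be disjoint")

    prof_c = aggregate_profile(control_matrix)
    prof_t = aggregate_profile(target_matrix)
    bg_c, bg_t = prof_c[bg].mean(), prof_t[bg].mean()
    if bg_c <= 0 or bg_t <= 0:
        raise EstimationError(
            "background-window mean is zero; increase the pseudocount or widen "
            "the background flanks"
        )
    sig_c, sig_t = prof_c[sig].mean(), prof_t[sig].mean()

    c = pseudocount
    site_sig_c = control_matrix.values[:, sig].mean(axis=1)
    site_sig_t = target_matrix.values[:, sig].mean(axis=1)
    site_bg_c = control_matrix.values[:, bg].mean(axis=1)
    site_bg_t = target_matrix.values[:, bg].mean(axis=1)
    summary = {}
    for label, v in (
        ("log2_signal_control", site_sig_c), ("log2_signal_target", site_sig_t),
        ("log2_background_control", site_bg_c), ("log2_background_target", site_bg_t),
    ):
        lv = np.log2(v + c)
        summary[f"{label}_mean"] = float(lv.mean())
        summary[f"{label}_sd"] = float(lv.std(ddof=1)) if len(lv) > 1 else 0.0

    n_in = n_references_input if n_references_input is not None else len(control_matrix.regions)
    return QCReport(
        n_references_input=int(n_in),
        n_outliers_removed=int(n_outliers_removed),
        background_scaling=float(bg_c / bg_t),
        snr_control=float(sig_c / bg_c),
        snr_target=float(sig_t / bg_t),
        summary=summary,
    )
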