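"""Two-tier normalization anchored on stable internal reference regions.

The model: a target coverage track differs from the control by (i) an
additive/multiplicative background shift, (ii) a depth-and-compression
distortion of true signal, well approximated by an affine map in log2
space. Five parameters capture this:

``sfbg``
    background scaling factor — ratio of control to target background
    level, estimated in flanking windows of the reference sites.
``sfsig``
    reference-signal scaling factor — ratio of background-subtracted
    aggregate signal at reference sites.
``alpha``, ``beta``
    slope and intercept of the log2-space affine map aligning the
    sfsig-scaled target reference signals to the control's; obtained in
    closed form by matching mean and standard deviation (a z-score map):
    alpha = sd(x)/sd(y), beta = mean(x) - alpha * mean(y).
``noise``
    the signal/background cutoff (track units): the crossing point of the
    background and signal log2 densities.

Genome bins whose sfsig-scaled value exceeds ``noise`` take the signal
branch ``2**(alpha * log2(v * sfsig + c) + beta) - c``; all other bins take
the background branch ``v * sfbg``. The control track is the anchor and is
never transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree
from scipy import stats
from scipy.optimize import brentq

from .errors import ConfigError, DataError, EstimationError
from .qc import QCReport, compute_qc, ma_transform, mahalanobis_filter
from .regions import GenomicRegion, bin_genome
from .tracks import (SignalMatrix, bin_track, extract_signal, open_bigwig,
                     write_bigwig)

__all__ = [
    "NormalizationParams",
    "BinClassification",
    "NormalizationResult",
    "estimate_scaling_factors",
    "estimate_alignment",
    "estimate_noise_cutoff",
    "classify_bins",
    "normalize_bins",
    "run_normalization",
    "spikein_ratio_factor",
    "spikein_profile_params",
]

logger = logging.getLogger(__name__)

SOURCES = ("estimated", "override", "spikein_ratio", "spikein_profile")


@dataclass
class NormalizationParams:
    """The five normalization parameters plus per-field provenance."""

    sfbg: float
    sfsig: float
    alpha: float
    beta: float
    noise: float
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sfbg <= 0 or self.sfsig <= 0:
            raise EstimationError(
                f"scale factors must be > 0 (sfbg={self.sfbg}, sfsig={self.sfsig})"
            )
        if self.alpha <= 0:
            raise EstimationError(
                f"alpha must be > 0 (got {self.alpha}): a non-positive slope would "
                "reverse the ranking of signal bins"
            )
        if self.noise < 0:
            raise EstimationError(f"noise cutoff must be >= 0, got {self.noise}")
        for key in ("sfbg", "sfsig", "alpha", "beta", "noise"):
            self.source.setdefault(key, "estimated")

    def to_rows(self) -> list[tuple[str, float, str]]:
        return [(k, getattr(self, k), self.source[k])
                for k in ("sfbg", "sfsig", "alpha", "beta", "noise")]


@dataclass
class BinClassification:
    """Per-bin background/signal labels and the cutoff that produced them.

    ``is_signal[chrom][i]`` is True iff the sfsig-scaled bin value strictly
    exceeds the noise cutoff (ties are background).
    """

    is_signal: dict[str, np.ndarray]
    noise: float

    @property
    def n_signal(self) -> int:
        return int(sum(m.sum() for m in self.is_signal.values()))

    @property
    def n_bins(self) -> int:
        return int(sum(m.size for m in self.is_signal.values()))


@dataclass
class NormalizationResult:
    """Everything :func:`run_normalization` produces for one target track."""

    params: NormalizationParams
    qc: QCReport
    classification: BinClassification | None
    normalized: dict[str, np.ndarray]
    output_path: Path | None
    ma: "tuple[np.ndarray, np.ndarray] | None" = None  # (M, A) of all reference sites
    removed_reference_indices: np.ndarray | None = None


def estimate_scaling_factors(control_profile: np.ndarray, target_profile: np.ndarray,
                             signal_window: np.ndarray, background_window: np.ndarray,
                             background_subtract: bool = True) -> tuple[float, float]:
    """Estimate (sfbg, sfsig) from paired aggregate profiles.

    sfbg is the ratio of background-window means (control / target). sfsig
    is the ratio of background-subtracted signal-window means, so that a
    pure background difference does not leak into the signal scale; pass
    ``background_subtract=False`` for raw signal-window ratios.
    """
    cp = np.asarray(control_profile, dtype=float)
    tp = np.asarray(target_profile, dtype=float)
    if cp.shape != tp.shape:
        raise DataError("profiles must have equal length")
    sig = np.asarray(signal_window, dtype=int)
    bg = np.asarray(background_window, dtype=int)
    if sig.size == 0 or bg.size == 0:
        raise DataError("signal and background windows must be non-empty")
    if np.intersect1d(sig, bg).size:
        raise DataError("signal and background windows must be disjoint")

    c_bg, t_bg = cp[bg].mean(), tp[bg].mean()
    if c_bg <= 0 or t_bg <= 0:
        raise EstimationError("background-window mean must be > 0 in both samples")
    sfbg = c_bg / t_bg

    if background_subtract:
        c_sig = cp[sig].mean() - c_bg
        t_sig = tp[sig].mean() - t_bg
        if c_sig <= 0 or t_sig <= 0:
            raise EstimationError(
                "reference sites show no enrichment over background; cannot "
                "estimate sfsig (background-subtracted signal <= 0)"
            )
    else:
        c_sig, t_sig = cp[sig].mean(), tp[sig].mean()
        if c_sig <= 0 or t_sig <= 0:
            raise EstimationError("signal-window mean must be > 0 in both samples")
    return float(sfbg), float(c_sig / t_sig)


def estimate_alignment(x_log2: np.ndarray, y_log2: np.ndarray) -> tuple[float, float]:
    """Closed-form z-score alignment of target to control in log2 space.

    alpha = sd(x)/sd(y), beta = mean(x) - alpha * mean(y); applying
    ``y_hat = alpha * y + beta`` matches the target's mean and sd to the
    control's exactly.
    """
    x = np.asarray(x_log2, dtype=float)
    y = np.asarray(y_log2, dtype=float)
    if x.shape != y.shape:
        raise DataError("x and y must have equal length")
    if x.size < 3:
        raise DataError(f"alignment needs >= 3 reference sites, got {x.size}")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sy <= 0:
        raise EstimationError("target reference signals are constant; cannot align")
    if sx <= 0:
        raise EstimationError("control reference signals are constant; cannot align")
    alpha = sx / sy
    beta = x.mean() - alpha * y.mean()
    return float(alpha), float(beta)


def _kde_bandwidth(kde: stats.gaussian_kde, values: np.ndarray) -> float:
    return float(kde.factor * np.asarray(values).std(ddof=1))


def estimate_noise_cutoff(background_values: np.ndarray, signal_values: np.ndarray,
                          pseudocount: float = 1.0,
                          ) -> tuple[float, dict]:
    """Noise cutoff from the intersection of the two log2 densities.

    Inputs are log2-transformed bin values (``log2(v + pseudocount)``) for
    background-like bins and for reference signal-window bins. A Gaussian
    KDE (Silverman bandwidth) is fitted to each; the cutoff is the density
    crossing between the background mode and the signal mode, mapped back
    to track units as ``2**crossing - pseudocount``. When no crossing
    exists in that interval (e.g. the signal mode sits below the background
    mode) the fallback is the midpoint of the two means, and the fallback
    is logged.

    Returns ``(noise, info)`` where ``info`` records the log2 cutoff, the
    KDE bandwidths, and whether the fallback was taken.
    """
    bg = np.asarray(background_values, dtype=float)
    sig = np.asarray(signal_values, dtype=float)
    if bg.size == 0 or sig.size == 0:
        raise DataError("background and signal samples must be non-empty")
    if (abs(bg.mean() - sig.mean()) < 1e-9
            and abs(bg.std(ddof=0) - sig.std(ddof=0)) < 1e-9):
        raise EstimationError(
            "background and signal log2 distributions are indistinguishable; "
            "supply a manual noise override"
        )
    if bg.std(ddof=0) < 1e-12 or sig.std(ddof=0) < 1e-12:
        # degenerate (constant) sample: KDE undefined, use midpoint fallback
        cutoff_log2 = 0.5 * (bg.mean() + sig.mean())
        info = {"log2_cutoff": float(cutoff_log2), "fallback": True,
                "bandwidth_bg": 0.0, "bandwidth_sig": 0.0}
        logger.warning("constant log2 distribution; noise cutoff set to midpoint of means")
        return float(max(2.0 ** cutoff_log2 - pseudocount, 0.0)), info

    kde_bg = stats.gaussian_kde(bg, bw_method="silverman")
    kde_sig = stats.gaussian_kde(sig, bw_method="silverman")
    lo = min(bg.min(), sig.min()) - 1.0
    hi = max(bg.max(), sig.max()) + 1.0
    grid = np.linspace(lo, hi, 1024)
    f_bg = kde_bg(grid)
    f_sig = kde_sig(grid)
    mode_bg = grid[np.argmax(f_bg)]
    mode_sig = grid[np.argmax(f_sig)]

    info = {
        "bandwidth_bg": _kde_bandwidth(kde_bg, bg),
        "bandwidth_sig": _kde_bandwidth(kde_sig, sig),
        "mode_bg_log2": float(mode_bg),
        "mode_sig_log2": float(mode_sig),
        "fallback": False,
    }

    cutoff_log2 = None
    if mode_sig > mode_bg:
        sel = (grid >= mode_bg) & (grid <= mode_sig)
        sub = grid[sel]
        diff = f_bg[sel] - f_sig[sel]
        sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
        if sign_change.size:
            j = sign_change[0]
            a, b = sub[j], sub[j + 1]
            try:
                cutoff_log2 = brentq(lambda t: kde_bg(t)[0] - kde_sig(t)[0], a, b)
            except ValueError:  # pragma: no cover - bracketing guaranteed by sign change
                cutoff_log2 = 0.5 * (a + b)
    if cutoff_log2 is None:
        cutoff_log2 = 0.5 * (bg.mean() + sig.mean())
        info["fallback"] = True
        logger.warning(
            "no density crossing between background mode (%.3f) and signal mode "
            "(%.3f); noise cutoff falls back to the midpoint of means (%.3f)",
            mode_bg, mode_sig, cutoff_log2,
        )
    info["log2_cutoff"] = float(cutoff_log2)
    return float(max(2.0 ** cutoff_log2 - pseudocount, 0.0)), info


def classify_bins(target_bin_values: dict[str, np.ndarray] | np.ndarray,
                  params: NormalizationParams) -> BinClassification:
    """Label genome bins signal/background on sfsig-scaled values.

    A bin is signal iff ``value * sfsig > noise`` (ties are background).
    Accepts either a per-chromosome dict or a single array (stored under
    chromosome key ``""``).
    """
    if isinstance(target_bin_values, np.ndarray):
        target_bin_values = {"": target_bin_values}
    is_signal = {
        chrom: np.asarray(v, dtype=float) * params.sfsig > params.noise
        for chrom, v in target_bin_values.items()
    }
    return BinClassification(is_signal=is_signal, noise=params.noise)


def normalize_bins(target_bin_values: np.ndarray, is_signal: np.ndarray,
                   params: NormalizationParams, pseudocount: float = 1.0) -> np.ndarray:
    """Apply the two-branch correction to one vector of bin values.

    Background bins: ``v * sfbg``. Signal bins:
    ``2**(alpha * log2(v * sfsig + c) + beta) - c``, floored at 0. Both
    branches are strictly increasing in ``v`` (alpha > 0 is enforced), so
    ranking within a class is preserved.
    """
    v = np.asarray(target_bin_values, dtype=float)
    mask = np.asarray(is_signal, dtype=bool)
    if v.shape != mask.shape:
        raise DataError("classification does not match the value vector")
    c = pseudocount
    out = v * params.sfbg
    if mask.any():
        vs = v[mask]
        out[mask] = 2.0 ** (params.alpha * np.log2(vs * params.sfsig + c) + params.beta) - c
    return np.maximum(out, 0.0)


def spikein_ratio_factor(control_spikein_count: float, target_spikein_count: float) -> float:
    """Global scaling factor from spike-in totals: control / target.

    Used in single-factor mode: every bin is multiplied by this factor
    (equivalently sfbg = sfsig = factor, alpha = 1, beta = 0).
    """
    if control_spikein_count <= 0 or target_spikein_count <= 0:
        raise DataError("spike-in counts must be > 0")
    return float(control_spikein_count) / float(target_spikein_count)


# ---------------------------------------------------------------------------
# Parameter estimation from reference sites (shared by the endogenous and
# spike-in profile paths)
# ---------------------------------------------------------------------------

def _signal_background_columns(flank: int, n_bins: int, signal_halfwidth: int,
                               bg_inner: int, bg_outer: int) -> tuple[np.ndarray, np.ndarray]:
    """Column indices of the central signal window and the background flanks
    within a center±flank window of n_bins equal bins."""
    centers = (np.arange(n_bins) + 0.5) * (2 * flank / n_bins) - flank
    sig = np.nonzero(np.abs(centers) < signal_halfwidth)[0]
    bg = np.nonzero((np.abs(centers) >= bg_inner) & (np.abs(centers) < bg_outer))[0]
    if sig.size == 0 or bg.size == 0:
        raise ConfigError(
            "signal/background windows are empty; check flank, signal_halfwidth, "
            "bg_inner, bg_outer"
        )
    return sig, bg


def _background_mask(regions: list[GenomicRegion], flank: int, n_bins: int,
                     bg_cols: np.ndarray) -> np.ndarray:
    """Boolean (n_regions, n_bg_cols) mask: True where a background bin does
    NOT overlap any other reference site (those bins are kept)."""
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
    bin_w = 2 * flank / n_bins
    mask = np.ones((len(regions), bg_cols.size), dtype=bool)
    for i, r in enumerate(regions):
        tree = trees[r.chrom]
        for j, col in enumerate(bg_cols):
            b_start = int(r.center - flank + col * bin_w)
            b_end = int(b_start + bin_w)
            hits = tree.overlap(max(0, b_start), b_end)
            if any(h.data is not r for h in hits):
                mask[i, j] = False
    return mask


def _masked_column_mean(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Column means ignoring masked-out cells; columns with no valid cell
    fall back to the plain mean."""
    counts = mask.sum(axis=0)
    sums = np.where(mask, values, 0.0).sum(axis=0)
    out = np.where(counts > 0, sums / np.maximum(counts, 1), values.mean(axis=0))
    return out


@dataclass
class _EstimationContext:
    """Intermediate state shared between estimation and reporting."""

    matrix_control: SignalMatrix
    matrix_target: SignalMatrix
    sig_cols: np.ndarray
    bg_cols: np.ndarray
    bg_mask: np.ndarray
    kept: np.ndarray
    removed: np.ndarray
    ma_M: np.ndarray
    ma_A: np.ndarray
    noise_info: dict
    bg_values_log2: np.ndarray | None = None
    sig_values_log2: np.ndarray | None = None


def estimate_parameters(control_track, target_track, reference_regions: list[GenomicRegion],
                        config) -> tuple[NormalizationParams, QCReport, _EstimationContext]:
    """Run the estimation stages: extraction, M-A outlier filtering, QC,
    scaling factors, log2 alignment, noise cutoff.

    ``config`` is a :class:`refnorm.config.RunConfig`. Overridden parameters
    (non-None config fields) skip their estimation stage and are flagged
    ``source='override'``.
    """
    cfg = config
    c = cfg.pseudocount
    if len(reference_regions) < 3:
        raise DataError(
            f"need >= 3 reference regions, got {len(reference_regions)}"
        )
    flank = cfg.bg_outer
    n_bins = int(round(2 * cfg.bg_outer / cfg.profile_bin))
    logger.info("extracting reference profiles: %d sites, +/-%d bp, %d bins",
                len(reference_regions), flank, n_bins)
    mat_c = extract_signal(control_track, reference_regions, n_bins=n_bins, flank=flank)
    mat_t = extract_signal(target_track, reference_regions, n_bins=n_bins, flank=flank)
    sig_cols, bg_cols = _signal_background_columns(
        flank, n_bins, cfg.signal_halfwidth, cfg.bg_inner, cfg.bg_outer)
    bg_mask = _background_mask(reference_regions, flank, n_bins, bg_cols)

    # per-site central means drive M-A outlier filtering
    x_site = mat_c.values[:, sig_cols].mean(axis=1)
    y_site = mat_t.values[:, sig_cols].mean(axis=1)
    ma = ma_transform(x_site, y_site, pseudocount=c)
    kept, removed, _ = mahalanobis_filter(ma, chi2_quantile=cfg.chi2_quantile)
    if cfg.second_pass and kept.size >= 3:
        ma2 = ma_transform(x_site[kept], y_site[kept], pseudocount=c)
        kept2, _, _ = mahalanobis_filter(ma2, chi2_quantile=cfg.chi2_quantile)
        removed = np.setdiff1d(np.arange(len(ma)), kept[kept2])
        kept = kept[kept2]
    if kept.size < 3:
        raise EstimationError(
            f"fewer than 3 reference sites survive outlier filtering ({kept.size})"
        )
    logger.info("outlier filtering removed %d of %d reference sites",
                removed.size, len(reference_regions))

    fmat_c = mat_c.subset(kept)
    fmat_t = mat_t.subset(kept)
    fmask = bg_mask[kept]

    qc = compute_qc(fmat_c, fmat_t, sig_cols, bg_cols,
                    n_outliers_removed=removed.size,
                    n_references_input=len(reference_regions), pseudocount=c)

    source: dict[str, str] = {}
    # masked aggregate profiles (background bins overlapping other reference
    # sites are excluded from the background estimate)
    prof_c = fmat_c.values.mean(axis=0).copy()
    prof_t = fmat_t.values.mean(axis=0).copy()
    prof_c[bg_cols] = _masked_column_mean(fmat_c.values[:, bg_cols], fmask)
    prof_t[bg_cols] = _masked_column_mean(fmat_t.values[:, bg_cols], fmask)

    if cfg.sfbg is not None and cfg.sfsig is not None:
        sfbg, sfsig = cfg.sfbg, cfg.sfsig
        source["sfbg"] = source["sfsig"] = "override"
        logger.info("scaling stage skipped (override): sfbg=%g sfsig=%g", sfbg, sfsig)
    else:
        est_sfbg, est_sfsig = estimate_scaling_factors(
            prof_c, prof_t, sig_cols, bg_cols,
            background_subtract=cfg.background_subtract)
        sfbg = cfg.sfbg if cfg.sfbg is not None else est_sfbg
        sfsig = cfg.sfsig if cfg.sfsig is not None else est_sfsig
        source["sfbg"] = "override" if cfg.sfbg is not None else "estimated"
        source["sfsig"] = "override" if cfg.sfsig is not None else "estimated"
        logger.info("scaling factors: sfbg=%.4g (%s), sfsig=%.4g (%s)",
                    sfbg, source["sfbg"], sfsig, source["sfsig"])

    x_site_f = x_site[kept]
    y_site_f = y_site[kept]
    if cfg.alpha is not None and cfg.beta is not None:
        alpha, beta = cfg.alpha, cfg.beta
        source["alpha"] = source["beta"] = "override"
        logger.info("alignment stage skipped (override): alpha=%g beta=%g", alpha, beta)
    else:
        x_log2 = np.log2(x_site_f + c)
        y_log2 = np.log2(y_site_f * sfsig + c)
        est_alpha, est_beta = estimate_alignment(x_log2, y_log2)
        alpha = cfg.alpha if cfg.alpha is not None else est_alpha
        beta = cfg.beta if cfg.beta is not None else est_beta
        source["alpha"] = "override" if cfg.alpha is not None else "estimated"
        source["beta"] = "override" if cfg.beta is not None else "estimated"
        logger.info("log2 alignment: alpha=%.4g (%s), beta=%.4g (%s)",
                    alpha, source["alpha"], beta, source["beta"])

    ctx = _EstimationContext(
        matrix_control=fmat_c, matrix_target=fmat_t, sig_cols=sig_cols,
        bg_cols=bg_cols, bg_mask=fmask, kept=kept, removed=removed,
        ma_M=ma.M, ma_A=ma.A, noise_info={},
    )

    if cfg.noise is not None:
        noise = cfg.noise
        source["noise"] = "override"
        logger.info("noise stage skipped (override): noise=%g", noise)
    else:
        # The classification rule compares sfsig-scaled target values to the
        # cutoff, so both samples are pooled on that scale: target values are
        # multiplied by sfsig; control background is transported via
        # sfsig/sfbg and control signal via the inverse of the log2 affine
        # alignment (which maps control-scale signal back to sfsig-scaled
        # target signal).
        inv_affine = lambda v: 2.0 ** ((np.log2(v + c) - beta) / alpha) - c
        bg_pool = np.concatenate([
            fmat_c.values[:, bg_cols][fmask] * (sfsig / sfbg),
            fmat_t.values[:, bg_cols][fmask] * sfsig,
        ])
        sig_pool = np.concatenate([
            np.maximum(inv_affine(fmat_c.values[:, sig_cols].ravel()), 0.0),
            fmat_t.values[:, sig_cols].ravel() * sfsig,
        ])
        bg_log2 = np.log2(bg_pool + c)
        sig_log2 = np.log2(sig_pool + c)
        noise, noise_info = estimate_noise_cutoff(bg_log2, sig_log2, pseudocount=c)
        source["noise"] = "estimated"
        ctx.noise_info = noise_info
        ctx.bg_values_log2 = bg_log2
        ctx.sig_values_log2 = sig_log2
        logger.info("noise cutoff: %.4g track units (log2 crossing %.4g%s)",
                    noise, noise_info["log2_cutoff"],
                    ", fallback" if noise_info["fallback"] else "")

    params = NormalizationParams(sfbg=float(sfbg), sfsig=float(sfsig),
                                 alpha=float(alpha), beta=float(beta),
                                 noise=float(noise), source=source)
    return params, qc, ctx


def spikein_profile_params(control_spikein_track, target_spikein_track,
                           spikein_regions: list[GenomicRegion], config
                           ) -> NormalizationParams:
    """Estimate the five parameters from spike-in tracks and regions.

    Runs the estimation stages (not the genome-wide application) on the
    spike-in genome; the returned parameters are flagged
    ``source='spikein_profile'`` and are meant to be passed as overrides
    when normalizing the endogenous target track.
    """
    params, _, _ = estimate_parameters(
        control_spikein_track, target_spikein_track, spikein_regions, config)
    params.source = {k: "spikein_profile" for k in params.source}
    return params


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_normalization(control_track, target_track, reference_regions,
                      config=None, outdir: str | Path | None = None,
                      chrom_sizes: dict[str, int] | None = None,
                      ) -> NormalizationResult:
    """Normalize one target track against a control track.

    Orchestrates extraction, M-A outlier filtering, QC, parameter
    estimation (or overrides / spike-in-derived values carried in
    ``config``), genome binning, bin classification, the two-branch
    correction, and BigWig output. The control track is the anchor and is
    emitted unchanged.

    Parameters
    ----------
    control_track, target_track
        BigWig paths (or open handles).
    reference_regions
        List of :class:`GenomicRegion` or a BED path.
    config
        :class:`refnorm.config.RunConfig`; defaults are used when None.
    outdir
        When given, writes ``<target>.norm.bw``, ``params.tsv``, ``qc.tsv``,
        plots, and ``run_config.resolved`` there.
    chrom_sizes
        Chromosomes to normalize; defaults to the target track's table.
    """
    from .config import RunConfig  # local import to avoid a cycle
    from .regions import read_bed

    cfg = config or RunConfig()
    if isinstance(reference_regions, (str, Path)):
        reference_regions = read_bed(reference_regions)

    if cfg.mode not in ("two-tier", "background-only", "single-factor"):
        raise ConfigError(f"unknown mode {cfg.mode!r}")

    with open_bigwig(target_track) as bw:
        track_chroms = dict(bw.chroms())
    if chrom_sizes is None:
        chrom_sizes = track_chroms
    bins = bin_genome(chrom_sizes, cfg.bin_size)
    ctx = None

    if cfg.mode == "single-factor":
        if cfg.single_factor is None:
            raise ConfigError(
                "single-factor mode requires a factor (e.g. from spikein_ratio_factor)"
            )
        factor = float(cfg.single_factor)
        if factor <= 0:
            raise ConfigError("single factor must be > 0")
        params = NormalizationParams(
            sfbg=factor, sfsig=factor, alpha=1.0, beta=0.0, noise=0.0,
            source={k: "spikein_ratio" for k in ("sfbg", "sfsig", "alpha", "beta", "noise")})
        qc = None
        target_values = bin_track(target_track, bins)
        classification = None
        normalized = {chrom: v * factor for chrom, v in target_values.items()}
        logger.info("single-factor mode: every bin scaled by %.4g", factor)
    else:
        params, qc, ctx = estimate_parameters(
            control_track, target_track, reference_regions, cfg)
        target_values = bin_track(target_track, bins)
        if cfg.mode == "background-only":
            classification = None
            normalized = {chrom: v * params.sfbg for chrom, v in target_values.items()}
            logger.info("background-only mode: every bin scaled by sfbg=%.4g", params.sfbg)
        else:
            classification = classify_bins(target_values, params)
            logger.info("classified %d / %d bins as signal",
                        classification.n_signal, classification.n_bins)
            normalized = {
                chrom: normalize_bins(target_values[chrom],
                                      classification.is_signal[chrom],
                                      params, pseudocount=cfg.pseudocount)
                for chrom in target_values
            }

    output_path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = Path(str(target_track)).stem if isinstance(target_track, (str, Path)) else "target"
        output_path = outdir / f"{stem}.norm.bw"
        write_bigwig(bins, normalized, output_path)
        _write_params_tsv(params, qc, outdir / "params.tsv")
        if qc is not None:
            _write_qc_tsv(qc, outdir / "qc.tsv")
        cfg.write_resolved(outdir / "run_config.resolved")
        if cfg.make_plots and ctx is not None:
            from .plotting import ma_plot, noise_density_plot
            removed_mask = np.zeros(len(ctx.ma_M), dtype=bool)
            removed_mask[ctx.removed] = True
            ma_plot(ctx.ma_M, ctx.ma_A, removed_mask, outdir / "ma_references.png")
            if ctx.bg_values_log2 is not None:
                noise_density_plot(ctx.bg_values_log2, ctx.sig_values_log2,
                                   ctx.noise_info.get("log2_cutoff"),
                                   outdir / "noise_densities.png")
        logger.info("normalized track written to %s", output_path)

    return NormalizationResult(
        params=params, qc=qc, classification=classification,
        normalized=normalized, output_path=output_path,
        ma=(ctx.ma_M, ctx.ma_A) if ctx is not None else None,
        removed_reference_indices=ctx.removed if ctx is not None else None,
    )


def _write_params_tsv(params: NormalizationParams, qc: QCReport | None, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("parameter\tvalue\tsource\n")
        for name, value, source in params.to_rows():
            fh.write(f"{name}\t{value:.10g}\t{source}\n")
        if qc is not None:
            fh.write(f"n_outliers_removed\t{qc.n_outliers_removed}\testimated\n")


def _write_qc_tsv(qc: QCReport, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name, value in qc.to_rows():
            fh.write(f"{name}\t{value:.10g}\n")
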