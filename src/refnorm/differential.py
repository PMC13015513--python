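"""Differential-feature calling over user-defined regions.

Works on two coverage tracks (typically the control and a normalized
target): quantifies mean signal per region, computes M/A/fold change, and
calls direction by a fold-change rule (boundary inclusive), an exact
two-sided Poisson test, or both. Region means are converted to the Poisson
count scale by multiplying by the region width in bins — tracks store
densities, the test needs counts.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .qc import ma_transform
from .regions import GenomicRegion, read_bed
from .tracks import open_bigwig

__all__ = ["quantify_regions", "fold_change_call", "poisson_test", "run_differential"]

logger = logging.getLogger(__name__)

CALL_COLUMNS = [
    "chrom", "start", "end", "name", "strand", "value_control", "value_target",
    "M", "A", "fold_change", "p_value", "q_value", "direction", "significant",
]


def quantify_regions(control_track, target_track, regions: list[GenomicRegion]
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Mean track value over [start, end) per region, for both samples.

    Missing data counts as 0. Chromosomes absent from a track are an error.
    """
    def _means(track) -> np.ndarray:
        out = np.zeros(len(regions), dtype=float)
        with open_bigwig(track) as bw:
            chrom_table = bw.chroms()
            missing = sorted({r.chrom for r in regions} - set(chrom_table))
            if missing:
                raise DataError("chromosome(s) absent from track: " + ", ".join(missing))
            for i, r in enumerate(regions):
                end = min(r.end, chrom_table[r.chrom])
                if end <= r.start:
                    continue
                vals = np.asarray(bw.values(r.chrom, r.start, end, numpy=True), dtype=float)
                vals = np.nan_to_num(vals, nan=0.0)
                # clipped tail counts as zero coverage over the full width
                out[i] = vals.sum() / r.length
        return out

    return _means(control_track), _means(target_track)


def fold_change_call(value_control: np.ndarray, value_target: np.ndarray,
                     fc_cutoff: float = 2.0, pseudocount: float = 1.0) -> np.ndarray:
    """Directional call from pseudocounted fold change, boundary inclusive.

    up when (target+c)/(control+c) >= cutoff, down when the reciprocal
    ratio >= cutoff, else unchanged.
    """
    if fc_cutoff < 1:
        raise ConfigError(f"fc_cutoff must be >= 1, got {fc_cutoff}")
    t = np.asarray(value_target, dtype=float) + pseudocount
    ctrl = np.asarray(value_control, dtype=float) + pseudocount
    ratio = t / ctrl
    out = np.full(ratio.shape, "unchanged", dtype=object)
    out[ratio >= fc_cutoff] = "up"
    out[1.0 / ratio >= fc_cutoff] = "down"
    return out


def poisson_test(count_control: float, count_target: float,
                 exposure_ratio: float = 1.0, pseudo_floor: float = 1.0) -> float:
    """Exact two-sided Poisson p-value for a target count given the control.

    The target count k (rounded, floored at ``pseudo_floor``) is tested
    against rate ``lambda = exposure_ratio * max(count_control,
    pseudo_floor)``; p = 2 * min(P[X <= k], P[X >= k]) capped at 1. The
    floor on both counts keeps empty regions from producing spurious
    significance.
    """
    if exposure_ratio <= 0:
        raise ConfigError(f"exposure_ratio must be > 0, got {exposure_ratio}")
    if count_control < 0 or count_target < 0:
        raise DataError("counts must be >= 0")
    lam = exposure_ratio * max(float(count_control), pseudo_floor)
    k = int(round(max(float(count_target), pseudo_floor)))
    lower = stats.poisson.cdf(k, lam)
    upper = stats.poisson.sf(k - 1, lam)
    return float(min(1.0, 2.0 * min(lower, upper)))


def run_differential(control_track, target_track, regions,
                     config=None, outdir: str | Path | None = None) -> pd.DataFrame:
    """Quantify regions in both tracks and call differential features.

    ``config.stat`` selects the rule: ``fc`` (fold change >= cutoff,
    boundary inclusive), ``poisson`` (exact test, BH-adjusted unless
    ``adjust`` is off), or ``both`` (both must pass). Returns the calls
    table; when ``outdir`` is given also writes ``calls.tsv``, ``ma.png``,
    and ``up.bed`` / ``down.bed`` / ``unchanged.bed``.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    if cfg.stat not in ("fc", "poisson", "both"):
        raise ConfigError(f"unknown stat {cfg.stat!r} (expected fc|poisson|both)")
    if isinstance(regions, (str, Path)):
        regions = read_bed(regions)

    c = cfg.pseudocount
    if len(regions) == 0:
        df = pd.DataFrame(columns=CALL_COLUMNS)
    else:
        v_ctrl, v_tgt = quantify_regions(control_track, target_track, regions)
        ma = ma_transform(v_ctrl, v_tgt, pseudocount=c)
        fold = (v_tgt + c) / (v_ctrl + c)
        fc_dir = fold_change_call(v_ctrl, v_tgt, cfg.fc_cutoff, c)

        p = np.full(len(regions), np.nan)
        q_adj = np.full(len(regions), np.nan)
        if cfg.stat in ("poisson", "both"):
            widths = np.array([max(1, round(r.length / cfg.bin_size)) for r in regions])
            k_ctrl = v_ctrl * widths
            k_tgt = v_tgt * widths
            p = np.array([
                poisson_test(kc, kt, cfg.exposure_ratio, cfg.pseudo_floor)
                for kc, kt in zip(k_ctrl, k_tgt)
            ])
            if cfg.adjust:
                q_adj = multipletests(p, method="fdr_bh")[1]
            else:
                q_adj = p
            pois_sig = q_adj <= cfg.q
        if cfg.stat == "fc":
            significant = fc_dir != "unchanged"
        elif cfg.stat == "poisson":
            significant = pois_sig
        else:
            significant = (fc_dir != "unchanged") & pois_sig

        direction = np.full(len(regions), "unchanged", dtype=object)
        direction[significant & (ma.M > 0)] = "up"
        direction[significant & (ma.M < 0)] = "down"
        significant = significant & (direction != "unchanged")

        df = pd.DataFrame({
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "name": [r.name or f"region_{i}" for i, r in enumerate(regions)],
            "strand": [r.strand for r in regions],
            "value_control": v_ctrl,
            "value_target": v_tgt,
            "M": ma.M,
            "A": ma.A,
            "fold_change": fold,
            "p_value": p,
            "q_value": q_adj,
            "direction": direction,
            "significant": significant,
        })

    counts = df["direction"].value_counts() if len(df) else {}
    logger.info("differential calls: %d up, %d down, %d unchanged",
                counts.get("up", 0) if len(df) else 0,
                counts.get("down", 0) if len(df) else 0,
                counts.get("unchanged", 0) if len(df) else 0)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "calls.tsv", sep="\t", index=False)
        for label in ("up", "down", "unchanged"):
            sub = df[df["direction"] == label] if len(df) else df
            _write_calls_bed(sub, outdir / f"{label}.bed")
        if cfg.make_plots and len(df):
            from .plotting import ma_plot
            ma_plot(df["M"].to_numpy(), df["A"].to_numpy(),
                    df["significant"].to_numpy(dtype=bool), outdir / "ma.png",
                    highlight_label="significant")
        cfg.write_resolved(outdir / "run_config.resolved")
    return df


def _write_calls_bed(df: pd.DataFrame, path: Path) -> None:
    """BED6 with M scaled x100 in the score column, clamped to [0, 1000]."""
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            score = int(np.clip(round(row["M"] * 100), 0, 1000))
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                     f"{row['name']}\t{score}\t{row['strand']}\n")
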