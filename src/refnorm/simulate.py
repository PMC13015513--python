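"""Synthetic paired coverage tracks with known ground truth.

The generator emulates the data the two-tier model assumes: a flat
background, Gaussian-shaped enrichment peaks at stable reference sites
(lognormal height spread, so M-A clouds look realistic), candidate regions
for differential testing, and a target sample produced by pushing the
control's latent signal through the *inverse* of the two-tier
normalization map — background divided by sfbg, signal bins through the
inverted log2-affine map — plus fresh multiplicative lognormal noise.
Planted differential regions get a region-level fold change before the
distortion; planted outlier reference sites get an independent fold so
outlier filtering has true positives.

Ground truth and identifiability
--------------------------------
``sfbg`` is identified exactly (background bins are scaled uniformly).
``sfsig``, ``alpha`` and ``beta`` as *dialed* are not jointly identifiable
under the model's estimation conventions: the model pins sfsig via the
background-subtracted aggregate signal ratio, which does not commute with
the nonlinear log2 map, and beta trades off against log2(sfsig).
:class:`SimulationTruth` therefore records the *effective* truth — the
parameter values the model's own definitions take on the noiseless latent
tracks, computed here by direct array slicing, independent of the
estimation code. Recovery tests compare estimates (from noisy data,
through the full extraction/filtering pipeline) to these effective truths.

Unless ``beta`` is dialed explicitly, it is chosen so the two distortion
branches agree at the signal threshold (a continuous distortion), which is
both more realistic and keeps near-threshold classification differences
from mattering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError
from .regions import GenomicRegion, bin_genome, write_bed
from .tracks import write_bigwig

__all__ = ["SimulationTruth", "simulate_pair", "simulate_spikein"]

DEFAULT_GENOME = {"chrA": 500_000, "chrB": 500_000}


@dataclass
class SimulationTruth:
    """Everything a test needs to score the pipeline against the generator."""

    true_sfbg: float
    true_sfsig: float
    true_alpha: float
    true_beta: float
    dialed: dict[str, float]
    reference_sites: list[GenomicRegion]
    planted_outlier_sites: list[int]        # indices into reference_sites
    candidate_regions: list[GenomicRegion]
    planted_differential: list[tuple[GenomicRegion, float]]  # (region, fold)
    seed: int
    signal_threshold: float                 # latent control units
    control_path: Path | None = None
    target_path: Path | None = None
    refs_bed: Path | None = None
    candidates_bed: Path | None = None
    extras: dict = field(default_factory=dict)


def _place_sites(genome: dict[str, int], n_sites: int, margin: int,
                 bin_size: int, min_gap: int, rng: np.random.Generator
                 ) -> list[tuple[str, int]]:
    """Jittered-grid site centers, snapped to the bin grid.

    Sites are split across chromosomes proportionally to usable length;
    the grid guarantees a minimum center-to-center gap or raises.
    """
    usable = {c: length - 2 * margin for c, length in genome.items()}
    if any(u <= 0 for u in usable.values()):
        raise DataError("chromosomes too short for the placement margin")
    total = sum(usable.values())
    counts = {c: int(round(n_sites * u / total)) for c, u in usable.items()}
    # fix rounding drift on the largest chromosome
    drift = n_sites - sum(counts.values())
    counts[max(usable, key=usable.get)] += drift
    centers: list[tuple[str, int]] = []
    for chrom, n in counts.items():
        if n == 0:
            continue
        spacing = usable[chrom] / n
        if spacing * 0.8 < min_gap:
            raise DataError(
                f"cannot place {n} sites on {chrom}: spacing {spacing:.0f} bp "
                f"< required gap {min_gap} bp (shrink the site count or grow the genome)"
            )
        jitter = rng.uniform(-0.1 * spacing, 0.1 * spacing, size=n)
        pos = margin + (np.arange(n) + 0.5) * spacing + jitter
        pos = (np.round(pos / bin_size) * bin_size).astype(int)
        centers.extend((chrom, int(p)) for p in pos)
    return centers


def simulate_pair(outdir: str | Path, *, genome: dict[str, int] | None = None,
                  n_refs: int = 100, n_diff: int = 60, frac_diff: float = 0.5,
                  diff_fold: float = 4.0, sfbg: float = 0.6, sfsig: float = 1.5,
                  alpha: float = 0.85, beta: float | None = None,
                  noise_sd: float = 0.05, n_outliers: int = 5,
                  outlier_fold: float = 4.0, bin_size: int = 50,
                  background: float = 1.0, peak_height: float = 12.0,
                  peak_height_log_sd: float = 0.5, peak_sd: float = 75.0,
                  signal_threshold: float | None = None, pseudocount: float = 1.0,
                  ref_width: int = 300, candidate_width: int = 400,
                  margin: int = 6000, signal_halfwidth: int = 200,
                  bg_inner: int = 2000, bg_outer: int = 4000,
                  seed: int = 0, control_name: str = "control.bw",
                  target_name: str = "target.bw") -> SimulationTruth:
    """Write a (control, target) BigWig pair plus BED files with known truth.

    Parameters of note: ``sfbg``/``sfsig``/``alpha``/``beta`` dial the
    distortion (``beta=None`` picks the continuous choice, see module
    docstring); ``peak_height`` is the median peak amplitude in units of
    ``background``; ``noise_sd`` is the sigma of the multiplicative
    lognormal bin noise; ``signal_threshold`` (default ``2*background``)
    splits the two distortion branches in latent control units.

    Returns the :class:`SimulationTruth`, with file paths filled in.
    """
    if sfbg <= 0 or sfsig <= 0 or alpha <= 0:
        raise ConfigError("sfbg, sfsig and alpha must all be > 0")
    if not 0 <= frac_diff <= 1:
        raise ConfigError("frac_diff must be in [0, 1]")
    if n_outliers >= n_refs:
        raise ConfigError("n_outliers must be smaller than n_refs")
    genome = dict(genome or DEFAULT_GENOME)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    c = pseudocount
    t0 = 2.0 * background if signal_threshold is None else float(signal_threshold)

    if beta is None:
        # continuity at the threshold: both branches agree at t0
        beta_d = float(np.log2(t0 + c) - alpha * np.log2(sfsig * t0 / sfbg + c))
    else:
        beta_d = float(beta)

    def inv_signal(v: np.ndarray) -> np.ndarray:
        return (2.0 ** ((np.log2(v + c) - beta_d) / alpha) - c) / sfsig

    if inv_signal(np.array([t0]))[0] <= 0:
        raise ConfigError(
            "distortion parameters map the signal threshold to a non-positive "
            "target value; adjust alpha/beta/sfsig"
        )

    min_gap = int(max(ref_width, candidate_width) + 6 * peak_sd)
    centers = _place_sites(genome, n_refs + n_diff, margin, bin_size, min_gap, rng)
    order = rng.permutation(len(centers))
    ref_centers = [centers[i] for i in order[:n_refs]]
    cand_centers = [centers[i] for i in order[n_refs:]]

    refs = [GenomicRegion(ch, p - ref_width // 2, p + ref_width // 2,
                          name=f"ref_{i}") for i, (ch, p) in enumerate(ref_centers)]
    cands = [GenomicRegion(ch, p - candidate_width // 2, p + candidate_width // 2,
                           name=f"cand_{i}") for i, (ch, p) in enumerate(cand_centers)]

    amps_ref = background * peak_height * rng.lognormal(0.0, peak_height_log_sd, n_refs)
    amps_cand = background * peak_height * rng.lognormal(0.0, peak_height_log_sd, n_diff)

    outlier_idx = sorted(rng.choice(n_refs, size=n_outliers, replace=False).tolist())
    n_changed = int(round(frac_diff * n_diff))
    changed_idx = sorted(rng.choice(n_diff, size=n_changed, replace=False).tolist())
    # alternate up and down folds among planted differential regions
    cand_folds = np.ones(n_diff)
    for j, ci in enumerate(changed_idx):
        cand_folds[ci] = diff_fold if j % 2 == 0 else 1.0 / diff_fold
    outlier_folds = np.array([outlier_fold if j % 2 == 0 else 1.0 / outlier_fold
                              for j in range(n_outliers)])

    bins = bin_genome(genome, bin_size)
    ctrl_latent: dict[str, np.ndarray] = {}
    tgt_biol: dict[str, np.ndarray] = {}
    for chrom in bins.chroms:
        n = bins.n_bins(chrom)
        ctrl_latent[chrom] = np.full(n, float(background))
        tgt_biol[chrom] = np.full(n, float(background))

    def add_peak(arr: dict[str, np.ndarray], chrom: str, center: int, amp: float) -> None:
        pos = (np.arange(bins.n_bins(chrom)) + 0.5) * bin_size
        lo = max(0, int((center - 5 * peak_sd) // bin_size))
        hi = min(bins.n_bins(chrom), int((center + 5 * peak_sd) // bin_size) + 1)
        arr[chrom][lo:hi] += amp * np.exp(
            -((pos[lo:hi] - center) ** 2) / (2 * peak_sd ** 2))

    for (chrom, p), amp in zip(ref_centers, amps_ref):
        add_peak(ctrl_latent, chrom, p, amp)
        add_peak(tgt_biol, chrom, p, amp)
    for (chrom, p), amp in zip(cand_centers, amps_cand):
        add_peak(ctrl_latent, chrom, p, amp)
        add_peak(tgt_biol, chrom, p, amp)

    # region-level biological changes in the target
    for j, ci in enumerate(changed_idx):
        r = cands[ci]
        sl = slice(r.start // bin_size, -(-r.end // bin_size))
        tgt_biol[r.chrom][sl] = tgt_biol[r.chrom][sl] * cand_folds[ci]
    for j, oi in enumerate(outlier_idx):
        r = refs[oi]
        sl = slice(r.start // bin_size, -(-r.end // bin_size))
        tgt_biol[r.chrom][sl] = tgt_biol[r.chrom][sl] * outlier_folds[j]

    # forward distortion: inverse of the two-tier normalization map
    tgt_raw: dict[str, np.ndarray] = {}
    for chrom in bins.chroms:
        v = tgt_biol[chrom]
        tgt_raw[chrom] = np.where(v > t0, inv_signal(v), v / sfbg)

    # ---- effective ground truth from the noiseless latent tracks ----
    keep = [i for i in range(n_refs) if i not in outlier_idx]
    hw = signal_halfwidth // bin_size
    x_sites, y_sites, bg_c_cells, bg_t_cells = [], [], [], []
    for i in keep:
        chrom, p = ref_centers[i]
        b0 = p // bin_size
        x_sites.append(ctrl_latent[chrom][b0 - hw:b0 + hw].mean())
        y_sites.append(tgt_raw[chrom][b0 - hw:b0 + hw].mean())
        for lo, hi in ((p - bg_outer, p - bg_inner), (p + bg_inner, p + bg_outer)):
            sl = slice(lo // bin_size, hi // bin_size)
            bg_c_cells.append(ctrl_latent[chrom][sl])
            bg_t_cells.append(tgt_raw[chrom][sl])
    x_sites = np.array(x_sites)
    y_sites = np.array(y_sites)
    bg_c = float(np.concatenate(bg_c_cells).mean())
    bg_t = float(np.concatenate(bg_t_cells).mean())
    true_sfbg = bg_c / bg_t
    true_sfsig = float((x_sites.mean() - bg_c) / (y_sites.mean() - bg_t))
    x_l = np.log2(x_sites + c)
    y_l = np.log2(true_sfsig * y_sites + c)
    true_alpha = float(x_l.std(ddof=1) / y_l.std(ddof=1))
    true_beta = float(x_l.mean() - true_alpha * y_l.mean())

    # ---- noise and output ----
    ctrl_out = {ch: v * rng.lognormal(0.0, noise_sd, v.shape) if noise_sd > 0 else v.copy()
                for ch, v in ctrl_latent.items()}
    tgt_out = {ch: v * rng.lognormal(0.0, noise_sd, v.shape) if noise_sd > 0 else v.copy()
               for ch, v in tgt_raw.items()}

    control_path = outdir / control_name
    target_path = outdir / target_name
    write_bigwig(bins, ctrl_out, control_path)
    write_bigwig(bins, tgt_out, target_path)
    refs_bed = outdir / "references.bed"
    cands_bed = outdir / "candidates.bed"
    write_bed(refs, refs_bed)
    write_bed(cands, cands_bed)

    return SimulationTruth(
        true_sfbg=float(true_sfbg), true_sfsig=true_sfsig,
        true_alpha=true_alpha, true_beta=true_beta,
        dialed={"sfbg": sfbg, "sfsig": sfsig, "alpha": alpha, "beta": beta_d,
                "noise_sd": noise_sd, "background": background,
                "peak_height": peak_height, "diff_fold": diff_fold},
        reference_sites=refs, planted_outlier_sites=outlier_idx,
        candidate_regions=cands,
        planted_differential=[(cands[ci], float(cand_folds[ci])) for ci in changed_idx],
        seed=seed, signal_threshold=t0,
        control_path=control_path, target_path=target_path,
        refs_bed=refs_bed, candidates_bed=cands_bed,
        extras={"latent_control_total": float(sum(v.sum() for v in ctrl_latent.values())),
                "latent_target_total": float(sum(v.sum() for v in tgt_raw.values()))},
    )


def simulate_spikein(outdir: str | Path, *, depth_ratio: float = 1.0,
                     seed: int = 0, noise_sd: float = 0.05,
                     genome: dict[str, int] | None = None, n_refs: int = 30,
                     **kwargs) -> SimulationTruth:
    """Paired spike-in tracks on a small auxiliary genome.

    ``depth_ratio`` is the target/control sequencing-depth ratio: the
    target track is the control's latent signal times ``depth_ratio``
    (plus fresh noise), so the total-signal ratio between the files equals
    ``depth_ratio`` up to noise, and the ratio-derived scaling factor is
    ``1/depth_ratio``.
    """
    if depth_ratio <= 0:
        raise ConfigError("depth_ratio must be > 0")
    genome = dict(genome or {"spike1": 250_000})
    factor = 1.0 / depth_ratio
    truth = simulate_pair(
        outdir, genome=genome, n_refs=n_refs, n_diff=0, frac_diff=0.0,
        n_outliers=0, sfbg=factor, sfsig=factor, alpha=1.0, beta=0.0,
        noise_sd=noise_sd, seed=seed,
        control_name="spikein_control.bw", target_name="spikein_target.bw",
        **kwargs)
    truth.extras["depth_ratio"] = depth_ratio
    truth.extras["expected_ratio_factor"] = factor
    return truth
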