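import numpy as np
import pytest

from refnorm import RunConfig, bin_genome, run_normalization, simulate_pair, write_bigwig


def make_track(path, chrom_arrays, bin_size=50):
    """Write per-chromosome bin-value arrays as a BigWig; returns GenomeBins."""
    sizes = {ch: len(v) * bin_size for ch, v in chrom_arrays.items()}
    bins = bin_genome(sizes, bin_size)
    write_bigwig(bins, {ch: np.asarray(v, dtype=float) for ch, v in chrom_arrays.items()}, path)
    return bins


@pytest.fixture(scope="session")
def default_pair(tmp_path_factory):
    """One simulated control/target pair at the default study conditions,
    shared across tests that only read it."""
    d = tmp_path_factory.mktemp("pair")
    return simulate_pair(d, seed=42)


@pytest.fixture(scope="session")
def normalized_pair(default_pair, tmp_path_factory):
    """The default pair run through the full normalization pipeline."""
    outdir = tmp_path_factory.mktemp("norm")
    cfg = RunConfig(make_plots=False)
    result = run_normalization(default_pair.control_path, default_pair.target_path,
                               default_pair.refs_bed, config=cfg, outdir=outdir)
    return default_pair, result
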