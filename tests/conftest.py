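import numpy as np
import pandas as pd
import pytest

from exoscan import SimConfig, simulate_panel
from exoscan.genotype import apply_reference_call_rule, mask_varietal_snps, filter_loci


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study (donor blocks present), seed fixed."""
    return simulate_panel(SimConfig(seed=1))


@pytest.fixture(scope="session")
def masked_matrix(default_sim):
    """Designated + varietal-masked calls: input to counts and donor scanning."""
    designated = apply_reference_call_rule(default_sim.matrix)
    return mask_varietal_snps(designated, default_sim.varietal_mask)


@pytest.fixture(scope="session")
def filtered_matrix(masked_matrix):
    """Post locus-filter matrix: input to density tracks and Fst."""
    return filter_loci(masked_matrix)


@pytest.fixture(scope="session")
def null_sim():
    """No-donor simulation: exotic lines exist but carry zero donor material."""
    import warnings

    with warnings.catch_warnings():
        # zero-width donor range is intentional here; the generator warns
        warnings.filterwarnings("ignore", message=".*clipping")
        return simulate_panel(SimConfig(seed=2, donor_fraction_range=(0.0, 0.0)))


@pytest.fixture(scope="session")
def null_masked(null_sim):
    designated = apply_reference_call_rule(null_sim.matrix)
    return mask_varietal_snps(designated, null_sim.varietal_mask)


def truth_bin_coverage(classified: pd.DataFrame, segments: pd.DataFrame) -> np.ndarray:
    """Fraction of each bin covered by truth segments (0..1)."""
    cov = np.zeros(len(classified), dtype=float)
    starts = classified["start"].to_numpy()
    ends = classified["end"].to_numpy()
    chroms = classified["chrom"].to_numpy()
    for _, r in segments.iterrows():
        lo = np.maximum(starts, r["start"])
        hi = np.minimum(ends, r["end"])
        cov += np.maximum(0, hi - lo) * (chroms == r["chrom"])
    return cov / (ends - starts)
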