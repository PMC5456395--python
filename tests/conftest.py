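import numpy as np
import pytest

from nadscape.layout import GenomeLayout
from nadscape.simulate import (
    EmissionParams,
    simulate_domain_truth,
    simulate_enrichment_arrays,
)
from nadscape import caller


@pytest.fixture(scope="session")
def small_truth():
    """Two 5 Mb chromosomes tiled with ~400 kb alternating domains."""
    layout = GenomeLayout.toy(2, 5_000_000)
    return simulate_domain_truth(layout, 400_000, 400_000, seed=11)


@pytest.fixture(scope="session")
def small_tracks(small_truth):
    params = EmissionParams(seed=11)
    return simulate_enrichment_arrays(small_truth, params)


@pytest.fixture(scope="session")
def called_domains(small_truth, small_tracks):
    """End-to-end called domains on the small simulated genome."""
    nucleolar, background = small_tracks
    enrich, _ = caller.compute_enrichment(
        caller.quantile_normalize(nucleolar), caller.quantile_normalize(background)
    )
    smoothed = caller.smooth_sliding_median(enrich)
    averaged = caller.average_replicates([smoothed])
    model = caller.fit_two_state_hmm(averaged)
    return caller.call_domains(averaged, model), model, averaged


def bp_label_array(domain_frame, chrom, length):
    """Per-basepair boolean oracle: True where a bp is covered (or NAD)."""
    arr = np.zeros(length, dtype=bool)
    grp = domain_frame[domain_frame["chrom"] == chrom]
    for _, row in grp.iterrows():
        if "label" not in row or row["label"] == "NAD":
            arr[row["start"] : row["end"]] = True
    return arr
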