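import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import hepatodecon as hd

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def refset():
    """Three-type reference panel with 20 exclusive markers each."""
    return hd.make_reference_set(3, 1000, 20, 7)


@pytest.fixture(scope="session")
def truth_marker_sets(refset):
    """Generator ground-truth markers wrapped as MarkerSet objects."""
    return {
        ct: hd.MarkerSet(ct, genes, pd.Series(dtype=float))
        for ct, genes in refset.marker_truth.items()
    }


def estimate_mixture_fractions(refs, lib, marker_sets=None, average="mean"):
    """Run the full estimation path: reads/kb -> per-type marker-ratio average."""
    tissue = hd.to_molecule_counts(lib)
    if marker_sets is None:
        marker_sets = {
            ct: hd.MarkerSet(ct, genes, pd.Series(dtype=float))
            for ct, genes in refs.marker_truth.items()
        }
    return {
        ct: hd.estimate_cell_fraction(marker_sets[ct], tissue, refs.profiles[ct], average)
        for ct in refs.cell_types
        if ct in marker_sets
    }
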