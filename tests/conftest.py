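import sys
from pathlib import Path

import pytest

import patchseqkit as pk

# make scripts/acceptance.py importable for the acceptance-target tests
sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "scripts"))


@pytest.fixture(scope="session")
def small_cfg() -> pk.SynthConfig:
    """Compact taxonomy: 3 classes (one glial) x 3 types, fast to generate."""
    return pk.SynthConfig(
        seed=11, n_classes=3, types_per_class=3, n_genes=400,
        markers_per_class=20, type_markers_per_type=10,
        n_ref_cells_per_type=15, glia_classes=1, noise_sd=0.3,
    )


@pytest.fixture(scope="session")
def small_ref(small_cfg) -> pk.ReferenceTaxonomy:
    return pk.make_reference(small_cfg)


@pytest.fixture(scope="session")
def marker_sets(small_ref):
    return pk.select_markers(small_ref, n_markers=20)


@pytest.fixture(scope="session")
def facs(small_ref, marker_sets):
    return pk.compute_facs_summary(small_ref, marker_sets)
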