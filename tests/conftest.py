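import numpy as np
import pandas as pd
import pytest

from alliumcw import synthgen


@pytest.fixture
def small_config():
    """Compact synthetic world: 3 onions, 60 cells/zone, 4 spectra/layer."""
    return synthgen.SynthConfig(
        seed=42, n_onions=3, cells_per_zone=60, spectra_per_layer=4
    )


@pytest.fixture
def cells(small_config):
    return synthgen.gen_cell_sizes(small_config)


def make_layer_table(rng, n=150, median=1000.0, sigma=0.5, c_bm=2.0, c_um=1.5,
                     layer="S1"):
    """Single-layer cell table under the exact proportional-growth null."""
    frames = []
    for zone, factor in (("B", c_bm), ("M", 1.0), ("U", c_um)):
        areas = rng.lognormal(np.log(median / factor), sigma, size=n)
        frames.append(
            pd.DataFrame(
                {"onion_id": "O1", "layer": layer, "zone": zone, "area_um2": areas}
            )
        )
    return pd.concat(frames, ignore_index=True)
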