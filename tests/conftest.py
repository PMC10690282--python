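import numpy as np
import pytest

import paralogscope as ps


@pytest.fixture(scope="session")
def noise_free_scene():
    """Two-class field with noise disabled, for exact bookkeeping checks."""
    return ps.generate_scene(
        8,
        ["cytoplasm"] * 4 + ["nucleus"] * 4,
        noise=ps.NoiseModel.off(),
        shape=(256, 256),
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_scene():
    return ps.generate_scene(10, "cytoplasm", shape=(300, 300), seed=5)


@pytest.fixture(scope="session")
def mini_panel():
    """A small two-pair panel (one programmed effect, one null) + metadata."""
    pairs = [
        ps.ParalogPair(
            "EFF1", "EFF2", "cytoplasm", "nucleus",
            effect_a=ps.EffectSpec(
                gene="EFF1", background="deletion", abundance_lfc=0.5,
                reloc_fraction=0.6, reloc_target="ER",
            ),
        ),
        ps.synthetic.null_pair("NUL1", "NUL2", "cytoplasm", "nucleus"),
    ]
    cfg = ps.GeneratorConfig(n_cells=20, shape=(256, 256))
    scenes, meta = ps.generate_strain_panel(
        pairs, replicates=2, fields_per_replicate=2, seed=31, config=cfg
    )
    return scenes, meta
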