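import warnings

import pandas as pd
import pytest

from desmonet import (
    BasalLaminaConfig,
    BodyPlanConfig,
    build_desmo_graph,
    generate_larva,
    largest_component,
)


def small_type_table() -> pd.DataFrame:
    """A reduced body plan (~200 cells) for fast tests: three trunk
    segments, muscles + epidermis + one hub rod per segment side."""
    rows = []
    for seg in ("sg1", "sg2", "sg3"):
        for side in ("left", "right"):
            rows += [
                dict(cell_type="MUSlongD", cell_class="muscle", segment=seg,
                     side=side, count=8),
                dict(cell_type="MUStrans", cell_class="muscle", segment=seg,
                     side=side, count=6),
                dict(cell_type="EC", cell_class="epidermal", segment=seg,
                     side=side, count=12),
                dict(cell_type="acicula_not", cell_class="other", segment=seg,
                     side=side, count=1),
                dict(cell_type="acFC_not", cell_class="follicle", segment=seg,
                     side=side, count=3),
            ]
    return pd.DataFrame(rows)


def small_config(seed: int = 0, **kw) -> BodyPlanConfig:
    defaults = dict(
        type_table=small_type_table(),
        basal_lamina=BasalLaminaConfig(total_cable=1_600_000.0),
        innervation_map=(
            ("MNcrab", "MUSlongD", 0.8),
            ("MNring", "MUStrans", 1.0),
        ),
        seed=seed,
    )
    defaults.update(kw)
    return BodyPlanConfig(**defaults)


@pytest.fixture(scope="session")
def small_larva():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return generate_larva(small_config(seed=0))


@pytest.fixture(scope="session")
def default_larva():
    """The default study conditions: full census, default wiring."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return generate_larva(BodyPlanConfig(seed=1))


@pytest.fixture(scope="session")
def default_graph(default_larva):
    g, _ = largest_component(build_desmo_graph(default_larva))
    return g
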