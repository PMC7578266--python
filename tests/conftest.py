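import numpy as np
import pytest

from osteoblast.chip_io import DEFAULT_CONTROL_ID, IntensityDataset, PeptideAnnotation


def make_annotation(spot_id: str, **kwargs) -> PeptideAnnotation:
    defaults = dict(
        sequence="AAAAAAYAAAAAA",
        protein_name=f"Protein {spot_id}",
        symbol=spot_id.split("_")[0],
        phospho_positions=(7,),
        uniprot_accession="P00000",
    )
    defaults.update(kwargs)
    return PeptideAnnotation(spot_id=spot_id, **defaults)


@pytest.fixture
def small_layout():
    return [
        make_annotation("AAA_1_13"),
        make_annotation("BBB_10_22"),
        make_annotation("CCC_5_17"),
        make_annotation(
            DEFAULT_CONTROL_ID,
            sequence="EAIYAAPFAKKKXC",
            symbol="ART",
            phospho_positions=(4,),
        ),
    ]


@pytest.fixture
def small_dataset(small_layout):
    rng = np.random.default_rng(42)
    groups = {
        "control": rng.uniform(50, 150, size=(4, 3)),
        "test": rng.uniform(50, 150, size=(4, 3)),
    }
    groups["control"][1, 0] = -5.0  # exercise flooring
    return IntensityDataset(layout=small_layout, groups=groups)
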