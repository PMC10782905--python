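import numpy as np
import pytest

from nabind.backbone import BackboneConfig
from nabind.seqio import LabeledDataset, LabelTrack, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_records():
    return [
        ProteinRecord("p1", "MKRAACDEFG"),
        ProteinRecord("p2", "KKRYYALLVI"),
    ]


@pytest.fixture
def tiny_dataset(tiny_records):
    labels = [
        LabelTrack("p1", (0, 1, 1, 0, 0, 0, 0, 0, 0, 0)),
        LabelTrack("p2", (1, 1, 1, 0, 0, 0, 0, 0, 0, 1)),
    ]
    return LabeledDataset(tiny_records, labels)


@pytest.fixture
def small_backbone_cfg():
    return BackboneConfig(
        in_dim=6, layer_dims=(8, 6, 4, 2), kernel_sizes=(5, 3, 3, 3), dropout_rate=0.2
    )
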