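import numpy as np
import pytest

from nabind.model import FusionModel, ModelConfig, featurize, pad_batch
from nabind.plm import StubBackend
from nabind.records import ProteinRecord


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    return ModelConfig(
        plm_width=16,
        stream_width=16,
        refine_heads=2,
        backbone_layers=1,
        backbone_heads=2,
        ffn_width=32,
        head_hidden=(16,),
        dropout=0.0,
    )


@pytest.fixture()
def tiny_model(tiny_config) -> FusionModel:
    return FusionModel(tiny_config, seed=7).set_training(False)


@pytest.fixture(scope="session")
def stub16() -> StubBackend:
    return StubBackend(width=16, seed=0)


@pytest.fixture()
def sample_record() -> ProteinRecord:
    return ProteinRecord(
        "p1", "MKRWLAEHGTKRKYVQNDSP", residue_labels=np.zeros(20, dtype=int)
    )


@pytest.fixture()
def forward_args(sample_record, stub16):
    batch = pad_batch(featurize([sample_record], stub16))
    return batch["plm"], batch["atchley"], batch["blosum"], batch["mask"]
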