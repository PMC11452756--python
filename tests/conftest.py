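import pytest

from autoicd.icd import CodeSet
from autoicd.preprocess import CorpusRecord, make_document
from autoicd.synth import SynthConfig, generate_records


def to_records(rows) -> list[CorpusRecord]:
    """Turn raw corpus dicts into preprocessed, label-parsed records."""
    return [
        CorpusRecord(
            make_document(r["id"], r["text"]),
            CodeSet.from_strings(r["main_code"], r["other_codes"]),
        )
        for r in rows
    ]


@pytest.fixture(scope="session")
def tiny_splits():
    """A small 10-code synthetic corpus shared across model unit tests."""
    cfg = SynthConfig(n_docs=60, num_codes=10, seed=7, split_fracs=(0.8, 0.1, 0.1))
    splits, codebook = generate_records(cfg)
    return splits, codebook


@pytest.fixture(scope="session")
def tiny_train(tiny_splits):
    return to_records(tiny_splits[0]["train"])


@pytest.fixture(scope="session")
def tiny_val(tiny_splits):
    return to_records(tiny_splits[0]["val"])
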