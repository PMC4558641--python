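import datetime as dt
from pathlib import Path

import pytest

from exomereview.annotation import load_store
from exomereview.config import ProjectConfig
from exomereview.variant_io import VariantRecord, parse_variant_table
from exomereview.vocab import AnalysisType

DATA = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA


@pytest.fixture
def config() -> ProjectConfig:
    return ProjectConfig()


@pytest.fixture
def uros_record() -> VariantRecord:
    """The homozygous porphyria-causing missense from the recessive list."""
    records = parse_variant_table(
        DATA / "case_study_recessive.tsv", AnalysisType.RECESSIVE
    )
    assert len(records) == 1
    return records[0]


@pytest.fixture
def de_novo_records() -> list[VariantRecord]:
    """Five missense de novo changes, all of uncertain significance."""
    return parse_variant_table(DATA / "case_study_de_novo.tsv", AnalysisType.DE_NOVO)


@pytest.fixture
def case_study_store():
    return load_store(DATA / "case_study_store.tsv")


@pytest.fixture
def deadline() -> dt.date:
    return dt.date.today() + dt.timedelta(days=14)
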