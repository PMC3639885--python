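import pytest

from cardiolift import builtin_units, read_legacy_table

# the worked first data row of the legacy sheet
WORKED_ROW_CSV = (
    "SBP,DBP,TOTALCHOL,HDL,TG,AGE,GENDER,HEIGHT,WEIGHT,"
    "TG GR,HDL GR,LDL GR,CHOL GR,BMI GR,DBP GR,SBP GR,RISK GR\n"
    "128,80.1,227,55,84,77,M,1.8288,78.1818,0,0,0,1,0,0,0,1\n"
)

WORKED_ROW_FLAGS = {"TG": 0, "HDL": 0, "LDL": 0, "CHOL": 1, "BMI": 0,
                    "DBP": 0, "SBP": 0}


@pytest.fixture(scope="session")
def registry():
    return builtin_units()


@pytest.fixture()
def worked_row_csv():
    return WORKED_ROW_CSV


@pytest.fixture()
def worked_record(registry):
    return read_legacy_table(WORKED_ROW_CSV, registry=registry)[0]
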