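import datetime as dt

import numpy as np
import pandas as pd
import pytest

import tempovar as tv


@pytest.fixture
def toy_csv(tmp_path):
    """Six records, two months, one categorical and one numeric column."""
    path = tmp_path / "records.csv"
    path.write_text(
        "date,dx,age\n"
        "1998-10-21,780.9,10\n"
        "1998-10-02,296.2,12\n"
        "1998-10-30,780.9,11\n"
        "1998-11-05,780.9,9\n"
        "1998-11-17,296.2,14\n"
        "1998-11-28,300.0,13\n"
    )
    return path


@pytest.fixture
def toy_table(toy_csv):
    # ICD-style codes are numeric strings, so categorical must be explicit
    return tv.read_table(toy_csv, date_column="date",
                         treatments={"dx": "categorical"})


@pytest.fixture
def toy_dtm(toy_table):
    return tv.estimate_data_temporal_map(toy_table, "dx", granularity="month")


def make_table(dates, values, column="dx", treatment="categorical"):
    """Build a RawClinicalTable directly from parallel date/value lists."""
    df = pd.DataFrame({"date": pd.to_datetime(dates), column: values})
    if treatment != "categorical":
        df[column] = df[column].astype(float)
    else:
        df[column] = df[column].astype(object)
    return tv.RawClinicalTable(
        data=df, date_column="date", variables={column: treatment}
    )


def random_prob_vector(rng, k):
    v = rng.random(k) + 1e-12
    return v / v.sum()
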