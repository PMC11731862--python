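import numpy as np
import pandas as pd
import pytest

from lookalike.harmonization import default_schema, load_rules
from lookalike.schema import HarmonizedTable, Schema, VariableSchema
from lookalike.synthetic import OutcomeModel, builtin_profile


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def default_rules():
    rules, filters = load_rules()
    return {r.target: r for r in rules}, filters


@pytest.fixture(scope="session")
def csew_profile():
    return builtin_profile("csew")


@pytest.fixture(scope="session")
def rcew_profile():
    return builtin_profile("rcew")


@pytest.fixture
def tiny_schema():
    return Schema(
        [
            VariableSchema("x", "continuous"),
            VariableSchema("g", "binary", categories=("a", "b"), reference="a"),
            VariableSchema("y", "continuous"),
        ]
    )


@pytest.fixture
def gaussian_outcome_model():
    return OutcomeModel(
        outcome="y",
        family="gaussian",
        predictors=["sv_type", "perpetrator", "gender", "age"],
        beta={
            "Intercept": 40.0,
            "sv_type[rape]": -2.0,
            "perpetrator[acquaintance]": 0.5,
            "perpetrator[stranger_unknown]": -1.5,
            "gender[male]": 3.0,
            "age": 0.1,
        },
        sigma2=25.0,
    )


def make_table(data: dict, schema: Schema, mask: dict | None = None) -> HarmonizedTable:
    df = pd.DataFrame(data)
    if mask is None:
        return HarmonizedTable(data=df, schema=schema)
    mdf = pd.DataFrame(mask, index=df.index).astype(bool)
    return HarmonizedTable(data=df.where(mdf), schema=schema, mask=mdf)
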