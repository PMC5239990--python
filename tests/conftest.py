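import numpy as np
import pandas as pd
import pytest

from roughrelief.table import MISSING, DecisionTable


def make_decision_table(columns: dict, kinds: dict, decision: str = "class") -> DecisionTable:
    """Build a DecisionTable from plain python lists (test helper)."""
    data = {}
    for name, values in columns.items():
        if name != decision and kinds.get(name) == "real":
            data[name] = pd.Series(
                [np.nan if v is None else float(v) for v in values], dtype=float
            )
        else:
            data[name] = pd.Series(
                [MISSING if v is None else v for v in values], dtype=object
            )
    return DecisionTable(pd.DataFrame(data), decision, kinds)


@pytest.fixture
def five_object_table():
    """5 objects, one binary attribute (0,0,1,1,1), decision (0,1,1,1,1)."""
    return make_decision_table(
        {"x": [0, 0, 1, 1, 1], "class": [0, 1, 1, 1, 1]},
        {"x": "nominal"},
    )


@pytest.fixture
def missing_toy_table():
    """Class '+' has known A values (y, y, y, x); two instances have A missing."""
    return make_decision_table(
        {
            "A": ["y", "y", "y", "x", None, "y", "x", None],
            "class": ["+", "+", "+", "+", "+", "-", "-", "-"],
        },
        {"A": "nominal"},
    )


@pytest.fixture
def statlog_like_file(tmp_path):
    """A synthetic flat file in the Statlog (Heart) 14-column layout."""
    from roughrelief.synthetic import make_statlog_like

    table = make_statlog_like(60, seed=5)
    lines = []
    for _, row in table.data.iterrows():
        fields = [str(float(row[f"C{i}"])) for i in range(1, 14)]
        fields.append("2.0" if row["class"] == "presence" else "1.0")
        lines.append(" ".join(fields))
    path = tmp_path / "heart.dat"
    path.write_text("\n".join(lines) + "\n")
    return path, table
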