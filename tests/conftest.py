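import numpy as np
import pandas as pd
import pytest

from mgmwas.profile_io import AbundanceTable, SampleMetadata


def make_table(rows: dict[str, list[float]], samples=None, **kw) -> AbundanceTable:
    """Build an AbundanceTable from {feature: values} with auto sample ids."""
    n = len(next(iter(rows.values())))
    samples = samples or [f"S{i + 1}" for i in range(n)]
    return AbundanceTable(pd.DataFrame(rows, index=samples).T, **kw)


def make_metadata(groups: dict[str, str], **columns) -> SampleMetadata:
    df = pd.DataFrame({"group": pd.Series(groups)})
    for name, values in columns.items():
        df[name] = pd.Series(values)
    df.index.name = "sample"
    return SampleMetadata(df)


@pytest.fixture
def two_group_metadata():
    rng = np.random.default_rng(0)
    groups = {f"MG{i:02d}": "case" for i in range(10)}
    groups.update({f"HC{i:02d}": "control" for i in range(10)})
    return make_metadata(groups, achrab={s: (2.0 if s.startswith("MG") and i % 2 == 0 else 0.1)
                                         for i, s in enumerate(groups)})
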