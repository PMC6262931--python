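import pandas as pd
import pytest

from copelink.gut import load_reference_incidence


@pytest.fixture(scope="session")
def reference_diet():
    """Packaged diet-incidence matrix, condition map and taxonomy."""
    return load_reference_incidence()


def incidence_matches(found: pd.DataFrame, planted: pd.DataFrame) -> bool:
    """True when two incidence matrices agree up to OTU relabelling.

    Columns that are all-zero in the planted matrix (OTUs never drawn)
    are ignored.
    """
    planted = planted.loc[:, planted.sum(axis=0) > 0]
    found = found.reindex(index=planted.index, fill_value=0)
    return sorted(map(tuple, found.T.values.tolist())) == sorted(
        map(tuple, planted.T.values.tolist())
    )
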