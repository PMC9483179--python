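import numpy as np
import pandas as pd
import pytest

from lactgwas.pedigree import trace_and_sort


@pytest.fixture
def toy_pedigree():
    """Five animals: two founders, their two offspring, one full-sib mating."""
    return trace_and_sort(
        pd.DataFrame(
            {
                "animal_id": [1, 2, 3, 4, 5],
                "sire_id": [0, 0, 1, 1, 3],
                "dam_id": [0, 0, 2, 2, 4],
                "birth_year": [2000, 2000, 2001, 2001, 2002],
            }
        )
    )


@pytest.fixture
def record_frame():
    """Small hand-built test-day record set with known filter outcomes."""
    def rec(cow, dim, my=30.0, fp=4.0, pp=3.2, scc=150.0, birth="2000-01-10",
            calving="2002-02-20", herd="H1"):
        calv = pd.Timestamp(calving)
        return {
            "cow_id": cow, "herd": herd,
            "test_date": (calv + pd.Timedelta(days=dim)).strftime("%Y-%m-%d"),
            "calving_date": calving, "birth_date": birth, "dim": dim,
            "my_kg": my, "fp_pct": fp, "pp_pct": pp, "scc_kcells_per_ml": scc,
            "fy_kg": np.nan, "py_kg": np.nan, "scs": np.nan,
        }
    return rec
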