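import numpy as np
import pandas as pd
import pytest

from gxescreen.cohort import CohortTable, SnpInfo
from gxescreen.simulate import generate_study_fixture

RS10757274 = SnpInfo("rs10757274", "G", "A")
RS6903956 = SnpInfo("rs6903956", "A", "G")


@pytest.fixture(scope="session")
def study_cohort() -> CohortTable:
    """One study-shaped synthetic cohort (502 cases / 308 controls)."""
    return generate_study_fixture(1)


def cohort_from_cells(
    cells: dict[tuple[int, int], tuple[int, int]],
    snp: SnpInfo = RS10757274,
    exposure: str = "t2dm",
) -> CohortTable:
    """Build a subject-level cohort from (carrier, exposed) -> (controls, cases).

    Carrier subjects get the heterozygote genotype; non-carriers the
    reference homozygote.  Used to turn printed contingency tables into
    analysable cohorts.
    """
    ref_hom, het, _ = snp.genotype_strings()
    rows = []
    for (g, e), (n_ctrl, n_case) in cells.items():
        for status, n in ((0, n_ctrl), (1, n_case)):
            for _ in range(n):
                rows.append(
                    {
                        "status": status,
                        snp.name: het if g else ref_hom,
                        exposure: float(e),
                    }
                )
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", [f"X{i}" for i in range(len(df))])
    return CohortTable(df, [snp])
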