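import numpy as np
import pandas as pd
import pytest

from itemcount import ResponseModelConfig, default_design, generate_cohort


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def noiseless_cohort(design):
    """Medium cohort with no misreporting or miscount noise."""
    return generate_cohort(4000, design, ResponseModelConfig(seed=11))


@pytest.fixture(scope="session")
def misreport_cohort(design):
    """Cohort where direct answers are socially biased but list answers
    are truthful (the regime list randomization is meant to fix)."""
    cfg = ResponseModelConfig(lambda_direct=0.3, lambda_list=0.0, seed=12)
    return generate_cohort(20000, design, cfg)


@pytest.fixture()
def tiny_canonical(design):
    """Hand-written 5-row canonical table: 3 Arm A, 2 Arm B respondents."""
    J = design.n_controls
    rows = []
    for i, (arm, stratum, thn, tref) in enumerate([
        ("A", "negative", 1, 0),
        ("A", "pos_linked", 0, 0),
        ("A", "refused", "", 1),
        ("B", "negative", 1, 0),
        ("B", "pos_unlinked", 0, 0),
    ]):
        row = {
            "respondent_id": f"r{i:06d}", "arm": arm, "stratum": stratum,
            "truth_hiv_negative": thn, "truth_refused": tref,
            "truth_brushed_teeth": 1, "truth_used_condom": 0, "truth_anal_sex": 0,
        }
        for b in design.block_ids:
            if arm == "A":
                row[f"count_block{b}"] = (i + b) % (J + 2)
                row[f"pos_block{b}"] = 1 + (i + b) % (J + 1)
            else:
                for k in range(1, J + 1):
                    row[f"ctrl_b{b}_i{k}"] = (i + b + k) % 2
                row[f"direct_b{b}"] = (i + b) % 2
        rows.append(row)
    return pd.DataFrame(rows)
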