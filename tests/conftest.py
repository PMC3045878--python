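"""Shared fixtures: published summary counts and small synthetic substrates."""

from __future__ import annotations

import pytest

from aiscreen.imbalance import AICall, BALANCED, LOSS_NEUTRAL, LOSS_RISK

# Published per-locus allelic-imbalance summaries for seven colorectal-cancer
# risk loci: (snp_id, n_informative, loss_neutral, loss_risk,
#             printed percent imbalanced, printed two-sided binomial P)
AI_LOCUS_TABLE = [
    ("rs4779584", 87, 8, 9, 20, "1.00"),
    ("rs10795668", 90, 6, 6, 13, "1.00"),
    ("rs3802842", 89, 4, 5, 10, "1.00"),
    ("rs4444235", 90, 7, 10, 19, "0.63"),
    ("rs9929218", 90, 6, 4, 11, "0.75"),
    ("rs10411210", 174, 10, 5, 9, "0.30"),
    ("rs961253", 88, 11, 16, 31, "0.44"),
]

# Published association rows reproducible from 3-decimal MAFs alone:
# (snp_id, maf_controls, maf_cases, printed OR)
OR_FROM_MAF_TABLE = [
    ("rs11631292", 0.123, 0.108, "1.16"),
    ("rs17485426", 0.129, 0.137, "1.07"),
    ("rs1999638", 0.123, 0.136, "1.12"),
    ("rs34812868", 0.431, 0.402, "1.13"),
    ("rs12893484", 0.384, 0.414, "1.13"),
    ("rs35614970", 0.705, 0.741, "1.20"),
]

# Rows where counts reconstructed from MAF x 2n also reproduce CI and P:
# (snp_id, maf_cases, maf_controls, n_cases, n_controls, CI_low, CI_high, P)
CI_P_TABLE = [
    ("rs34812868", 0.402, 0.431, 913, 821, "0.99", "1.29", "0.08"),
    ("rs12893484", 0.414, 0.384, 1010, 824, "0.99", "1.29", "0.07"),
]


def make_calls(n_loss_neutral: int, n_loss_risk: int, n_balanced: int) -> list[AICall]:
    """Synthesise AI calls with the requested composition (ratios are nominal)."""
    thresholds = (0.6, 1.67)
    return (
        [AICall(2.0, LOSS_NEUTRAL, thresholds)] * n_loss_neutral
        + [AICall(0.5, LOSS_RISK, thresholds)] * n_loss_risk
        + [AICall(1.0, BALANCED, thresholds)] * n_balanced
    )


@pytest.fixture(scope="session")
def ai_locus_table():
    return AI_LOCUS_TABLE


@pytest.fixture(scope="session")
def or_from_maf_table():
    return OR_FROM_MAF_TABLE


@pytest.fixture(scope="session")
def ci_p_table():
    return CI_P_TABLE
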