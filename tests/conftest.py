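import pytest

from emrcea import build_arm_tree, default_parameters, rollback


@pytest.fixture(scope="session")
def table():
    return default_parameters()


@pytest.fixture(scope="session")
def base_outcomes(table):
    return {arm: rollback(build_arm_tree(table, arm)) for arm in ("EMR", "NGEMR")}


def closed_form_outcome(v: dict):
    """Independent algebraic marginalization of the care pathway.

    Derived by summing over the strata directly instead of walking a tree:
    the expected cost is the entry (NUP) cost, plus — among attendees — the
    duplicate-mixed SOC cost and the admission risk, plus — among
    non-attendees — the combined ED-and-admission risk; QALYs interpolate the
    two utilities by the overall admission probability.
    """
    p_att = v["p_wait_lt20"] * v["p_attend_lt20"] + (1 - v["p_wait_lt20"]) * v["p_attend_ge20"]
    e_soc = v["c_soc_visit"] + v["p_duplicate"] * (
        v["c_soc_visit_duplicate"] - v["c_soc_visit"]
    )
    p_admit = p_att * v["p_admission"] + (1 - p_att) * v["p_ed_admission"]
    cost = (
        v["c_nup_visit"]
        + p_att * (e_soc + v["p_admission"] * v["c_admission"])
        + (1 - p_att) * v["p_ed_admission"] * (v["c_ed_visit"] + v["c_admission"])
    )
    qalys = v["u_nonadmitted"] - p_admit * (v["u_nonadmitted"] - v["u_admitted"])
    return cost, qalys, p_admit
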