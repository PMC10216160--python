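import numpy as np
import pandas as pd
import pytest

from bntvbm.item_scoring import (
    ADMINISTERED_ITEMS,
    NormTable,
    Outcome,
    ParticipantRecord,
    load_default_frequencies,
    load_default_norms,
)


@pytest.fixture(scope="session")
def norms():
    return load_default_norms()


@pytest.fixture(scope="session")
def frequencies():
    return load_default_frequencies()


def make_record(
    correct=(), cued=(), missing=(), participant_id="P001", group="control",
    age=75.0, education=16.0, sex="F",
):
    """Record with the given items correct/cued/missing, all else incorrect."""
    outcomes = {}
    for item in ADMINISTERED_ITEMS:
        if item in missing:
            outcomes[item] = Outcome.MISSING
        elif item in correct:
            outcomes[item] = Outcome.CORRECT_FIRST_ATTEMPT
        elif item in cued:
            outcomes[item] = Outcome.CORRECT_AFTER_CUE
        else:
            outcomes[item] = Outcome.INCORRECT
    return ParticipantRecord(
        participant_id=participant_id, group=group, age=age,
        education=education, sex=sex, outcomes=outcomes,
    )


def spearman_classic(x, y):
    """Independent Spearman oracle: mid-rank assignment by hand, then the
    Pearson product-moment correlation of the ranks."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
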