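"""Item-level scoring of the 30-item (odd trials) Boston Naming Test.

Each administered item is classified from its raw response code and scored
against a normative table of sensorimotor-interaction (SMI) ratings.  Two
per-participant scores are derived:

* a *quantitative* score — the count of items named correctly on the first
  attempt among the 27 items that carry an SMI norm, and
* a *qualitative* score — the arithmetic mean of the SMI values of those
  correctly named items (lower means indicate success on harder, low-SMI
  words).

The module also computes per-item group summaries: proportion correct per
diagnostic group, 2x2 chi-square group contrasts, and the Spearman rank
correlation between SMI and per-item naming frequency.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Outcome",
    "NormTable",
    "ParticipantRecord",
    "ScorePair",
    "load_norm_table",
    "load_default_norms",
    "load_default_frequencies",
    "read_responses",
    "write_scores",
    "clean_cohort",
    "score_participant",
    "score_cohort",
    "item_proportions",
    "smi_difficulty_correlation",
    "group_item_test",
    "N_CONTROL",
    "N_MCI",
]

#: Group sizes of the reference cohorts behind the packaged naming-frequency
#: table (controls / MCI after all exclusions).
N_CONTROL = 197
N_MCI = 350

ADMINISTERED_ITEMS = tuple(range(1, 60, 2))  # the 30 odd trials

#: Raw response-code dialect (mirrors the ADNI item-level spreadsheet).
CODE_INCORRECT = 0
CODE_CORRECT = 1
CODE_CUED = 2
CODE_MISSING = 999


class Outcome(enum.Enum):
    """Outcome of a single naming trial.

    Cued successes are kept distinct in the raw representation but are
    collapsed into "incorrect" for scoring: only first-attempt successes
    count as correct.
    """

    CORRECT_FIRST_ATTEMPT = "correct_first_attempt"
    CORRECT_AFTER_CUE = "correct_after_cue"
    INCORRECT = "incorrect"
    MISSING = "missing"

    @classmethod
    def from_code(cls, code: int) -> "Outcome":
        try:
            return _CODE_MAP[int(code)]
        except (KeyError, ValueError):
            raise ValueError(f"unrecognised response code {code!r}") from None

    def to_code(self) -> int:
        return _OUTCOME_CODES[self]


_CODE_MAP = {
    CODE_INCORRECT: Outcome.INCORRECT,
    CODE_CORRECT: Outcome.CORRECT_FIRST_ATTEMPT,
    CODE_CUED: Outcome.CORRECT_AFTER_CUE,
    CODE_MISSING: Outcome.MISSING,
}
_OUTCOME_CODES = {v: k for k, v in _CODE_MAP.items()}


@dataclass(frozen=True)
class NormTable:
    """Normative SMI table for the administered items.

    ``smi`` holds NaN for items without a norm; only items with a valid SMI
    value ("scoreable" items) enter the quantitative and qualitative scores.
    """

    df: pd.DataFrame  # columns: item_id (index), word, smi

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicate item_id(s): {dupes}")
        if not all(int(i) % 2 == 1 for i in df.index):
            raise ValueError("item_ids must be odd trial numbers")
        smi = df["smi"].dropna()
        if ((smi < 1.0) | (smi > 7.0)).any():
            bad = smi[(smi < 1.0) | (smi > 7.0)]
            raise ValueError(f"SMI out of [1, 7]: {bad.to_dict()}")

    @property
    def item_ids(self) -> list[int]:
        return [int(i) for i in self.df.index]

    @property
    def scoreable_items(self) -> list[int]:
        """Items carrying an SMI norm, in table order."""
        return [int(i) for i in self.df.index[self.df["smi"].notna()]]

    @property
    def smi(self) -> pd.Series:
        """SMI values of the scoreable items, indexed by item_id."""
        return self.df["smi"].dropna()

    def word(self, item_id: int) -> str:
        return str(self.df.loc[item_id, "word"])

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ParticipantRecord:
    """One participant: demographics, diagnostic group, per-item outcomes."""

    participant_id: str
    group: str  # "control" | "mci"
    age: float
    education: float
    sex: str  # "F" | "M", descriptive only
    outcomes: dict[int, Outcome]

    def __post_init__(self) -> None:
        if self.group not in ("control", "mci"):
            raise ValueError(f"unknown group {self.group!r}")
        missing = set(ADMINISTERED_ITEMS) - set(self.outcomes)
        extra = set(self.outcomes) - set(ADMINISTERED_ITEMS)
        if missing or extra:
            raise ValueError(
                f"outcomes must cover exactly the administered items; "
                f"missing={sorted(missing)}, extra={sorted(extra)}"
            )

    def n_missing(self) -> int:
        return sum(1 for o in self.outcomes.values() if o is Outcome.MISSING)

    def correct_items(self, norms: NormTable) -> list[int]:
        """Scoreable items named correctly on the first attempt."""
        return [
            i
            for i in norms.scoreable_items
            if self.outcomes[i] is Outcome.CORRECT_FIRST_ATTEMPT
        ]


@dataclass(frozen=True)
class ScorePair:
    """Quantitative count and qualitative (mean-SMI) score.

    ``qualitative`` is None when fewer than two scoreable items were named
    correctly: a mean over fewer than two items is not treated as a score.
    """

    quantitative: int
    qualitative: float | None


# ---------------------------------------------------------------------------
# Norm-table and response I/O


def load_norm_table(source) -> NormTable:
    """Read a delimited norm table with columns item_id, word, smi.

    An empty smi field marks an item without a norm. Duplicate item_ids and
    SMI values outside [1, 7] are rejected.
    """
    df = pd.read_csv(source, sep="\t", dtype={"word": str})
    required = {"item_id", "word", "smi"}
    if not required.issubset(df.columns):
        raise ValueError(f"norm table needs columns {sorted(required)}")
    df["smi"] = pd.to_numeric(df["smi"], errors="coerce")
    df = df.set_index(df["item_id"].astype(int))[["word", "smi"]]
    return NormTable(df)


def load_default_norms() -> NormTable:
    """The packaged 30-item norm table (27 items with SMI values)."""
    ref = importlib.resources.files("bntvbm.data") / "bnt_smi_norms.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_norm_table(path)


def load_default_frequencies() -> pd.DataFrame:
    """Packaged per-item naming frequencies of the two reference sub-cohorts.

    Columns ``prop_control`` / ``prop_mci`` give, for each of the 27
    scoreable items, the proportion of each group naming it correctly on the
    first attempt (group sizes ``N_CONTROL`` / ``N_MCI``).
    """
    ref = importlib.resources.files("bntvbm.data") / "naming_frequencies.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df.set_index(df["item_id"].astype(int))[["prop_control", "prop_mci"]]


def read_responses(source) -> list[ParticipantRecord]:
    """Read a delimited response table into participant records.

    Expected columns: participant_id, group, age, education, sex, then one
    ``item_<k>`` column per administered item with codes 1 (correct first
    attempt), 2 (correct after cue), 0 (incorrect), 999 (missing).
    """
    df = pd.read_csv(source, sep="\t")
    records = []
    for _, row in df.iterrows():
        outcomes = {
            i: Outcome.from_code(row[f"item_{i:02d}"]) for i in ADMINISTERED_ITEMS
        }
        records.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                education=float(row["education"]),
                sex=str(row["sex"]),
                outcomes=outcomes,
            )
        )
    return records


def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Inverse of :func:`read_responses` (used by the simulator's writer)."""
    rows = []
    for r in records:
        row: dict = {
            "participant_id": r.participant_id,
            "group": r.group,
            "age": r.age,
            "education": r.education,
            "sex": r.sex,
        }
        for i in ADMINISTERED_ITEMS:
            row[f"item_{i:02d}"] = r.outcomes[i].to_code()
        rows.append(row)
    return pd.DataFrame(rows)


def write_scores(
    records: Sequence[ParticipantRecord],
    scores: Sequence[ScorePair | None],
    reasons: Mapping[str, str],
    path,
) -> None:
    """Write participant_id, group, quantitative, qualitative, excluded_reason."""
    rows = []
    for r, s in zip(records, scores):
        rows.append(
            {
                "participant_id": r.participant_id,
                "group": r.group,
                "quantitative": "" if s is None else s.quantitative,
                "qualitative": ""
                if s is None or s.qualitative is None
                else f"{s.qualitative:.6f}",
                "excluded_reason": reasons.get(r.participant_id, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Scoring


def score_participant(record: ParticipantRecord, norms: NormTable) -> ScorePair:
    """Score one participant against the norm table.

    Only first-attempt successes on SMI-valid items count; cued successes
    and outcomes on the SMI-less items contribute to neither score.  The
    record must have no missing outcomes (clean first).
    """
    if record.n_missing():
        raise ValueError(
            f"participant {record.participant_id} has missing outcomes; "
            "run clean_cohort first"
        )
    correct = record.correct_items(norms)
    quantitative = len(correct)
    if quantitative < 2:
        return ScorePair(quantitative=quantitative, qualitative=None)
    qualitative = float(norms.smi.loc[correct].mean())
    return ScorePair(quantitative=quantitative, qualitative=qualitative)


def clean_cohort(
    records: Iterable[ParticipantRecord],
    norms: NormTable | None = None,
) -> tuple[list[ParticipantRecord], list[tuple[ParticipantRecord, str]]]:
    """Apply the two exclusion rules, preserving order of kept records.

    First drop any record with one or more missing item outcomes
    (``missing_items``); then drop records with fewer than two first-attempt
    successes on scoreable items (``too_few_correct``), for which no
    qualitative score exists.
    """
    if norms is None:
        norms = load_default_norms()
    kept: list[ParticipantRecord] = []
    dropped: list[tuple[ParticipantRecord, str]] = []
    for rec in records:
        if rec.n_missing() > 0:
            dropped.append((rec, "missing_items"))
        elif len(rec.correct_items(norms)) < 2:
            dropped.append((rec, "too_few_correct"))
        else:
            kept.append(rec)
    return kept, dropped


def score_cohort(
    records: Sequence[ParticipantRecord], norms: NormTable | None = None
) -> pd.DataFrame:
    """Score a cleaned cohort; returns a per-participant frame."""
    if norms is None:
        norms = load_default_norms()
    rows = []
    for rec in records:
        pair = score_participant(rec, norms)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "group": rec.group,
                "age": rec.age,
                "education": rec.education,
                "sex": rec.sex,
                "quantitative": pair.quantitative,
                "qualitative": pair.qualitative,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-item group summaries


def item_proportions(
    records: Sequence[ParticipantRecord], norms: NormTable | None = None
) -> pd.DataFrame:
    """Per-item proportion of each group naming the item correctly.

    Returns a frame indexed by item_id with one ``prop_<group>`` column per
    group present, plus ``n_<group>`` group sizes.
    """
    if norms is None:
        norms = load_default_norms()
    groups = sorted({r.group for r in records})
    if not groups:
        raise ValueError("empty cohort")
    out = pd.DataFrame(index=pd.Index(norms.scoreable_items, name="item_id"))
    for g in groups:
        members = [r for r in records if r.group == g]
        if not members:
            raise ValueError(f"empty group {g!r}")
        props = []
        for item in norms.scoreable_items:
            n_correct = sum(
                1
                for r in members
                if r.outcomes[item] is Outcome.CORRECT_FIRST_ATTEMPT
            )
            props.append(n_correct / len(members))
        out[f"prop_{g}"] = props
        out[f"n_{g}"] = len(members)
    return out


def smi_difficulty_correlation(
    norms: NormTable, proportions: pd.Series | Sequence[float]
) -> float:
    """Spearman rho between SMI and per-item proportion correct.

    Average (mid-rank) ranks are assigned to ties.  ``proportions`` must be
    aligned with the norm table's scoreable items (a Series indexed by
    item_id, or a sequence in scoreable-item order).  Returns NaN when either
    variable has zero rank variance.
    """
    smi = norms.smi
    if isinstance(proportions, pd.Series):
        props = proportions.reindex(smi.index)
        if props.isna().any():
            raise ValueError("proportions missing for some scoreable items")
        props = props.to_numpy(float)
    else:
        props = np.asarray(proportions, dtype=float)
        if len(props) != len(smi):
            raise ValueError(
                f"expected {len(smi)} proportions, got {len(props)}"
            )
    if len(smi) < 3:
        raise ValueError("need at least 3 (smi, proportion) pairs")
    if np.ptp(props) == 0 or np.ptp(smi.to_numpy()) == 0:
        return float("nan")  # zero rank variance: correlation undefined
    rho = stats.spearmanr(smi.to_numpy(), props).statistic
    return float(rho)


def group_item_test(
    prop_a: float, n_a: int, prop_b: float, n_b: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Counts are reconstructed by rounding proportion x n to the nearest
    integer.  When both proportions equal 1.0 there is nothing to test and
    ``(nan, nan)`` is returned ("not assessed").
    """
    for p, n in ((prop_a, n_a), (prop_b, n_b)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
        if n <= 0:
            raise ValueError(f"group size {n} must be positive")
    if prop_a == 1.0 and prop_b == 1.0:
        return (float("nan"), float("nan"))
    a = round(prop_a * n_a)
    b = round(prop_b * n_b)
    if not (0 <= a <= n_a and 0 <= b <= n_b):
        raise ValueError("reconstructed count outside [0, n]")
    table = np.array([[a, n_a - a], [b, n_b - b]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return (float(chi2), float(p))


def item_summary_table(
    proportions: pd.DataFrame, norms: NormTable | None = None
) -> pd.DataFrame:
    """Per-item summary mirroring the packaged frequency table's layout.

    Expects the output of :func:`item_proportions` for a two-group cohort
    with groups ``control`` and ``mci``; appends the chi-square contrast.
    """
    if norms is None:
        norms = load_default_norms()
    out = proportions.copy()
    out.insert(0, "word", [norms.word(i) for i in out.index])
    out.insert(1, "smi", norms.smi.reindex(out.index).to_numpy())
    chi2s, ps = [], []
    for item in out.index:
        chi2, p = group_item_test(
            out.loc[item, "prop_control"],
            int(out.loc[item, "n_control"]),
            out.loc[item, "prop_mci"],
            int(out.loc[item, "n_mci"]),
        )
        chi2s.append(chi2)
        ps.append(p)
    out["chi2"] = chi2s
    out["p"] = ps
    return out
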