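"""Inter-rater reliability of binary expert assessments.

Three physiotherapists independently mark each subject's execution of a
functional test against 15 binary error parameters (1 = error present,
"faulty"; 0 = absent).  Agreement per parameter is quantified with
Fleiss's kappa; consensus labels come from a per-subject majority vote.
Parameters enter classification only when kappa reaches at least 0.41
(moderate agreement) *and* the consensus minority class holds at least 8
subjects — without both, no trustworthy reference standard exists.

When every rating in a table is identical, both observed and chance
agreement equal one and the kappa formula degenerates to 0/0; the
complete-agreement convention returns 1.0 in that case.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .errors import ConfigurationError, MissingRatingsError

DEFAULT_KAPPA_MIN = 0.41
DEFAULT_MIN_MINORITY = 8

_REFERENCE_RESOURCE = "expert_agreement.tsv"


@dataclass
class RatingTable:
    """Complete subjects x raters x parameters binary assessments."""

    ratings: np.ndarray  # (n_subjects, n_raters, n_parameters) in {0, 1}
    subjects: list[str]
    raters: list[str]
    parameters: list[str]

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=int)
        expected = (len(self.subjects), len(self.raters), len(self.parameters))
        if self.ratings.shape != expected:
            raise ValueError(
                f"ratings shape {self.ratings.shape} != ids {expected}"
            )
        if not np.isin(self.ratings, (0, 1)).all():
            raise MissingRatingsError("ratings must be binary 0/1 with no gaps")

    def for_parameter(self, parameter: str) -> np.ndarray:
        """(subjects x raters) slice for one parameter."""
        return self.ratings[:, :, self.parameters.index(parameter)]

    def to_long(self) -> pd.DataFrame:
        s, r, p = self.ratings.shape
        return pd.DataFrame({
            "subject_id": np.repeat(self.subjects, r * p),
            "rater_id": np.tile(np.repeat(self.raters, p), s),
            "parameter": np.tile(self.parameters, s * r),
            "rating": self.ratings.reshape(-1),
        })

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "RatingTable":
        subjects = sorted(df["subject_id"].astype(str).unique())
        raters = sorted(df["rater_id"].astype(str).unique())
        parameters = list(pd.unique(df["parameter"].astype(str)))
        arr = np.full((len(subjects), len(raters), len(parameters)), -1, dtype=int)
        si = {s: i for i, s in enumerate(subjects)}
        ri = {r: i for i, r in enumerate(raters)}
        pi = {p: i for i, p in enumerate(parameters)}
        for row in df.itertuples(index=False):
            arr[si[str(row.subject_id)], ri[str(row.rater_id)],
                pi[str(row.parameter)]] = int(row.rating)
        if (arr < 0).any():
            raise MissingRatingsError(
                "rating table incomplete: some subject/rater/parameter cells absent"
            )
        return cls(arr, subjects, raters, parameters)

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        return cls.from_long(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Fleiss's kappa
# ---------------------------------------------------------------------------

def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss's kappa for one parameter's (subjects x raters) binary ratings.

    Delegates the generic statistic to statsmodels and adds the
    complete-agreement convention: a table in which every rating is the
    same category returns 1.0 (the formula's 0/0 case).

    Raises
    ------
    MissingRatingsError
        On non-binary or incomplete input, or fewer than 2 subjects/raters.
    """
    arr = np.asarray(ratings)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise MissingRatingsError(
            f"need a complete table of >=2 subjects x >=2 raters, got {arr.shape}"
        )
    if np.isnan(np.asarray(arr, dtype=float)).any():
        raise MissingRatingsError("rating table contains missing cells")
    arr = arr.astype(int)
    if not np.isin(arr, (0, 1)).all():
        raise MissingRatingsError("ratings must be binary 0/1")
    if (arr == arr.flat[0]).all():
        return 1.0  # complete agreement: observed == chance == 1
    pos = arr.sum(axis=1)
    table = np.column_stack([arr.shape[1] - pos, pos])
    return float(_sm_fleiss_kappa(table, method="fleiss"))


def consensus_labels(
    ratings: np.ndarray,
    tie_rule: str | None = None,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Majority-vote consensus per subject plus (faulty, non_faulty) counts.

    With an even number of raters a ``tie_rule`` ("faulty" or
    "non_faulty") must be configured; with odd raters ties cannot occur.
    """
    arr = np.asarray(ratings, dtype=int)
    n_raters = arr.shape[1]
    if n_raters % 2 == 0 and tie_rule is None:
        raise ConfigurationError(
            f"{n_raters} raters: even panel needs an explicit tie_rule"
        )
    if tie_rule not in (None, "faulty", "non_faulty"):
        raise ConfigurationError(f"unknown tie_rule {tie_rule!r}")
    pos = arr.sum(axis=1)
    labels = (pos * 2 > n_raters).astype(int)
    if tie_rule == "faulty":
        labels[pos * 2 == n_raters] = 1
    faulty = int(labels.sum())
    return labels, (faulty, len(labels) - faulty)


# ---------------------------------------------------------------------------
# Agreement report and the eligibility gate
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Per-parameter kappa, consensus-class frequencies and eligibility.

    ``frame`` columns: parameter, kappa, faulty, non_faulty, eligible.
    """

    frame: pd.DataFrame
    kappa_min: float = DEFAULT_KAPPA_MIN
    min_minority: int = DEFAULT_MIN_MINORITY
    consensus: dict[str, np.ndarray] = field(default_factory=dict)

    def eligible_parameters(self) -> list[str]:
        return list(self.frame.loc[self.frame["eligible"], "parameter"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _gate(kappa: float, faulty: int, non_faulty: int,
          kappa_min: float, min_minority: int) -> bool:
    return bool(kappa >= kappa_min and min(faulty, non_faulty) >= min_minority)


def build_report(
    table: RatingTable,
    kappa_min: float = DEFAULT_KAPPA_MIN,
    min_minority: int = DEFAULT_MIN_MINORITY,
    tie_rule: str | None = None,
) -> AgreementReport:
    """Kappa, consensus counts and the eligibility gate for every parameter."""
    rows = []
    consensus = {}
    for p in table.parameters:
        r = table.for_parameter(p)
        kappa = fleiss_kappa(r)
        labels, (faulty, non_faulty) = consensus_labels(r, tie_rule)
        consensus[p] = labels
        rows.append({
            "parameter": p,
            "kappa": kappa,
            "faulty": faulty,
            "non_faulty": non_faulty,
            "eligible": _gate(kappa, faulty, non_faulty, kappa_min, min_minority),
        })
    return AgreementReport(pd.DataFrame(rows), kappa_min, min_minority, consensus)


def report_from_summary(
    summary: pd.DataFrame,
    kappa_min: float = DEFAULT_KAPPA_MIN,
    min_minority: int = DEFAULT_MIN_MINORITY,
) -> AgreementReport:
    """Build a report from pre-computed (kappa, faulty, non_faulty) rows."""
    frame = summary[["parameter", "kappa", "faulty", "non_faulty"]].copy()
    frame["eligible"] = [
        _gate(r.kappa, r.faulty, r.non_faulty, kappa_min, min_minority)
        for r in frame.itertuples(index=False)
    ]
    return AgreementReport(frame.reset_index(drop=True), kappa_min, min_minority)


def select_parameters(
    report: AgreementReport,
    kappa_min: float | None = None,
    min_minority: int | None = None,
) -> list[str]:
    """Parameters passing the label-quality gate.

    The gate keeps a parameter when its kappa is at least ``kappa_min``
    (inclusive) and the smaller consensus class holds at least
    ``min_minority`` subjects.  Defaults come from the report.
    """
    kappa_min = report.kappa_min if kappa_min is None else kappa_min
    min_minority = report.min_minority if min_minority is None else min_minority
    return [
        r.parameter
        for r in report.frame.itertuples(index=False)
        if _gate(r.kappa, r.faulty, r.non_faulty, kappa_min, min_minority)
    ]


# ---------------------------------------------------------------------------
# Packaged reference agreement summary
# ---------------------------------------------------------------------------

_CELL_RE = re.compile(r"^\s*(\d+,\d+)\s*\(\s*(\d+)\s*,\s*(\d+)\s*\)\s*$")


def _parse_cell(cell: str) -> tuple[float, int, int]:
    m = _CELL_RE.match(cell)
    if not m:
        raise ConfigurationError(f"cannot parse agreement cell {cell!r}")
    # decimal commas in the source typography are normalised at ingest
    kappa = float(m.group(1).replace(",", "."))
    return kappa, int(m.group(2)), int(m.group(3))


def load_reference_agreement(path: str | Path | None = None) -> pd.DataFrame:
    """The bundled agreement summary of the 46-subject expert-rating study.

    Three physiotherapists rated 15 binary error parameters per test
    (Step Down Test and Single Leg Squat Test); each cell of the shipped
    TSV carries ``kappa (faulty, non_faulty)`` in its original typography
    with decimal commas.  Returns tidy rows: test, parameter, kappa,
    faulty, non_faulty.
    """
    if path is None:
        ref = importlib.resources.files("movequal") / "data" / _REFERENCE_RESOURCE
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[0] != "parameter":
        raise ConfigurationError("reference summary must start with 'parameter'")
    tests = header[1:]
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ConfigurationError(f"malformed reference row: {ln!r}")
        for test, cell in zip(tests, cells[1:]):
            kappa, faulty, non_faulty = _parse_cell(cell)
            rows.append({"test": test, "parameter": cells[0], "kappa": kappa,
                         "faulty": faulty, "non_faulty": non_faulty})
    return pd.DataFrame(rows)


def reference_report(
    test: str,
    kappa_min: float = DEFAULT_KAPPA_MIN,
    min_minority: int = DEFAULT_MIN_MINORITY,
    path: str | Path | None = None,
) -> AgreementReport:
    """Agreement report for one test of the bundled reference summary."""
    df = load_reference_agreement(path)
    sub = df[df["test"] == test]
    if sub.empty:
        raise ConfigurationError(
            f"unknown test {test!r}; available: {sorted(df['test'].unique())}"
        )
    return report_from_summary(sub, kappa_min, min_minority)
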