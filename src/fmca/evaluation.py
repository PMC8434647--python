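"""Agreement and correlation statistics for score tables.

A :class:`ScoreTable` holds one record per subject x test with the
clinician's conventional three-point score (fm3), the system's crisp
three-point score (fm3a), the clinician's extended seven-point score (fm7)
and the system's continuous score (fm_ca). The analyses here quantify
(1) data validity — percent agreement and Cohen's kappa between fm3a and
fm3; (2) how well the continuous scale tracks the clinician — Pearson
correlations per trial, per test, and on per-subject sums; and (3) how
often the clinician actually used the extended grades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import FM7_SYMBOLS, fm7_to_numeric

_COLUMNS = ["subject", "test_id", "fm3", "fm3a", "fm7", "fm_ca"]
_EXTENDED = frozenset({"0+", "1-", "1+", "2-"})


@dataclass(frozen=True)
class ScoreRecord:
    subject: str
    test_id: str
    fm3: int
    fm3a: int
    fm7: str
    fm_ca: float

    def __post_init__(self):
        if self.fm3 not in (0, 1, 2) or self.fm3a not in (0, 1, 2):
            raise ValueError("fm3/fm3a must be 0, 1 or 2")
        if self.fm7 not in FM7_SYMBOLS:
            raise ValueError(f"fm7 must be one of {FM7_SYMBOLS}, got {self.fm7!r}")
        if not 0.0 <= self.fm_ca <= 1.0:
            raise ValueError("fm_ca must lie in [0, 1]")


class ScoreTable:
    """Per-trial score records with uniqueness on (subject, test_id)."""

    def __init__(self, records):
        if isinstance(records, pd.DataFrame):
            df = records.copy()
        else:
            df = pd.DataFrame([r.__dict__ if isinstance(r, ScoreRecord) else r
                               for r in records])
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"score table lacks columns {sorted(missing)}")
        df = df[_COLUMNS].reset_index(drop=True)
        df["fm7"] = df["fm7"].astype(str).str.strip().str.replace("−", "-")
        # validate via the record type
        for row in df.itertuples(index=False):
            ScoreRecord(str(row.subject), str(row.test_id), int(row.fm3),
                        int(row.fm3a), str(row.fm7), float(row.fm_ca))
        if df.duplicated(["subject", "test_id"]).any():
            raise ValueError("duplicate (subject, test_id) records")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def fm7_numeric(self) -> np.ndarray:
        return self.df["fm7"].map(fm7_to_numeric).to_numpy()


@dataclass(frozen=True)
class ContingencyTable:
    """3x3 cross-tabulation, rows = clinician fm3, columns = system fm3a."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def contingency(table: ScoreTable) -> ContingencyTable:
    ct = pd.crosstab(table.df["fm3"], table.df["fm3a"])
    ct = ct.reindex(index=[0, 1, 2], columns=[0, 1, 2], fill_value=0)
    return ContingencyTable(ct.to_numpy())


def agreement(ct: ContingencyTable) -> float:
    """Percent of trials on the diagonal (rater agreement), 0-100."""
    if ct.total == 0:
        raise ValueError("empty contingency table")
    return 100.0 * float(np.trace(ct.counts)) / ct.total


def cohens_kappa(ct: ContingencyTable) -> float:
    """Chance-corrected agreement, (p_o - p_e) / (1 - p_e)."""
    n = ct.total
    if n == 0:
        raise ValueError("empty contingency table")
    p_o = np.trace(ct.counts) / n
    p_e = float(ct.counts.sum(axis=1) @ ct.counts.sum(axis=0)) / n**2
    if p_e >= 1.0:
        raise ValueError("degenerate marginals: expected agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


def pearson(x, y) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the samples")
    return float(stats.pearsonr(x, y).statistic)


def subject_sums(table: ScoreTable, scale: str) -> dict[str, float]:
    """Per-subject sum across tests of fm3, fm7 (numeric) or fm_ca."""
    df = table.df
    counts = df.groupby("subject")["test_id"].nunique()
    n_tests = df["test_id"].nunique()
    short = counts[counts < n_tests]
    if len(short):
        raise ValueError(f"incomplete test grid for subject(s): "
                         f"{', '.join(short.index)}")
    if scale == "fm3":
        series = df.groupby("subject")["fm3"].sum()
    elif scale == "fm7-numeric":
        series = df.assign(v=table.fm7_numeric).groupby("subject")["v"].sum()
    elif scale == "fm_ca":
        series = df.groupby("subject")["fm_ca"].sum()
    else:
        raise ValueError("scale must be 'fm3', 'fm7-numeric' or 'fm_ca'")
    return {str(k): float(v) for k, v in series.items()}


def extended_scale_fraction(table: ScoreTable) -> tuple[int, float]:
    """(count, percent) of trials rated with an extended grade (0+,1-,1+,2-)."""
    n = len(table)
    count = int(table.df["fm7"].isin(_EXTENDED).sum())
    return count, (100.0 * count / n if n else 0.0)


def evaluation_report(table: ScoreTable,
                      exclude: tuple[str, str] | None = None) -> dict:
    """All headline statistics of a score table, in one JSON-able dict.

    ``exclude`` optionally names one (subject, test_id) trial to drop from
    an additional per-test correlation (used to isolate the single
    fm3/fm3a disagreement).
    """
    df = table.df
    ct = contingency(table)
    fm7n = table.fm7_numeric
    report = {
        "n_trials": len(table),
        "agreement_percent": agreement(ct),
        "cohens_kappa": cohens_kappa(ct),
        "contingency": ct.counts.tolist(),
        "pearson_fmca_fm3": pearson(df["fm_ca"], df["fm3"]),
        "pearson_fmca_fm7": pearson(df["fm_ca"], fm7n),
        "per_test": {},
    }
    for tid, sub in df.assign(fm7n=fm7n).groupby("test_id"):
        report["per_test"][str(tid)] = {
            "pearson_fmca_fm3": pearson(sub["fm_ca"], sub["fm3"]),
            "pearson_fmca_fm7": pearson(sub["fm_ca"], sub["fm7n"]),
        }
    sums_ca = subject_sums(table, "fm_ca")
    subjects = sorted(sums_ca)
    for scale, key in (("fm3", "pearson_sum_fm3"), ("fm7-numeric", "pearson_sum_fm7")):
        s = subject_sums(table, scale)
        report[key] = pearson([sums_ca[k] for k in subjects],
                              [s[k] for k in subjects])
    count, pct = extended_scale_fraction(table)
    report["extended_scale_count"] = count
    report["extended_scale_percent"] = pct
    if exclude is not None:
        subj, tid = exclude
        sub = df.assign(fm7n=fm7n)
        sub = sub[(sub["test_id"] == tid) &
                  ~((sub["subject"] == subj) & (sub["test_id"] == tid))]
        report["pearson_fmca_fm7_excluded"] = {
            "test_id": tid, "excluded_subject": subj,
            "r": pearson(sub["fm_ca"], sub["fm7n"]),
        }
    return report
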