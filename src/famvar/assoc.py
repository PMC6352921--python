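"""Cohort-level phenotypic statistics.

Prevalence, relative risk with Wald confidence intervals, variable
standardisation, and phenotype-phenotype association in a mixed model with
a pedigree random effect (the same machinery used for PRS association).
The cohort table models a questionnaire design in which respondents endorse
up to 12 recent stressful life events, classifiable as dependent (partly a
consequence of own behaviour), independent (beyond the person's control) or
personal (directly affecting only the respondent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relmat import RelationshipMatrix
from .vcomp import LiabilityParams
from . import prs as _prs

# Default classification of the 12 life-event items.  The exact published
# item taxonomy is questionnaire-specific and configurable; this default
# follows the usual dependent/independent split of threatening-experience
# lists (own illness/relationship/work/financial events dependent or
# personal, events happening to others independent).
DEFAULT_ITEM_CLASSES: dict[int, str] = {
    1: "personal",     # serious illness or injury to self
    2: "independent",  # serious illness or injury to a close relative
    3: "independent",  # death of a parent, child or spouse
    4: "independent",  # death of a close family friend or relative
    5: "dependent",    # marital separation or broken relationship
    6: "dependent",    # serious problem with a close friend or relative
    7: "dependent",    # unemployment or seeking work unsuccessfully
    8: "dependent",    # sacked from a job
    9: "personal",     # major financial crisis
    10: "dependent",   # problems with the police or a court appearance
    11: "personal",    # something valued lost or stolen
    12: "dependent",   # serious dispute at work
}


@dataclass
class CohortTable:
    """Phenotype table: case status, demographics and SLE counts."""

    df: pd.DataFrame = field(repr=False)
    max_events: int = 12
    item_classes: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_ITEM_CLASSES))

    def __post_init__(self) -> None:
        if "iid" not in self.df.columns:
            raise ValueError("cohort table needs an 'iid' column")
        for col in self.df.columns:
            if col.startswith("sle"):
                v = self.df[col].dropna()
                if ((v < 0) | (v > self.max_events) | (v % 1 != 0)).any():
                    raise ValueError(f"{col}: SLE counts must be integers in "
                                     f"[0, {self.max_events}]")
        bad = set(self.item_classes.values()) - {"dependent", "independent", "personal"}
        if bad:
            raise ValueError(f"unknown item classes: {bad}")


def standardise(values: np.ndarray, log_transform: bool = False) -> np.ndarray:
    """Optionally log(1+x)-transform, then scale to mean 0 and SD 1.

    ``log1p`` is used for count variables so zeros stay finite; downstream
    regression coefficients are then in SD units.  Raises on constant input.
    """
    x = np.asarray(values, float).astype(float)
    if log_transform:
        if np.nanmin(x) < 0:
            raise ValueError("log transform requires non-negative values")
        x = np.log1p(x)
    sd = np.nanstd(x, ddof=0)
    if sd == 0:
        raise ValueError("cannot standardise a constant vector")
    return (x - np.nanmean(x)) / sd


def prevalence(status: np.ndarray | pd.Series) -> float:
    """Case fraction among individuals with non-missing 0/1 status."""
    s = pd.Series(status).dropna().astype(float)
    if len(s) == 0:
        raise ValueError("no non-missing case status")
    if not s.isin([0.0, 1.0]).all():
        raise ValueError("status must be binary 0/1")
    return float(s.mean())


@dataclass
class RelativeRiskResult:
    rr: float
    ci_low: float
    ci_high: float
    table: tuple[tuple[float, float], tuple[float, float]]  # (cases, non) x (exposed, unexposed)


def relative_risk(exposed_cases: int, exposed_n: int, unexposed_cases: int,
                  unexposed_n: int, continuity_correction: bool = False
                  ) -> RelativeRiskResult:
    """Relative risk with a 95% Wald (log-scale) confidence interval.

    RR = (a/n1) / (c/n0);  CI = exp(ln RR +- 1.96 * sqrt(1/a - 1/n1 + 1/c -
    1/n0)).  Zero cells raise unless ``continuity_correction`` adds 0.5 to
    every cell.
    """
    a, n1, c, n0 = map(float, (exposed_cases, exposed_n, unexposed_cases, unexposed_n))
    if min(n1, n0) <= 0 or a > n1 or c > n0 or min(a, c) < 0:
        raise ValueError("invalid 2x2 counts")
    if a == 0 or c == 0 or a == n1 or c == n0:
        if not continuity_correction:
            raise ValueError("zero cell in the 2x2 table; re-run with "
                             "continuity_correction=True to add 0.5 to all cells")
        a, c = a + 0.5, c + 0.5
        n1, n0 = n1 + 1.0, n0 + 1.0
    rr = (a / n1) / (c / n0)
    log_se = np.sqrt(1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n0)
    lo, hi = np.exp(np.log(rr) + np.array([-1.96, 1.96]) * log_se)
    return RelativeRiskResult(float(rr), float(lo), float(hi),
                              ((a, n1 - a), (c, n0 - c)))


def trait_assoc(y: np.ndarray, x: np.ndarray, X: np.ndarray | None,
                K: RelationshipMatrix | None,
                liability: LiabilityParams | None = None
                ) -> tuple[float, float, float, float]:
    """Phenotype-phenotype association in the pedigree mixed model.

    Same contract as the PRS association: returns (beta, se, r2, p) for the
    standardised predictor ``x``, with the optional observed-to-liability
    conversion for binary outcomes.
    """
    return _prs.prs_assoc(y, x, X, K, liability=liability)


def risk_by_dose(case_status: np.ndarray, counts: np.ndarray,
                 max_count: int = 6) -> pd.DataFrame:
    """Relative risk of caseness at each event count versus zero events.

    Counts at or above ``max_count`` are pooled into a top bin.  Rows with
    missing status or count are dropped.
    """
    df = pd.DataFrame({"case": case_status, "k": counts}).dropna()
    df["k"] = np.minimum(df["k"].astype(int), max_count)
    ref = df[df["k"] == 0]
    c0, n0 = int(ref["case"].sum()), len(ref)
    rows = []
    for k in range(1, max_count + 1):
        grp = df[df["k"] == k]
        if len(grp) == 0:
            continue
        res = relative_risk(int(grp["case"].sum()), len(grp), c0, n0,
                            continuity_correction=True)
        rows.append({"events": k, "rr": res.rr, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "n": len(grp)})
    return pd.DataFrame(rows)
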