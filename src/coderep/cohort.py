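"""Tumor-cohort stratification and survival analysis.

Expression z-scores are computed against the *normal-tissue* reference
class (its mean and n-1 SD), so a tumor sample's z answers "how many
normal-tissue SDs above normal is this tumor?"; the headline statistic
is then the fraction of a class at or above a threshold (>= 3 SD,
inclusive).  High/low stratification takes the top and bottom
floor(10% * n) samples with deterministic sample-id tie-breaking.
Survival uses the Kaplan-Meier product-limit estimator and the
two-group log-rank test (via lifelines).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ValidationError

TISSUE_CLASSES = ("normal", "primary", "metastatic")
META_COLUMNS = ("sample", "tissue", "time", "event")


@dataclass
class CohortTable:
    """Per-sample tissue class, optional survival, and gene expression."""

    df: pd.DataFrame

    def __post_init__(self):
        for col in ("sample", "tissue"):
            if col not in self.df.columns:
                raise ValidationError(f"cohort table lacks column {col!r}")
        if self.df["sample"].duplicated().any():
            raise ValidationError("duplicate sample ids in cohort table")
        bad = set(self.df["tissue"]) - set(TISSUE_CLASSES)
        if bad:
            raise ValidationError(f"unknown tissue class(es): {sorted(bad)}")
        if "time" in self.df.columns:
            has_time = self.df["time"].notna()
            if (self.df.loc[has_time, "time"] < 0).any():
                raise ValidationError("survival times must be nonnegative")
            if "event" not in self.df.columns or self.df.loc[has_time, "event"].isna().any():
                raise ValidationError("event indicator required wherever time is set")

    @property
    def genes(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLUMNS]

    def expression(self, gene: str) -> pd.Series:
        if gene not in self.df.columns:
            raise ValidationError(f"gene {gene!r} absent from cohort table")
        return pd.Series(
            self.df[gene].to_numpy(dtype=float), index=self.df["sample"], name=gene
        )

    def samples_in_class(self, tissue_class: str) -> pd.Index:
        if tissue_class not in TISSUE_CLASSES:
            raise ValidationError(f"unknown tissue class {tissue_class!r}")
        return pd.Index(self.df.loc[self.df["tissue"] == tissue_class, "sample"])

    def survival(self, samples=None) -> tuple[np.ndarray, np.ndarray]:
        """(times, events) for the given samples (default: all with time)."""
        if "time" not in self.df.columns:
            raise ValidationError("cohort table has no survival columns")
        df = self.df.set_index("sample")
        if samples is not None:
            df = df.loc[list(samples)]
        df = df[df["time"].notna()]
        return df["time"].to_numpy(dtype=float), df["event"].to_numpy(dtype=int)


def zscore_vs_reference(
    cohort: CohortTable, gene: str, reference_class: str = "normal"
) -> pd.Series:
    """z of every sample against the reference class's mean and n-1 SD."""
    expr = cohort.expression(gene)
    ref = expr.loc[cohort.samples_in_class(reference_class)]
    if len(ref) < 2:
        raise ValidationError(
            f"reference class {reference_class!r} needs >=2 samples"
        )
    sd = ref.std(ddof=1)
    if sd == 0:
        raise ValidationError("reference class has zero expression SD")
    return (expr - ref.mean()) / sd


def fraction_above(z, threshold: float = 3.0) -> float:
    """Fraction of values at or above the threshold (inclusive)."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValidationError("empty class for fraction_above")
    return float((z >= threshold).mean())


def stratify_deciles(
    values: pd.Series, decile: float = 0.10
) -> tuple[list[str], list[str]]:
    """(high, low) sample-id lists: top/bottom floor(decile * n) by value.

    Ties are broken deterministically by sample id (ascending).
    """
    if not 0 < decile < 0.5:
        raise ValidationError("decile must be in (0, 0.5)")
    n = len(values)
    if n < 10:
        raise ValidationError(f"need >=10 samples to take deciles (got {n})")
    k = int(np.floor(decile * n))
    order = sorted(values.index, key=lambda s: (values[s], s))
    low = order[:k]
    high = order[-k:]
    return high, low


@dataclass
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("event times must be strictly increasing")
        if np.any(self.survival < 0) or np.any(self.survival > 1):
            raise ValidationError("survival estimates must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValidationError("survival must be non-increasing")

    def at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (nan if never reached)."""
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else float("nan")


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator of the survival function."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size != e.size:
        raise ValidationError("times and events lengths differ")
    if np.any(t < 0):
        raise ValidationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    # drop the t=0 at-risk anchor row unless events occurred there
    surv = kmf.survival_function_["KM_estimate"]
    event_times = ev.index.to_numpy(dtype=float)
    return SurvivalCurve(
        times=event_times,
        survival=surv.loc[ev.index].to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=int),
    )


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p with 1 df).

    Each group is a (times, events) pair.  Symmetric in group order.
    """
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValidationError("log-rank test undefined with no events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)
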