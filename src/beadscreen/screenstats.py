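"""Screening statistics: percent change, specificity matrices, ANOVA.

A buffer screen measures every bead population's rMFI under a series of
buffer conditions, one of which is designated the reference for each
aptamer.  The outputs mirror how such screens are interpreted:

* signed percent change of a condition's rMFI against the reference,
* a conditions x non-target-populations percent-change matrix (the
  "specificity heat map" data) with the target population reported
  separately,
* one-way ANOVA of replicate rMFI values across conditions with
  many-to-one comparisons against the control condition (two-sided t-tests
  with Bonferroni adjustment, a conservative stand-in for Dunnett's test).

Percent changes are always computed on QC'd rMFI summaries, never on raw
pixel statistics; invalid summaries propagate as masked (NaN) cells, never
as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import PopulationSummary

__all__ = [
    "ExperimentDesign",
    "ScreenTable",
    "ControlComparison",
    "percent_change",
    "specificity_matrix",
    "compare_to_control",
]


def percent_change(test: float, reference: float) -> float:
    """Signed percent change 100*(test - reference)/reference.

    Undefined for a non-positive reference (raises ``ValueError``); matrix
    builders catch this and mask the cell.
    """
    if not np.isfinite(reference) or reference <= 0:
        raise ValueError(f"reference rMFI must be positive, got {reference}")
    if not np.isfinite(test):
        raise ValueError(f"test rMFI must be finite, got {test}")
    return 100.0 * (test - reference) / reference


@dataclass(frozen=True)
class ExperimentDesign:
    """The well plan: one row per well with its aptamer, condition and dose.

    Required columns: ``well``, ``aptamer``, ``condition``, ``reference``
    (boolean; exactly one reference condition per aptamer).  Arbitrary
    covariate columns (e.g. ``dose`` in mM) pass through untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"well", "aptamer", "condition", "reference"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if df["well"].duplicated().any():
            dupes = df.loc[df["well"].duplicated(), "well"].tolist()
            raise ValueError(f"duplicate well ids: {dupes}")
        for aptamer, grp in df.groupby("aptamer"):
            n_ref = int(grp["reference"].astype(bool).sum())
            if n_ref != 1:
                raise ValueError(
                    f"aptamer {aptamer!r} has {n_ref} reference conditions; need exactly 1"
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExperimentDesign":
        df = pd.read_csv(path)
        if "reference" in df.columns:
            df["reference"] = df["reference"].astype(bool)
        return cls(df)

    def reference_condition(self, aptamer: str) -> str:
        grp = self.table[self.table["aptamer"] == aptamer]
        if grp.empty:
            raise KeyError(f"aptamer {aptamer!r} not in design")
        return str(grp.loc[grp["reference"].astype(bool), "condition"].iloc[0])

    def conditions(self, aptamer: str) -> list[str]:
        grp = self.table[self.table["aptamer"] == aptamer]
        return list(dict.fromkeys(grp["condition"].astype(str)))


@dataclass(frozen=True)
class ScreenTable:
    """rMFI of every population under every condition of one aptamer screen.

    ``summaries`` maps condition -> population id -> PopulationSummary;
    ``target_populations`` maps aptamer -> its target population id, which
    implicitly annotates every other population as a specificity control.
    """

    aptamer: str
    reference_condition: str
    summaries: Mapping[str, Mapping[str, PopulationSummary]]
    target_populations: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.reference_condition not in self.summaries:
            raise ValueError(
                f"reference condition {self.reference_condition!r} missing from summaries"
            )
        if self.aptamer not in self.target_populations:
            raise ValueError(f"no target population declared for {self.aptamer!r}")

    @property
    def conditions(self) -> list[str]:
        return list(self.summaries)

    @property
    def populations(self) -> list[str]:
        first = next(iter(self.summaries.values()))
        return list(first)

    def rmfi_frame(self) -> pd.DataFrame:
        """Conditions x populations rMFI matrix (NaN for invalid cells)."""
        data = {
            cond: {pid: (s.rmfi if s.valid else np.nan) for pid, s in pops.items()}
            for cond, pops in self.summaries.items()
        }
        return pd.DataFrame(data).T.reindex(self.conditions)


def specificity_matrix(
    table: ScreenTable, aptamer: str | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Percent-change matrix of the non-target populations, plus the target.

    Rows are conditions, columns the specificity-control populations; each
    cell is the percent change of that population's rMFI under that
    condition against the aptamer's reference condition.  Invalid or
    undefined cells (invalid summary, non-positive reference) are NaN.  The
    target population's percent changes are returned separately as a Series.
    """
    aptamer = aptamer or table.aptamer
    target_pop = table.target_populations[aptamer]
    rmfi = table.rmfi_frame()
    if target_pop not in rmfi.columns:
        raise KeyError(f"target population {target_pop!r} not in screen table")
    ref = rmfi.loc[table.reference_condition]

    def col_change(col: pd.Series, ref_val: float) -> pd.Series:
        if not np.isfinite(ref_val) or ref_val <= 0:
            return pd.Series(np.nan, index=col.index)
        return 100.0 * (col - ref_val) / ref_val

    changes = pd.DataFrame(
        {pid: col_change(rmfi[pid], ref[pid]) for pid in rmfi.columns},
        index=rmfi.index,
    )
    target_series = changes[target_pop].rename(f"target:{target_pop}")
    controls = changes.drop(columns=[target_pop])
    return controls, target_series


@dataclass(frozen=True)
class ControlComparison:
    """One-way ANOVA across conditions plus many-to-one tests vs control."""

    f_statistic: float
    p_value: float
    control: str
    comparisons: pd.DataFrame  # condition, mean_diff, percent_change, cohens_d, p_raw, p_adjusted
    degenerate: bool = False


def compare_to_control(
    groups: Mapping[str, Sequence[float]],
    control: str,
    adjustment: str = "bonferroni",
) -> ControlComparison:
    """Test replicate rMFI values of several conditions against a control.

    Classical one-way ANOVA (F and overall p) over all groups, then each
    non-control condition vs the control with a two-sided pooled-variance
    t-test; p-values are Bonferroni-adjusted over the number of comparisons
    (a conservative substitute for Dunnett's many-to-one procedure).  Effect
    sizes (mean difference, percent change vs control, Cohen's d) accompany
    every comparison.

    Groups need >= 2 replicates each; with zero within-group variance
    everywhere the ANOVA is degenerate and flagged as such.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    if control not in groups:
        raise KeyError(f"control group {control!r} missing")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has {arr.size} replicates; need >= 2")

    within_var = sum(float(np.var(a, ddof=1)) for a in arrays.values())
    degenerate = within_var == 0.0
    if degenerate:
        f_stat, p_val = float("nan"), float("nan")
    else:
        f_stat, p_val = stats.f_oneway(*arrays.values())
        f_stat, p_val = float(f_stat), float(p_val)

    ctrl = arrays[control]
    others = [k for k in arrays if k != control]
    n_comp = len(others)
    rows = []
    for name in others:
        grp = arrays[name]
        diff = float(grp.mean() - ctrl.mean())
        pct = (
            100.0 * diff / float(ctrl.mean())
            if np.isfinite(ctrl.mean()) and ctrl.mean() > 0 else float("nan")
        )
        pooled = np.sqrt(
            ((grp.size - 1) * grp.var(ddof=1) + (ctrl.size - 1) * ctrl.var(ddof=1))
            / (grp.size + ctrl.size - 2)
        )
        d = diff / float(pooled) if pooled > 0 else float("nan")
        if degenerate or pooled == 0:
            p_raw = float("nan")
        else:
            p_raw = float(stats.ttest_ind(grp, ctrl, equal_var=True).pvalue)
        p_adj = (
            min(p_raw * n_comp, 1.0)
            if adjustment == "bonferroni" and np.isfinite(p_raw) else p_raw
        )
        rows.append(
            {"condition": name, "mean_diff": diff, "percent_change": pct,
             "cohens_d": d, "p_raw": p_raw, "p_adjusted": p_adj}
        )
    return ControlComparison(
        f_statistic=f_stat, p_value=p_val, control=control,
        comparisons=pd.DataFrame(rows), degenerate=degenerate,
    )
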