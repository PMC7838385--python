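"""Richness, gene overlap between groups, and per-unit two-group tests.

A probe counts as detected in a sample when its normalized intensity is
positive.  Group richness is the count of probes detected in at least
one sample of the group; overlap is set algebra on the two groups'
detected-probe sets.  Category/subcategory/family tests compare the
per-sample summed intensity between the elevation groups with a
two-sample t test (Welch by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import HIGH, LOW, PipelineError, RelativeMatrix, SignalMatrix, StudyDesign

TEST_LEVELS = ("category", "subcategory", "gene_family")


@dataclass
class RichnessSummary:
    per_sample: pd.Series  # sample -> detected probe count
    per_group: pd.Series  # group -> probes detected in >= 1 sample of group
    per_group_category: pd.DataFrame  # category x group counts
    total: int  # probes detected anywhere

    def group_count(self, group: str) -> int:
        return int(self.per_group.get(group, 0))


def richness(
    matrix: SignalMatrix, design: StudyDesign, annotation: pd.DataFrame
) -> RichnessSummary:
    """Detected-probe counts per sample, per group, and per category."""
    design.validate_samples(matrix.samples)
    detected = matrix.values > 0
    per_sample = detected.sum(axis=0)
    groups = design.groups
    per_group = {}
    per_group_cat = {}
    cats = annotation.loc[matrix.probes, "category"]
    for g in groups:
        cols = [s for s in matrix.samples if design.group_of_sample(s) == g]
        in_group = detected[cols].any(axis=1)
        per_group[g] = int(in_group.sum())
        per_group_cat[g] = in_group.groupby(cats).sum()
    return RichnessSummary(
        per_sample=per_sample,
        per_group=pd.Series(per_group),
        per_group_category=pd.DataFrame(per_group_cat).fillna(0).astype(int),
        total=int(detected.any(axis=1).sum()),
    )


@dataclass
class OverlapSummary:
    scope: str
    n_shared: int
    n_unique_low: int
    n_unique_high: int

    @property
    def union(self) -> int:
        return self.n_shared + self.n_unique_low + self.n_unique_high

    @property
    def pct_shared(self) -> float:
        return 100.0 * self.n_shared / self.union if self.union else 0.0

    @property
    def pct_unique_low(self) -> float:
        return 100.0 * self.n_unique_low / self.union if self.union else 0.0

    @property
    def pct_unique_high(self) -> float:
        return 100.0 * self.n_unique_high / self.union if self.union else 0.0

    def per_group_percentages(self) -> dict:
        """Shared percentage relative to each group's own total."""
        n_low = self.n_shared + self.n_unique_low
        n_high = self.n_shared + self.n_unique_high
        return {
            "pct_shared_of_low": 100.0 * self.n_shared / n_low if n_low else 0.0,
            "pct_shared_of_high": 100.0 * self.n_shared / n_high if n_high else 0.0,
        }


def overlap(
    matrix: SignalMatrix,
    design: StudyDesign,
    annotation: pd.DataFrame | None = None,
    scope: str = "all",
) -> OverlapSummary:
    """Shared/unique detected-probe sets between the two elevation groups.

    ``scope`` is ``"all"`` or a category name (requires ``annotation``).
    Percentages are relative to the union of the two groups' sets;
    per-group denominators are available on the result.
    """
    detected = matrix.values > 0
    if scope != "all":
        if annotation is None:
            raise ValueError("category scope requires an annotation table")
        keep = annotation.loc[matrix.probes, "category"] == scope
        detected = detected[keep.to_numpy()]
    sets = {}
    for g in (LOW, HIGH):
        cols = [s for s in matrix.samples if design.group_of_sample(s) == g]
        sets[g] = set(detected.index[detected[cols].any(axis=1)])
    shared = sets[LOW] & sets[HIGH]
    return OverlapSummary(
        scope=scope,
        n_shared=len(shared),
        n_unique_low=len(sets[LOW] - shared),
        n_unique_high=len(sets[HIGH] - shared),
    )


@dataclass
class CategoryTestResult:
    unit: str
    level: str
    mean_low: float
    mean_high: float
    se_low: float
    se_high: float
    n_low: int
    n_high: int
    t: float | None
    p: float | None
    testable: bool = True
    group_exclusive: str | None = None  # group holding all the signal, if any


def _group_sample_sums(
    values: pd.DataFrame, design: StudyDesign, units: pd.Series
) -> pd.DataFrame:
    """Per-unit, per-sample summed intensity (units x samples)."""
    return values.groupby(units.to_numpy()).sum()


def _welch_row(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    t, p = stats.ttest_ind(b, a, equal_var=equal_var)
    if np.isnan(t):  # zero variance in both groups with equal means
        return 0.0, 1.0
    return float(t), float(p)


def category_ttest(
    matrix: SignalMatrix | RelativeMatrix,
    design: StudyDesign,
    annotation: pd.DataFrame,
    level: str = "category",
    equal_var: bool = False,
    bh_adjust: bool = False,
) -> list[CategoryTestResult]:
    """Two-group t test of per-sample summed intensity for every unit.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled-variance variant).  The t statistic is oriented high minus
    low.  Units carried by a single group are flagged not-testable.
    ``bh_adjust`` adds Benjamini-Hochberg adjusted p values.
    """
    if level not in TEST_LEVELS:
        raise ValueError(f"level must be one of {TEST_LEVELS}, got {level!r}")
    values = matrix.values
    design.validate_samples(values.columns)
    low = [s for s in values.columns if design.group_of_sample(s) == LOW]
    high = [s for s in values.columns if design.group_of_sample(s) == HIGH]
    if len(low) < 2 or len(high) < 2:
        raise PipelineError("need >= 2 samples per group")
    units = annotation.loc[values.index, level]
    sums = _group_sample_sums(values, design, units)
    results = []
    for unit, row in sums.iterrows():
        a = row[low].to_numpy(dtype=float)
        b = row[high].to_numpy(dtype=float)
        res = CategoryTestResult(
            unit=str(unit),
            level=level,
            mean_low=float(a.mean()),
            mean_high=float(b.mean()),
            se_low=float(a.std(ddof=1) / np.sqrt(len(a))),
            se_high=float(b.std(ddof=1) / np.sqrt(len(b))),
            n_low=len(a),
            n_high=len(b),
            t=None,
            p=None,
        )
        if a.sum() == 0 and b.sum() > 0:
            res.testable, res.group_exclusive = False, HIGH
        elif b.sum() == 0 and a.sum() > 0:
            res.testable, res.group_exclusive = False, LOW
        else:
            res.t, res.p = _welch_row(a, b, equal_var)
        results.append(res)
    if bh_adjust:
        _attach_bh(results)
    return results


def _attach_bh(results: list[CategoryTestResult]) -> None:
    tested = [r for r in results if r.p is not None]
    if not tested:
        return
    p = np.array([r.p for r in tested])
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, p[i] * m / (rank_pos + 1))
        adj[i] = running
    for r, q in zip(tested, adj):
        r.p_adjusted = float(q)  # type: ignore[attr-defined]


def taxa_function_aggregate(
    matrix: SignalMatrix | RelativeMatrix,
    annotation: pd.DataFrame,
    design: StudyDesign,
    category: str,
    lineage_level: str = "lineage",
) -> list[CategoryTestResult]:
    """Per-lineage two-group tests within one functional category.

    Probe intensities are summed within (lineage, category) per sample
    before testing.  Lineages with signal in only one group are reported
    as group-exclusive and not tested.
    """
    cats = annotation.loc[matrix.probes, "category"]
    if category not in set(cats):
        raise ValueError(f"unknown category {category!r}")
    keep = (cats == category).to_numpy()
    sub_values = matrix.values[keep]
    sub_annot = annotation.loc[sub_values.index]
    low = [s for s in sub_values.columns if design.group_of_sample(s) == LOW]
    high = [s for s in sub_values.columns if design.group_of_sample(s) == HIGH]
    units = sub_annot[lineage_level]
    sums = sub_values.groupby(units.to_numpy()).sum()
    results = []
    for unit, row in sums.iterrows():
        a = row[low].to_numpy(dtype=float)
        b = row[high].to_numpy(dtype=float)
        res = CategoryTestResult(
            unit=str(unit),
            level=f"{lineage_level}x{category}",
            mean_low=float(a.mean()),
            mean_high=float(b.mean()),
            se_low=float(a.std(ddof=1) / np.sqrt(len(a))),
            se_high=float(b.std(ddof=1) / np.sqrt(len(b))),
            n_low=len(a),
            n_high=len(b),
            t=None,
            p=None,
        )
        if a.sum() == 0 and b.sum() > 0:
            res.testable, res.group_exclusive = False, HIGH
        elif b.sum() == 0 and a.sum() > 0:
            res.testable, res.group_exclusive = False, LOW
        else:
            res.t, res.p = _welch_row(a, b, equal_var=False)
        results.append(res)
    return results


def results_table(results: list[CategoryTestResult]) -> pd.DataFrame:
    """Flatten test results to a tidy DataFrame (one row per unit)."""
    rows = []
    for r in results:
        row = {
            "unit": r.unit,
            "level": r.level,
            "mean_low": r.mean_low,
            "mean_high": r.mean_high,
            "se_low": r.se_low,
            "se_high": r.se_high,
            "t": r.t,
            "p": r.p,
            "testable": r.testable,
            "group_exclusive": r.group_exclusive,
        }
        if hasattr(r, "p_adjusted"):
            row["p_adjusted"] = r.p_adjusted  # type: ignore[attr-defined]
        rows.append(row)
    return pd.DataFrame(rows)
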