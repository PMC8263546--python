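"""Forward-prediction scenarios and accuracy metrics.

Forward prediction trains on earlier series-years and predicts clones first
appearing in a later year, emulating deployment in a breeding program.
Accuracy is the Pearson correlation between genomic predictions (GEBV or
GPCP) and adjusted phenotypes, per region, with SE = sqrt((1 - r^2)/(n - 2)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import KernelMatrix

logger = logging.getLogger(__name__)


@dataclass
class Scenario:
    """Clone-disjoint training/test split by series-year."""

    name: str
    train_years: frozenset[int]
    test_year: int
    train_clones: frozenset[str]
    test_clones: frozenset[str]

    def __post_init__(self) -> None:
        assert not (self.train_clones & self.test_clones)


@dataclass
class AccuracyResult:
    """Per-region and overall Pearson accuracy for one model/trait."""

    model_label: str
    trait: str
    per_region: pd.DataFrame  # region, n, r, se
    overall: float
    overall_weighted: float

    def to_frame(self) -> pd.DataFrame:
        df = self.per_region.copy()
        df.insert(0, "trait", self.trait)
        df.insert(0, "model", self.model_label)
        return df


def correlation_se(r: float, n: int) -> float:
    """Standard error of a Pearson correlation: sqrt((1 - r^2)/(n - 2))."""
    if n <= 2:
        raise ValueError("need more than 2 observations")
    return math.sqrt((1.0 - r * r) / (n - 2))


def build_scenario(
    ph: pd.DataFrame,
    train_years: set[int],
    test_year: int,
    name: str | None = None,
) -> Scenario:
    """Split clones by first appearance; overlap is removed from training.

    Test clones are those whose first record year is ``test_year``; any clone
    with records in both periods is excluded from training so the reference
    and validation sets share no clones.
    """
    years = set(ph["year"].unique())
    missing = ({test_year} | set(train_years)) - years
    if missing:
        raise ValueError(f"years {sorted(missing)} not present in phenotype table")
    first_year = ph.groupby("clone")["year"].min()
    test_clones = frozenset(first_year.index[first_year == test_year])
    if not test_clones:
        raise ValueError(f"no clones first appear in {test_year}")
    in_train = set(ph.loc[ph["year"].isin(train_years), "clone"])
    train_clones = frozenset(in_train - test_clones)
    overlap = len(in_train & test_clones)
    if overlap:
        logger.info("%d overlapping clones removed from the training side", overlap)
    logger.info(
        "scenario %s: %d training, %d test clones",
        name or test_year, len(train_clones), len(test_clones),
    )
    return Scenario(
        name=name or f"predict-{test_year}",
        train_years=frozenset(train_years),
        test_year=test_year,
        train_clones=train_clones,
        test_clones=test_clones,
    )


def accuracy(
    preds: dict[str, float] | pd.Series,
    ph: pd.DataFrame,
    trait: str,
    by_region: bool = True,
    model_label: str = "",
    min_n: int = 3,
) -> AccuracyResult:
    """Pearson accuracy of predictions against adjusted phenotypes.

    Each clone's phenotype within a region is the mean of its records there; a
    clone tested in several regions is evaluated in each.  Overall accuracy is
    the unweighted mean of the per-region correlations (an n-weighted mean is
    also reported).  Strata with fewer than ``min_n`` clones, or with
    zero-variance predictions, yield a missing r with a warning.
    """
    preds = pd.Series(preds, dtype=float)
    df = ph.loc[ph[trait].notna() & ph["clone"].isin(preds.index)]
    if df.empty:
        raise ValueError("no phenotyped clones with predictions")
    group_cols = ["region"] if by_region else []
    rows = []
    groups = df.groupby(group_cols) if group_cols else [(("all",), df)]
    for key, sub in groups:
        region = key[0] if isinstance(key, tuple) else key
        clone_means = sub.groupby("clone")[trait].mean()
        n = len(clone_means)
        if n < min_n:
            logger.warning("region %s has n=%d < %d; accuracy undefined", region, n, min_n)
            rows.append({"region": region, "n": n, "r": np.nan, "se": np.nan})
            continue
        p = preds[clone_means.index].to_numpy()
        yv = clone_means.to_numpy()
        if np.std(p) == 0 or np.std(yv) == 0:
            logger.warning("zero-variance predictions in region %s", region)
            rows.append({"region": region, "n": n, "r": np.nan, "se": np.nan})
            continue
        r = float(np.corrcoef(p, yv)[0, 1])
        rows.append({"region": region, "n": n, "r": r, "se": correlation_se(r, n)})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["r"])
    overall = float(valid["r"].mean()) if len(valid) else float("nan")
    weighted = (
        float(np.average(valid["r"], weights=valid["n"])) if len(valid) else float("nan")
    )
    return AccuracyResult(
        model_label=model_label, trait=trait, per_region=table,
        overall=overall, overall_weighted=weighted,
    )


def relative_improvement(r_new: float, r_base: float) -> int:
    """Percent improvement round((r_new/r_base - 1) * 100), half away from zero."""
    if r_base <= 0:
        raise ValueError("baseline accuracy must be positive")
    pct = (r_new / r_base - 1.0) * 100.0
    return int(math.floor(abs(pct) + 0.5) * (1 if pct >= 0 else -1))


def top_fraction_relatedness(
    G: KernelMatrix,
    ref: set[str],
    valid: set[str],
    fraction: float = 0.10,
) -> float:
    """Mean of each validation clone's top-fraction relationships to the reference.

    A connectedness diagnostic: for every validation clone, its relationships
    to the reference clones are sorted and the top round(fraction * |ref|)
    (at least one) averaged; the result is the mean over validation clones.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if not ref or not valid:
        raise ValueError("reference and validation sets must be nonempty")
    if ref & valid:
        raise ValueError("reference and validation sets must be disjoint")
    pos = {c: i for i, c in enumerate(G.clone_ids)}
    ref_idx = np.array([pos[c] for c in sorted(ref)])
    k = max(1, int(math.floor(fraction * len(ref_idx) + 0.5)))
    means = []
    for c in sorted(valid):
        rel = G.values[pos[c], ref_idx]
        top = np.sort(rel)[-k:]
        means.append(top.mean())
    return float(np.mean(means))
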