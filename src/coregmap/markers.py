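"""Subclass-specific regulators and CRISPR dependency cross-referencing.

Differentially influencing regulators (DIRs) are found per class with a
one-vs-rest two-sided Wilcoxon rank-sum test on influence values,
filtered by a detection fraction (min.pct-style) and an effect-size
floor, with Bonferroni correction across all (regulator, class) tests.
Because influence is a signed statistic rather than a positive
abundance, the effect size is the difference of class means, not a
log-ratio, and "detected" means |influence| above a floor.

Dependency ranking contrasts CERES knockout-fitness scores of the cell
lines assigned to a class against the rest (Wilcoxon–Mann–Whitney).
CERES is signed: negative means the knockout reduces viability, so a
class-essential regulator has an in-class mean below the viability
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

logger = logging.getLogger("coregmap")

__all__ = ["DirRecord", "DependencyRecord", "find_dirs", "rank_dependencies"]


@dataclass(frozen=True)
class DirRecord:
    regulator: str
    class_name: str
    mean_in: float
    mean_out: float
    delta: float  # mean_in − mean_out
    pct: float  # fraction of in-class samples with |influence| above floor
    p_value: float
    p_adjusted: float


@dataclass(frozen=True)
class DependencyRecord:
    regulator: str
    class_name: str
    mean_in: float
    mean_out: float
    p_value: float
    essential: bool  # mean_in strictly below the viability threshold


def find_dirs(
    infl,
    labels,
    min_pct: float = 0.25,
    delta_threshold: float = 0.20,
    alpha: float = 0.05,
    detection_floor: float = 0.25,
    bonferroni: str = "global",
) -> list:
    """One-vs-rest differential influence per (regulator, class).

    Keeps records with in-class detection fraction ≥ ``min_pct``,
    |mean difference| ≥ ``delta_threshold`` and Bonferroni-adjusted
    two-sided rank-sum p < ``alpha``. The Bonferroni factor is the
    total number of tests performed (``global``, regulators × classes)
    or the number of regulators (``per-class``). Classes with fewer
    than 3 samples are skipped with a warning.
    """
    values = infl.values if hasattr(infl, "provenance") else infl
    labels = pd.Series(labels).reindex(values.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a class label")
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    tested_classes = []
    for c in classes:
        if (labels == c).sum() < 3:
            logger.warning("class %s has fewer than 3 samples; skipped", c)
        else:
            tested_classes.append(c)
    n_tests = values.shape[0] * len(tested_classes)
    factor = {"global": n_tests, "per-class": values.shape[0]}[bonferroni]

    records = []
    mat = values.to_numpy(dtype=float)
    lab = labels.to_numpy()
    for c in tested_classes:
        mask = lab == c
        x_in, x_out = mat[:, mask], mat[:, ~mask]
        for i, reg in enumerate(values.index):
            a, b = x_in[i], x_out[i]
            mean_in, mean_out = float(a.mean()), float(b.mean())
            delta = mean_in - mean_out
            pct = float((np.abs(a) > detection_floor).mean())
            if pct < min_pct or abs(delta) < delta_threshold:
                continue
            p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
            p_adj = min(p * factor, 1.0)
            if p_adj < alpha:
                records.append(
                    DirRecord(
                        regulator=str(reg),
                        class_name=str(c),
                        mean_in=mean_in,
                        mean_out=mean_out,
                        delta=float(delta),
                        pct=pct,
                        p_value=p,
                        p_adjusted=p_adj,
                    )
                )
    return records


def rank_dependencies(
    ceres: pd.DataFrame,
    class_assignment,
    viability_threshold: float = -0.5,
    regulators=None,
) -> list:
    """In-class vs out-of-class CERES contrast per regulator and class.

    ``ceres`` is regulator × cell-line; ``class_assignment`` maps cell
    lines to classes. Regulators absent from the table are skipped and
    reported. A regulator is flagged essential for a class when its
    in-class mean CERES is strictly below ``viability_threshold``.
    """
    assign = pd.Series(class_assignment)
    lines = [s for s in assign.index if s in ceres.columns]
    if not lines:
        raise ValueError("no assigned cell line is present in the CERES table")
    assign = assign.loc[lines]
    if regulators is not None:
        missing = [r for r in regulators if r not in ceres.index]
        if missing:
            logger.warning("regulators absent from CERES table (skipped): %s", missing[:10])
        regulators = [r for r in regulators if r in ceres.index]
    else:
        regulators = list(ceres.index)

    records = []
    for c in sorted(assign.unique()):
        in_lines = assign.index[assign == c]
        out_lines = assign.index[assign != c]
        if len(in_lines) < 2 or len(out_lines) < 2:
            logger.warning("class %s has fewer than 2 cell lines on one side; skipped", c)
            continue
        for reg in regulators:
            a = ceres.loc[reg, in_lines].to_numpy(dtype=float)
            b = ceres.loc[reg, out_lines].to_numpy(dtype=float)
            mean_in = float(np.nanmean(a))
            p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
            records.append(
                DependencyRecord(
                    regulator=str(reg),
                    class_name=str(c),
                    mean_in=mean_in,
                    mean_out=float(np.nanmean(b)),
                    p_value=p,
                    essential=mean_in < viability_threshold,
                )
            )
    return records
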