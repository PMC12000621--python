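"""Per-sample regulator influence from network structure.

The influence of a regulator r in a sample is the Welch two-sample t
statistic contrasting the expression of its activated targets A^r
against its repressed targets I^r:

    Influence(r) = (mean E(A^r) − mean E(I^r))
                   / sqrt(s²(A^r)/|A^r| + s²(I^r)/|I^r|)

with s² the sample variance (ddof=1). A positive value means the
regulator's activated targets sit above its repressed targets, i.e.
the regulator behaves as active in that sample. Because the statistic
contrasts two gene sets *within* a sample, global per-sample shifts
cancel and cohort-level batch offsets are strongly attenuated — the
property that makes influence suitable for multi-cohort maps.

A regulator's influence is only computed when both sides of the
contrast carry at least ``min_genes`` targets; small sides are padded
with the targets for which the regulator has the highest regression R²
among the retained candidate programs. Cells that remain incomputable
fall back to the median of the regulator's computed influences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("coregmap")

__all__ = [
    "RegulonSplit",
    "InfluenceMatrix",
    "welch_influence",
    "build_regulon_splits",
    "influence_matrix",
]

#: cap for the degenerate zero-variance, unequal-means case
DEGENERATE_CAP = 1e6

COMPUTED = "computed"
FALLBACK = "median-fallback"


@dataclass
class RegulonSplit:
    """A regulator's activated/repressed target sets plus fill ranking."""

    regulator: str
    activated: frozenset
    repressed: frozenset
    fill_ranking: list = field(default_factory=list)  # [(target, r2)], r2 desc
    usable: bool = True

    def __post_init__(self):
        self.activated = frozenset(self.activated)
        self.repressed = frozenset(self.repressed)
        if self.activated & self.repressed:
            raise ValueError("activated and repressed sets must be disjoint")


@dataclass
class InfluenceMatrix:
    """Regulator × sample influence values with per-cell provenance."""

    values: pd.DataFrame
    provenance: pd.DataFrame  # same shape, entries COMPUTED / FALLBACK

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("influence matrix must have no missing cells")
        if not self.values.shape == self.provenance.shape:
            raise ValueError("values and provenance shapes differ")


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    if denom == 0.0:
        if ma == mb:
            return 0.0
        return DEGENERATE_CAP if ma > mb else -DEGENERATE_CAP
    return float((ma - mb) / denom)


def welch_influence(expr_sample, split: RegulonSplit) -> float:
    """Influence of one regulator in one sample (Welch t statistic).

    ``expr_sample`` maps gene → expression value; regulon members with
    missing (absent or non-finite) expression are skipped. Raises if
    fewer than two members remain on either side.
    """
    sides = []
    for members in (split.activated, split.repressed):
        vals = []
        for g in sorted(members):
            v = expr_sample.get(g)
            if v is not None and np.isfinite(v):
                vals.append(float(v))
        if len(vals) < 2:
            raise ValueError(
                f"regulator {split.regulator}: fewer than 2 expressed targets on one side"
            )
        sides.append(np.asarray(vals))
    return _welch(sides[0], sides[1])


def build_regulon_splits(grn, min_genes: int = 5) -> list:
    """Split the network into per-regulator activated/repressed regulons.

    A side smaller than ``min_genes`` is padded, highest regression R²
    first, with targets drawn from the regulator's retained candidate
    programs that are not already in either side. Padding never removes
    or relabels existing members. Regulators for which a side still
    falls short are flagged unusable (their influence can only be
    median-filled downstream, and they are dropped if nothing is ever
    computable).
    """
    programs = list(grn)
    if not programs:
        raise ValueError("cannot build regulon splits from an empty GRN")
    pools = getattr(grn, "candidates", {}) or {}

    activated: dict = {}
    repressed: dict = {}
    for prog in programs:
        for r in prog.activators:
            activated.setdefault(r, set()).add(prog.target)
            repressed.setdefault(r, set())
        for r in prog.inhibitors:
            repressed.setdefault(r, set()).add(prog.target)
            activated.setdefault(r, set())

    # best candidate-pool R² of each (regulator, target) pair
    best_r2: dict = {}
    for tgt, cands in pools.items():
        for c in cands:
            for r in c.regulators:
                key = (r, tgt)
                if c.r2 > best_r2.get(key, -1.0):
                    best_r2[key] = c.r2

    splits = []
    for r in sorted(activated):
        a, i = set(activated[r]), set(repressed[r])
        ranking = sorted(
            ((tgt, r2) for (reg, tgt), r2 in best_r2.items() if reg == r and tgt not in a | i),
            key=lambda x: (-x[1], x[0]),
        )
        queue = list(ranking)
        for side in (a, i):
            while len(side) < min_genes and queue:
                tgt, _ = queue.pop(0)
                if tgt not in a | i:
                    side.add(tgt)
        usable = len(a) >= min_genes and len(i) >= min_genes
        splits.append(
            RegulonSplit(
                regulator=r,
                activated=frozenset(a),
                repressed=frozenset(i),
                fill_ranking=ranking,
                usable=usable,
            )
        )
    return splits


def _impute_missing(expr: pd.DataFrame, needed, reference: pd.DataFrame) -> pd.DataFrame:
    """Nearest-correlated-gene transfer of missing target genes.

    For a regulon gene g absent from ``expr``: find the gene g* present
    in both ``expr`` and ``reference`` with the highest absolute
    correlation to g across reference samples, and transfer g*'s
    standardized profile onto g's reference location/scale. Genes with
    no usable proxy stay missing.
    """
    shared = [g for g in reference.index if g in expr.index]
    if not shared:
        return expr
    ref_shared = reference.loc[shared].to_numpy(dtype=float)
    ref_sd = ref_shared.std(axis=1, ddof=1)
    ok = ref_sd > 0
    rows = []
    for g in needed:
        if g in expr.index or g not in reference.index:
            continue
        target_prof = reference.loc[g].to_numpy(dtype=float)
        if target_prof.std(ddof=1) == 0 or not ok.any():
            continue
        centered = ref_shared - ref_shared.mean(axis=1, keepdims=True)
        tc = target_prof - target_prof.mean()
        denom = np.sqrt((centered**2).sum(axis=1) * (tc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, centered @ tc / denom, 0.0)
        best = int(np.nanargmax(np.abs(corr)))
        proxy = shared[best]
        rho = corr[best]
        if rho == 0:
            continue
        x = expr.loc[proxy].to_numpy(dtype=float)
        x_sd = np.nanstd(x, ddof=1)
        if x_sd == 0:
            continue
        z = (x - np.nanmean(x)) / x_sd
        imputed = reference.loc[g].mean() + np.sign(rho) * z * target_prof.std(ddof=1)
        rows.append(pd.Series(imputed, index=expr.columns, name=g))
    if not rows:
        return expr
    logger.info("imputed %d missing regulon genes from reference", len(rows))
    return pd.concat([expr, pd.DataFrame(rows)])


def influence_matrix(
    expr: pd.DataFrame,
    splits,
    reference: pd.DataFrame | None = None,
) -> InfluenceMatrix:
    """Assemble the regulator × sample influence matrix.

    Per usable regulator, the Welch statistic is computed per sample on
    the regulon members present in ``expr`` (optionally completed from
    ``reference`` by correlated-gene imputation). Any cell that cannot
    be computed takes the median of the regulator's computed cells and
    is flagged; regulators with no computable cell at all are dropped.
    """
    usable = [s for s in splits if s.usable]
    if not usable:
        raise ValueError("no usable regulator regulon (all below the minimum gene count)")
    needed = sorted(set().union(*[s.activated | s.repressed for s in usable]))
    if reference is not None:
        expr = _impute_missing(expr, needed, reference)
    if not any(g in expr.index for g in needed):
        raise ValueError("expression matrix shares no gene with any regulon")

    n_samples = expr.shape[1]
    values, prov, kept = [], [], []
    mat = expr.to_numpy(dtype=float)
    row_of = {g: i for i, g in enumerate(expr.index)}
    for split in usable:
        side_stats = []
        for members in (split.activated, split.repressed):
            idx = [row_of[g] for g in sorted(members) if g in row_of]
            sub = mat[idx] if idx else np.empty((0, n_samples))
            finite = np.isfinite(sub)
            cnt = finite.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean = np.where(cnt > 0, np.nansum(np.where(finite, sub, 0.0), axis=0) / np.maximum(cnt, 1), np.nan)
                sq = np.nansum(np.where(finite, (sub - mean) ** 2, 0.0), axis=0)
                var = np.where(cnt > 1, sq / np.maximum(cnt - 1, 1), np.nan)
            side_stats.append((mean, var, cnt))
        (ma, va, na), (mi, vi, ni) = side_stats
        valid = (na >= 2) & (ni >= 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.sqrt(va / na + vi / ni)
            t = (ma - mi) / denom
        t = np.where(denom == 0, np.where(ma == mi, 0.0, np.sign(ma - mi) * DEGENERATE_CAP), t)
        t = np.where(valid, t, np.nan)
        computed = np.isfinite(t)
        if not computed.any():
            logger.warning("regulator %s has no computable influence cell; dropped", split.regulator)
            continue
        med = float(np.median(t[computed]))
        filled = np.where(computed, t, med)
        values.append(filled)
        prov.append(np.where(computed, COMPUTED, FALLBACK))
        kept.append(split.regulator)
    if not kept:
        raise ValueError("no regulator produced a computable influence")
    vdf = pd.DataFrame(np.vstack(values), index=kept, columns=expr.columns)
    pdf = pd.DataFrame(np.vstack(prov), index=kept, columns=expr.columns)
    return InfluenceMatrix(values=vdf, provenance=pdf)
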