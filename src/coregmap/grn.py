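"""Inference of co-regulatory programs from bulk expression.

The pipeline follows the hybrid-LICORN recipe in four steps:

1. ternary discretization of each gene against its own distribution
   (−1 under-expressed, 0 baseline, +1 over-expressed) and removal of
   genes with too few non-zero calls;
2. frequent-itemset mining over the regulator rows to find sets of
   regulators that are simultaneously over-expressed (candidate
   co-activator sets) or simultaneously under-expressed (candidate
   co-inhibitor sets);
3. per target gene, scoring of every admissible (activator set,
   inhibitor set) pair by an association-rule metric on the ternary
   data and retention of the best candidates;
4. ordinary-least-squares scoring of each retained candidate program
   (target expression ~ mean activator expression + mean inhibitor
   expression), retention of the top candidates by R², and selection
   of the final program by a merged score that folds in external
   regulation / cooperation evidence when available.

The ternary semantics used throughout: a regulator *set* is at its
polarity sign in a sample only if **all** members are (unanimity), and
an active co-inhibitor set dominates the prediction (predicted target
state is −1 whenever the inhibitor set is collectively over-expressed,
otherwise it equals the collective activator state).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("coregmap")

__all__ = [
    "EvidenceSet",
    "RegulatorSet",
    "RegulatoryProgram",
    "GRN",
    "GrnParams",
    "discretize",
    "filter_supported_genes",
    "mine_coregulator_sets",
    "select_candidate_programs",
    "score_program_regression",
    "integrate_evidence",
    "infer_grn",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

ACTIVATOR = "activator-set"
INHIBITOR = "inhibitor-set"


@dataclass(frozen=True)
class RegulatorSet:
    """A set of regulators jointly at one ternary sign.

    ``support`` is the fraction of samples in which every member is
    simultaneously at the set's polarity sign (+1 for activator sets,
    −1 for inhibitor sets).
    """

    members: tuple[str, ...]  # stored sorted
    polarity: str  # ACTIVATOR or INHIBITOR
    support: float

    def __post_init__(self):
        if not self.members:
            raise ValueError("RegulatorSet must be non-empty")
        if self.polarity not in (ACTIVATOR, INHIBITOR):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if not 0 < self.support <= 1:
            raise ValueError("support must be in (0, 1]")
        object.__setattr__(self, "members", tuple(sorted(self.members)))


@dataclass(frozen=True)
class EvidenceSet:
    """External regulation (TF→target) and cooperation (TF–TF) evidence."""

    regulation_pairs: frozenset = frozenset()  # of (regulator, target)
    cooperation_pairs: frozenset = frozenset()  # of sorted (tf, tf) tuples

    @classmethod
    def from_pairs(cls, regulation=(), cooperation=()):
        reg = frozenset((str(a), str(b)) for a, b in regulation)
        coop = frozenset(tuple(sorted((str(a), str(b)))) for a, b in cooperation)
        if any(a == b for a, b in coop):
            raise ValueError("cooperation pairs must join distinct regulators")
        return cls(regulation_pairs=reg, cooperation_pairs=coop)

    def has_cooperation(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.cooperation_pairs


@dataclass
class RegulatoryProgram:
    """Selected (co-activator, co-inhibitor) explanation of one target gene."""

    target: str
    activators: frozenset
    inhibitors: frozenset
    rule_score: float
    r2: float = 0.0
    merged_score: float = 0.0

    def __post_init__(self):
        self.activators = frozenset(self.activators)
        self.inhibitors = frozenset(self.inhibitors)
        if self.activators & self.inhibitors:
            raise ValueError("activator and inhibitor sets must be disjoint")
        if not (self.activators or self.inhibitors):
            raise ValueError("program must name at least one regulator")
        if self.target in self.activators | self.inhibitors:
            raise ValueError("target cannot regulate itself in a program")

    @property
    def regulators(self) -> frozenset:
        return self.activators | self.inhibitors

    @property
    def size(self) -> int:
        return len(self.activators) + len(self.inhibitors)

    def sort_key(self):
        return (sorted(self.activators), sorted(self.inhibitors))


@dataclass
class GRN:
    """An inferred network: one selected program per retained target.

    ``candidates`` keeps, per target, the top candidate programs by R²
    (the pool later used to pad small regulons for influence scoring).
    """

    programs: list = field(default_factory=list)
    candidates: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.programs)

    def __len__(self):
        return len(self.programs)

    @property
    def targets(self) -> list:
        return [p.target for p in self.programs]


@dataclass
class GrnParams:
    """Tunable parameters of the inference pipeline."""

    threshold_sd: float = 1.0
    center: str = "median"
    min_gene_support: float = 0.1
    min_support: float = 0.1
    max_set_size: int = 4
    num_candidates: int = 2000  # rule-score pool fed to regression
    top_r2: int = 10  # candidates retained per target after regression
    evidence_weights: tuple = (1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------


def validate_expression(expr: pd.DataFrame, min_samples: int = 2) -> None:
    if expr.size == 0:
        raise ValueError("expression matrix is empty")
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
    if expr.shape[1] < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {expr.shape[1]}")


# ---------------------------------------------------------------------------
# Step 1 — discretization
# ---------------------------------------------------------------------------


def discretize(
    expr: pd.DataFrame, threshold_sd: float = 1.0, center: str = "median"
) -> pd.DataFrame:
    """Ternarize each gene against its own distribution.

    A value becomes +1 when it sits at or above ``center(g) +
    threshold_sd·sd(g)``, −1 at or below the mirror cut, 0 otherwise.
    The sample standard deviation (ddof=1) is used; genes with zero
    spread discretize to all zeros. Missing cells discretize to 0.
    """
    validate_expression(expr)
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    vals = expr.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if center == "median":
            loc = np.nanmedian(vals, axis=1)
        elif center == "mean":
            loc = np.nanmean(vals, axis=1)
        else:
            raise ValueError("center must be 'median' or 'mean'")
        sd = np.nanstd(vals, axis=1, ddof=1)
    centered = vals - loc[:, None]
    cut = threshold_sd * sd[:, None]
    out = np.zeros_like(vals, dtype=np.int8)
    ok = (sd > 0)[:, None] & np.isfinite(centered)
    out[ok & (centered >= cut)] = 1
    out[ok & (centered <= -cut)] = -1
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def filter_supported_genes(disc: pd.DataFrame, min_gene_support: float = 0.1) -> pd.DataFrame:
    """Keep genes whose fraction of non-zero ternary calls is ≥ the floor."""
    if not 0 <= min_gene_support <= 1:
        raise ValueError("min_gene_support must be in [0, 1]")
    frac = (disc.to_numpy() != 0).mean(axis=1)
    return disc.loc[frac >= min_gene_support]


# ---------------------------------------------------------------------------
# Step 2 — frequent-itemset mining of co-regulator sets
# ---------------------------------------------------------------------------


def _apriori(indicator: np.ndarray, names: list, min_count: int, max_size: int):
    """Levelwise frequent-itemset search on a boolean genes × samples array.

    Yields (member-index tuple, joint indicator vector). Candidates are
    generated by extending each frequent k-set with strictly larger item
    indices, so every itemset is enumerated exactly once.
    """
    n_items = indicator.shape[0]
    frontier = []
    for i in range(n_items):
        vec = indicator[i]
        if int(vec.sum()) >= min_count:
            frontier.append(((i,), vec))
            yield (i,), vec
    size = 1
    while frontier and size < max_size:
        nxt = []
        for members, vec in frontier:
            for j in range(members[-1] + 1, n_items):
                joint = vec & indicator[j]
                if int(joint.sum()) >= min_count:
                    cand = members + (j,)
                    nxt.append((cand, joint))
                    yield cand, joint
        frontier = nxt
        size += 1


def mine_coregulator_sets(
    disc_regulators: pd.DataFrame,
    min_support: float = 0.1,
    max_set_size: int = 4,
) -> list:
    """Enumerate all co-activator and co-inhibitor sets above support.

    A set of regulators is an activator set with support s if all its
    members are simultaneously +1 in a fraction s ≥ ``min_support`` of
    samples; inhibitor sets are the −1 mirror. Anti-monotonicity of the
    unanimity rule makes the levelwise search exhaustive.
    """
    if disc_regulators.shape[0] == 0:
        raise ValueError("no regulator rows to mine")
    if not 0 < min_support <= 1:
        raise ValueError("min_support must be in (0, 1]")
    if max_set_size < 1:
        raise ValueError("max_set_size must be >= 1")
    n_samples = disc_regulators.shape[1]
    min_count = int(np.ceil(min_support * n_samples))
    min_count = max(min_count, 1)
    names = list(disc_regulators.index)
    mat = disc_regulators.to_numpy()
    out = []
    for polarity, sign in ((ACTIVATOR, 1), (INHIBITOR, -1)):
        ind = mat == sign
        for members, joint in _apriori(ind, names, min_count, max_set_size):
            out.append(
                RegulatorSet(
                    members=tuple(names[i] for i in members),
                    polarity=polarity,
                    support=float(joint.sum()) / n_samples,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Step 3 — association-rule scoring of candidate programs
# ---------------------------------------------------------------------------


def collective_state(members, disc_regulators: pd.DataFrame) -> np.ndarray:
    """Unanimity state of a regulator set per sample: +1 when every
    member is +1, −1 when every member is −1, 0 otherwise."""
    sub = disc_regulators.loc[list(members)].to_numpy()
    state = np.zeros(sub.shape[1], dtype=np.int8)
    state[(sub == 1).all(axis=0)] = 1
    state[(sub == -1).all(axis=0)] = -1
    return state


def predicted_state(s_act: np.ndarray, s_inh: np.ndarray) -> np.ndarray:
    """Inhibition-dominant truth table h(s(A), s(I)): predict −1 whenever
    the co-inhibitor set is collectively over-expressed (s(I) = +1),
    otherwise predict the collective activator state."""
    return np.where(np.asarray(s_inh) == 1, -1, s_act).astype(np.int8)


def select_candidate_programs(
    target_disc: np.ndarray,
    candidate_sets: list,
    disc_regulators: pd.DataFrame,
    num_candidates: int = 100,
    target: str = "target",
) -> list:
    """Rank admissible (A, I) programs by ternary rule agreement.

    The rule score is the fraction of samples with a non-zero target
    state in which the predicted state equals the target state. Pairs
    must be disjoint, exclude the target itself, and not both be empty.
    Ties break toward smaller programs, then lexicographic members.
    """
    target_disc = np.asarray(target_disc, dtype=np.int8)
    if num_candidates < 1:
        raise ValueError("num_candidates must be >= 1")
    mask = target_disc != 0
    if not mask.any():
        return []

    act_sets = [s for s in candidate_sets if s.polarity == ACTIVATOR and target not in s.members]
    inh_sets = [s for s in candidate_sets if s.polarity == INHIBITOR and target not in s.members]

    # stack collective-state vectors; slot 0 = empty set (state 0)
    n = len(target_disc)
    SA = np.zeros((len(act_sets) + 1, n), dtype=np.int8)
    for i, s in enumerate(act_sets, start=1):
        SA[i] = collective_state(s.members, disc_regulators)
    SI = np.zeros((len(inh_sets) + 1, n), dtype=np.int8)
    for j, s in enumerate(inh_sets, start=1):
        SI[j] = collective_state(s.members, disc_regulators)

    t = target_disc[mask]
    SAm, SIm = SA[:, mask], SI[:, mask]
    # score[i, j] over all pairs via broadcasting (chunked over activators)
    n_eff = t.size
    scores = np.empty((SA.shape[0], SI.shape[0]), dtype=np.float64)
    inh_active = SIm == 1  # (nI, m)
    chunk = max(1, int(2e7) // max(1, SI.shape[0] * n_eff))
    for lo in range(0, SA.shape[0], chunk):
        hi = min(lo + chunk, SA.shape[0])
        pred = np.where(inh_active[None, :, :], -1, SAm[lo:hi, None, :])
        scores[lo:hi] = (pred == t).mean(axis=2)

    members_a = [frozenset()] + [frozenset(s.members) for s in act_sets]
    members_i = [frozenset()] + [frozenset(s.members) for s in inh_sets]

    ranked = []
    for i, j in itertools.product(range(len(members_a)), range(len(members_i))):
        if i == 0 and j == 0:
            continue
        A, I = members_a[i], members_i[j]
        if A & I:
            continue
        ranked.append((-scores[i, j], len(A) + len(I), sorted(A), sorted(I), i, j))
    ranked.sort(key=lambda r: r[:4])
    out = []
    for neg, _, _, _, i, j in ranked[:num_candidates]:
        out.append(
            RegulatoryProgram(
                target=target,
                activators=members_a[i],
                inhibitors=members_i[j],
                rule_score=-neg,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Step 4 — regression scoring and evidence-integrated selection
# ---------------------------------------------------------------------------


def score_program_regression(expr: pd.DataFrame, program: RegulatoryProgram) -> float:
    """R² of OLS: target ~ intercept + meanExpr(A) [+ meanExpr(I)].

    Returns 0 for degenerate fits (< 3 samples, zero-variance target or
    covariate). Clipped to [0, 1].
    """
    y = expr.loc[program.target].to_numpy(dtype=float)
    n = y.size
    if n < 3:
        return 0.0
    cols = []
    for members in (program.activators, program.inhibitors):
        if members:
            cols.append(expr.loc[sorted(members)].to_numpy(dtype=float).mean(axis=0))
    if np.ptp(y) == 0:
        return 0.0
    for c in cols:
        if np.ptp(c) == 0:
            return 0.0
    X = np.column_stack([np.ones(n)] + cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return float(min(max(r2, 0.0), 1.0))


class _BatchR2:
    """Closed-form OLS R² for programs built from precomputed covariates.

    Covariates are the per-set mean expression vectors of the mined
    activator and inhibitor sets. For a two-covariate program the R² of
    ``y ~ 1 + x_A + x_I`` follows from the centered second moments:

        R² = (c_A² v_I + c_I² v_A − 2 c_A c_I c_AI) / (v_y (v_A v_I − c_AI²))

    with c = covariances against y and v = variances. Single-covariate
    programs reduce to the squared correlation. Agrees with
    :func:`score_program_regression` and exists only to keep large
    candidate pools affordable.
    """

    def __init__(self, expr: pd.DataFrame, act_sets, inh_sets):
        n = expr.shape[1]
        self.n = n
        mat = expr.to_numpy(dtype=float)
        row_of = {g: i for i, g in enumerate(expr.index)}

        def cov_matrix(sets):
            if not sets:
                return np.empty((0, n))
            rows = [mat[[row_of[m] for m in members]].mean(axis=0) for members in sets]
            return np.asarray(rows)

        self.a_index = {frozenset(m): i for i, m in enumerate(act_sets)}
        self.i_index = {frozenset(m): i for i, m in enumerate(inh_sets)}
        A = cov_matrix(act_sets)
        I = cov_matrix(inh_sets)
        self.Ac = A - A.mean(axis=1, keepdims=True) if A.size else A
        self.Ic = I - I.mean(axis=1, keepdims=True) if I.size else I
        d = max(n - 1, 1)
        self.va = (self.Ac**2).sum(axis=1) / d
        self.vi = (self.Ic**2).sum(axis=1) / d
        self.cai = (self.Ac @ self.Ic.T) / d if A.size and I.size else np.empty((len(act_sets), len(inh_sets)))

    def score(self, y: np.ndarray, programs) -> None:
        """Fill ``r2`` in-place for each program."""
        n = self.n
        if n < 3:
            for p in programs:
                p.r2 = 0.0
            return
        yc = y - y.mean()
        vy = float(yc @ yc) / (n - 1)
        cy_a = (self.Ac @ yc) / (n - 1) if self.Ac.size else np.empty(0)
        cy_i = (self.Ic @ yc) / (n - 1) if self.Ic.size else np.empty(0)
        for p in programs:
            if vy == 0:
                p.r2 = 0.0
                continue
            ia = self.a_index.get(p.activators) if p.activators else None
            ii = self.i_index.get(p.inhibitors) if p.inhibitors else None
            if ia is not None and self.va[ia] == 0 or ii is not None and self.vi[ii] == 0:
                p.r2 = 0.0
                continue
            if ia is not None and ii is not None:
                v1, v2 = self.va[ia], self.vi[ii]
                c1, c2 = cy_a[ia], cy_i[ii]
                c12 = self.cai[ia, ii]
                det = v1 * v2 - c12 * c12
                if det <= 1e-12 * v1 * v2:
                    r2 = max(c1 * c1 / (v1 * vy), c2 * c2 / (v2 * vy))
                else:
                    r2 = (c1 * c1 * v2 + c2 * c2 * v1 - 2 * c1 * c2 * c12) / (vy * det)
            elif ia is not None:
                r2 = cy_a[ia] ** 2 / (self.va[ia] * vy)
            else:
                r2 = cy_i[ii] ** 2 / (self.vi[ii] * vy)
            p.r2 = float(min(max(r2, 0.0), 1.0))


def _evidence_fractions(program: RegulatoryProgram, evidence: EvidenceSet):
    edges = [(r, program.target) for r in program.regulators]
    f_reg = sum(e in evidence.regulation_pairs for e in edges) / len(edges)
    pairs = [
        tuple(sorted(p))
        for group in (program.activators, program.inhibitors)
        for p in itertools.combinations(sorted(group), 2)
    ]
    if not pairs:
        f_coop = 1.0
    else:
        f_coop = sum(p in evidence.cooperation_pairs for p in pairs) / len(pairs)
    return f_reg, f_coop


def integrate_evidence(
    candidates: list,
    evidence: EvidenceSet | None,
    weights: tuple = (1.0, 1.0, 1.0),
) -> RegulatoryProgram:
    """Pick the candidate with the highest merged score.

    merged = (w_r2·R² + w_reg·f_reg + w_coop·f_coop) / Σw, where f_reg
    is the fraction of the program's regulator→target edges backed by
    regulation evidence and f_coop the fraction of its within-set
    regulator pairs backed by cooperation evidence. A weight is dropped
    when its evidence table is absent or empty, so with no evidence the
    selection reduces to argmax R².
    """
    if not candidates:
        raise ValueError("no candidate programs to select from")
    w_r2, w_reg, w_coop = (float(w) for w in weights)
    if min(w_r2, w_reg, w_coop) < 0 or w_r2 + w_reg + w_coop <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    if evidence is None or not evidence.regulation_pairs:
        w_reg = 0.0
    if evidence is None or not evidence.cooperation_pairs:
        w_coop = 0.0
    if w_r2 + w_reg + w_coop == 0:
        w_r2 = 1.0
    total = w_r2 + w_reg + w_coop

    best = None
    for prog in candidates:
        if evidence is not None and (w_reg or w_coop):
            f_reg, f_coop = _evidence_fractions(prog, evidence)
        else:
            f_reg, f_coop = 0.0, 0.0
        merged = (w_r2 * prog.r2 + w_reg * f_reg + w_coop * f_coop) / total
        # rule_score in the tie chain separates a program from its sign
        # mirror (A and I swapped), which has identical OLS R² by symmetry
        key = (-merged, -prog.r2, -prog.rule_score, prog.size, prog.sort_key())
        if best is None or key < best[0]:
            best = (key, prog, merged)
    _, prog, merged = best
    return replace(prog, merged_score=merged)


def infer_grn(
    expr: pd.DataFrame,
    regulators,
    evidence: EvidenceSet | None = None,
    params: GrnParams | None = None,
) -> GRN:
    """Run the full four-step inference and return one program per target.

    Deterministic for fixed inputs: every ranking uses total orderings
    (score, program size, lexicographic members). Targets for which no
    admissible candidate exists are omitted.
    """
    params = params or GrnParams()
    regulators = list(dict.fromkeys(regulators))
    present_regs = [r for r in regulators if r in expr.index]
    if not present_regs:
        raise ValueError("no regulator from the list is present in the expression matrix")

    disc = discretize(expr, params.threshold_sd, params.center)
    disc = filter_supported_genes(disc, params.min_gene_support)
    reg_set = set(present_regs)
    disc_reg = disc.loc[[g for g in disc.index if g in reg_set]]
    targets = [g for g in disc.index if g not in reg_set]
    if disc_reg.shape[0] == 0 or not targets:
        logger.warning("no retained regulators or targets after support filtering")
        return GRN()

    sets = mine_coregulator_sets(disc_reg, params.min_support, params.max_set_size)
    if not sets:
        logger.warning("no frequent co-regulator set at min_support=%g", params.min_support)
        return GRN()

    act_sets = [s.members for s in sets if s.polarity == ACTIVATOR]
    inh_sets = [s.members for s in sets if s.polarity == INHIBITOR]
    scorer = _BatchR2(expr, act_sets, inh_sets)

    programs, pools = [], {}
    disc_np = disc.to_numpy()
    row_of = {g: i for i, g in enumerate(disc.index)}
    expr_np = expr.to_numpy(dtype=float)
    erow_of = {g: i for i, g in enumerate(expr.index)}
    for tgt in targets:
        cands = select_candidate_programs(
            disc_np[row_of[tgt]], sets, disc_reg, params.num_candidates, target=tgt
        )
        if not cands:
            continue
        scorer.score(expr_np[erow_of[tgt]], cands)
        cands.sort(key=lambda p: (-p.r2, -p.rule_score, p.size, p.sort_key()))
        top = cands[: params.top_r2]
        selected = integrate_evidence(top, evidence, params.evidence_weights)
        programs.append(selected)
        pools[tgt] = top
    if not programs:
        logger.warning("no target retained an admissible program; GRN is empty")
    return GRN(programs=programs, candidates=pools)
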