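"""Synthetic expression cohorts with planted regulatory structure.

The generator emulates the statistical structure the influence model
assumes: a latent per-sample *activity* for every regulator, class
structure expressed as class-specific activity means, and target genes
produced as (mean activity of their co-activators) − (mean activity of
their co-inhibitors) plus Gaussian noise. Co-activator sets are drawn
within a class module — co-activators must actually be co-active for
frequent-itemset mining to have anything to find, which is precisely
the co-regulation hypothesis the inference encodes. Optional per-gene
additive batch offsets emulate cross-cohort technical shifts.

Every draw flows from one ``numpy`` Generator seeded at construction,
so identical seeds give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grn import GRN, RegulatoryProgram

__all__ = ["SyntheticTruth", "generate_grn", "simulate_expression", "true_cooperative_pairs"]


@dataclass
class SyntheticTruth:
    """Planted ground truth: network, class activity means, seed."""

    grn: GRN
    regulators: list
    targets: list
    class_names: list
    #: regulator × class matrix of latent-activity means
    class_activity: pd.DataFrame
    activators_per_target: int
    inhibitors_per_target: int
    seed: int


def generate_grn(
    n_regulators: int = 20,
    n_targets: int = 200,
    activators_per_target: int = 2,
    inhibitors_per_target: int = 1,
    n_classes: int = 3,
    class_effect: float = 3.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Plant a bipartite regulator → target network with class modules.

    Regulators are assigned round-robin to ``n_classes`` modules. Each
    regulator's latent activity mean is ``+class_effect`` in its own
    class, ``−class_effect`` in the next class, and 0 elsewhere (with
    two classes, just ±class_effect). Within each module the regulators
    are partitioned into recurring co-activator groups of size
    ``activators_per_target`` (regulatory complexes): each target picks
    a class, adopts one of that class's groups as its activator set,
    and draws its co-inhibitors from the remaining modules. Recurring
    groups concentrate shared targets on the planted pairs, which is
    what makes them recoverable cooperative edges.
    """
    if min(n_regulators, n_targets, n_classes) < 1 or activators_per_target < 1:
        raise ValueError("counts must be positive")
    if inhibitors_per_target < 0:
        raise ValueError("inhibitors_per_target must be >= 0")
    modules = {c: [] for c in range(n_classes)}
    regulators = [f"R{i:03d}" for i in range(n_regulators)]
    for i, r in enumerate(regulators):
        modules[i % n_classes].append(r)
    if any(len(m) < activators_per_target for m in modules.values()):
        raise ValueError("a class module is smaller than activators_per_target")
    outside = {
        c: [r for cc, mem in modules.items() if cc != c for r in mem] for c in range(n_classes)
    }
    if n_classes > 1 and any(len(o) < inhibitors_per_target for o in outside.values()):
        raise ValueError("too few out-of-module regulators for inhibitors_per_target")

    rng = np.random.default_rng(seed)
    # fixed co-activator groups per module; wrap around when the module
    # size is not a multiple of the group size
    groups = {}
    for c, mem in modules.items():
        order = list(rng.permutation(mem))
        groups[c] = [
            tuple(
                sorted(order[(i + k) % len(order)] for k in range(activators_per_target))
            )
            for i in range(0, len(order), activators_per_target)
        ]
    targets = [f"T{i:04d}" for i in range(n_targets)]
    programs = []
    for tgt in targets:
        c = int(rng.integers(n_classes))
        acts = list(groups[c][int(rng.integers(len(groups[c])))])
        pool = outside[c] if n_classes > 1 else [r for r in regulators if r not in acts]
        inhs = (
            sorted(rng.choice(pool, size=inhibitors_per_target, replace=False))
            if inhibitors_per_target
            else []
        )
        programs.append(
            RegulatoryProgram(
                target=tgt,
                activators=frozenset(acts),
                inhibitors=frozenset(inhs),
                rule_score=1.0,
                r2=1.0,
            )
        )

    class_names = [f"C{c}" for c in range(n_classes)]
    means = pd.DataFrame(0.0, index=regulators, columns=class_names)
    for c, mem in modules.items():
        means.loc[mem, class_names[c]] = class_effect
        if n_classes > 1:
            means.loc[mem, class_names[(c + 1) % n_classes]] = -class_effect
    return SyntheticTruth(
        grn=GRN(programs=programs),
        regulators=regulators,
        targets=targets,
        class_names=class_names,
        class_activity=means,
        activators_per_target=activators_per_target,
        inhibitors_per_target=inhibitors_per_target,
        seed=seed,
    )


def simulate_expression(
    truth: SyntheticTruth,
    n_samples_per_class: int = 40,
    sigma: float = 0.25,
    n_batches: int = 1,
    batch_sd: float = 2.0,
    seed: int = 0,
):
    """Draw an expression matrix from the planted model.

    Per sample s of class c: activity a_r(s) ~ N(mean[r, c], 1);
    regulator expression = a_r(s) + N(0, σ²); target expression =
    mean activity of its activators − mean activity of its inhibitors
    + N(0, σ²). With ``n_batches`` > 1, samples are split evenly across
    batches within each class and every batch except the first adds a
    per-gene offset ~ N(0, batch_sd²) shared by its samples.

    Returns ``(expr, labels, batches)``: a gene × sample DataFrame and
    two aligned Series of class and batch labels.
    """
    if sigma < 0 or n_samples_per_class < 1 or n_batches < 1:
        raise ValueError("invalid simulation sizes")
    rng = np.random.default_rng(seed)
    classes = truth.class_names
    sample_ids, labels, batches = [], [], []
    for c in classes:
        for i in range(n_samples_per_class):
            sample_ids.append(f"{c}_S{i:03d}")
            labels.append(c)
            batches.append(f"B{i % n_batches}")
    n = len(sample_ids)

    means = truth.class_activity.loc[truth.regulators, labels].to_numpy()
    activity = means + rng.standard_normal((len(truth.regulators), n))
    act_df = pd.DataFrame(activity, index=truth.regulators, columns=sample_ids)

    reg_expr = activity + sigma * rng.standard_normal(activity.shape)
    tgt_rows = np.empty((len(truth.targets), n))
    for k, prog in enumerate(truth.grn.programs):
        a = act_df.loc[sorted(prog.activators)].to_numpy().mean(axis=0)
        if prog.inhibitors:
            a = a - act_df.loc[sorted(prog.inhibitors)].to_numpy().mean(axis=0)
        tgt_rows[k] = a
    tgt_expr = tgt_rows + sigma * rng.standard_normal(tgt_rows.shape)

    genes = truth.regulators + truth.targets
    expr = np.vstack([reg_expr, tgt_expr])
    if n_batches > 1:
        offsets = {
            f"B{b}": batch_sd * rng.standard_normal(len(genes)) if b else np.zeros(len(genes))
            for b in range(n_batches)
        }
        for j, b in enumerate(batches):
            expr[:, j] = expr[:, j] + offsets[b]
    expr_df = pd.DataFrame(expr, index=genes, columns=sample_ids)
    return (
        expr_df,
        pd.Series(labels, index=sample_ids, name="class"),
        pd.Series(batches, index=sample_ids, name="batch"),
    )


def true_cooperative_pairs(truth: SyntheticTruth, min_shared: int = 5) -> set:
    """Regulator pairs sharing ≥ ``min_shared`` planted targets."""
    from .cooperativity import regulons_from_grn
    import itertools

    regulons = regulons_from_grn(truth.grn)
    pairs = set()
    for a, b in itertools.combinations(sorted(regulons), 2):
        if len(regulons[a] & regulons[b]) >= min_shared:
            pairs.add((a, b))
    return pairs
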