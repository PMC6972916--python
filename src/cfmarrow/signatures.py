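"""Cell-type-specific and pairwise-enriched gene calls from reference atlases.

A gene is *specific* to a tissue or cell type when its expression there is
strictly more than ``fold_threshold`` (default 20) times its expression in
every other tissue/cell type of the reference — the rule used to mine
GTEx-style tissue atlases and Blueprint-style hematopoietic atlases for
marker genes.  A gene is *enriched* in one of two bulk transcriptomes (e.g.
bone marrow vs whole blood) when its pseudocounted expression ratio exceeds
``fold_threshold`` (default 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpecificityCall", "call_specific_genes", "call_enriched_genes"]


@dataclass(frozen=True)
class SpecificityCall:
    """One gene called specific to one entity of the reference."""

    gene: str
    top_entity: str
    top_value: float
    runner_up_value: float
    fold: float  # top_value / runner_up_value; inf when runner-up is 0


def call_specific_genes(
    reference: pd.DataFrame,
    fold_threshold: float = 20.0,
    min_top_expression: float = 1.0,
) -> list[SpecificityCall]:
    """Call genes specific to one entity of an entity x gene reference.

    A gene is called for its top-expressing entity when that expression is
    strictly greater than ``fold_threshold`` times the expression in every
    other entity, and at least ``min_top_expression`` (TPM).  Ties for the
    top entity yield no call, since the rule requires a unique top entity.

    Parameters
    ----------
    reference
        Entity x gene expression (TPM scale, non-negative).
    fold_threshold
        Strict fold requirement over the runner-up entity; must be > 1.
    min_top_expression
        Expression floor for the top entity; suppresses unstable calls on
        genes expressed at trace levels everywhere.

    Returns
    -------
    list of :class:`SpecificityCall`, in the reference's gene order.
    """
    if reference.shape[0] < 2:
        raise ValueError("specificity rule needs at least two entities")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if (reference.to_numpy() < 0).any():
        raise ValueError("reference contains negative expression values")

    values = reference.to_numpy(dtype=float)
    order = np.argsort(values, axis=0)
    top_idx = order[-1]
    cols = np.arange(values.shape[1])
    top = values[top_idx, cols]
    runner_up = values[order[-2], cols]

    calls: list[SpecificityCall] = []
    for j, gene in enumerate(reference.columns):
        if top[j] < min_top_expression or top[j] == runner_up[j]:
            continue  # below floor, or tied top entity
        fold = top[j] / runner_up[j] if runner_up[j] > 0 else math.inf
        if fold > fold_threshold:
            calls.append(
                SpecificityCall(
                    gene=str(gene),
                    top_entity=str(reference.index[top_idx[j]]),
                    top_value=float(top[j]),
                    runner_up_value=float(runner_up[j]),
                    fold=float(fold),
                )
            )
    return calls


def call_enriched_genes(
    expr_a: pd.Series,
    expr_b: pd.Series,
    fold_threshold: float = 5.0,
    pseudocount: float = 0.1,
) -> tuple[list[str], list[str]]:
    """Genes enriched in one of two bulk transcriptomes over the other.

    Gene g is A-enriched when ``(a_g + pc) / (b_g + pc) > fold_threshold``;
    B-enriched symmetrically.  With ``pseudocount = 0`` a zero denominator
    gives infinite fold (strict ratio behavior); the default small
    pseudocount keeps the rule defined at zero expression.

    Returns
    -------
    (a_enriched, b_enriched)
        Two disjoint gene lists in the shared gene order.
    """
    if not expr_a.index.equals(expr_b.index):
        raise ValueError("expression vectors must share an identical gene universe")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    a = expr_a.to_numpy(dtype=float) + pseudocount
    b = expr_b.to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.divide(a, b, out=np.full_like(a, np.nan), where=b > 0)
        inv = np.divide(b, a, out=np.full_like(a, np.nan), where=a > 0)
    # a zero denominator with a positive numerator counts as infinite fold
    ratio[(b == 0) & (a > 0)] = np.inf
    inv[(a == 0) & (b > 0)] = np.inf

    genes = expr_a.index
    a_enriched = [str(g) for g, r in zip(genes, ratio) if r > fold_threshold]
    b_enriched = [str(g) for g, r in zip(genes, inv) if r > fold_threshold]
    return a_enriched, b_enriched


def calls_to_frame(calls: list[SpecificityCall]) -> pd.DataFrame:
    """Tabulate specificity calls (gene, entity, top, runner-up, fold)."""
    return pd.DataFrame(
        [
            (c.gene, c.top_entity, c.top_value, c.runner_up_value, c.fold)
            for c in calls
        ],
        columns=["gene", "entity", "top_value", "runner_up_value", "fold"],
    )
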