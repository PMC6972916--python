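"""Tissue/cell-type contribution estimates for cf-mRNA transcriptomes.

Two complementary routes are provided:

1. **Unsupervised NMF.**  Genes below 20 TPM in every sample are removed,
   each remaining gene is divided by its maximum across samples (so every
   row peaks at 1), and the resulting matrix is factorized into 8-12
   non-negative components.  Components are then annotated by majority vote
   of the cell-type-specificity calls among their highest-loading genes,
   and per-sample contributions are read off the annotated activities.

2. **Signature-based quadratic programming.**  Given a signature matrix of
   cell-type-specific genes, a sample's composition is the solution of
   ``min ||x - S^T p||^2  s.t.  p >= 0, sum(p) = 1`` — non-negative least
   squares on the simplex.  The equality constraint is enforced through a
   heavily weighted augmented row on top of a standard NNLS solve, followed
   by an exact renormalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import NMF

from cfmarrow.signatures import SpecificityCall

__all__ = [
    "NmfDecomposition",
    "FractionEstimate",
    "filter_and_normalize",
    "nmf_decompose",
    "select_rank",
    "annotate_components",
    "estimate_fractions",
    "estimate_fractions_matrix",
    "component_fractions",
]


@dataclass
class NmfDecomposition:
    """Result of a non-negative matrix factorization of a gene x sample matrix."""

    loadings: pd.DataFrame  # gene x component, >= 0
    activities: pd.DataFrame  # component x sample, >= 0
    n_components: int
    reconstruction_error: float  # Frobenius norm of the residual
    converged: bool
    annotations: dict[str, str] = field(default_factory=dict)
    annotation_evidence: pd.DataFrame | None = None


@dataclass
class FractionEstimate:
    """Per-sample non-negative cell-type proportions summing to 1."""

    sample: str
    fractions: pd.Series  # entity -> proportion
    residual_norm: float
    rank_deficient: bool = False


def filter_and_normalize(
    matrix: pd.DataFrame, min_tpm: float = 20.0
) -> tuple[pd.DataFrame, list[str]]:
    """Drop low-expression genes and max-normalize each remaining gene.

    Genes whose maximum over samples is below ``min_tpm`` are excluded; each
    retained gene's row is divided by its own maximum, so every row attains
    exactly 1.  This brings all genes to a comparable scale so that the
    factorization captures shared expression *patterns* rather than
    absolute levels.

    Returns
    -------
    (normalized, retained)
        The normalized gene x sample matrix and the retained gene list.
    """
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    row_max = matrix.max(axis=1)
    keep = row_max >= min_tpm
    if not keep.any():
        raise ValueError(f"no gene reaches {min_tpm} TPM in any sample")
    sub = matrix.loc[keep]
    normalized = sub.div(sub.max(axis=1), axis=0)
    return normalized, [str(g) for g in sub.index]


def nmf_decompose(
    normalized: pd.DataFrame,
    n_components: int,
    seed: int = 0,
    max_iter: int = 20_000,
    tol: float = 1e-10,
) -> NmfDecomposition:
    """Factorize a normalized gene x sample matrix into additive components.

    Uses coordinate-descent NMF (monotone non-increasing Frobenius
    objective) with a deterministic non-negative double-SVD initialization,
    so results are reproducible given the seed.  The generous default
    iteration budget lets exactly low-rank inputs be factorized to near
    machine precision; noisy inputs stop early on ``tol``.
    Non-convergence within ``max_iter`` is reported through the
    ``converged`` flag rather than raised.
    """
    n_genes, n_samples = normalized.shape
    if not 1 <= n_components <= min(n_genes, n_samples):
        raise ValueError(
            f"n_components must lie in [1, {min(n_genes, n_samples)}]"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on max_iter
        model = NMF(
            n_components=n_components,
            init="nndsvda",
            solver="cd",
            max_iter=max_iter,
            tol=tol,
            random_state=seed,
        )
        W = model.fit_transform(normalized.to_numpy(dtype=float))
    H = model.components_
    comp = [f"C{i + 1}" for i in range(n_components)]
    return NmfDecomposition(
        loadings=pd.DataFrame(W, index=normalized.index, columns=comp),
        activities=pd.DataFrame(H, index=comp, columns=normalized.columns),
        n_components=n_components,
        reconstruction_error=float(model.reconstruction_err_),
        converged=model.n_iter_ < max_iter,
    )


def select_rank(
    normalized: pd.DataFrame,
    rank_min: int = 8,
    rank_max: int = 12,
    seed: int = 0,
    holdout_fraction: float = 0.1,
    max_iter: int = 500,
) -> tuple[int, pd.Series]:
    """Pick the factorization rank by held-out entry reconstruction error.

    A fixed random mask of ``holdout_fraction`` of the entries is set to the
    matrix mean, each candidate rank is fitted, and the rank minimizing the
    RMSE on the masked entries wins.  Returns the chosen rank and the
    per-rank held-out errors (for logging).
    """
    rng = np.random.default_rng(seed)
    X = normalized.to_numpy(dtype=float)
    mask = rng.random(X.shape) < holdout_fraction
    X_train = X.copy()
    X_train[mask] = X.mean()

    errors = {}
    for rank in range(rank_min, rank_max + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = NMF(
                n_components=rank,
                init="nndsvda",
                solver="cd",
                max_iter=max_iter,
                random_state=seed,
            )
            W = model.fit_transform(X_train)
        recon = W @ model.components_
        errors[rank] = float(np.sqrt(np.mean((recon[mask] - X[mask]) ** 2)))
    per_rank = pd.Series(errors, name="holdout_rmse")
    return int(per_rank.idxmin()), per_rank


def annotate_components(
    decomposition: NmfDecomposition,
    specific_calls: list[SpecificityCall],
    top_n: int = 25,
    min_fraction: float = 0.5,
) -> dict[str, str]:
    """Label each component by the cell type its top-loading genes mark.

    For each component the ``top_n`` genes with the highest loadings are
    collected; the component is assigned the entity holding a plurality of
    those genes' specificity calls, provided that plurality exceeds
    ``min_fraction`` of ``top_n``.  Components whose top genes carry too few
    or conflicting calls stay ``"unannotated"``.  The vote tallies are kept
    on the decomposition as ``annotation_evidence`` for review.
    """
    if top_n > decomposition.loadings.shape[0]:
        raise ValueError("top_n exceeds the number of genes in the decomposition")
    call_map = {c.gene: c.top_entity for c in specific_calls}

    annotations: dict[str, str] = {}
    evidence_rows = []
    for comp in decomposition.loadings.columns:
        top_genes = decomposition.loadings[comp].nlargest(top_n).index
        votes = pd.Series(
            [call_map[g] for g in top_genes if g in call_map], dtype=object
        ).value_counts()
        if len(votes) and votes.iloc[0] > min_fraction * top_n:
            annotations[str(comp)] = str(votes.index[0])
        else:
            annotations[str(comp)] = "unannotated"
        evidence_rows.append(
            {
                "component": comp,
                "label": annotations[str(comp)],
                "votes": votes.to_dict(),
                "n_called": int(votes.sum()) if len(votes) else 0,
            }
        )
    decomposition.annotations = annotations
    decomposition.annotation_evidence = pd.DataFrame(evidence_rows)
    return annotations


def estimate_fractions(
    sample: pd.Series,
    signature: pd.DataFrame,
    constraint_weight: float | None = None,
    sample_name: str = "sample",
) -> FractionEstimate:
    """Simplex-constrained least-squares deconvolution of one sample.

    Solves ``min ||x - S^T p||^2`` subject to ``p >= 0`` and ``sum(p) = 1``,
    where ``x`` is the sample's expression over signature genes and ``S`` is
    the entity x gene signature matrix.  A sample whose overall scale does
    not match the signature (e.g. a sub-vector of a TPM profile) is first
    brought onto the signature's scale using an unconstrained NNLS solve,
    so the estimate is invariant to rescaling the sample alone.  The sum
    constraint is then imposed via an augmented row with weight
    ``constraint_weight`` (default 1e3 times the mean signature magnitude)
    inside a standard NNLS solve; the returned vector is renormalized to
    sum exactly 1.

    An exactly collinear signature (rank-deficient S) is flagged via
    ``rank_deficient`` with a warning, and the estimate is still returned.
    """
    if signature.shape[0] < 2:
        raise ValueError("signature needs at least two entities")
    if not sample.index.equals(signature.columns):
        sample = sample.reindex(signature.columns)
        if sample.isna().any():
            raise ValueError("sample and signature must share a gene universe")

    A = signature.to_numpy(dtype=float).T  # genes x entities
    b = sample.to_numpy(dtype=float)
    rank_deficient = np.linalg.matrix_rank(A) < A.shape[1]
    if rank_deficient:
        warnings.warn(
            "signature matrix is rank-deficient; fractions are not uniquely "
            "identifiable",
            RuntimeWarning,
            stacklevel=2,
        )

    # scale calibration: an unconstrained solve estimates the sample's total
    # mass in signature units, so a rescaled sample still maps to the simplex
    p0, _ = nnls(A, b)
    scale = p0.sum()
    if scale > 0:
        b = b / scale

    if constraint_weight is None:
        constraint_weight = 1e3 * float(np.abs(A).mean())
    A_aug = np.vstack([A, np.full((1, A.shape[1]), constraint_weight)])
    b_aug = np.concatenate([b, [constraint_weight]])
    p, _ = nnls(A_aug, b_aug)
    total = p.sum()
    if total > 0:
        p = p / total
    residual = float(np.linalg.norm(A @ p - b))
    return FractionEstimate(
        sample=sample_name,
        fractions=pd.Series(p, index=signature.index),
        residual_norm=residual,
        rank_deficient=rank_deficient,
    )


def estimate_fractions_matrix(
    matrix: pd.DataFrame, signature: pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """Column-wise :func:`estimate_fractions`; returns sample x entity fractions."""
    rows = {}
    for col in matrix.columns:
        est = estimate_fractions(matrix[col], signature, sample_name=str(col), **kwargs)
        rows[col] = est.fractions
    return pd.DataFrame(rows).T


def component_fractions(decomposition: NmfDecomposition) -> pd.DataFrame:
    """Per-sample contribution of each annotated component label.

    Each sample's activity column is normalized to sum 1 and aggregated by
    annotation label (components sharing a label pool their shares; the
    ``"unannotated"`` bucket keeps the shares summing to 1 per sample).

    Returns
    -------
    sample x label DataFrame of shares.
    """
    if not decomposition.annotations:
        raise ValueError("decomposition has no component annotations")
    labels = pd.Series(decomposition.annotations)
    if (labels == "unannotated").all():
        raise ValueError("all components are unannotated")

    H = decomposition.activities
    shares = H.div(H.sum(axis=0), axis=1)  # component x sample, columns sum 1
    grouped = shares.groupby(labels.reindex(shares.index)).sum()
    return grouped.T
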