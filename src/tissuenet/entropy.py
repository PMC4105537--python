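"""Tissue specificity by Shannon entropy with a permutation threshold.

Per-tissue mean RPKM is turned into a proportion profile p_it; the entropy
H = -sum p log2 p measures how concentrated a gene's expression is (0 for a
single tissue, log2(T) when uniform over T tissues).  The categorical score
Q_it = H - log2(p_it) approaches 0 when gene i is specific to tissue t.
Significance comes from shuffling tissue labels across libraries: the
smallest entropy seen anywhere in the permuted data is the calling
threshold.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .exprio import ExpressionMatrix, SampleSheet

Q_INF = np.inf  # sentinel for Q where p_it = 0


@dataclass
class TissueProfile:
    gene_ids: list[str]
    tissues: list[str]
    mean_expr: np.ndarray  # genes x tissues mean RPKM
    proportions: np.ndarray  # rows sum to 1


def tissue_profile(mat: ExpressionMatrix, sheet: SampleSheet) -> TissueProfile:
    """Mean RPKM per tissue (states pooled) and row-normalized proportions.

    Genes with zero total expression are excluded with a warning.
    """
    tissues = sheet.tissues
    for t in tissues:
        if not sheet.mask(tissue=t).any():
            raise ValidationError(f"tissue {t} has no libraries")
    means = np.column_stack(
        [mat.values[:, sheet.mask(tissue=t)].mean(axis=1) for t in tissues]
    ) if mat.n_genes else np.zeros((0, len(tissues)))
    totals = means.sum(axis=1)
    keep = totals > 0
    if (~keep).any():
        warnings.warn(
            f"excluding {int((~keep).sum())} gene(s) with zero total expression",
            RuntimeWarning,
        )
    means = means[keep]
    genes = [g for g, k in zip(mat.gene_ids, keep) if k]
    props = means / means.sum(axis=1, keepdims=True) if len(genes) else means
    return TissueProfile(genes, tissues, means, props)


def _entropy(props: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(props > 0, props * np.log2(props), 0.0)
    return -plogp.sum(axis=1)


def entropy_and_q(profile: TissueProfile) -> pd.DataFrame:
    """Entropy H, per-tissue Q = H - log2(p), and the argmin-Q assignment.

    Ties in Q resolve to the lexicographically first tissue and are flagged.
    """
    H = _entropy(profile.proportions)
    with np.errstate(divide="ignore"):
        Q = H[:, None] - np.log2(profile.proportions)
    Q = np.where(profile.proportions > 0, Q, Q_INF)

    order = np.argsort(profile.tissues)  # lexicographic tie-break
    sorted_tissues = [profile.tissues[i] for i in order]
    q_sorted = Q[:, order]
    amin = np.argmin(q_sorted, axis=1) if len(profile.gene_ids) else np.array([], dtype=int)
    assigned = [sorted_tissues[i] for i in amin]
    qmin = q_sorted[np.arange(len(amin)), amin] if len(amin) else np.array([])
    tied = (q_sorted == qmin[:, None]).sum(axis=1) > 1 if len(amin) else np.array([], dtype=bool)

    out = pd.DataFrame(
        {
            "H": H,
            "assigned_tissue": assigned,
            "Q_at_assigned": qmin,
            "tied_assignment": tied,
        },
        index=pd.Index(profile.gene_ids, name="gene"),
    )
    for j, t in enumerate(profile.tissues):
        out[f"Q_{t}"] = Q[:, j]
    return out


def permutation_threshold(
    mat: ExpressionMatrix,
    sheet: SampleSheet,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Smallest entropy observed under random tissue relabelling.

    Each permutation shuffles the tissue labels across libraries (per-tissue
    library counts preserved), recomputes every gene's entropy, and records
    the minimum; the threshold is the minimum over permutations.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    tissues = sheet.tissues
    labels = np.array([tissues.index(t) for t in sheet.frame["tissue"]])
    counts = np.bincount(labels, minlength=len(tissues)).astype(float)
    values = mat.values
    totals = values.sum(axis=1)
    keep = totals > 0
    values = values[keep]
    if values.shape[0] == 0:
        raise ValidationError("no genes with nonzero expression")

    eye = np.eye(len(tissues))
    threshold = np.inf
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        means = (values @ eye[perm]) / counts[None, :]
        props = means / means.sum(axis=1, keepdims=True)
        threshold = min(threshold, float(_entropy(props).min()))
    return threshold


def ts_table(
    mat: ExpressionMatrix,
    sheet: SampleSheet,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full tissue-specificity table: H, assignment, TS call and threshold."""
    profile = tissue_profile(mat, sheet)
    stats = entropy_and_q(profile)
    thr = permutation_threshold(mat, sheet, n_perm=n_perm, seed=seed)
    stats["is_ts"] = stats["H"] < thr
    stats["threshold"] = thr
    return stats
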