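"""Partial-correlation-and-information-theory (PCIT) edge filtering.

For every gene trio (x, y, z) the three first-order partial correlations are
computed; their average ratio to the corresponding direct correlations forms
a local tolerance epsilon.  The x-y association is discarded when some third
gene z explains it, i.e. |r_xy| < |eps * r_xz| and |r_xy| < |eps * r_yz|.
Pairs never eliminated by any trio are the significant network edges.

The vectorized implementation loops over the candidate eliminator z and
processes all (x, y) pairs at once; an independent brute-force triple loop
in the test suite is the normative reference.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .exprio import ExpressionMatrix, SampleSheet
from .normalization import NormalizedExpression


def partial_correlation(rxy: float, rxz: float, ryz: float) -> float:
    """First-order partial correlation of x and y given z."""
    for name, v in (("rxy", rxy), ("rxz", rxz), ("ryz", ryz)):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} outside [-1, 1]")
    denom = (1.0 - rxz * rxz) * (1.0 - ryz * ryz)
    if denom <= 0.0:
        raise ValidationError(
            "partial correlation undefined: a conditioning correlation is +-1"
        )
    return (rxy - rxz * ryz) / np.sqrt(denom)


def pcit(corr: np.ndarray) -> np.ndarray:
    """Boolean significance mask for a symmetric correlation matrix.

    Ratio terms with vanishing denominators are dropped from the tolerance
    average; a trio with no well-defined term eliminates nothing.  The output
    is symmetric with a False diagonal and is independent of gene order.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.ndim != 2 or corr.shape[1] != n:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValidationError("correlation matrix must be symmetric")
    if n < 2:
        return np.zeros((n, n), dtype=bool)

    R = corr.copy()
    np.fill_diagonal(R, 1.0)
    absR = np.abs(R)
    eliminated = np.zeros((n, n), dtype=bool)
    one_minus_sq = 1.0 - R * R  # 0 where |r| = 1

    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(n):
            rz = R[:, z]  # r_xz for all x
            omz = one_minus_sq[:, z]  # 1 - r_xz^2

            # partials for the trio (x, y, z), vectorized over the (x, y) grid
            p_xy_z = (R - np.outer(rz, rz)) / np.sqrt(np.outer(omz, omz))
            p_xz_y = (rz[:, None] - R * rz[None, :]) / np.sqrt(
                one_minus_sq * omz[None, :]
            )
            p_yz_x = (rz[None, :] - R * rz[:, None]) / np.sqrt(
                one_minus_sq * omz[:, None]
            )

            t1 = p_xy_z / R
            t2 = p_xz_y / rz[:, None]
            t3 = p_yz_x / rz[None, :]
            terms = np.stack([t1, t2, t3])
            valid = np.isfinite(terms)
            nvalid = valid.sum(axis=0)
            eps = np.where(
                nvalid > 0,
                np.where(valid, terms, 0.0).sum(axis=0) / np.maximum(nvalid, 1),
                np.nan,
            )

            cond = (absR < np.abs(eps * rz[:, None])) & (
                absR < np.abs(eps * rz[None, :])
            )
            cond &= np.isfinite(eps)
            cond[z, :] = False
            cond[:, z] = False
            np.fill_diagonal(cond, False)
            eliminated |= cond

    significant = ~eliminated & (absR > 0)
    np.fill_diagonal(significant, False)
    return significant


@dataclass
class StateNetwork:
    """PCIT-significant co-expression network for one physiological state."""

    state: str
    gene_ids: list[str]
    corr: np.ndarray
    significant: np.ndarray  # boolean mask, symmetric
    node_attrs: pd.DataFrame  # tissue_of_max_expression, is_TF, mean_expr

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.significant, k=1).sum())

    @property
    def connectivity(self) -> pd.Series:
        return pd.Series(self.significant.sum(axis=1), index=self.gene_ids)

    def edges(self) -> list[tuple[str, str, float]]:
        iu = np.triu_indices(len(self.gene_ids), k=1)
        out = []
        for i, j in zip(*iu):
            if self.significant[i, j]:
                out.append((self.gene_ids[i], self.gene_ids[j], float(self.corr[i, j])))
        return out

    def neighbor_sets(self) -> dict[str, set[str]]:
        ids = self.gene_ids
        return {
            ids[i]: {ids[j] for j in np.where(self.significant[i])[0]}
            for i in range(len(ids))
        }

    def write_sif(self, path) -> None:
        with open(path, "w") as fh:
            for a, b, _ in self.edges():
                fh.write(f"{a}\tpp\t{b}\n")

    def edge_frame(self) -> pd.DataFrame:
        rows = [(a, b, r, self.state) for a, b, r in self.edges()]
        return pd.DataFrame(rows, columns=["geneA", "geneB", "r", "state"])


def _pearson_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations; zero-variance rows correlate as 0."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc**2).sum(axis=1))
    zero = sd < 1e-12
    sd_safe = np.where(zero, 1.0, sd)
    C = (Xc / sd_safe[:, None]) @ (Xc / sd_safe[:, None]).T
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    return C


def build_state_network(
    norm: NormalizedExpression,
    sheet: SampleSheet,
    genes: list[str],
    state: str,
    rpkm: ExpressionMatrix | None = None,
    tf_ids: set[str] | None = None,
) -> StateNetwork:
    """Pearson correlations over one state's libraries, filtered by PCIT.

    Node attributes carry the tissue of maximum mean RPKM (falling back to
    normalized values when no RPKM matrix is supplied), a TF flag and the
    mean expression within the state.
    """
    genes = sorted(genes)
    mask = sheet.mask(state=state)
    if mask.sum() < 3:
        raise ValidationError(f"state {state} has {int(mask.sum())} libraries; need >= 3")
    pos = {g: i for i, g in enumerate(norm.gene_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing}")
    rows = [pos[g] for g in genes]
    X = norm.values[np.ix_(rows, np.where(mask)[0])]
    corr = _pearson_rows(X)
    significant = pcit(corr)

    src = rpkm if rpkm is not None else None
    tissues = sheet.tissues
    if src is not None:
        spos = {g: i for i, g in enumerate(src.gene_ids)}
        srows = [spos[g] for g in genes]
        per_tissue = np.column_stack(
            [src.values[np.ix_(srows, np.where(sheet.mask(tissue=t))[0])].mean(axis=1) for t in tissues]
        )
    else:
        per_tissue = np.column_stack(
            [norm.values[np.ix_(rows, np.where(sheet.mask(tissue=t))[0])].mean(axis=1) for t in tissues]
        )
    max_tissue = [tissues[i] for i in np.argmax(per_tissue, axis=1)]
    tf_ids = tf_ids or set()
    attrs = pd.DataFrame(
        {
            "tissue_of_max_expression": max_tissue,
            "is_TF": [g in tf_ids for g in genes],
            "mean_expr_state": X.mean(axis=1),
        },
        index=pd.Index(genes, name="gene"),
    )
    return StateNetwork(state, genes, corr, significant, attrs)


def find_hubs(net: StateNetwork, n_sd: float = 2.0) -> set[str]:
    """Nodes whose connectivity exceeds mean + n_sd standard deviations."""
    if len(net.gene_ids) < 2:
        raise ValidationError("need at least 2 nodes")
    k = net.connectivity
    cut = k.mean() + n_sd * k.std(ddof=0)
    return set(k.index[k > cut])
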