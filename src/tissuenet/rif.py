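"""Regulator impact scoring from differential wiring between two states.

For each candidate regulator r and each DE/TS target j, co-expression
correlations are computed separately over the PRE and POST libraries (r1 and
r2); their difference dw = r1 - r2 is the differential wiring.  Two scores
summarize a regulator's footprint over the n targets:

    score1_r = (1/n) sum_j a_j * d_j * dw_rj^2
    score2_r = (1/n) sum_j [(e1_j * r1_rj)^2 - (e2_j * r2_rj)^2]

with a_j the target's average expression over all samples, d_j its
differential expression, and e1_j/e2_j its average expression per state.
Scores are z-standardized across regulators; |z| >= 1.96 marks nominal 5%
significance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .exprio import SampleSheet
from .normalization import NormalizedExpression

RIF_CRITERIA = (
    "rif1",
    "rif2",
    "overall_de",
    "max_de",
    "connections_pre",
    "connections_post",
    "connection_fold_change",
    "expansion_pre",
    "expansion_post",
)


@dataclass
class RegulatorSet:
    regulators: list[str]
    targets: list[str]

    def __post_init__(self) -> None:
        self.regulators = list(dict.fromkeys(self.regulators))
        self.targets = list(dict.fromkeys(self.targets))
        if len(self.targets) < 1:
            raise ValidationError("need at least one DE/TS target")

    @property
    def n_dets(self) -> int:
        return len(self.targets)


def state_correlations(
    norm: NormalizedExpression,
    sheet: SampleSheet,
    regulators: list[str],
    targets: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regulator x target Pearson correlations per state (PRE -> r1, POST -> r2).

    Zero-variance profiles yield correlation 0 (flagged via attrs).
    """
    out = []
    pos = {g: i for i, g in enumerate(norm.gene_ids)}
    missing = [g for g in list(regulators) + list(targets) if g not in pos]
    if missing:
        raise ValidationError(f"ids absent from normalized matrix: {sorted(set(missing))}")
    for state in ("PRE", "POST"):
        mask = sheet.mask(state=state)
        if mask.sum() < 3:
            raise ValidationError(f"state {state} has fewer than 3 libraries")
        X = norm.values[:, mask]
        R = X[[pos[r] for r in regulators]]
        T = X[[pos[t] for t in targets]]
        Rc = R - R.mean(axis=1, keepdims=True)
        Tc = T - T.mean(axis=1, keepdims=True)
        rsd = np.sqrt((Rc**2).sum(axis=1))
        tsd = np.sqrt((Tc**2).sum(axis=1))
        rz, tz = rsd < 1e-12, tsd < 1e-12
        C = (Rc / np.where(rz, 1.0, rsd)[:, None]) @ (Tc / np.where(tz, 1.0, tsd)[:, None]).T
        C[rz, :] = 0.0
        C[:, tz] = 0.0
        C = np.clip(C, -1.0, 1.0)
        df = pd.DataFrame(C, index=regulators, columns=targets)
        df.attrs["zero_variance_regulators"] = [r for r, z in zip(regulators, rz) if z]
        df.attrs["zero_variance_targets"] = [t for t, z in zip(targets, tz) if z]
        out.append(df)
    return out[0], out[1]


def rif_scores(
    reg: RegulatorSet,
    r1: pd.DataFrame,
    r2: pd.DataFrame,
    a: pd.Series,
    d: pd.Series,
    e1: pd.Series,
    e2: pd.Series,
) -> pd.DataFrame:
    """Raw and z-standardized impact scores per regulator.

    Self-pairs (a regulator that is also a target) contribute nothing to its
    own sums.
    """
    if reg.n_dets == 0:
        raise ValidationError("empty target set")
    targets = reg.targets
    for name, s in (("a", a), ("d", d), ("e1", e1), ("e2", e2)):
        missing = set(targets) - set(s.index)
        if missing:
            raise ValidationError(f"{name} missing targets: {sorted(missing)}")
    av = a[targets].to_numpy()
    dv = d[targets].to_numpy()
    e1v = e1[targets].to_numpy()
    e2v = e2[targets].to_numpy()
    R1 = r1.loc[reg.regulators, targets].to_numpy()
    R2 = r2.loc[reg.regulators, targets].to_numpy()

    self_mask = np.array(
        [[rg == tg for tg in targets] for rg in reg.regulators], dtype=bool
    )
    dw = R1 - R2
    term1 = av[None, :] * dv[None, :] * dw**2
    term2 = (e1v[None, :] * R1) ** 2 - (e2v[None, :] * R2) ** 2
    term1 = np.where(self_mask, 0.0, term1)
    term2 = np.where(self_mask, 0.0, term2)
    n = reg.n_dets
    rif1_raw = term1.sum(axis=1) / n
    rif2_raw = term2.sum(axis=1) / n

    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    out = pd.DataFrame(
        {
            "rif1_raw": rif1_raw,
            "rif1_z": zscore(rif1_raw),
            "rif2_raw": rif2_raw,
            "rif2_z": zscore(rif2_raw),
        },
        index=pd.Index(reg.regulators, name="regulator"),
    )
    out["significant"] = (out["rif1_z"].abs() >= 1.96) | (out["rif2_z"].abs() >= 1.96)
    return out


def rank_regulators(criteria: pd.DataFrame) -> pd.DataFrame:
    """Aggregate nine-criteria ranking of regulators.

    Each criterion ranks descending by absolute value (rank 1 = strongest);
    the aggregate is the mean rank, ties broken by the first-criterion rank,
    then by id for full determinism.  Input row order is irrelevant.
    """
    missing = [c for c in RIF_CRITERIA if c not in criteria.columns]
    if missing:
        raise ValidationError(f"missing criterion column(s): {missing}")
    ranks = pd.DataFrame(index=criteria.index)
    for c in RIF_CRITERIA:
        ranks[f"rank_{c}"] = criteria[c].abs().rank(ascending=False, method="average")
    out = criteria.copy().join(ranks)
    out["aggregate_rank"] = ranks.mean(axis=1)
    idx_name = out.index.name or "regulator"
    out.index.name = idx_name
    out = (
        out.reset_index()
        .sort_values(
            by=["aggregate_rank", f"rank_{RIF_CRITERIA[0]}", idx_name], kind="stable"
        )
        .set_index(idx_name)
    )
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out
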