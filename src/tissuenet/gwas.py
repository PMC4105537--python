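"""GWAS-expression integration: SNP associations joined to DE/TS evidence.

A SNP row survives when its association p-value and gene distance pass the
thresholds, its gene is expressed, and that gene carries DE or TS evidence
in at least one tissue.  The emitted record mirrors the reference
integrated-locus table packaged with the module (also used by the tests).
"""
from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_P_MAX = 0.01
DEFAULT_MAX_DIST = 10_000

LOCUS_COLUMNS = [
    "gene",
    "de_flag",
    "ts_flag",
    "tissue",
    "fold_change",
    "snp",
    "chrom",
    "pos",
    "distance_bp",
    "side",
    "trait",
    "pvalue",
]

UTERINE_TISSUES = {"UTE", "END", "UTERUS", "ENDOMETRIUM"}


def _validate_snps(snps: pd.DataFrame) -> pd.DataFrame:
    required = {"snp", "chrom", "pos", "trait", "pvalue", "gene", "distance_bp", "side"}
    missing = required - set(snps.columns)
    if missing:
        raise ValidationError(f"SNP table missing columns: {sorted(missing)}")
    snps = snps.copy()
    snps["pvalue"] = snps["pvalue"].astype(float)
    snps["distance_bp"] = snps["distance_bp"].astype(int)
    if (snps["distance_bp"] < 0).any():
        raise ValidationError("negative distance_bp")
    bad = snps[(snps["distance_bp"] == 0) != (snps["side"] == "within")]
    if len(bad):
        raise ValidationError(
            f"distance 0 must pair with side='within' (and vice versa); offending SNPs: "
            f"{list(bad['snp'].head())}"
        )
    if ((snps["pvalue"] <= 0) | (snps["pvalue"] > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return snps


def intersect(
    snps: pd.DataFrame,
    expressed: set[str],
    de_calls: pd.DataFrame,
    ts_result: pd.DataFrame,
    p_max: float = DEFAULT_P_MAX,
    max_dist: int = DEFAULT_MAX_DIST,
) -> pd.DataFrame:
    """Integrated loci: filtered SNPs whose gene has DE or TS evidence.

    Parameters
    ----------
    de_calls
        Long-format DE table (columns gene, tissue, is_de, posterior_null,
        fold_change).
    ts_result
        Tissue-specificity table indexed by gene with columns is_ts and
        assigned_tissue.

    The evidence tissue is the DE tissue with the smallest posterior null
    when the gene is DE anywhere, otherwise the TS assigned tissue; the fold
    change is taken from the DE measure in that tissue when available.
    """
    snps = _validate_snps(snps)
    de_hit: dict[str, pd.Series] = {}
    if len(de_calls):
        de_sig = de_calls[de_calls["is_de"]]
        for gene, grp in de_sig.groupby("gene"):
            de_hit[gene] = grp.loc[grp["posterior_null"].idxmin()]
    ts_hit = (
        ts_result[ts_result["is_ts"]]["assigned_tissue"].to_dict() if len(ts_result) else {}
    )
    fold_lookup = (
        de_calls.set_index(["gene", "tissue"])["fold_change"].to_dict()
        if len(de_calls)
        else {}
    )

    kept = snps[(snps["pvalue"] < p_max) & (snps["distance_bp"] < max_dist)]
    n_unknown = int((~kept["gene"].isin(expressed)).sum())
    if n_unknown:
        logger.info("dropping %d SNP rows whose gene is not in the expression universe", n_unknown)
    kept = kept[kept["gene"].isin(expressed)]

    rows = []
    for _, r in kept.iterrows():
        gene = r["gene"]
        is_de = gene in de_hit
        is_ts = gene in ts_hit
        if not (is_de or is_ts):
            continue
        tissue = de_hit[gene]["tissue"] if is_de else ts_hit[gene]
        fold = fold_lookup.get((gene, tissue), np.nan)
        rows.append(
            {
                "gene": gene,
                "de_flag": int(is_de),
                "ts_flag": int(is_ts),
                "tissue": tissue,
                "fold_change": fold,
                "snp": r["snp"],
                "chrom": r["chrom"],
                "pos": r["pos"],
                "distance_bp": r["distance_bp"],
                "side": r["side"],
                "trait": r["trait"],
                "pvalue": r["pvalue"],
            }
        )
    return pd.DataFrame(rows, columns=LOCUS_COLUMNS)


def summarize(loci: pd.DataFrame) -> dict[str, int]:
    """Headline counts over an integrated-locus table."""
    if len(loci) == 0:
        base = {"total": 0, "within_gene": 0, "uterus_endometrium": 0, "de": 0, "ts": 0}
        base.update({f"trait_{t}": 0 for t in ("ACL", "FSC", "HPG")})
        return base
    out = {
        "total": int(len(loci)),
        "within_gene": int((loci["distance_bp"] == 0).sum()),
        "uterus_endometrium": int(
            loci["tissue"].astype(str).str.upper().isin(UTERINE_TISSUES).sum()
        ),
        "de": int((loci["de_flag"] == 1).sum()),
        "ts": int((loci["ts_flag"] == 1).sum()),
    }
    for t in ("ACL", "FSC", "HPG"):
        out[f"trait_{t}"] = int((loci["trait"] == t).sum())
    return out


def load_reference_loci() -> pd.DataFrame:
    """The packaged 25-row integrated-locus reference table."""
    with resources.files("tissuenet.data").joinpath(
        "integrated_loci_reference.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
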