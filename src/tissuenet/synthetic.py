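"""Synthetic multi-tissue expression datasets with planted ground truth.

Simulation operates on the log2 scale under the same additive structure the
normalization model assumes (library offset + gene + gene x tissue +
gene x animal + gene x state + noise) and exponentiates to RPKM at the end.
Planted signals — state-shifted genes, tissue-restricted genes, regulators
whose target co-expression flips between states — are recorded in a truth
table so recovery tests can score every downstream stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .exprio import ExpressionMatrix, SampleSheet

DEFAULT_TISSUES = ("HYP", "PIT", "UTE", "END", "OVA", "FAT", "LIV", "LDM")
TRAITS = ("ACL", "FSC", "HPG")


@dataclass
class SimConfig:
    """Knobs for one simulated dataset; a single seed drives all randomness."""

    n_genes: int = 500
    n_tissues: int = 8
    n_animals_per_state: int = 4
    tissue_names: tuple[str, ...] = DEFAULT_TISSUES
    # (sigma2_G, sigma2_GT, sigma2_GA, sigma2_GP, sigma2_e); the gene-level
    # component doubles as the baseline log2-abundance spread (sd 2 default).
    variance_components: tuple[float, float, float, float, float] = (
        4.0,
        0.5,
        0.25,
        0.25,
        0.5,
    )
    baseline_mean: float = 3.0
    library_effect_sd: float = 0.0
    n_de: int = 0
    de_shift: float = 2.0
    de_frac_down: float = 0.0
    n_ts: int = 0
    ts_boost: float = 5.0
    n_regulators: int = 0
    n_rewired_regulators: int = 0
    rewire_strength: float = 1.0
    n_targets_per_regulator: int = 10
    latent_factor_sd: float = 3.0
    # rewired regulators additionally shifted by de_shift at POST (a regulator
    # driving a coherent module is typically itself responsive)
    rewired_are_de: bool = False
    n_snps: int = 0
    drop_libraries: int = 0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_de": self.n_de,
            "n_ts": self.n_ts,
            "n_regulators": self.n_regulators,
            "n_rewired_regulators": self.n_rewired_regulators,
            "n_snps": self.n_snps,
            "drop_libraries": self.drop_libraries,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if self.n_tissues <= 0 or self.n_animals_per_state <= 0:
            raise ConfigurationError("n_tissues and n_animals_per_state must be positive")
        if len(self.tissue_names) != self.n_tissues:
            raise ConfigurationError(
                f"need {self.n_tissues} tissue names, got {len(self.tissue_names)}"
            )
        if len(set(self.tissue_names)) != len(self.tissue_names):
            raise ConfigurationError("tissue names must be distinct")
        if any(c < 0 for c in self.variance_components):
            raise ConfigurationError("variance components must be nonnegative")
        if self.library_effect_sd < 0:
            raise ConfigurationError("library_effect_sd must be nonnegative")
        if self.n_de + self.n_ts > self.n_genes:
            raise ConfigurationError("n_de + n_ts exceeds n_genes")
        if self.n_rewired_regulators > self.n_regulators:
            raise ConfigurationError("n_rewired_regulators exceeds n_regulators")
        if not 0.0 <= self.rewire_strength <= 2.0:
            raise ConfigurationError("rewire_strength must be in [0, 2]")
        if not 0.0 <= self.de_frac_down <= 1.0:
            raise ConfigurationError("de_frac_down must be in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth of one generation run, keyed by gene/SNP id."""

    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed shift
    ts_genes: dict[str, str] = field(default_factory=dict)  # gene -> planted tissue
    regulators: list[str] = field(default_factory=list)
    rewired_regulators: set[str] = field(default_factory=set)
    regulator_targets: dict[str, list[str]] = field(default_factory=dict)
    snp_truth: dict[str, tuple[str, str, bool]] = field(default_factory=dict)
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, s in self.de_genes.items():
            rows.append({"id": g, "kind": "DE", "value": s})
        for g, t in self.ts_genes.items():
            rows.append({"id": g, "kind": "TS", "value": t})
        for r in self.regulators:
            kind = "REWIRED_TF" if r in self.rewired_regulators else "TF"
            rows.append({"id": r, "kind": kind, "value": ""})
        for snp, (g, trait, within) in self.snp_truth.items():
            rows.append({"id": snp, "kind": "SNP", "value": f"{g}|{trait}|{int(within)}"})
        return pd.DataFrame(rows, columns=["id", "kind", "value"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_dataset(config: SimConfig) -> tuple[ExpressionMatrix, SampleSheet, TruthTable]:
    """Simulate RPKM = 2^(log2 signal) for the configured design.

    Libraries are one per animal x tissue x state; PRE and POST use disjoint
    animal cohorts, mirroring a cross-sectional design.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    s2g, s2gt, s2ga, s2gp, s2e = config.variance_components

    tissues = list(config.tissue_names)
    states = ("PRE", "POST")
    animals = {
        "PRE": [f"A{i + 1}" for i in range(config.n_animals_per_state)],
        "POST": [f"A{i + 1 + config.n_animals_per_state}" for i in range(config.n_animals_per_state)],
    }
    rows = []
    for state in states:
        for animal in animals[state]:
            for tissue in tissues:
                rows.append(
                    {
                        "library": f"{tissue}_{state}_{animal}",
                        "tissue": tissue,
                        "animal": animal,
                        "state": state,
                    }
                )
    sheet = SampleSheet(pd.DataFrame(rows))
    n_lib = len(rows)
    J = config.n_genes
    genes = _gene_ids(J)

    truth = TruthTable(seed=config.seed)
    if J == 0:
        mat = ExpressionMatrix([], sheet.libraries, np.zeros((0, n_lib)))
        return mat, sheet, truth

    tissue_idx = np.array([tissues.index(t) for t in sheet.frame["tissue"]])
    all_animals = animals["PRE"] + animals["POST"]
    animal_idx = np.array([all_animals.index(a) for a in sheet.frame["animal"]])
    state_idx = np.array([states.index(s) for s in sheet.frame["state"]])

    G = rng.normal(0.0, np.sqrt(s2g), size=J)
    GT = rng.normal(0.0, np.sqrt(s2gt), size=(J, len(tissues)))
    GA = rng.normal(0.0, np.sqrt(s2ga), size=(J, len(all_animals)))
    GP = rng.normal(0.0, np.sqrt(s2gp), size=(J, 2))
    L = rng.normal(0.0, config.library_effect_sd, size=n_lib)
    E = rng.normal(0.0, np.sqrt(s2e), size=(J, n_lib))

    log2sig = (
        config.baseline_mean
        + G[:, None]
        + GT[:, tissue_idx]
        + GA[:, animal_idx]
        + GP[:, state_idx]
        + L[None, :]
        + E
    )

    # -- planted signals ----------------------------------------------------
    perm = rng.permutation(J)
    de_rows = perm[: config.n_de]
    ts_rows = perm[config.n_de : config.n_de + config.n_ts]
    remaining = perm[config.n_de + config.n_ts :]

    post_mask = state_idx == 1
    n_down = int(round(config.de_frac_down * config.n_de))
    for rank, j in enumerate(de_rows):
        shift = -config.de_shift if rank < n_down else config.de_shift
        log2sig[j, post_mask] += shift
        truth.de_genes[genes[j]] = shift

    for j in ts_rows:
        t = int(rng.integers(len(tissues)))
        log2sig[j, tissue_idx == t] += config.ts_boost
        truth.ts_genes[genes[j]] = tissues[t]

    # Regulators are drawn from genes without planted DE/TS structure when
    # possible; rewired ones share a latent library factor with their targets,
    # with opposite-signed target coupling in the two states.
    if config.n_regulators > 0:
        pool = remaining if len(remaining) >= config.n_regulators else perm
        reg_rows = pool[: config.n_regulators]
        truth.regulators = [genes[j] for j in reg_rows]
        # coherent modules: prefer up-shifted DE targets (plus TS genes) so a
        # regulator's wiring is not self-cancelling across target directions
        target_pool = [g for g, s in truth.de_genes.items() if s > 0] + list(truth.ts_genes)
        if not target_pool:
            target_pool = list(truth.de_genes) or [
                genes[j] for j in perm if j not in set(reg_rows)
            ]
        gamma = config.latent_factor_sd
        v_within = s2gt + s2ga + s2e  # per-library spread within one state
        var_reg = gamma**2 + v_within
        rho_max = 0.95 * gamma / np.sqrt(var_reg)
        # symmetric split (+s/2 in PRE, -s/2 in POST) keeps per-state coupling
        # moderate, so the regulator explains its targets' cross-correlations
        # instead of drowning in a saturated clique
        rho_pre = float(np.clip(config.rewire_strength / 2.0, 0.0, rho_max))
        rho_post = -float(np.clip(config.rewire_strength - rho_pre, 0.0, rho_max))
        gene_pos = {g: i for i, g in enumerate(genes)}
        for j in reg_rows[: config.n_rewired_regulators]:
            rid = genes[j]
            truth.rewired_regulators.add(rid)
            if config.rewired_are_de:
                log2sig[j, post_mask] += config.de_shift
                truth.de_genes[rid] = config.de_shift
            factor = rng.normal(0.0, 1.0, size=n_lib)
            log2sig[j] += gamma * factor
            n_t = min(config.n_targets_per_regulator, len(target_pool))
            targets = list(rng.choice(target_pool, size=n_t, replace=False))
            truth.regulator_targets[rid] = targets
            for r, mask in ((rho_pre, ~post_mask), (rho_post, post_mask)):
                if abs(r) < 1e-12:
                    continue
                beta = r * np.sqrt(
                    var_reg * v_within / (gamma**2 - r**2 * var_reg)
                )
                for tg in targets:
                    log2sig[gene_pos[tg], mask] += beta * factor[mask]

    # -- optional library dropout ------------------------------------------
    if config.drop_libraries > 0:
        frame = sheet.frame
        keep = np.ones(n_lib, dtype=bool)
        for _ in range(config.drop_libraries):
            cells = frame.loc[keep].groupby(["tissue", "state"]).size()
            droppable = [
                i
                for i in np.where(keep)[0]
                if cells.get((frame.at[i, "tissue"], frame.at[i, "state"]), 0) > 1
            ]
            if not droppable:
                break
            keep[rng.choice(droppable)] = False
        log2sig = log2sig[:, keep]
        sheet = SampleSheet(frame.loc[keep])

    mat = ExpressionMatrix(genes, sheet.libraries, np.exp2(log2sig))
    return mat, sheet, truth


def generate_snp_table(config: SimConfig, truth: TruthTable) -> pd.DataFrame:
    """Emit a SNP association table; ~70% of rows tag planted DE/TS genes.

    Truth rows sit within their gene (distance 0) with p < 0.01; decoys point
    at random genes at 1..10,000 bp with p > 0.01.
    """
    config.validate()
    if config.n_snps > config.n_genes * 3:
        raise ConfigurationError("n_snps may not exceed 3 x n_genes")
    rng = np.random.default_rng(config.seed + 104729)  # independent stream
    genes = _gene_ids(config.n_genes)
    planted = sorted(set(truth.de_genes) | set(truth.ts_genes))

    n_truth = int(round(0.7 * config.n_snps)) if planted else 0
    records = []
    for i in range(config.n_snps):
        snp = f"rs{900000 + i}"
        trait = TRAITS[int(rng.integers(len(TRAITS)))]
        chrom = int(rng.integers(1, 30))
        pos = int(rng.integers(1, 120_000_000))
        if i < n_truth:
            gene = planted[int(rng.integers(len(planted)))]
            dist, side = 0, "within"
            p = float(rng.uniform(1e-5, 0.009))
            truth.snp_truth[snp] = (gene, trait, True)
        else:
            gene = genes[int(rng.integers(len(genes)))]
            dist = int(rng.integers(1, 10_001))
            side = "upstream" if rng.random() < 0.5 else "downstream"
            p = float(rng.uniform(0.011, 1.0))
        records.append(
            {
                "snp": snp,
                "chrom": chrom,
                "pos": pos,
                "trait": trait,
                "pvalue": p,
                "gene": gene,
                "distance_bp": dist,
                "side": side,
            }
        )
    cols = ["snp", "chrom", "pos", "trait", "pvalue", "gene", "distance_bp", "side"]
    return pd.DataFrame(records, columns=cols)


def write_dataset(outdir, mat: ExpressionMatrix, sheet: SampleSheet, truth: TruthTable,
                  snps: pd.DataFrame | None = None) -> dict[str, str]:
    """Write all generator outputs as tab-delimited text; returns path map."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    mat.write_tsv(out / "expression.tsv")
    paths["expression"] = str(out / "expression.tsv")
    sheet.write_tsv(out / "samples.tsv")
    paths["samples"] = str(out / "samples.tsv")
    truth.write_tsv(out / "truth.tsv")
    paths["truth"] = str(out / "truth.tsv")
    (out / "tf_list.txt").write_text("".join(f"{r}\n" for r in truth.regulators))
    paths["tf_list"] = str(out / "tf_list.txt")
    if snps is not None:
        snps.to_csv(out / "snps.tsv", sep="\t", index=False)
        paths["snps"] = str(out / "snps.tsv")
    return paths
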