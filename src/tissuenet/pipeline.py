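"""End-to-end orchestration: simulate/ingest through GWAS integration.

Stages run in dependency order; enabling a stage pulls in its prerequisites
(logged).  A single global seed is fanned out into per-stage sub-seeds so
that toggling one stage never shifts another stage's random stream.  The run
manifest records seeds, per-stage row counts and sha256 hashes of every
output file, which makes reproducibility checks a hash comparison.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, ValidationError
from .exprio import filter_expressed, log_transform, read_expression
from .gwas import intersect, summarize
from .mixture import de_table
from .netanalysis import best_trio, compare_networks, expansion_ability, extract_subnetwork
from .normalization import cluster_check, fit_mixed_model, normalize
from .pcit import build_state_network, find_hubs
from .rif import RegulatorSet, rank_regulators, rif_scores, state_correlations
from .synthetic import SimConfig, generate_dataset, generate_snp_table, write_dataset
from .entropy import ts_table

logger = logging.getLogger(__name__)

STAGES = ("data", "filter", "normalize", "de", "ts", "rif", "networks", "delta", "gwas")

DEPENDENCIES = {
    "data": (),
    "filter": ("data",),
    "normalize": ("filter",),
    "de": ("normalize",),
    "ts": ("filter",),
    "rif": ("de", "ts"),
    "networks": ("de", "ts"),
    "delta": ("networks", "rif"),
    "gwas": ("de", "ts"),
}

CONFIG_VERSION = 1

DEFAULT_THRESHOLDS = {
    "rpkm": 0.2,
    "fdr": 0.01,
    "ts_permutations": 1000,
    "gwas_p": 0.01,
    "gwas_distance": 10000,
    "hub_sd": 2.0,
    "rif_z": 1.96,
}


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulation: SimConfig | None = None
    expression_path: str | None = None
    samples_path: str | None = None
    snps_path: str | None = None
    tf_list_path: str | None = None
    tfbs_path: str | None = None
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    stages: tuple[str, ...] = STAGES
    subnetwork_tissues: tuple[str, ...] = ("HYP", "PIT")

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
        extra = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if extra:
            raise ConfigurationError(f"unknown threshold(s): {sorted(extra)}")
        th = {**DEFAULT_THRESHOLDS, **self.thresholds}
        if not 0 < th["fdr"] < 1 or not 0 < th["gwas_p"] <= 1:
            raise ConfigurationError("fdr and gwas_p must be in (0, 1)")
        if th["rpkm"] <= 0 or th["gwas_distance"] <= 0 or th["ts_permutations"] < 1:
            raise ConfigurationError("rpkm, gwas_distance and ts_permutations must be positive")
        self.thresholds = th
        if self.simulation is None and (self.expression_path is None or self.samples_path is None):
            raise ConfigurationError("either a simulation block or input file paths are required")


def load_config(path) -> PipelineConfig:
    """Parse a config file (flat YAML mapping); unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if raw.get("version") != CONFIG_VERSION:
        raise ConfigurationError(f"config version must be {CONFIG_VERSION}")
    allowed = {
        "version",
        "outdir",
        "seed",
        "simulation",
        "inputs",
        "thresholds",
        "stages",
        "subnetwork_tissues",
    }
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    sim = None
    if "simulation" in raw:
        sim_keys = {f.name for f in dc_fields(SimConfig)}
        bad = set(raw["simulation"]) - sim_keys
        if bad:
            raise ConfigurationError(f"unknown simulation key(s): {sorted(bad)}")
        sim_kwargs = dict(raw["simulation"])
        for tup_key in ("tissue_names", "variance_components"):
            if tup_key in sim_kwargs:
                sim_kwargs[tup_key] = tuple(sim_kwargs[tup_key])
        sim = SimConfig(**sim_kwargs)
    inputs = raw.get("inputs", {}) or {}
    bad_inputs = set(inputs) - {"expression", "samples", "snps", "tf_list", "tfbs"}
    if bad_inputs:
        raise ConfigurationError(f"unknown input key(s): {sorted(bad_inputs)}")
    cfg = PipelineConfig(
        outdir=raw.get("outdir", "tissuenet_out"),
        seed=int(raw.get("seed", 0)),
        simulation=sim,
        expression_path=inputs.get("expression"),
        samples_path=inputs.get("samples"),
        snps_path=inputs.get("snps"),
        tf_list_path=inputs.get("tf_list"),
        tfbs_path=inputs.get("tfbs"),
        thresholds=raw.get("thresholds", {}) or {},
        stages=tuple(raw.get("stages", STAGES)),
        subnetwork_tissues=tuple(raw.get("subnetwork_tissues", ("HYP", "PIT"))),
    )
    cfg.validate()
    return cfg


def stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16)


def _closure(stages: tuple[str, ...]) -> list[str]:
    enabled = set(stages)
    changed = True
    while changed:
        changed = False
        for s in list(enabled):
            for dep in DEPENDENCIES[s]:
                if dep not in enabled:
                    logger.info("stage %s requires %s; enabling it", s, dep)
                    enabled.add(dep)
                    changed = True
    return [s for s in STAGES if s in enabled]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = _closure(config.stages)
    th = config.thresholds
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": stages,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in stages},
        "counts": {},
        "outputs": {},
    }

    ctx: dict = {}
    current = None
    try:
        for stage in stages:
            current = stage
            logger.info("running stage %s", stage)
            _run_stage(stage, config, ctx, out, th, manifest)
    except Exception as exc:  # noqa: BLE001 - abort semantics per contract
        (out / f"{current}.failed").write_text(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"stage {current!r} failed: {exc}") from exc

    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_stage(stage, config, ctx, out, th, manifest):
    if stage == "data":
        if config.simulation is not None:
            sim = config.simulation
            mat, sheet, truth = generate_dataset(sim)
            snps = generate_snp_table(sim, truth) if sim.n_snps else None
            write_dataset(out, mat, sheet, truth, snps)
            ctx.update(mat=mat, sheet=sheet, truth=truth, snps=snps,
                       tf_list=list(truth.regulators))
        else:
            mat, sheet = read_expression(config.expression_path, config.samples_path)
            snps = (
                pd.read_csv(config.snps_path, sep="\t") if config.snps_path else None
            )
            tf_list = []
            if config.tf_list_path:
                tf_list = [
                    l.strip()
                    for l in Path(config.tf_list_path).read_text().splitlines()
                    if l.strip()
                ]
            if config.tfbs_path:
                tfbs = pd.read_csv(config.tfbs_path, sep="\t")
                tf_list = list(dict.fromkeys(tf_list + list(tfbs["TF"].astype(str))))
            ctx.update(mat=mat, sheet=sheet, truth=None, snps=snps, tf_list=tf_list)
        manifest["counts"]["data"] = {
            "genes": ctx["mat"].n_genes,
            "libraries": ctx["mat"].n_libraries,
            "snps": 0 if ctx["snps"] is None else len(ctx["snps"]),
        }
        return

    if stage == "filter":
        mat, sheet = ctx["mat"], ctx["sheet"]
        expressed = filter_expressed(mat, sheet, threshold=th["rpkm"])
        keep = [g in expressed for g in mat.gene_ids]
        sub = mat.values[np.array(keep, dtype=bool)] if mat.n_genes else mat.values
        from .exprio import ExpressionMatrix

        fmat = ExpressionMatrix(
            [g for g in mat.gene_ids if g in expressed], mat.library_ids, sub
        )
        ctx.update(expressed=expressed, fmat=fmat)
        pd.Series(sorted(expressed), name="gene").to_csv(
            out / "expressed_genes.tsv", sep="\t", index=False
        )
        manifest["counts"]["filter"] = {"expressed": len(expressed)}
        return

    if stage == "normalize":
        fmat, sheet = ctx["fmat"], ctx["sheet"]
        logmat = log_transform(fmat, floor=th["rpkm"])
        fit = fit_mixed_model(logmat, sheet, gene_ids=fmat.gene_ids)
        norm = normalize(fit, sheet, allow_unconverged=True)
        labels, agreement = cluster_check(norm, sheet)
        norm.write_tsv(out / "normalized.tsv")
        summary = {
            "variance_components": dict(
                zip(("sigma2_G", "sigma2_GT", "sigma2_GA", "sigma2_GP", "sigma2_e"),
                    fit.variance_components)
            ),
            "n_reml_iterations": fit.n_reml_iterations,
            "converged": bool(fit.converged),
            "cluster_agreement": agreement,
        }
        (out / "model_fit.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        pd.DataFrame(
            {"library": norm.library_ids, "cluster": labels,
             "tissue": list(sheet.frame["tissue"])}
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        # library-effect-adjusted values (mu and L removed, residual kept):
        # per-sample expression for co-expression work, where solutions-only
        # values would have no within-state degrees of freedom
        from .normalization import NormalizedExpression

        b = fit.mu + fit.library_effects.to_numpy()
        adjusted = NormalizedExpression(
            fmat.gene_ids, norm.library_ids, logmat - b[None, :]
        )
        ctx.update(fit=fit, norm=norm, logmat=logmat, adjusted=adjusted)
        manifest["counts"]["normalize"] = {
            "iterations": fit.n_reml_iterations,
            "converged": bool(fit.converged),
        }
        return

    if stage == "de":
        calls = de_table(
            ctx["norm"], ctx["sheet"], fdr_target=th["fdr"],
            seed=stage_seed(config.seed, "de"),
        )
        calls.to_csv(out / "de_calls.tsv", sep="\t", index=False)
        ctx["de_calls"] = calls
        de_genes = sorted(calls.loc[calls["is_de"], "gene"].unique())
        ctx["de_genes"] = de_genes
        manifest["counts"]["de"] = {
            "called_pairs": int(calls["is_de"].sum()),
            "unique_genes": len(de_genes),
        }
        return

    if stage == "ts":
        tstab = ts_table(
            ctx["fmat"], ctx["sheet"], n_perm=int(th["ts_permutations"]),
            seed=stage_seed(config.seed, "ts"),
        )
        tstab.to_csv(out / "ts_table.tsv", sep="\t")
        ctx["ts_result"] = tstab
        ctx["ts_genes"] = sorted(tstab.index[tstab["is_ts"]])
        manifest["counts"]["ts"] = {"ts_genes": len(ctx["ts_genes"])}
        return

    if stage == "rif":
        norm, sheet = ctx["norm"], ctx["sheet"]
        targets = sorted(set(ctx["de_genes"]) | set(ctx["ts_genes"]))
        regulators = [r for r in ctx["tf_list"] if r in set(norm.gene_ids)]
        if not regulators or not targets:
            logger.warning("rif stage skipped: no regulators or no targets")
            ctx["rif"] = None
            manifest["counts"]["rif"] = {"regulators": 0, "targets": len(targets)}
            return
        reg = RegulatorSet(regulators, targets)
        r1, r2 = state_correlations(ctx["adjusted"], sheet, reg.regulators, reg.targets)
        # abundance weights on the log2 RPKM scale (positive), wiring from the
        # normalized solutions
        gpos = pd.Index(norm.gene_ids)
        logmat = ctx["logmat"]
        a = pd.Series(logmat.mean(axis=1), index=gpos)
        per_tissue_d = ctx["de_calls"].pivot(index="gene", columns="tissue", values="d")
        d = per_tissue_d.mean(axis=1)
        e1 = pd.Series(logmat[:, sheet.mask(state="PRE")].mean(axis=1), index=gpos)
        e2 = pd.Series(logmat[:, sheet.mask(state="POST")].mean(axis=1), index=gpos)
        scores = rif_scores(reg, r1, r2, a, d, e1, e2)
        scores.to_csv(out / "rif_scores.tsv", sep="\t")
        ctx.update(rif=scores, rif_inputs=dict(a=a, d=d, e1=e1, e2=e2,
                                               per_tissue_d=per_tissue_d, reg=reg))
        manifest["counts"]["rif"] = {
            "regulators": len(reg.regulators),
            "targets": reg.n_dets,
            "significant": int(scores["significant"].sum()),
        }
        return

    if stage == "networks":
        norm, sheet, fmat = ctx["norm"], ctx["sheet"], ctx["fmat"]
        tf_set = set(ctx["tf_list"]) & set(norm.gene_ids)
        snp_genes: set[str] = set()
        if ctx.get("snps") is not None:
            s = ctx["snps"]
            snp_genes = set(
                s.loc[
                    (s["pvalue"] < th["gwas_p"]) & (s["distance_bp"] < th["gwas_distance"]),
                    "gene",
                ]
            ) & set(norm.gene_ids)
        genes = sorted(
            (set(ctx["de_genes"]) | set(ctx["ts_genes"]) | tf_set | snp_genes)
            & set(norm.gene_ids)
        )
        if len(genes) < 3:
            raise ValidationError("fewer than 3 informative genes for networks")
        nets = {}
        for state in ("PRE", "POST"):
            net = build_state_network(
                ctx["adjusted"], sheet, genes, state, rpkm=fmat, tf_ids=tf_set
            )
            net.write_sif(out / f"network_{state}.sif")
            net.edge_frame().to_csv(out / f"network_{state}.tsv", sep="\t", index=False)
            hubs = find_hubs(net, n_sd=th["hub_sd"])
            attrs = net.node_attrs.assign(
                connectivity=net.connectivity, is_hub=[g in hubs for g in net.gene_ids]
            )
            attrs.to_csv(out / f"nodes_{state}.tsv", sep="\t")
            nets[state] = net
            manifest["counts"][f"network_{state}"] = {
                "nodes": len(net.gene_ids),
                "edges": net.n_edges,
                "hubs": len(hubs),
            }
        ctx["networks"] = nets
        return

    if stage == "delta":
        nets = ctx["networks"]
        delta = compare_networks(nets["PRE"], nets["POST"])
        delta.tissue_table.to_csv(out / "network_delta.tsv", sep="\t")
        tf_in_net = sorted(
            set(ctx["tf_list"]) & set(nets["PRE"].gene_ids)
        )
        trio_info = {}
        if len(tf_in_net) >= 3:
            for state, net in nets.items():
                trio = best_trio(net, tf_in_net)
                trio_info[state] = {
                    "trio": list(trio.trio),
                    "coverage": trio.coverage,
                    "redundancy": trio.redundancy,
                    "n_trios_examined": trio.n_trios_examined,
                }
        (out / "trio_report.json").write_text(json.dumps(trio_info, indent=2, sort_keys=True))

        if ctx.get("rif") is not None and len(tf_in_net) >= 3:
            rifs = ctx["rif"]
            per_tissue_d = ctx["rif_inputs"]["per_tissue_d"]
            exp_pre = expansion_ability(nets["PRE"], tf_in_net)
            exp_post = expansion_ability(nets["POST"], tf_in_net)
            tfs = [t for t in tf_in_net if t in rifs.index]
            crit = pd.DataFrame(index=pd.Index(tfs, name="regulator"))
            crit["rif1"] = rifs.loc[tfs, "rif1_z"]
            crit["rif2"] = rifs.loc[tfs, "rif2_z"]
            dsub = per_tissue_d.reindex(tfs)
            crit["overall_de"] = dsub.abs().mean(axis=1).fillna(0.0)
            crit["max_de"] = dsub.abs().max(axis=1).fillna(0.0)
            crit["connections_pre"] = nets["PRE"].connectivity.reindex(tfs).fillna(0)
            crit["connections_post"] = nets["POST"].connectivity.reindex(tfs).fillna(0)
            # log scale so gains and losses rank symmetrically by |value|
            crit["connection_fold_change"] = np.log2(
                delta.connection_fold_change.reindex(tfs).fillna(1.0)
            )
            crit["expansion_pre"] = exp_pre.reindex(tfs).fillna(0)
            crit["expansion_post"] = exp_post.reindex(tfs).fillna(0)
            ranked = rank_regulators(crit)
            ranked.to_csv(out / "tf_ranking.tsv", sep="\t")
            ctx["tf_ranking"] = ranked
            manifest["counts"]["delta"] = {
                "persistent": len(delta.persistent),
                "disappeared": len(delta.disappeared),
                "emerged": len(delta.emerged),
                "ranked_tfs": len(ranked),
            }
        else:
            manifest["counts"]["delta"] = {
                "persistent": len(delta.persistent),
                "disappeared": len(delta.disappeared),
                "emerged": len(delta.emerged),
            }
        ctx["delta"] = delta

        sub_tissues = tuple(
            t for t in config.subnetwork_tissues if t in ctx["sheet"].tissues
        )
        if sub_tissues and ctx.get("de_calls") is not None:
            sub = extract_subnetwork(nets["POST"], ctx["de_calls"], tissues=sub_tissues)
            sub.write_sif(out / "subnetwork.sif")
            sub.node_attrs.to_csv(out / "subnetwork_nodes.tsv", sep="\t")
        return

    if stage == "gwas":
        if ctx.get("snps") is None:
            logger.warning("gwas stage skipped: no SNP table")
            manifest["counts"]["gwas"] = {"loci": 0}
            return
        loci = intersect(
            ctx["snps"],
            ctx["expressed"],
            ctx["de_calls"],
            ctx["ts_result"],
            p_max=th["gwas_p"],
            max_dist=int(th["gwas_distance"]),
        )
        loci.to_csv(out / "integrated_loci.tsv", sep="\t", index=False)
        summary = summarize(loci)
        (out / "gwas_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest["counts"]["gwas"] = summary
        return

    raise ConfigurationError(f"unknown stage {stage!r}")
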