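"""End-to-end orchestration: preprocess -> per-layer DE -> integration ->
condition-specific networks -> contrast -> optional enrichment.

The two layers must share sample ids (a paired design): cross-layer network
nodes are built by averaging z-scored profiles of genes significant in both
layers, which is only meaningful when the columns line up.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, integrate, io, network, preprocess
from .enrichment import enrich, enrichment_report, read_gmt
from .exceptions import NPOmicsError, ValidationError
from .matrix import ExpressionMatrix

log = logging.getLogger("npomics")


@dataclass
class PipelineConfig:
    """Paths, thresholds and options for a full pipeline run."""

    protein_path: str = ""
    mrna_path: str = ""
    group_map_path: str = ""
    id_map_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "npomics_out"
    protein_scale: str = "log2"
    mrna_scale: str = "log2"
    pseudocount: float = 1.0
    quantile_normalize: bool = False
    protein_p: float = 0.05
    protein_fc: float = 2.0
    mrna_p: float = 0.05
    mrna_fc: float = 1.5
    use_q_instead_of_p: bool = False
    network_r_threshold: float = network.DEFAULT_R_THRESHOLD
    network_q_threshold: float = network.DEFAULT_Q_THRESHOLD
    enrichment_q_threshold: float = 0.05
    cluster_features: str = "differential"  # or "all"
    top_hubs: int = 10
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("protein_path", "mrna_path", "group_map_path"):
            value = getattr(self, name)
            if not value:
                raise ValidationError(f"{name} is required")
            if not Path(value).exists():
                raise ValidationError(f"{name}: no such file: {value}")
        for name in ("id_map_path", "gmt_path"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise ValidationError(f"{name}: no such file: {value}")
        if self.cluster_features not in ("differential", "all"):
            raise ValidationError("cluster_features must be 'differential' or 'all'")


def _prepare(matrix: ExpressionMatrix, config: PipelineConfig) -> ExpressionMatrix:
    if matrix.scale == "linear":
        matrix = preprocess.log2_transform(matrix, pseudocount=config.pseudocount)
    if config.quantile_normalize:
        matrix = preprocess.quantile_normalize(matrix)
    matrix.check_finite()
    return matrix


def combined_profiles(
    protein: ExpressionMatrix,
    mrna: ExpressionMatrix,
    protein_sig: set[str],
    mrna_sig: set[str],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Cross-layer profile table over the union of significant features.

    Each feature profile is z-scored across all samples of its own layer.
    Genes significant in both layers contribute one node whose profile is
    the mean of the two z-scored profiles and whose layer tag is ``both``.
    """
    if list(protein.sample_ids) != list(mrna.sample_ids):
        raise ValidationError(
            "network construction across layers requires identical sample ids "
            "in the protein and mRNA matrices (paired design)"
        )

    def zscore(df: pd.DataFrame) -> pd.DataFrame:
        centered = df.sub(df.mean(axis=1), axis=0)
        sd = df.std(axis=1, ddof=0).replace(0.0, np.nan)
        return centered.div(sd, axis=0).fillna(0.0)

    zp = zscore(protein.data.loc[sorted(protein_sig & set(protein.feature_ids))])
    zm = zscore(mrna.data.loc[sorted(mrna_sig & set(mrna.feature_ids))])
    both = sorted(set(zp.index) & set(zm.index))
    layers: dict[str, str] = {}
    rows = []
    for gene in both:
        rows.append(((zp.loc[gene] + zm.loc[gene]) / 2.0).rename(gene))
        layers[gene] = "both"
    for gene in zp.index.difference(both):
        rows.append(zp.loc[gene])
        layers[gene] = "protein"
    for gene in zm.index.difference(both):
        rows.append(zm.loc[gene])
        layers[gene] = "mrna"
    profiles = pd.DataFrame(rows) if rows else pd.DataFrame(columns=protein.sample_ids)
    return profiles.sort_index(), layers


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline, write every stage's outputs, return the summary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    stage = "load"
    try:
        groups = io.read_group_map(config.group_map_path)
        protein = io.read_expression_tsv(
            config.protein_path, layer="protein", scale=config.protein_scale, groups=groups
        )
        mrna = io.read_expression_tsv(
            config.mrna_path, layer="mrna", scale=config.mrna_scale, groups=groups
        )

        stage = "preprocess"
        protein, mrna = _prepare(protein, config), _prepare(mrna, config)

        stage = "diffexpr"
        de_results = {}
        for matrix, p_thr, fc_thr in (
            (protein, config.protein_p, config.protein_fc),
            (mrna, config.mrna_p, config.mrna_fc),
        ):
            log.info(
                "calling %s layer at p<%s, |fc|>=%s (gate=%s)",
                matrix.layer, p_thr, fc_thr,
                "q" if config.use_q_instead_of_p else "p",
            )
            results = diffexpr.two_group_test(
                matrix,
                p_threshold=p_thr,
                fc_threshold=fc_thr,
                use_q_instead_of_p=config.use_q_instead_of_p,
            )
            results.to_csv(out / f"de_{matrix.layer}.tsv", sep="\t", index=False)
            de_results[matrix.layer] = results
            summary[f"de_{matrix.layer}"] = diffexpr.de_summary(results)

        stage = "cluster"
        for matrix in (protein, mrna):
            results = de_results[matrix.layer]
            if config.cluster_features == "differential":
                feats = list(results.loc[results["significant"], "feature_id"])
            else:
                feats = matrix.feature_ids
            if len(feats) >= 2:
                centered = preprocess.median_center(matrix.restrict_features(feats))
                dendro = preprocess.hierarchical_cluster(centered, axis="features")
                (out / f"dendrogram_{matrix.layer}.newick").write_text(dendro.to_newick() + "\n")
                pd.Series(dendro.leaf_order, name="feature_id").to_csv(
                    out / f"leaf_order_{matrix.layer}.tsv", sep="\t", index=False
                )

        stage = "integrate"
        id_map = io.read_id_map(config.id_map_path) if config.id_map_path else None
        records = integrate.match_features(de_results["protein"], de_results["mrna"], id_map)
        records.to_csv(out / "integration.tsv", sep="\t", index=False)
        venn = integrate.venn_counts(records)
        conc_counts, _ = integrate.classify_concordance(records)
        io.write_json(venn._asdict(), out / "venn.json")
        pd.Series(integrate.concordant_genes(records), name="gene_id").to_csv(
            out / "concordant_genes.tsv", sep="\t", index=False
        )
        summary["venn"] = venn._asdict()
        summary["concordance"] = conc_counts

        stage = "network"
        protein_sig = set(de_results["protein"].loc[de_results["protein"]["significant"], "feature_id"])
        mrna_sig = set(de_results["mrna"].loc[de_results["mrna"]["significant"], "feature_id"])
        profiles, layers = combined_profiles(protein, mrna, protein_sig, mrna_sig)
        nets = {}
        summary["network"] = {}
        for condition in ("IDD", "IVD"):
            if len(profiles) >= 2:
                net = network.condition_network(
                    profiles,
                    condition,
                    groups=groups,
                    node_layers=layers,
                    q_threshold=config.network_q_threshold,
                    r_threshold=config.network_r_threshold,
                )
            else:
                import networkx as nx

                net = network.kcore_decompose(nx.Graph(condition=condition))
            nets[condition] = net
            network.write_graphml(net, out / f"network_{condition}.graphml")
            network.edge_table(net).to_csv(out / f"edges_{condition}.tsv", sep="\t", index=False)
            network.node_table(net).to_csv(out / f"nodes_{condition}.tsv", sep="\t", index=False)
            summary["network"][condition] = {
                "top_hubs": network.rank_hubs(net, config.top_hubs)
            }
        contrast = network.contrast_networks(nets["IDD"], nets["IVD"])
        (out / "contrast.json").write_text(contrast.to_json() + "\n")
        summary["network"]["contrast"] = dataclasses.asdict(contrast)

        if config.gmt_path:
            stage = "enrichment"
            annotation = read_gmt(config.gmt_path)
            query = mrna_sig & annotation.universe
            if query:
                results = enrich(query, annotation)
                results.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                report = enrichment_report(results, config.enrichment_q_threshold)
                summary["enrichment"] = {
                    "n_terms_tested": int(len(results)),
                    "n_terms_significant": int(len(report)),
                    "top_terms": list(results.head(5)["term_id"]),
                }
    except NPOmicsError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc
    except Exception as exc:  # pragma: no cover - defensive
        raise NPOmicsError(f"stage {stage!r}: {exc}") from exc

    io.write_json(summary, out / "summary.json")
    return summary
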