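"""Synthetic paired proteome/transcriptome generator with known ground truth.

The generator emulates the design of a small clinical profiling study of
nucleus pulposus (NP) cells: two conditions (IVD = normal disc, IDD =
degenerated disc), three samples per condition per layer, log2-scale signal
with Gaussian noise around per-feature baselines. On top of that null
structure it plants, and records in a :class:`GroundTruth`:

* differentially expressed (DE) features with a fixed |log2 fold change|,
* shared genes whose protein and mRNA effects are concordant or discordant,
* blocks of features sharing a latent factor (correlated modules), so that
  co-expression network recovery can be scored against known membership,
* one annotation term overrepresented among the planted DE genes.

All randomness flows from ``SimulationConfig.seed`` through fixed,
documented sub-streams (``default_rng([seed, k])`` with one ``k`` per
purpose), so identical configs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet
from .exceptions import ValidationError
from .matrix import ExpressionMatrix

# sub-stream keys of the single global seed
_STREAM_BASELINE = 0
_STREAM_ASSIGN = 1
_STREAM_NOISE_PROTEIN = 2
_STREAM_NOISE_MRNA = 3
_STREAM_MODULE = 4
_STREAM_ANNOTATION = 5

ENRICHED_TERM_ID = "TERM0001"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the paired-omics simulation.

    Defaults mirror the study design being emulated: 3 samples per
    condition, a proteome of 656 features, log2-scale Gaussian noise.
    """

    n_features_protein: int = 656
    n_features_mrna: int = 2000
    n_shared_genes: int = 400
    n_samples_per_group: int = 3
    frac_de: float = 0.1
    log2_effect: float = 2.0
    noise_sd: float = 0.5
    frac_concordant: float = 2.0 / 3.0
    n_modules: int = 2
    module_size: int = 10
    module_rho: float = 0.9
    module_condition: str = "IDD"
    n_terms: int = 20
    enriched_term_size: int = 30
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_features_protein": self.n_features_protein,
            "n_features_mrna": self.n_features_mrna,
            "n_samples_per_group": self.n_samples_per_group,
            "n_terms": self.n_terms,
            "enriched_term_size": self.enriched_term_size,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValidationError(f"{name} must be a positive integer, got {value!r}")
        if not 0 <= self.n_shared_genes <= min(self.n_features_protein, self.n_features_mrna):
            raise ValidationError(
                "n_shared_genes must satisfy 0 <= n_shared_genes <= "
                f"min(n_features_protein, n_features_mrna), got {self.n_shared_genes}"
            )
        for name in ("frac_de", "frac_concordant"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
        if not 0.0 <= self.module_rho < 1.0:
            raise ValidationError(f"module_rho must lie in [0, 1), got {self.module_rho!r}")
        if self.noise_sd <= 0:
            raise ValidationError(f"noise_sd must be > 0, got {self.noise_sd!r}")
        if self.n_modules < 0 or self.module_size < 0:
            raise ValidationError("n_modules and module_size must be >= 0")
        if self.n_modules * self.module_size > self.n_features_mrna:
            raise ValidationError(
                "n_modules * module_size exceeds n_features_mrna; modules must fit in the mRNA layer"
            )
        if self.module_condition not in ("IVD", "IDD", "both"):
            raise ValidationError(
                f"module_condition must be 'IVD', 'IDD' or 'both', got {self.module_condition!r}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError(f"seed must be an integer, got {self.seed!r}")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed the way scoring needs it.

    ``de_features_by_layer`` maps layer -> {feature id -> planted direction
    (+1 up in IDD, -1 down)}. ``concordance_class_by_gene`` covers shared
    genes only. ``module_membership`` maps mRNA feature id -> module index.
    """

    de_features_by_layer: dict[str, dict[str, int]] = field(default_factory=dict)
    concordance_class_by_gene: dict[str, str] = field(default_factory=dict)
    module_membership: dict[str, int] = field(default_factory=dict)
    enriched_term_id: str = ENRICHED_TERM_ID

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            de_features_by_layer={
                layer: {f: int(d) for f, d in feats.items()}
                for layer, feats in raw["de_features_by_layer"].items()
            },
            concordance_class_by_gene=raw["concordance_class_by_gene"],
            module_membership={f: int(m) for f, m in raw["module_membership"].items()},
            enriched_term_id=raw["enriched_term_id"],
        )


def _alternating_signs(n: int) -> np.ndarray:
    signs = np.ones(n, dtype=int)
    signs[1::2] = -1
    return signs


def _feature_names(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    """Shared gene symbols plus layer-prefixed symbols for unique features."""
    shared = [f"GENE{i:04d}" for i in range(1, config.n_shared_genes + 1)]
    n_up = config.n_features_protein - config.n_shared_genes
    n_um = config.n_features_mrna - config.n_shared_genes
    protein_only = [f"PROT{i:04d}" for i in range(1, n_up + 1)]
    mrna_only = [f"TRAN{i:04d}" for i in range(1, n_um + 1)]
    return shared, protein_only, mrna_only


def generate_paired_omics(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate paired protein and mRNA matrices with planted signal.

    Returns log2-scale matrices (features x samples, sample ids shared
    between layers) and the ground truth describing every planted effect.
    DE features have an IDD-minus-IVD group-mean difference of exactly
    ``±log2_effect`` before noise; module members share a per-sample latent
    factor giving pairwise expected Pearson correlation ``module_rho`` in
    the ``module_condition`` samples.
    """
    config.validate()
    shared, protein_only, mrna_only = _feature_names(config)
    protein_features = shared + protein_only
    mrna_features = shared + mrna_only

    n = config.n_samples_per_group
    samples = [f"IVD_{i}" for i in range(1, n + 1)] + [f"IDD_{i}" for i in range(1, n + 1)]
    groups = {s: ("IVD" if s.startswith("IVD") else "IDD") for s in samples}
    idd_mask = np.array([groups[s] == "IDD" for s in samples])

    assign_rng = np.random.default_rng([config.seed, _STREAM_ASSIGN])

    # --- plant DE among shared genes, split concordant / discordant ---------
    n_de_shared = round(config.frac_de * config.n_shared_genes)
    de_shared = list(assign_rng.choice(shared, size=n_de_shared, replace=False))
    n_conc = round(config.frac_concordant * n_de_shared)
    conc_genes, disc_genes = de_shared[:n_conc], de_shared[n_conc:]
    conc_signs = _alternating_signs(len(conc_genes))
    disc_signs = _alternating_signs(len(disc_genes))

    truth = GroundTruth(de_features_by_layer={"protein": {}, "mrna": {}})
    for gene in shared:
        truth.concordance_class_by_gene[gene] = "null"
    for gene, s in zip(conc_genes, conc_signs):
        truth.de_features_by_layer["protein"][gene] = int(s)
        truth.de_features_by_layer["mrna"][gene] = int(s)
        truth.concordance_class_by_gene[gene] = "concordant_up" if s > 0 else "concordant_down"
    for gene, s in zip(disc_genes, disc_signs):
        # alternating protein-up/mRNA-down and the reverse
        truth.de_features_by_layer["protein"][gene] = int(s)
        truth.de_features_by_layer["mrna"][gene] = int(-s)
        truth.concordance_class_by_gene[gene] = "discordant"

    # --- plant DE among layer-unique features -------------------------------
    for layer, unique in (("protein", protein_only), ("mrna", mrna_only)):
        n_de_unique = round(config.frac_de * len(unique))
        chosen = list(assign_rng.choice(unique, size=n_de_unique, replace=False)) if n_de_unique else []
        for feat, s in zip(chosen, _alternating_signs(len(chosen))):
            truth.de_features_by_layer[layer][feat] = int(s)

    # --- correlated modules in the mRNA layer -------------------------------
    n_module_feats = config.n_modules * config.module_size
    if n_module_feats:
        members = assign_rng.choice(mrna_features, size=n_module_feats, replace=False)
        for i, feat in enumerate(members):
            truth.module_membership[str(feat)] = i // config.module_size

    # --- assemble matrices ---------------------------------------------------
    def build_layer(layer: str, features: list[str], stream: int) -> pd.DataFrame:
        baseline_rng = np.random.default_rng([config.seed, _STREAM_BASELINE, stream])
        noise_rng = np.random.default_rng([config.seed, stream])
        baseline = baseline_rng.uniform(4.0, 12.0, size=len(features))
        eps = noise_rng.standard_normal((len(features), len(samples)))
        values = baseline[:, None] + config.noise_sd * eps
        de = truth.de_features_by_layer[layer]
        pos = {f: i for i, f in enumerate(features)}
        for feat, direction in de.items():
            values[pos[feat], idd_mask] += direction * config.log2_effect
        if layer == "mrna" and truth.module_membership and config.module_rho > 0:
            module_rng = np.random.default_rng([config.seed, _STREAM_MODULE])
            factors = module_rng.standard_normal((config.n_modules, len(samples)))
            if config.module_condition == "both":
                cond_mask = np.ones(len(samples), dtype=bool)
            else:
                cond_mask = np.array(
                    [groups[s] == config.module_condition for s in samples]
                )
            rho = config.module_rho
            for feat, mod in truth.module_membership.items():
                i = pos[feat]
                latent = np.sqrt(rho) * factors[mod] + np.sqrt(1 - rho) * eps[i]
                mean_row = baseline[i] + de.get(feat, 0) * config.log2_effect * idd_mask
                values[i, cond_mask] = (
                    mean_row[cond_mask] + config.noise_sd * latent[cond_mask]
                )
        return pd.DataFrame(values, index=features, columns=samples)

    protein_df = build_layer("protein", protein_features, _STREAM_NOISE_PROTEIN)
    mrna_df = build_layer("mrna", mrna_features, _STREAM_NOISE_MRNA)

    protein = ExpressionMatrix(protein_df, layer="protein", scale="log2", groups=dict(groups))
    mrna = ExpressionMatrix(mrna_df, layer="mrna", scale="log2", groups=dict(groups))
    return protein, mrna, truth


def generate_annotation(config: SimulationConfig, truth: GroundTruth) -> AnnotationSet:
    """Annotation terms over the mRNA universe, one planted enriched term.

    The term with id ``truth.enriched_term_id`` draws 80% of its genes from
    the planted mRNA DE set; every other term is sampled uniformly from the
    universe. Serves as an offline stand-in for a curated gene-set database.
    """
    config.validate()
    _, _, mrna_only = _feature_names(config)
    shared = [f"GENE{i:04d}" for i in range(1, config.n_shared_genes + 1)]
    universe = shared + mrna_only
    de_genes = sorted(truth.de_features_by_layer.get("mrna", {}))
    if config.enriched_term_size > len(de_genes):
        raise ValidationError(
            f"enriched_term_size ({config.enriched_term_size}) exceeds the number of "
            f"planted mRNA DE genes ({len(de_genes)})"
        )
    rng = np.random.default_rng([config.seed, _STREAM_ANNOTATION])
    non_de = sorted(set(universe) - set(de_genes))
    n_hit = round(0.8 * config.enriched_term_size)
    hits = list(rng.choice(de_genes, size=n_hit, replace=False))
    fillers = list(rng.choice(non_de, size=config.enriched_term_size - n_hit, replace=False))
    terms: dict[str, tuple[str, frozenset[str]]] = {
        truth.enriched_term_id: ("planted enriched term", frozenset(hits + fillers))
    }
    for i in range(2, config.n_terms + 1):
        term_id = f"TERM{i:04d}"
        genes = rng.choice(universe, size=config.enriched_term_size, replace=False)
        terms[term_id] = (f"random term {i}", frozenset(str(g) for g in genes))
    return AnnotationSet(terms=terms, universe=frozenset(universe))


def generate_qpcr_plate(
    n_genes: int,
    n_replicates: int,
    planted_log2fc,
    seed: int,
    n_samples_per_group: int = 3,
    noise_sd: float = 0.1,
    reference_gene: str = "GAPDH",
) -> pd.DataFrame:
    """Long-format Ct table with a planted fold change per target gene.

    Target Ct shifts by ``-planted_log2fc`` cycles in the treated condition
    relative to the reference gene, so downstream 2^-ddCt recovers
    ``2**planted_log2fc`` exactly at ``noise_sd=0``. Replicate noise is
    Gaussian on the Ct scale.
    """
    if n_genes < 1 or n_replicates < 1 or n_samples_per_group < 1:
        raise ValidationError("n_genes, n_replicates and n_samples_per_group must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    fc = np.broadcast_to(np.asarray(planted_log2fc, dtype=float), (n_genes,))
    rng = np.random.default_rng([int(seed), 0])
    baselines = rng.uniform(22.0, 30.0, size=n_genes)
    genes = [f"TGT{i:02d}" for i in range(1, n_genes + 1)]
    rows = []
    for cond, prefix in (("control", "C"), ("treated", "T")):
        for s in range(1, n_samples_per_group + 1):
            sample = f"{prefix}{s}"
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd else 0.0
                rows.append((sample, cond, reference_gene, rep, 20.0 + noise))
                for gene, base, shift in zip(genes, baselines, fc):
                    ct = base - (shift if cond == "treated" else 0.0)
                    noise = rng.normal(0.0, noise_sd) if noise_sd else 0.0
                    rows.append((sample, cond, gene, rep, ct + noise))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene_id", "replicate", "ct"])
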