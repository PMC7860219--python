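"""Join protein and mRNA differential results by gene and classify
protein-mRNA concordance.

A gene significant in both layers is *concordant* when its protein and mRNA
fold changes share a sign and *discordant* when they oppose. Genes
significant in exactly one layer are ``protein_only`` / ``mrna_only``, the
rest ``neither``. Matching is by exact gene symbol, optionally through a
protein-accession -> symbol map (many-to-one collapses keep the protein
feature with the smallest p-value; collapses whose significant directions
contradict are flagged ambiguous and excluded from concordance counts).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import ValidationError

CONCORDANCE_CLASSES = (
    "concordant_up",
    "concordant_down",
    "discordant",
    "protein_only",
    "mrna_only",
    "neither",
)

INTEGRATION_COLUMNS = [
    "gene_id",
    "protein_log2fc",
    "mrna_log2fc",
    "protein_significant",
    "mrna_significant",
    "concordance",
    "ambiguous",
]


class VennCounts(NamedTuple):
    protein_only: int
    mrna_only: int
    both: int


def _collapse_proteins(protein_results: pd.DataFrame, id_map: dict[str, str]) -> tuple[pd.DataFrame, pd.Series]:
    """Map protein features to gene symbols; collapse many-to-one by min p.

    Returns the collapsed table (indexed by gene) and a boolean Series
    marking genes whose significant protein features disagreed in direction.
    """
    mapped = protein_results.copy()
    mapped["gene_id"] = [id_map.get(f, f) for f in mapped["feature_id"]]
    ambiguous = {}
    for gene, grp in mapped.groupby("gene_id"):
        sig_dirs = set(grp.loc[grp["significant"], "direction"]) - {"none"}
        ambiguous[gene] = len(sig_dirs) > 1
    collapsed = (
        mapped.sort_values(["p_value", "feature_id"], kind="stable")
        .groupby("gene_id", sort=True)
        .head(1)
        .set_index("gene_id")
    )
    return collapsed, pd.Series(ambiguous)


def match_features(
    protein_results: pd.DataFrame,
    mrna_results: pd.DataFrame,
    id_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One IntegrationRecord row per gene in the union of both layers."""
    for name, tbl in (("protein", protein_results), ("mrna", mrna_results)):
        for col in ("feature_id", "log2fc", "p_value", "significant", "direction"):
            if col not in tbl.columns:
                raise ValidationError(f"{name} results missing column {col!r}")
    if id_map is not None:
        prot, ambiguous = _collapse_proteins(protein_results, id_map)
    else:
        if protein_results["feature_id"].duplicated().any():
            raise ValidationError("duplicate protein feature ids without an id_map")
        prot = protein_results.set_index("feature_id")
        ambiguous = pd.Series(False, index=prot.index)
    mrna = mrna_results.set_index("feature_id")
    if mrna.index.has_duplicates:
        raise ValidationError("duplicate mRNA feature ids")
    genes = sorted(set(prot.index) | set(mrna.index))
    rows = []
    for gene in genes:
        p_there, m_there = gene in prot.index, gene in mrna.index
        p_fc = float(prot.at[gene, "log2fc"]) if p_there else np.nan
        m_fc = float(mrna.at[gene, "log2fc"]) if m_there else np.nan
        p_sig = bool(prot.at[gene, "significant"]) if p_there else False
        m_sig = bool(mrna.at[gene, "significant"]) if m_there else False
        amb = bool(ambiguous.get(gene, False))
        rows.append((gene, p_fc, m_fc, p_sig, m_sig, _classify(p_fc, m_fc, p_sig, m_sig), amb))
    return pd.DataFrame(rows, columns=INTEGRATION_COLUMNS)


def _classify(p_fc: float, m_fc: float, p_sig: bool, m_sig: bool) -> str:
    if p_sig and m_sig:
        if p_fc > 0 and m_fc > 0:
            return "concordant_up"
        if p_fc < 0 and m_fc < 0:
            return "concordant_down"
        if p_fc * m_fc < 0:
            return "discordant"
        # a zero fold change has no direction: kept out of all three classes
        return "zero_direction"
    if p_sig:
        return "protein_only"
    if m_sig:
        return "mrna_only"
    return "neither"


def venn_counts(records: pd.DataFrame) -> VennCounts:
    """Genes significant in only the protein layer / only mRNA / both.

    Ambiguous records (contradictory protein directions after id-map
    collapse) are excluded, matching their exclusion from concordance.
    """
    ok = records.loc[~records["ambiguous"]]
    p, m = ok["protein_significant"], ok["mrna_significant"]
    return VennCounts(
        protein_only=int((p & ~m).sum()),
        mrna_only=int((m & ~p).sum()),
        both=int((p & m).sum()),
    )


def classify_concordance(records: pd.DataFrame) -> tuple[dict[str, int], pd.DataFrame]:
    """Class counts plus the labeled table (ambiguous records set aside).

    Every non-ambiguous gene carries exactly one class; both-significant
    genes with a zero fold change are reported under ``zero_direction``
    rather than inflating the concordant or discordant counts.
    """
    ok = records.loc[~records["ambiguous"]]
    counts = {cls: int((ok["concordance"] == cls).sum()) for cls in CONCORDANCE_CLASSES}
    n_zero = int((ok["concordance"] == "zero_direction").sum())
    if n_zero:
        counts["zero_direction"] = n_zero
    counts["ambiguous"] = int(records["ambiguous"].sum())
    return counts, records.copy()


def concordant_genes(records: pd.DataFrame) -> list[str]:
    """Genes concordant in both layers (the validation-candidate list)."""
    mask = records["concordance"].isin(["concordant_up", "concordant_down"]) & ~records["ambiguous"]
    return sorted(records.loc[mask, "gene_id"])
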