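"""Comparative 2^-ddCt relative quantification for qPCR validation.

Per sample, replicates are averaged on the Ct scale and
``dCt = mean Ct(target) - mean Ct(reference)``; then
``ddCt = mean dCt(treated) - mean dCt(control)`` and the relative
expression is ``fold = 2**(-ddCt)``. Per-sample folds
``2**-(dCt - mean control dCt)`` feed a two-sided Student's t-test between
the groups, mirroring the usual presentation of qPCR validation panels
normalized to a housekeeping gene such as GAPDH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

CT_COLUMNS = ["sample_id", "condition", "gene_id", "replicate", "ct"]


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format Ct TSV (sample_id, condition, gene_id, replicate, ct)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    return validate_ct_table(table)


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    ct = pd.to_numeric(table["ct"], errors="coerce")
    bad = ~np.isfinite(ct) | (ct <= 0)
    if bad.any():
        raise ValidationError(f"non-finite or non-positive Ct values at rows {list(table.index[bad])[:5]}")
    return table.assign(ct=ct)


@dataclass
class RelativeExpression:
    """2^-ddCt result for one target gene."""

    gene_id: str
    delta_ct_per_sample: dict[str, float]
    delta_delta_ct: float
    fold: float
    per_sample_fold: dict[str, float]
    control_mean: float
    control_sd: float
    treated_mean: float
    treated_sd: float
    p_value: float

    def as_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "delta_delta_ct": self.delta_delta_ct,
            "fold": self.fold,
            "control_mean": self.control_mean,
            "control_sd": self.control_sd,
            "treated_mean": self.treated_mean,
            "treated_sd": self.treated_sd,
            "p_value": self.p_value,
        }


def ddct(
    ct_table: pd.DataFrame,
    target: str,
    reference: str,
    control: str = "control",
    treated: str = "treated",
) -> RelativeExpression:
    """Relative expression of ``target`` against ``reference`` by 2^-ddCt."""
    if target == reference:
        raise ValidationError("target and reference genes must differ")
    table = validate_ct_table(ct_table)
    conditions = dict(
        table.drop_duplicates("sample_id").set_index("sample_id")["condition"]
    )
    samples = sorted(conditions)
    delta_ct = {}
    for sample in samples:
        sub = table.loc[table["sample_id"] == sample]
        t_ct = sub.loc[sub["gene_id"] == target, "ct"]
        r_ct = sub.loc[sub["gene_id"] == reference, "ct"]
        if r_ct.empty:
            raise ValidationError(f"reference gene {reference!r} missing for sample {sample!r}")
        if t_ct.empty:
            raise ValidationError(f"target gene {target!r} missing for sample {sample!r}")
        delta_ct[sample] = float(t_ct.mean() - r_ct.mean())
    ctrl = [delta_ct[s] for s in samples if conditions[s] == control]
    trt = [delta_ct[s] for s in samples if conditions[s] == treated]
    if not ctrl or not trt:
        raise ValidationError(f"need samples in both {control!r} and {treated!r} conditions")
    ddct_value = float(np.mean(trt) - np.mean(ctrl))
    fold = float(2.0 ** (-ddct_value))
    ctrl_mean_dct = float(np.mean(ctrl))
    per_sample_fold = {s: float(2.0 ** (-(delta_ct[s] - ctrl_mean_dct))) for s in samples}
    ctrl_folds = np.array([per_sample_fold[s] for s in samples if conditions[s] == control])
    trt_folds = np.array([per_sample_fold[s] for s in samples if conditions[s] == treated])
    if len(ctrl_folds) >= 2 and len(trt_folds) >= 2:
        with warnings.catch_warnings():
            # zero-noise plates give constant folds; the nan p is patched below
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_ind(trt_folds, ctrl_folds, equal_var=True).pvalue)
        if np.isnan(p):  # both groups constant
            p = 1.0 if np.mean(trt_folds) == np.mean(ctrl_folds) else 0.0
    else:
        p = float("nan")
    return RelativeExpression(
        gene_id=target,
        delta_ct_per_sample=delta_ct,
        delta_delta_ct=ddct_value,
        fold=fold,
        per_sample_fold=per_sample_fold,
        control_mean=float(ctrl_folds.mean()),
        control_sd=float(ctrl_folds.std(ddof=1)) if len(ctrl_folds) > 1 else 0.0,
        treated_mean=float(trt_folds.mean()),
        treated_sd=float(trt_folds.std(ddof=1)) if len(trt_folds) > 1 else 0.0,
        p_value=p,
    )


def ddct_panel(
    ct_table: pd.DataFrame,
    reference: str,
    control: str = "control",
    treated: str = "treated",
) -> pd.DataFrame:
    """2^-ddCt for every non-reference gene in the table."""
    genes = sorted(set(ct_table["gene_id"]) - {reference})
    rows = [ddct(ct_table, g, reference, control, treated).as_row() for g in genes]
    return pd.DataFrame(rows)


def write_relative_expression(panel: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    panel.to_csv(path, sep="\t", index=False)
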