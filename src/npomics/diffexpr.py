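"""Two-group differential expression: fold change, t-test, BH FDR, calling.

The convention throughout is that the degenerated condition (IDD) is the
numerator: ``log2fc = mean(IDD) - mean(IVD)`` on log2-scale signal, and the
signed linear fold change is ``2**log2fc`` for up-regulation and
``-2**(-log2fc)`` for down-regulation (the "+/- 1.5-fold" idiom, so its
range is (-inf, -1] u [1, inf)). A feature is called differential when its
raw p-value (optionally its BH q-value) is below ``p_threshold`` and
``|signed_fc|`` reaches ``fc_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .matrix import ExpressionMatrix

NEG_LOG10_P_CAP = 320.0  # cap applied when p underflows to 0

RESULT_COLUMNS = [
    "feature_id",
    "mean_ivd",
    "mean_idd",
    "log2fc",
    "signed_fc",
    "t",
    "p_value",
    "q_value",
    "direction",
    "significant",
]


@dataclass(frozen=True)
class DEThresholds:
    """Calling thresholds.

    ``fc_threshold`` is on the signed linear scale (1.5 means 1.5-fold
    either way). The mRNA layer is conventionally called at 1.5-fold and the
    protein layer at 2-fold; both gates use the raw p-value unless
    ``use_q_instead_of_p`` is set.
    """

    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    use_q_instead_of_p: bool = False

    def __post_init__(self) -> None:
        if self.p_threshold <= 0:
            raise ValidationError("p_threshold must be > 0")
        if self.fc_threshold < 1:
            raise ValidationError("fc_threshold must be >= 1 (signed linear scale)")


PROTEIN_DEFAULTS = DEThresholds(fc_threshold=2.0)
MRNA_DEFAULTS = DEThresholds(fc_threshold=1.5)


def signed_fold_change(log2fc: np.ndarray) -> np.ndarray:
    """Map log2 fold change to the signed linear convention (bijective)."""
    log2fc = np.asarray(log2fc, dtype=float)
    return np.where(log2fc >= 0, np.exp2(log2fc), -np.exp2(-log2fc))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class DifferentialExpression(BaseEstimator):
    """Per-feature two-group comparison, scikit-learn style.

    ``fit(X, y)`` takes ``X`` of shape (n_samples, n_features) on the log2
    scale and group labels ``y``; it computes group means, fold changes, a
    two-sided Student's t-test per feature (pooled variance by default,
    Welch with ``equal_var=False``), BH q-values, and significance calls.

    Attributes
    ----------
    results_ : DataFrame with one row per feature (``RESULT_COLUMNS``).
    n_up_, n_down_, n_significant_ : summary counts.
    """

    def __init__(
        self,
        p_threshold: float = 0.05,
        fc_threshold: float = 1.5,
        use_q_instead_of_p: bool = False,
        equal_var: bool = True,
        reference: str = "IVD",
        treatment: str = "IDD",
    ):
        self.p_threshold = p_threshold
        self.fc_threshold = fc_threshold
        self.use_q_instead_of_p = use_q_instead_of_p
        self.equal_var = equal_var
        self.reference = reference
        self.treatment = treatment

    @property
    def thresholds(self) -> DEThresholds:
        return DEThresholds(self.p_threshold, self.fc_threshold, self.use_q_instead_of_p)

    def fit(self, X, y):
        feature_ids = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValidationError("X must be 2-dimensional (n_samples, n_features)")
        if feature_ids is None:
            feature_ids = [f"f{i}" for i in range(X.shape[1])]
        ref_mask = y == self.reference
        trt_mask = y == self.treatment
        unknown = ~(ref_mask | trt_mask)
        if unknown.any():
            raise ValidationError(
                f"labels other than {self.reference!r}/{self.treatment!r} present"
            )
        if ref_mask.sum() < 2 or trt_mask.sum() < 2:
            raise ValidationError("each group needs at least 2 samples")
        a, b = X[trt_mask], X[ref_mask]  # treatment first: log2fc = IDD - IVD
        mean_ref, mean_trt = b.mean(axis=0), a.mean(axis=0)
        log2fc = mean_trt - mean_ref
        import warnings

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # zero-variance features are handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            t_stat, p = stats.ttest_ind(a, b, axis=0, equal_var=self.equal_var)
        t_stat = np.asarray(t_stat, dtype=float)
        p = np.asarray(p, dtype=float)
        # degenerate features: no variance anywhere
        zero_var = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
        same = zero_var & (log2fc == 0)
        diff = zero_var & (log2fc != 0)
        t_stat[same], p[same] = 0.0, 1.0
        t_stat[diff] = np.sign(log2fc[diff]) * np.inf
        p[diff] = 0.0
        results = pd.DataFrame(
            {
                "feature_id": feature_ids,
                "mean_ivd": mean_ref,
                "mean_idd": mean_trt,
                "log2fc": log2fc,
                "signed_fc": signed_fold_change(log2fc),
                "t": t_stat,
                "p_value": p,
                "q_value": bh_adjust(p),
            }
        )
        self.results_ = call_differential(results, self.thresholds)
        self.n_significant_ = int(self.results_["significant"].sum())
        self.n_up_ = int((self.results_["direction"] == "up").sum())
        self.n_down_ = int((self.results_["direction"] == "down").sum())
        return self


def two_group_test(matrix: ExpressionMatrix, **params) -> pd.DataFrame:
    """Run :class:`DifferentialExpression` on an ExpressionMatrix.

    Thresholds default to the layer convention (2-fold for protein,
    1.5-fold for mRNA) unless overridden via ``params``.
    """
    if matrix.scale != "log2":
        raise ValidationError("two_group_test expects log2-scale input")
    defaults = PROTEIN_DEFAULTS if matrix.layer == "protein" else MRNA_DEFAULTS
    params = {
        "p_threshold": defaults.p_threshold,
        "fc_threshold": defaults.fc_threshold,
        "use_q_instead_of_p": defaults.use_q_instead_of_p,
        **params,
    }
    X = matrix.data.T  # samples x features
    y = np.array([matrix.groups[s] for s in matrix.data.columns])
    de = DifferentialExpression(**params).fit(X, y)
    return de.results_


def call_differential(
    results: pd.DataFrame, thresholds: DEThresholds = DEThresholds()
) -> pd.DataFrame:
    """Set the ``significant`` flag and ``direction`` per the thresholds."""
    out = results.copy()
    if len(out) == 0:
        out["direction"] = pd.Series(dtype=object)
        out["significant"] = pd.Series(dtype=bool)
        return out
    gate_p = out["q_value"] if thresholds.use_q_instead_of_p else out["p_value"]
    significant = (gate_p < thresholds.p_threshold) & (
        out["signed_fc"].abs() >= thresholds.fc_threshold
    )
    direction = np.where(
        ~significant, "none", np.where(out["log2fc"] > 0, "up", np.where(out["log2fc"] < 0, "down", "none"))
    )
    out["direction"] = direction
    out["significant"] = significant.to_numpy()
    return out


def de_summary(results: pd.DataFrame) -> dict[str, int]:
    """Up/down/total counts of called features."""
    return {
        "up": int((results["direction"] == "up").sum()),
        "down": int((results["direction"] == "down").sum()),
        "total": int(results["significant"].sum()),
    }


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-feature (log2fc, -log10 p, class) with class in {up, down, ns}."""
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(results["p_value"].to_numpy(dtype=float))
    neg_log10_p = np.minimum(neg_log10_p, NEG_LOG10_P_CAP)
    cls = results["direction"].replace({"none": "ns"})
    return pd.DataFrame(
        {
            "feature_id": results["feature_id"],
            "log2fc": results["log2fc"],
            "neg_log10_p": neg_log10_p,
            "class": cls,
        }
    ).reset_index(drop=True)
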