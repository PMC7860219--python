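"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices are TSV with the feature id in the first column and one
column per sample (the shape of a processed GEO series-matrix table); the
group map is a two-column TSV ``sample<TAB>condition``. Parse errors carry
line numbers; a duplicated feature id keeps the row with the higher mean
signal (warned), the common rule when several probes report one gene.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .matrix import ExpressionMatrix


def read_group_map(path) -> dict[str, str]:
    groups: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 'sample<TAB>condition'")
        sample, condition = parts
        if sample == "sample" and condition == "condition":  # optional header
            continue
        if sample in groups:
            raise ValidationError(f"{path}:{lineno}: duplicate sample {sample!r}")
        groups[sample] = condition
    if not groups:
        raise ValidationError(f"{path}: empty group map")
    return groups


def write_group_map(groups: dict[str, str], path) -> None:
    lines = ["sample\tcondition"] + [f"{s}\t{c}" for s, c in groups.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_tsv(
    path,
    layer: str,
    scale: str = "log2",
    group_map_path=None,
    groups: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a features x samples TSV into a validated ExpressionMatrix."""
    if groups is None:
        if group_map_path is None:
            raise ValidationError("either groups or group_map_path is required")
        groups = read_group_map(group_map_path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed TSV: {exc}") from exc
    if raw.columns.size == 0:
        raise ValidationError(f"{path}: no sample columns found")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = map(int, np.argwhere(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at line {i + 2}, "
            f"feature {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = map(int, np.argwhere(numeric.isna().to_numpy())[0])
        raise ValidationError(
            f"{path}: missing value at line {i + 2}, feature {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}"
        )
    unmapped = [s for s in numeric.columns if s not in groups]
    if unmapped:
        raise ValidationError(f"{path}: samples absent from group map: {unmapped}")
    if numeric.index.has_duplicates:
        dups = sorted(set(numeric.index[numeric.index.duplicated()]))
        warnings.warn(
            f"{path}: duplicated feature id(s) {dups[:5]}; keeping the row with "
            "the higher mean signal",
            stacklevel=2,
        )
        numeric = (
            numeric.assign(_mean=numeric.mean(axis=1))
            .sort_values("_mean", ascending=False, kind="stable")
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_mean")
        )
        numeric = numeric.loc[sorted(numeric.index)]
    return ExpressionMatrix(
        numeric,
        layer=layer,
        scale=scale,
        groups={s: groups[s] for s in numeric.columns},
    )


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.data.to_csv(path, sep="\t", index_label="feature_id")


def read_id_map(path) -> dict[str, str]:
    """Two-column TSV mapping protein feature id -> gene symbol."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 'protein<TAB>gene'")
        mapping[parts[0]] = parts[1]
    return mapping


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
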