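"""Tabular input/output for expression matrices, sample sheets, annotations
and the ranked mRNA–miRNA pair table, plus ALDA-scale responder classification.

All artifacts are plain TSV (UTF-8, "." decimal, no quoting). Expression
matrices are features × samples with a ``feature_id`` corner cell; the pair
table uses the published column names verbatim with a leading rank index.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUP_RESPONDER = "R"
GROUP_NONRESPONDER = "NR"

#: Verbatim pair-table column names (the published ranked-pair schema),
#: preceded by a "rank" index column when written to disk.
PAIR_TABLE_COLUMNS = [
    "Mature miRNA",
    "mRNA",
    "cor",
    "p-value",
    "logratio.miRNA",
    "meanExp.miRNA",
    "logratio.mRNA",
    "meanExp.mRNA",
    "adj.p-value",
    "S score",
    "FC.miRNA (R vs NR)",
    "FC.mRNA (R vs NR)",
]

#: PairResult attribute corresponding to each pair-table column.
_PAIR_FIELD_FOR_COLUMN = {
    "Mature miRNA": "mirna_id",
    "mRNA": "mrna_id",
    "cor": "cor",
    "p-value": "p_value",
    "logratio.miRNA": "logratio_mirna",
    "meanExp.miRNA": "mean_exp_mirna",
    "logratio.mRNA": "logratio_mrna",
    "meanExp.mRNA": "mean_exp_mrna",
    "adj.p-value": "adj_p",
    "S score": "s_score",
    "FC.miRNA (R vs NR)": "fc_mirna",
    "FC.mRNA (R vs NR)": "fc_mrna",
}


class FormatError(ValueError):
    """A tabular artifact violates the expected dialect or an invariant."""


@dataclasses.dataclass
class ExpressionMatrix:
    """Log2-scale intensity values for one modality, features × samples."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 2:
            raise FormatError("an expression matrix needs at least 2 samples")
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise FormatError(f"duplicate {name} id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, feature_id: str) -> np.ndarray:
        try:
            idx = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature {feature_id!r}") from None
        return self.values[idx]

    def subset_features(self, keep: Sequence[str]) -> "ExpressionMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in keep]
        return ExpressionMatrix(list(keep), list(self.sample_ids), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclasses.dataclass
class SampleSheet:
    """Per-sample responder/non-responder labels with optional ALDA subscores."""

    sample_ids: list[str]
    groups: list[str]
    alda_a: list | None = None
    alda_b: list | None = None

    def __post_init__(self) -> None:
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise FormatError(f"duplicate sample id {dup!r}")
        if len(self.groups) != len(self.sample_ids):
            raise FormatError("groups and sample_ids differ in length")
        bad = [g for g in self.groups if g not in (GROUP_RESPONDER, GROUP_NONRESPONDER)]
        if bad:
            raise FormatError(f"invalid group label {bad[0]!r}; expected R or NR")

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups], dtype=bool)

    def masks_for(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (R, NR) masks aligned to ``sample_ids`` order."""
        lookup = dict(zip(self.sample_ids, self.groups))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise FormatError(f"samples missing from sheet: {missing}")
        labels = np.array([lookup[s] for s in sample_ids])
        return labels == GROUP_RESPONDER, labels == GROUP_NONRESPONDER


def classify_alda(a_score: int, b_score: int, threshold: int = 7) -> tuple[int, str]:
    """Total ALDA score and responder label from the A and B subscales.

    The total is A minus B clamped to the scale's 0–10 range; a patient is a
    lithium responder (``"R"``) when the total reaches ``threshold``
    (inclusive), otherwise a non-responder (``"NR"``).
    """
    if not 0 <= a_score <= 10:
        raise ValueError(f"ALDA A score must be in 0..10, got {a_score}")
    if b_score < 0:
        raise ValueError(f"ALDA B score must be >= 0, got {b_score}")
    total = max(0, min(10, a_score - b_score))
    label = GROUP_RESPONDER if total >= threshold else GROUP_NONRESPONDER
    return total, label


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a features × samples TSV of log2 intensities.

    First row is the sample header (corner cell ignored), first column the
    feature id. Raises :class:`FormatError` naming the offending cell for
    duplicate ids, non-numeric values or ragged rows.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    width = len(header)
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != width:
            raise FormatError(
                f"{path}: ragged row at line {lineno} "
                f"({len(cells)} cells, expected {width})"
            )
        feature_ids.append(cells[0])
        parsed = []
        for j, cell in enumerate(cells[1:]):
            try:
                parsed.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at line {lineno}, "
                    f"column {sample_ids[j]!r}"
                ) from None
        rows.append(parsed)
    return ExpressionMatrix(feature_ids, sample_ids, np.array(rows, dtype=float))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the dialect :func:`read_expression_matrix` reads.

    Values are written in full repr precision so the round trip is lossless.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise FormatError(f"{path}: sample sheet needs sample_id and group columns")
    return SampleSheet(
        sample_ids=df["sample_id"].tolist(),
        groups=df["group"].tolist(),
        alda_a=df["alda_A"].tolist() if "alda_A" in df.columns else None,
        alda_b=df["alda_B"].tolist() if "alda_B" in df.columns else None,
    )


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    data = {"sample_id": sheet.sample_ids, "group": sheet.groups}
    if sheet.alda_a is not None:
        data["alda_A"] = sheet.alda_a
    if sheet.alda_b is not None:
        data["alda_B"] = sheet.alda_b
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a feature annotation TSV (feature_id plus kind-specific columns)."""
    df = pd.read_csv(path, sep="\t")
    if "feature_id" not in df.columns:
        raise FormatError(f"{path}: annotation needs a feature_id column")
    dup = _first_duplicate(df["feature_id"].tolist())
    if dup is not None:
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    return df


def _format_2dp(x: float) -> str:
    return f"{float(x):.2f}"


def _format_pvalue(x: float) -> str:
    return f"{float(x):.2E}"


def write_pair_table(pairs: Iterable, path: str | Path) -> None:
    """Write ranked pairs as a TSV in the published schema.

    Numeric columns are rounded to 2 decimals; the raw correlation p-value is
    rendered in scientific notation with 2 significant digits (the adjusted
    p-value stays on the 2-decimal scale, as printed). One row per pair, in
    input order, ranked from 1.
    """
    formatters = {"p-value": _format_pvalue}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\t" + "\t".join(PAIR_TABLE_COLUMNS) + "\n")
        for rank, pair in enumerate(pairs, start=1):
            cells = [str(rank)]
            for col in PAIR_TABLE_COLUMNS:
                field = _PAIR_FIELD_FOR_COLUMN[col]
                try:
                    value = getattr(pair, field)
                except AttributeError:
                    raise FormatError(f"pair is missing field {field!r}") from None
                if isinstance(value, str):
                    cells.append(value)
                else:
                    cells.append(formatters.get(col, _format_2dp)(value))
            fh.write("\t".join(cells) + "\n")


def read_pair_table(path: str | Path) -> pd.DataFrame:
    """Read a pair-table TSV back into a DataFrame with verbatim columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PAIR_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: pair table missing columns {missing}")
    return df


def _first_duplicate(ids: Sequence[str]):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None
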