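"""Reading, cleaning, transforming and splitting specimen-level trait tables.

The exchange object is :class:`TraitTable`: a pandas DataFrame of
specimen rows by trait/attribute columns, with declared column kinds
(continuous vs categorical), per-continuous-column scale tags (``raw`` or
``log``) and missingness represented as NaN — a cell is either observed
(finite for continuous columns) or missing, never both.

Preprocessing follows the usual course for morphometric regression:
configurable record cleaning, a natural-log transform of strictly positive
measurements (body measurements are right-skewed and multiplicative),
first-appearance label encoding of categoricals, pairwise-complete Pearson
screening of candidate predictors against the log target, and a seeded
70/30 train/validation split that is a pure function of (seed, N) so every
method and feature combination sees the same partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TraitTable",
    "EncodingMap",
    "CleaningConfig",
    "CorrelationReport",
    "read_trait_table",
    "write_trait_table",
    "clean",
    "log_transform",
    "encode_categoricals",
    "pairwise_pearson",
    "split",
    "load_config",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: code assigned at predict time to category tokens unseen during fitting
UNSEEN_CODE = -1


@dataclass
class TraitTable:
    """Specimen rows x trait/attribute columns with explicit missingness.

    ``data`` holds observed values, NaN marking missing cells; continuous
    columns are float, categorical columns hold tokens (or integer codes
    after encoding). ``scale_tags`` records, per continuous column, whether
    it stores raw measurements or their natural logs.
    """

    data: pd.DataFrame
    column_kinds: dict[str, str]
    scale_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        cols = list(self.data.columns)
        if len(cols) != len(set(cols)):
            raise ValueError("column names must be unique")
        unknown = set(self.column_kinds) - set(cols)
        if unknown:
            raise ValueError(f"column_kinds refer to absent columns: {sorted(unknown)}")
        for c in self.continuous_columns:
            vals = pd.to_numeric(self.data[c], errors="coerce")
            observed = self.data[c].notna()
            if (observed & ~np.isfinite(vals.astype(float).fillna(np.nan))).any():
                raise ValueError(f"non-finite observed value in continuous column {c!r}")
            self.data[c] = vals.astype(float)
        self.scale_tags = {
            c: self.scale_tags.get(c, "raw") for c in self.continuous_columns
        }

    # -- basic views ------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where a cell is missing."""
        return self.data.isna()

    @property
    def continuous_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.column_kinds.get(c) == CONTINUOUS]

    @property
    def categorical_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.column_kinds.get(c) == CATEGORICAL]

    def copy(self) -> "TraitTable":
        return TraitTable(
            data=self.data.copy(),
            column_kinds=dict(self.column_kinds),
            scale_tags=dict(self.scale_tags),
        )

    def take_rows(self, index) -> "TraitTable":
        return TraitTable(
            data=self.data.loc[index].copy(),
            column_kinds=dict(self.column_kinds),
            scale_tags=dict(self.scale_tags),
        )


@dataclass
class EncodingMap:
    """Per-column injective token -> integer-code maps (codes 0, 1, 2, ...).

    Tokens unseen at fit time map to the reserved :data:`UNSEEN_CODE`.
    """

    columns: dict[str, dict[str, int]] = field(default_factory=dict)

    def encode_token(self, column: str, token) -> int:
        mapping = self.columns[column]
        code = mapping.get(str(token))
        if code is None:
            warnings.warn(
                f"unseen category {token!r} in column {column!r}; "
                f"using reserved code {UNSEEN_CODE}",
                stacklevel=2,
            )
            return UNSEEN_CODE
        return code

    def decode(self, column: str, code: int):
        for token, c in self.columns[column].items():
            if c == code:
                return token
        raise KeyError(f"code {code} not present in column {column!r}")

    def as_dict(self) -> dict:
        return {c: dict(m) for c, m in self.columns.items()}


@dataclass
class CleaningConfig:
    """Declarative record-cleaning rules.

    required_columns : rows missing any of these are dropped.
    qc_flag_column / qc_pass_values : optional quality-control gate; rows
        whose flag is not among the accepted tokens are dropped.
    drop_all_missing_rows : drop rows with every continuous trait missing.
    """

    required_columns: list[str] = field(default_factory=list)
    qc_flag_column: str | None = None
    qc_pass_values: list[str] = field(default_factory=list)
    drop_all_missing_rows: bool = True


@dataclass
class CorrelationReport:
    """Pearson screening of candidate predictors against one target.

    ``entries`` is a list of (feature, r, n_pairs); features with fewer
    than two complete pairs or zero variance carry r = None and are never
    returned by :meth:`screened`.
    """

    target: str
    entries: list[tuple[str, float | None, int]]

    def screened(self, min_abs_r: float = 0.1) -> list[str]:
        return [
            name
            for name, r, _ in self.entries
            if r is not None and abs(r) >= min_abs_r
        ]


# ---------------------------------------------------------------------------
# I/O


def read_trait_table(
    path,
    format: str | None = None,
    column_kinds: dict[str, str] | None = None,
    missing_tokens: list[str] | None = None,
) -> TraitTable:
    """Read a delimited or Excel trait table into a :class:`TraitTable`.

    Cells that are empty or equal to one of ``missing_tokens`` (default
    {"", "NA", "NaN"}) are masked. Continuous cells that are neither numeric
    nor missing raise a cell-parse error naming the row and column. When
    ``column_kinds`` is omitted, columns that parse fully as numbers are
    treated as continuous and the rest as categorical.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(
            path.suffix.lower(), "csv"
        )
    if missing_tokens is None:
        missing_tokens = ["", "NA", "NaN"]

    try:
        if format == "csv":
            raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        elif format == "tsv":
            raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        elif format == "xlsx":
            raw = pd.read_excel(path, sheet_name=0, dtype=str, keep_default_na=False)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {format}: {exc}") from exc

    raw = raw.mask(raw.isin(missing_tokens))

    if column_kinds is None:
        column_kinds = {}
        for c in raw.columns:
            obs = raw[c].dropna()
            numeric = pd.to_numeric(obs, errors="coerce")
            column_kinds[c] = CONTINUOUS if (len(obs) == 0 or numeric.notna().all()) else CATEGORICAL

    data = raw.copy()
    for c, kind in column_kinds.items():
        if kind != CONTINUOUS or c not in data.columns:
            continue
        parsed = pd.to_numeric(data[c], errors="coerce")
        bad = parsed.isna() & data[c].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"cell-parse error: non-numeric value {data[c].iloc[i]!r} "
                f"in continuous column {c!r}, row {i}"
            )
        data[c] = parsed.astype(float)

    return TraitTable(data=data, column_kinds=column_kinds)


def write_trait_table(table: TraitTable, path, extra_columns: pd.DataFrame | None = None) -> None:
    """Write the table as CSV; floats carry 12+ significant digits."""
    out = table.data.copy()
    if extra_columns is not None:
        out = pd.concat([out, extra_columns], axis=1)
    out.to_csv(path, index=False, float_format="%.15g", na_rep="NA")


def load_config(path) -> dict:
    """Load a YAML run configuration (column kinds, missing tokens, cleaning, seed)."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


# ---------------------------------------------------------------------------
# Preprocessing operations


def clean(table: TraitTable, rules: CleaningConfig) -> TraitTable:
    """Drop records failing the declared rules; row order is preserved."""
    missing_cols = set(rules.required_columns) - set(table.columns)
    if missing_cols:
        raise ValueError(f"required_columns not in table: {sorted(missing_cols)}")
    if rules.qc_flag_column is not None and rules.qc_flag_column not in table.columns:
        raise ValueError(f"qc_flag_column {rules.qc_flag_column!r} not in table")

    keep = pd.Series(True, index=table.data.index)
    n0 = int(keep.sum())
    for col in rules.required_columns:
        keep &= table.data[col].notna()
    n_required = n0 - int(keep.sum())
    if rules.qc_flag_column is not None:
        keep &= table.data[rules.qc_flag_column].isin(rules.qc_pass_values)
    n_qc = n0 - n_required - int(keep.sum())
    n_allmiss = 0
    if rules.drop_all_missing_rows and table.continuous_columns:
        any_obs = table.data[table.continuous_columns].notna().any(axis=1)
        before = int(keep.sum())
        keep &= any_obs
        n_allmiss = before - int(keep.sum())
    logger.info(
        "clean: %d rows in, removed %d (required fields), %d (QC flag), "
        "%d (all traits missing), %d rows out",
        n0, n_required, n_qc, n_allmiss, int(keep.sum()),
    )
    return table.take_rows(table.data.index[keep])


def log_transform(table: TraitTable, columns: list[str]) -> TraitTable:
    """Replace observed values in the named continuous columns by natural logs."""
    out = table.copy()
    for c in columns:
        if table.column_kinds.get(c) != CONTINUOUS:
            raise ValueError(f"column {c!r} is not continuous")
        vals = out.data[c]
        nonpos = vals.notna() & (vals <= 0)
        if nonpos.any():
            i = int(np.flatnonzero(nonpos.to_numpy())[0])
            raise ValueError(
                f"positivity error: value {vals.iloc[i]} <= 0 in column {c!r}, "
                f"row index {vals.index[i]}"
            )
        out.data[c] = np.log(vals)
        out.scale_tags[c] = "log"
    return out


def encode_categoricals(
    table: TraitTable,
    columns: list[str],
    mapping: EncodingMap | None = None,
) -> tuple[TraitTable, EncodingMap]:
    """Replace categorical tokens by integer codes.

    Without a ``mapping``, codes are assigned in first-appearance order
    (deterministic for a fixed row order). With a stored mapping, known
    tokens reuse their codes and unseen tokens receive :data:`UNSEEN_CODE`
    with a warning. Missing cells stay missing. Encoded columns remain
    categorical in kind but hold numeric codes usable as model inputs.
    """
    out = table.copy()
    built = EncodingMap() if mapping is None else mapping
    for c in columns:
        if table.column_kinds.get(c) != CATEGORICAL:
            raise ValueError(f"column {c!r} is not categorical")
        col = out.data[c]
        if mapping is None:
            tokens = [str(t) for t in col.dropna().tolist()]
            codes: dict[str, int] = {}
            for t in tokens:
                if t not in codes:
                    codes[t] = len(codes)
            built.columns[c] = codes
        encoded = col.map(
            lambda t: np.nan if pd.isna(t) else built.encode_token(c, t)
        )
        out.data[c] = encoded.astype(float)
    return out, built


def pairwise_pearson(
    table: TraitTable, target: str, candidates: list[str]
) -> CorrelationReport:
    """Pearson r of each candidate against the target over complete pairs.

    Candidates with fewer than two complete pairs or zero variance in
    either variable are reported with r = None (excluded from screening).
    """
    if target not in table.columns:
        raise ValueError(f"target column {target!r} not in table")
    ty = pd.to_numeric(table.data[target], errors="coerce")
    entries: list[tuple[str, float | None, int]] = []
    for c in candidates:
        x = pd.to_numeric(table.data[c], errors="coerce")
        both = ty.notna() & x.notna()
        n_pairs = int(both.sum())
        if n_pairs < 2:
            entries.append((c, None, n_pairs))
            continue
        xv, yv = x[both].to_numpy(), ty[both].to_numpy()
        if np.std(xv) == 0 or np.std(yv) == 0:
            entries.append((c, None, n_pairs))
            continue
        r = float(stats.pearsonr(xv, yv).statistic)
        entries.append((c, r, n_pairs))
    return CorrelationReport(target=target, entries=entries)


def split(
    table: TraitTable, train_fraction: float = 0.7, seed: int = 0
) -> tuple[TraitTable, TraitTable]:
    """Seeded uniform row partition into train and validation tables.

    The permutation depends only on (seed, N), so every model and baseline
    fitted on the same table under the same seed sees the identical split.
    Train size is round(N * train_fraction).
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = table.n_rows
    if n < 2:
        raise ValueError(f"cannot split a table with {n} row(s)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    idx = table.data.index.to_numpy()
    return (
        table.take_rows(idx[np.sort(perm[:n_train])]),
        table.take_rows(idx[np.sort(perm[n_train:])]),
    )
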