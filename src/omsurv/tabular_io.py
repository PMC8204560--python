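"""CSV ingestion, the unified sample-aligned table, and the seeded train/test split.

The on-disk contract is a plain CSV with a header row: one row per sample,
one column each for survival time and event status, optional categorical
clinical columns, and the remaining numeric columns treated as omics
features. Column roles are declared in a :class:`Schema` (loadable from
YAML/JSON mappings).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParameterError, SchemaError, ValidationError

#: feature block tags understood by the table
BLOCKS = ("gene", "methyl", "mirna", "clinical", "other")

#: tokens treated as missing on read (case-insensitive)
MISSING_TOKENS = ["", "NA", "NaN", "na", "nan", "Na", "nA", "NAN"]


@dataclass
class Schema:
    """Column-role mapping for :func:`load_dataset`.

    ``block_map`` assigns block tags by exact feature name; ``block_prefixes``
    by column-name prefix (e.g. ``{"cg": "methyl"}``). Unmatched features get
    tag "other".
    """

    time_col: str
    event_col: str
    id_col: str | None = None
    label_col: str | None = None
    categorical_cols: tuple[str, ...] = ()
    block_map: dict[str, str] = field(default_factory=dict)
    block_prefixes: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, m: dict) -> "Schema":
        return cls(
            time_col=m["time_col"],
            event_col=m["event_col"],
            id_col=m.get("id_col"),
            label_col=m.get("label_col"),
            categorical_cols=tuple(m.get("categorical_cols", ())),
            block_map=dict(m.get("block_map", {})),
            block_prefixes=dict(m.get("block_prefixes", {})),
        )

    def block_of(self, feature: str) -> str:
        if feature in self.block_map:
            tag = self.block_map[feature]
        else:
            tag = "other"
            for prefix, b in self.block_prefixes.items():
                if feature.startswith(prefix):
                    tag = b
                    break
        if tag not in BLOCKS:
            raise SchemaError(f"unknown block tag {tag!r} for feature {feature!r}")
        return tag


@dataclass
class OmicsClinicalTable:
    """Sample-aligned omics + clinical survival table.

    ``features`` is a samples x features DataFrame indexed by sample id;
    ``time`` / ``event`` are Series on the same index; ``labels`` is an
    optional categorical per-sample column (e.g. tumor stage) and
    ``categorical`` holds further discrete clinical covariates.
    """

    features: pd.DataFrame
    time: pd.Series
    event: pd.Series
    blocks: dict[str, str] = field(default_factory=dict)
    labels: pd.Series | None = None
    categorical: pd.DataFrame | None = None

    def __post_init__(self):
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        idx = self.features.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        if self.features.columns.has_duplicates:
            dup = self.features.columns[self.features.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dup}")
        for part, name in ((self.time, "time"), (self.event, "event")):
            if not part.index.equals(idx):
                raise ValidationError(f"{name} index does not align with features")
        t = self.time.to_numpy(dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            raise ValidationError("survival time must be finite and >= 0")
        ev = self.event.to_numpy(dtype=float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            raise ValidationError("event indicator must be 0 or 1")
        for f in self.blocks:
            if f not in self.features.columns:
                raise ValidationError(f"block tag for unknown feature {f!r}")

    # -- convenience --------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return self.features.index.tolist()

    @property
    def feature_ids(self) -> list[str]:
        return self.features.columns.tolist()

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def block_of(self, feature: str) -> str:
        return self.blocks.get(feature, "other")

    def subset_samples(self, ids) -> "OmicsClinicalTable":
        return OmicsClinicalTable(
            features=self.features.loc[ids].copy(),
            time=self.time.loc[ids].copy(),
            event=self.event.loc[ids].copy(),
            blocks=dict(self.blocks),
            labels=None if self.labels is None else self.labels.loc[ids].copy(),
            categorical=None if self.categorical is None else self.categorical.loc[ids].copy(),
        )

    def subset_features(self, feature_ids) -> "OmicsClinicalTable":
        missing = [f for f in feature_ids if f not in self.features.columns]
        if missing:
            raise ValidationError(f"unknown features: {missing}")
        return replace(
            self,
            features=self.features[list(feature_ids)].copy(),
            blocks={f: self.blocks[f] for f in feature_ids if f in self.blocks},
        )

    def with_features(self, features: pd.DataFrame) -> "OmicsClinicalTable":
        return replace(self, features=features)

    def to_frame(self, schema: Schema | None = None) -> pd.DataFrame:
        """Assemble the single-CSV representation (time/event first)."""
        time_col = schema.time_col if schema else "time"
        event_col = schema.event_col if schema else "event"
        out = pd.DataFrame(index=self.features.index)
        out[time_col] = self.time
        out[event_col] = self.event
        if self.labels is not None:
            out[(schema.label_col if schema and schema.label_col else "label")] = self.labels
        if self.categorical is not None:
            for c in self.categorical.columns:
                out[c] = self.categorical[c]
        return pd.concat([out, self.features], axis=1)

    def write_csv(self, path, schema: Schema | None = None) -> None:
        self.to_frame(schema).to_csv(path, index=True, index_label="sample_id")


@dataclass
class SplitSpec:
    """Train/test split: ``fraction`` of samples go to training (default 0.7)."""

    fraction: float = 0.7
    seed: int = 0
    stratify_by_event: bool = False

    def __post_init__(self):
        if not (0.0 < self.fraction <= 1.0):
            raise ParameterError("split fraction must lie in (0, 1]")


def load_dataset(path, schema: Schema | dict) -> OmicsClinicalTable:
    """Read a CSV file into a validated :class:`OmicsClinicalTable`.

    Non-numeric entries in feature columns become missing values; row order
    is preserved. Raises :class:`SchemaError` when the declared time/event
    columns are absent, :class:`ValidationError` on duplicate sample or
    feature ids, :class:`EmptyInputError` on a header-only file.
    """
    if isinstance(schema, dict):
        schema = Schema.from_mapping(schema)
    header = pd.read_csv(path, header=None, nrows=1).iloc[0].astype(str)
    if header.duplicated().any():
        dup = header[header.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate column names in header: {dup}")
    df = pd.read_csv(path, na_values=MISSING_TOKENS, keep_default_na=False, skipinitialspace=True)
    if len(df) == 0:
        raise EmptyInputError(f"no data rows in {path}")
    return table_from_frame(df, schema)


def table_from_frame(df: pd.DataFrame, schema: Schema) -> OmicsClinicalTable:
    """Build a table from an in-memory DataFrame using the schema roles."""
    for col in (schema.time_col, schema.event_col):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found in input")
    df = df.copy()
    if schema.id_col is not None:
        if schema.id_col not in df.columns:
            raise SchemaError(f"id column {schema.id_col!r} not found in input")
        df = df.set_index(schema.id_col)
    elif df.columns[0].lower() in ("id", "sample", "sample_id"):
        df = df.set_index(df.columns[0])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dup}")

    reserved = {schema.time_col, schema.event_col}
    label = None
    if schema.label_col is not None:
        if schema.label_col not in df.columns:
            raise SchemaError(f"label column {schema.label_col!r} not found")
        label = df[schema.label_col]
        reserved.add(schema.label_col)
    cat = None
    if schema.categorical_cols:
        missing = [c for c in schema.categorical_cols if c not in df.columns]
        if missing:
            raise SchemaError(f"categorical columns not found: {missing}")
        cat = df[list(schema.categorical_cols)]
        reserved.update(schema.categorical_cols)

    feat_cols = [c for c in df.columns if c not in reserved]
    feats = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    blocks = {c: schema.block_of(c) for c in feat_cols}
    return OmicsClinicalTable(
        features=feats,
        time=pd.to_numeric(df[schema.time_col]),
        event=pd.to_numeric(df[schema.event_col]),
        blocks=blocks,
        labels=label,
        categorical=cat,
    )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_train_test(
    table: OmicsClinicalTable, spec: SplitSpec | None = None
) -> tuple[OmicsClinicalTable, OmicsClinicalTable]:
    """Seeded random partition into train/test; |train| = round(fraction * n).

    Simple random sampling by default; event-stratified sampling when
    ``spec.stratify_by_event`` is set.
    """
    spec = spec or SplitSpec()
    n = table.n_samples
    if n == 0:
        raise EmptyInputError("cannot split an empty table")
    rng = np.random.default_rng(spec.seed)
    ids = np.asarray(table.sample_ids, dtype=object)
    if spec.stratify_by_event:
        train_pos = []
        for val in (0, 1):
            grp = np.flatnonzero(table.event.to_numpy() == val)
            k = _round_half_away(spec.fraction * grp.size)
            train_pos.extend(rng.permutation(grp)[:k].tolist())
        train_idx = np.array(sorted(train_pos), dtype=int)
    else:
        k = _round_half_away(spec.fraction * n)
        train_idx = np.sort(rng.permutation(n)[:k])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return table.subset_samples(ids[mask].tolist()), table.subset_samples(ids[~mask].tolist())


def write_split_membership(path, train: OmicsClinicalTable, test: OmicsClinicalTable) -> None:
    rows = [(s, "train") for s in train.sample_ids] + [(s, "test") for s in test.sample_ids]
    pd.DataFrame(rows, columns=["sample_id", "partition"]).to_csv(path, index=False)
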