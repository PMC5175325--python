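"""Survey item registry and response-matrix assembly.

Three latent indices of national pharmaceutical regulation are built from
binary WHO survey items: *State Regulatory Infrastructure* (14 items),
*Monitoring the Private Market* (26 items, one of which — the regularity of
inspections — is derived from per-segment inspection frequencies), and
*Public Quality Control* (18 items).  This module loads the packaged item
registry, validates raw country x question tables against it, and applies
the composite coding rules to produce analysis-ready response matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CodingError, RegistryFormatError, RegistryValidationError

INDEX_NAMES = ("infrastructure", "private_market", "public_quality")

#: Required item counts per index.
INDEX_SIZES = {"infrastructure": 14, "private_market": 26, "public_quality": 18}

#: Canonical question ids per index (the packaged default), used to name
#: missing/extra ids when a custom registry fails the cardinality check.
CANONICAL_ITEM_IDS: dict[str, frozenset[str]] = {
    "infrastructure": frozenset(
        {
            "3.01.04", "3.01.12", "3.01.14", "3.01.16", "5.01.01", "5.01.02",
            "5.01.04.02", "5.01.10", "5.01.11", "5.01.15", "5.02.15S",
            "5.05.03", "5.05.07", "5.05.11",
        }
    ),
    "private_market": frozenset(
        {
            "5.02.08", "5.02.12S", "5.05.01", "5.05.02", "5.05.05", "5.05.06",
            "5.05.08", "5.05.09", "5.07.01", "5.03.05.01", "5.03.05.02",
            "5.03.05.03", "5.03.05.05", "Inspections", "5.04.02", "5.04.03",
            "5.04.04", "5.05.04", "5.10.01", "5.10.02", "5.10.03", "5.10.22S",
            "5.10.05", "5.10.06", "5.10.10", "5.10.16S",
        }
    ),
    "public_quality": frozenset(
        {
            "5.03.05.04", "5.03.05.05", "5.05.08", "5.05.10", "5.06.04.01",
            "5.06.04.06", "7.01.03", "7.01.04", "7.01.05", "7.01.07S",
            "7.01.10S", "7.01.11S", "7.01.12.01S", "7.01.12.02S", "7.02.03",
            "7.10.10.01S", "7.10.10.02S", "7.10.10.03S",
        }
    ),
}

#: Inspection-frequency segments feeding the composite item, in canonical order.
INSPECTION_SEGMENTS = ("manufacturers", "retail", "dispensing")

VARIANTS = ("regular", "annual")

MISSING_TOKENS = {"", "na", "nan", "none", "null", "."}


def build_inspections_composite(
    frequencies: Sequence[float | None] | Mapping[str, float | None],
    variant: str = "regular",
) -> float:
    """Code the composite inspections item from per-segment frequencies.

    Parameters
    ----------
    frequencies
        Years between inspections for the three market segments
        (manufacturers, retail distributors, dispensing points), either as a
        length-3 sequence in that order or as a mapping keyed by segment
        name.  ``None``/NaN marks a missing segment.
    variant
        ``"regular"``: 1 if every segment is inspected at least every three
        years, or any single segment at least every year.  ``"annual"``: 1
        only if every segment is inspected at least every year.

    Returns
    -------
    float
        1.0, 0.0, or NaN if any source segment is missing.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown inspections variant {variant!r}; expected one of {VARIANTS}")
    if isinstance(frequencies, Mapping):
        freqs = [frequencies.get(seg) for seg in INSPECTION_SEGMENTS]
    else:
        freqs = list(frequencies)
    if len(freqs) != len(INSPECTION_SEGMENTS):
        raise ValueError(
            f"expected {len(INSPECTION_SEGMENTS)} segment frequencies, got {len(freqs)}"
        )
    clean: list[float] = []
    for seg, f in zip(INSPECTION_SEGMENTS, freqs):
        if f is None or (isinstance(f, float) and math.isnan(f)):
            return math.nan
        f = float(f)
        if f <= 0:
            raise ValueError(f"inspection frequency for {seg} must be positive, got {f}")
        clean.append(f)
    if variant == "regular":
        hit = all(f <= 3.0 for f in clean) or any(f <= 1.0 for f in clean)
    else:
        hit = all(f <= 1.0 for f in clean)
    return 1.0 if hit else 0.0


@dataclass(frozen=True)
class CompositeRule:
    """Declarative derivation of a composite item from raw frequency columns."""

    source_columns: Mapping[str, str]  # segment name -> raw column name

    def __post_init__(self) -> None:
        missing = set(INSPECTION_SEGMENTS) - set(self.source_columns)
        if missing:
            raise RegistryFormatError(
                f"composite rule missing source columns for segments: {sorted(missing)}"
            )

    def evaluate(self, row: Mapping[str, float], variant: str = "regular") -> float:
        freqs = {seg: row.get(col) for seg, col in self.source_columns.items()}
        return build_inspections_composite(freqs, variant=variant)


@dataclass(frozen=True)
class ItemDefinition:
    """One binary survey question and its place in an index."""

    item_id: str
    label: str
    index_membership: str
    aspect: str | None = None
    derivation: CompositeRule | None = None

    @property
    def is_derived(self) -> bool:
        return self.derivation is not None


@dataclass(frozen=True)
class IndexDefinition:
    """An ordered set of items defining one latent index."""

    name: str
    title: str
    items: tuple[ItemDefinition, ...]
    anchor_item: str

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class Registry:
    """The three index definitions keyed by index name."""

    indices: Mapping[str, IndexDefinition]

    def __getitem__(self, name: str) -> IndexDefinition:
        if name not in self.indices:
            raise KeyError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")
        return self.indices[name]


def _parse_index_block(name: str, block: object) -> IndexDefinition:
    if not isinstance(block, dict) or "items" not in block:
        raise RegistryFormatError(f"index block {name!r} must be a mapping with an 'items' list")
    raw_items = block["items"]
    if not isinstance(raw_items, list) or not raw_items:
        raise RegistryFormatError(f"index block {name!r}: 'items' must be a non-empty list")
    items: list[ItemDefinition] = []
    for entry in raw_items:
        if not isinstance(entry, dict) or "id" not in entry:
            raise RegistryFormatError(f"index block {name!r}: each item needs an 'id'")
        rule = None
        if "derived" in entry:
            sources = entry["derived"].get("sources")
            if not isinstance(sources, dict):
                raise RegistryFormatError(
                    f"index block {name!r}: derived item {entry['id']!r} needs a "
                    "'sources' mapping"
                )
            rule = CompositeRule(source_columns=dict(sources))
        items.append(
            ItemDefinition(
                item_id=str(entry["id"]),
                label=str(entry.get("label", entry["id"])),
                index_membership=name,
                aspect=entry.get("aspect"),
                derivation=rule,
            )
        )
    anchor = str(block.get("anchor", items[0].item_id))
    return IndexDefinition(
        name=name, title=str(block.get("title", name)), items=tuple(items), anchor_item=anchor
    )


def _validate_registry(reg: Registry) -> None:
    for name, expected in INDEX_SIZES.items():
        idx = reg.indices[name]
        ids = list(idx.item_ids)
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise RegistryValidationError(f"index {name!r}: duplicate item ids {sorted(dupes)}")
        if len(ids) != expected:
            canon = CANONICAL_ITEM_IDS[name]
            missing_ids = sorted(canon - set(ids))
            extra_ids = sorted(set(ids) - canon)
            raise RegistryValidationError(
                f"index {name!r}: expected {expected} items, got {len(ids)}; "
                f"missing vs packaged default: {missing_ids}; extra: {extra_ids}"
            )
        if idx.anchor_item not in ids:
            raise RegistryValidationError(
                f"index {name!r}: anchor item {idx.anchor_item!r} is not in the item set"
            )
        n_derived = sum(it.is_derived for it in idx.items)
        if name == "private_market" and n_derived != 1:
            raise RegistryValidationError(
                f"index 'private_market' must contain exactly one derived item, got {n_derived}"
            )
        if name != "private_market" and n_derived != 0:
            raise RegistryValidationError(f"index {name!r} must not contain derived items")


def load_registry(config_path: str | Path | None = None) -> Registry:
    """Load and validate an item registry; the packaged default needs no path."""
    if config_path is None:
        text = resources.files("pharmirt.data").joinpath("registry.yaml").read_text()
    else:
        text = Path(config_path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough context
        raise RegistryFormatError(f"registry config does not parse as YAML: {exc}") from exc
    if not isinstance(doc, dict) or "indices" not in doc:
        raise RegistryFormatError("registry config must contain a top-level 'indices' mapping")
    blocks = doc["indices"]
    missing = set(INDEX_NAMES) - set(blocks)
    if missing:
        raise RegistryFormatError(f"registry config missing index blocks: {sorted(missing)}")
    reg = Registry(indices={name: _parse_index_block(name, blocks[name]) for name in INDEX_NAMES})
    _validate_registry(reg)
    return reg


def write_registry(reg: Registry, path: str | Path) -> None:
    """Serialize a registry back to the YAML dialect ``load_registry`` reads."""
    doc: dict = {"indices": {}}
    for name, idx in reg.indices.items():
        entries = []
        for it in idx.items:
            e: dict = {"id": it.item_id, "label": it.label}
            if it.aspect:
                e["aspect"] = it.aspect
            if it.derivation is not None:
                e["derived"] = {"sources": dict(it.derivation.source_columns)}
            entries.append(e)
        doc["indices"][name] = {"title": idx.title, "anchor": idx.anchor_item, "items": entries}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass
class ResponseMatrix:
    """N countries x J binary items with missingness (NaN) mask."""

    country_ids: list[str]
    item_ids: list[str]
    values: np.ndarray  # float array, entries in {0.0, 1.0, nan}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, j = self.values.shape
        if len(self.country_ids) != n or len(self.item_ids) != j:
            raise RegistryValidationError("id lists do not match matrix dimensions")
        if len(set(self.country_ids)) != n:
            raise RegistryValidationError("duplicate country ids")
        if len(set(self.item_ids)) != j:
            raise RegistryValidationError("duplicate item ids")
        obs = ~np.isnan(self.values)
        bad = obs & ~np.isin(self.values, (0.0, 1.0))
        if bad.any():
            i, jj = map(int, np.argwhere(bad)[0])
            raise CodingError(
                f"non-binary observed value {self.values[i, jj]!r} at "
                f"country {self.country_ids[i]!r}, item {self.item_ids[jj]!r}"
            )
        empty_rows = np.flatnonzero(~obs.any(axis=1))
        if empty_rows.size:
            raise RegistryValidationError(
                f"country {self.country_ids[int(empty_rows[0])]!r} has no observed responses"
            )
        empty_cols = np.flatnonzero(~obs.any(axis=0))
        if empty_cols.size:
            raise RegistryValidationError(
                f"item {self.item_ids[int(empty_cols[0])]!r} has no observed responses"
            )

    @property
    def n_countries(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.country_ids, columns=self.item_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseMatrix":
        return cls(
            country_ids=[str(c) for c in df.index],
            item_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "country"
        df.to_csv(path, float_format="%.0f", na_rep="NA")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResponseMatrix":
        return cls.from_frame(read_survey_csv(path))


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    """Read the survey CSV dialect: 'country' key column, question-id headers.

    Missing cells may be empty or any of the usual NA tokens.  Cells are
    returned as floats with NaN for missing; non-numeric tokens raise
    :class:`CodingError` with their coordinates.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0].lower() != "country":
        raise RegistryFormatError(
            f"survey CSV must have 'country' as its first column, got {df.columns[0]!r}"
        )
    df = df.set_index(df.columns[0])
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns, dtype=float)
    for col in df.columns:
        for country, raw in df[col].items():
            token = str(raw).strip()
            if token.lower() in MISSING_TOKENS:
                out.loc[country, col] = np.nan
                continue
            try:
                out.loc[country, col] = float(token)
            except ValueError as exc:
                raise CodingError(
                    f"cannot code cell (country {country!r}, item {col!r}): {raw!r}"
                ) from exc
    return out


def assemble_matrix(
    raw_table: pd.DataFrame,
    item_set: IndexDefinition,
    variant: str = "regular",
) -> ResponseMatrix:
    """Build a validated ResponseMatrix for one index from a raw survey table.

    Derived items are computed row-wise from their source frequency columns
    (already-coded 0/1 columns for derived items are accepted as-is, which
    makes assembly idempotent).  Column order follows the registry.
    """
    cols: dict[str, np.ndarray] = {}
    for it in item_set.items:
        if it.item_id in raw_table.columns:
            cols[it.item_id] = raw_table[it.item_id].to_numpy(dtype=float)
        elif it.is_derived:
            rule = it.derivation
            missing_src = [c for c in rule.source_columns.values() if c not in raw_table.columns]
            if missing_src:
                raise RegistryValidationError(
                    f"derived item {it.item_id!r}: raw table lacks source columns {missing_src}"
                )
            vals = np.array(
                [rule.evaluate(row, variant=variant) for _, row in raw_table.iterrows()],
                dtype=float,
            )
            cols[it.item_id] = vals
        else:
            raise RegistryValidationError(
                f"raw table is missing required item column {it.item_id!r}"
            )
    values = np.column_stack([cols[i] for i in item_set.item_ids])
    return ResponseMatrix(
        country_ids=[str(c) for c in raw_table.index],
        item_ids=list(item_set.item_ids),
        values=values,
    )
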