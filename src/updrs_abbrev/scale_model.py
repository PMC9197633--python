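"""Structure of the MDS-UPDRS instrument and remote-practicality constraint sets.

The Movement Disorder Society Unified Parkinson's Disease Rating Scale
(MDS-UPDRS) has four parts — I non-motor experiences of daily living,
II motor experiences of daily living, III motor examination, IV motor
complications — comprising 50 items rated through 65 individual 0-4
ratings (several part-III items are rated per side or per body region).
An item's score is the sum of its rating fields, and the scale total is
the sum of all 65 ratings, following the standard total-score convention.

Two constraint sets matter for remote (telemedicine) administration:
items that require hands-on, face-to-face assessment (rigidity, postural
stability) and items that require the patient's lower limbs or gait to be
observed, which is impractical with a desk-mounted device.

The instrument definition lives in a packaged TSV
(``data/mds_updrs_items.tsv``) so that a different instrument can be
plugged in without touching code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "ExclusionReason",
    "ItemDef",
    "ItemRegistry",
    "ItemSet",
    "InstrumentDefinitionError",
    "build_registry",
    "candidate_pool",
    "named_subset",
    "item_sort_key",
]


class InstrumentDefinitionError(ValueError):
    """Raised when the packaged instrument-definition file is malformed."""


class ExclusionReason(str, Enum):
    NONE = "none"
    FACE_TO_FACE = "face_to_face"
    LOWER_LIMB = "lower_limb"


def item_sort_key(item_id: str) -> tuple[int, int]:
    """Canonical ordering key: (part, item number) parsed from ``'P.N'``.

    Numeric, not lexicographic, so that 3.9 sorts before 3.10.
    """
    part_s, _, num_s = item_id.partition(".")
    try:
        return int(part_s), int(num_s)
    except ValueError as exc:
        raise ValueError(f"item id {item_id!r} is not of the form 'P.N'") from exc


@dataclass(frozen=True)
class ItemDef:
    """One scale item: its part, rating fields, and remote-exclusion status."""

    item_id: str
    name: str
    part: int
    rating_fields: tuple[str, ...]
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    @property
    def remote_excluded(self) -> bool:
        return self.exclusion_reason is not ExclusionReason.NONE

    @property
    def n_ratings(self) -> int:
        return len(self.rating_fields)


@dataclass(frozen=True)
class ItemSet:
    """An ordered, duplicate-free set of item ids in canonical order.

    Canonical order is (part, item number); all serialized subsets use it
    so equal subsets always render identically.
    """

    item_ids: tuple[str, ...]

    def __init__(self, item_ids: Iterable[str]) -> None:
        ids = list(item_ids)
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids: {dupes}")
        object.__setattr__(
            self, "item_ids", tuple(sorted(ids, key=item_sort_key))
        )

    def __iter__(self) -> Iterator[str]:
        return iter(self.item_ids)

    def __len__(self) -> int:
        return len(self.item_ids)

    def __contains__(self, item_id: object) -> bool:
        return item_id in self.item_ids

    def __str__(self) -> str:
        return ",".join(self.item_ids)

    @classmethod
    def parse(cls, text: str) -> "ItemSet":
        """Parse a comma-separated id list, e.g. ``"1.13,2.5,3.4"``."""
        return cls(t.strip() for t in text.split(",") if t.strip())

    def intersection(self, other: "ItemSet") -> "ItemSet":
        return ItemSet(i for i in self.item_ids if i in other)


@dataclass(frozen=True)
class ItemRegistry:
    """The full instrument: items keyed by id, plus field-level indexes."""

    items: tuple[ItemDef, ...]
    _by_id: dict[str, ItemDef] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        by_id: dict[str, ItemDef] = {}
        field_owner: dict[str, str] = {}
        for it in self.items:
            if it.item_id in by_id:
                raise InstrumentDefinitionError(
                    f"duplicate item id {it.item_id!r}"
                )
            by_id[it.item_id] = it
            for f in it.rating_fields:
                if f in field_owner:
                    raise InstrumentDefinitionError(
                        f"rating field {f!r} appears under both "
                        f"{field_owner[f]!r} and {it.item_id!r}"
                    )
                field_owner[f] = it.item_id
        object.__setattr__(self, "_by_id", by_id)

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, item_id: object) -> bool:
        return item_id in self._by_id

    def item(self, item_id: str) -> ItemDef:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise KeyError(f"unknown item id {item_id!r}") from None

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def rating_fields(self) -> tuple[str, ...]:
        return tuple(f for it in self.items for f in it.rating_fields)

    @property
    def n_rating_fields(self) -> int:
        return len(self.rating_fields)

    def rating_fields_of(self, subset: ItemSet | Iterable[str]) -> tuple[str, ...]:
        """All rating fields belonging to the given items, canonical order."""
        ids = set(subset)
        unknown = ids - set(self._by_id)
        if unknown:
            raise KeyError(f"unknown item ids: {sorted(unknown)}")
        return tuple(
            f for it in self.items if it.item_id in ids for f in it.rating_fields
        )

    def validate_subset(self, subset: ItemSet) -> None:
        unknown = [i for i in subset if i not in self._by_id]
        if unknown:
            raise KeyError(f"subset contains unknown item ids: {unknown}")


_DEFAULT_DEFINITION = "mds_updrs_items.tsv"

_REQUIRED_COLUMNS = ("item_id", "name", "part", "rating_fields", "exclusion_reason")


def _parse_definition_rows(rows: Iterable[dict[str, str]]) -> tuple[ItemDef, ...]:
    items: list[ItemDef] = []
    for row in rows:
        item_id = (row.get("item_id") or "").strip()
        try:
            part = int(row["part"])
            if part not in (1, 2, 3, 4):
                raise ValueError(f"part must be 1-4, got {part}")
            fields = tuple(
                f.strip() for f in row["rating_fields"].split(",") if f.strip()
            )
            if not fields:
                raise ValueError("no rating fields")
            reason = ExclusionReason(row["exclusion_reason"].strip())
            item_sort_key(item_id)
            items.append(
                ItemDef(
                    item_id=item_id,
                    name=row["name"].strip(),
                    part=part,
                    rating_fields=fields,
                    exclusion_reason=reason,
                )
            )
        except (KeyError, ValueError) as exc:
            raise InstrumentDefinitionError(
                f"malformed instrument definition at item {item_id or row!r}: {exc}"
            ) from exc
    return tuple(sorted(items, key=lambda it: item_sort_key(it.item_id)))


def build_registry(definition_path: str | Path | None = None) -> ItemRegistry:
    """Load the instrument registry from its definition TSV.

    With no argument, loads the packaged MDS-UPDRS definition (50 items,
    65 rating fields). A custom path may point at any file with the same
    schema, enabling other instruments.
    """
    if definition_path is None:
        ref = resources.files("updrs_abbrev.data").joinpath(_DEFAULT_DEFINITION)
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(definition_path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    missing = set(_REQUIRED_COLUMNS) - set(reader.fieldnames or ())
    if missing:
        raise InstrumentDefinitionError(
            f"instrument definition missing columns: {sorted(missing)}"
        )
    return ItemRegistry(items=_parse_definition_rows(reader))


def candidate_pool(registry: ItemRegistry, mode: str = "any_item") -> ItemSet:
    """The item pool searched under a given administration mode.

    ``any_item`` places no constraint; ``remote`` drops items flagged as
    needing face-to-face contact or lower-limb observation.
    """
    if mode == "any_item":
        return ItemSet(registry.item_ids)
    if mode == "remote":
        return ItemSet(
            it.item_id for it in registry.items if not it.remote_excluded
        )
    raise ValueError(f"unknown candidate-pool mode {mode!r}")


#: Published optimal 8-item subsets: the remote-constrained winner and the
#: unconstrained ("any-item") winner. They share four items.
_NAMED_SUBSETS: dict[str, tuple[str, ...]] = {
    "remote_optimal": ("1.13", "2.5", "2.10", "2.12", "3.2", "3.4", "3.9", "4.3"),
    "any_item_optimal": ("1.13", "2.1", "2.5", "2.10", "3.5", "3.7", "3.13", "4.3"),
}


def named_subset(name: str) -> ItemSet:
    """Return one of the published optimal 8-item subsets by name."""
    try:
        return ItemSet(_NAMED_SUBSETS[name])
    except KeyError:
        raise ValueError(
            f"unknown named subset {name!r}; known: {sorted(_NAMED_SUBSETS)}"
        ) from None
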