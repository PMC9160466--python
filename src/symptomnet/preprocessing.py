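"""Item selection and binarization of 5-point Likert symptom responses.

The analysis set is the 13 SCL-90 depression-subscale items plus the guilt
item, identified by short codes (``WL`` worthlessness, ``HL`` hopelessness,
``SB`` self-blame, ``GU`` guilt, ``LS`` loss of sexual interest, ``LE`` low
energy, ``NI`` no interest, ...).  Responses are dichotomized at the
moderate-distress boundary: categories 1-2 (absent/mild) map to 0 and 3-5
(moderate to extreme) map to 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import BinaryMatrix, LikertMatrix
from .errors import InvalidResponseError, InvalidSpecError, MissingItemError

__all__ = [
    "CatalogItem",
    "ItemCatalog",
    "default_catalog",
    "binarize",
    "endorsement_frequencies",
    "select_items",
    "ZUNG_SDS_SCREEN_CUTOFF",
]

#: Zung Self-Rating Depression Scale score at or above which prospective
#: healthy-control participants are screened out.  Recorded for documentation;
#: screening itself is outside this package's scope.
ZUNG_SDS_SCREEN_CUTOFF = 50


@dataclass(frozen=True)
class CatalogItem:
    """One analysis item: short code, instrument item number and wording."""

    code: str
    number: int
    full_text: str
    subscale_member: bool  # True for the 13 depression-subscale items
    probe: bool = False  # the single probe symptom of an analysis run


# The depression subscale of the 90-item checklist plus the guilt item.
# Wording follows the standard instrument; the catalog is config-overridable
# because translated adaptations may renumber items.
_DEFAULT_ITEMS: tuple[CatalogItem, ...] = (
    CatalogItem("LS", 5, "loss of sexual interest or pleasure", True),
    CatalogItem("LE", 14, "feeling low in energy or slowed down", True),
    CatalogItem("ST", 15, "thoughts of ending your life", True),
    CatalogItem("CR", 20, "crying easily", True),
    CatalogItem("TR", 22, "feelings of being trapped or caught", True),
    CatalogItem("SB", 26, "blaming yourself for things", True),
    CatalogItem("LO", 29, "feeling lonely", True),
    CatalogItem("BL", 30, "feeling blue", True),
    CatalogItem("WO", 31, "worrying too much about things", True),
    CatalogItem("NI", 32, "feeling no interest in things", True),
    CatalogItem("HL", 54, "feeling hopeless about the future", True),
    CatalogItem("EF", 71, "feeling everything is an effort", True),
    CatalogItem("WL", 79, "feelings of worthlessness", True, probe=True),
    CatalogItem("GU", 89, "feelings of guilt", False),
)


@dataclass
class ItemCatalog:
    """The ordered set of analysis items.

    Invariants: codes unique; exactly one item flagged as the probe symptom.
    """

    items: tuple[CatalogItem, ...] = _DEFAULT_ITEMS

    def __post_init__(self) -> None:
        codes = [it.code for it in self.items]
        if len(set(codes)) != len(codes):
            raise InvalidSpecError("catalog item codes must be unique")
        n_probe = sum(it.probe for it in self.items)
        if n_probe != 1:
            raise InvalidSpecError(
                f"catalog must flag exactly one probe item, found {n_probe}"
            )

    @property
    def codes(self) -> list[str]:
        return [it.code for it in self.items]

    @property
    def probe(self) -> str:
        return next(it.code for it in self.items if it.probe)

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_file(cls, path: str | Path) -> "ItemCatalog":
        """Load a catalog from YAML or JSON: a list of item mappings."""
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        items = tuple(
            CatalogItem(
                code=str(d["code"]),
                number=int(d.get("number", i + 1)),
                full_text=str(d.get("full_text", "")),
                subscale_member=bool(d.get("subscale_member", True)),
                probe=bool(d.get("probe", False)),
            )
            for i, d in enumerate(raw)
        )
        return cls(items)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        raw = [
            {
                "code": it.code,
                "number": it.number,
                "full_text": it.full_text,
                "subscale_member": it.subscale_member,
                "probe": it.probe,
            }
            for it in self.items
        ]
        if path.suffix == ".json":
            path.write_text(json.dumps(raw, indent=2))
        else:
            path.write_text(yaml.safe_dump(raw, sort_keys=False))


def default_catalog() -> ItemCatalog:
    """The 14-item analysis catalog (13 depression-subscale items + guilt)."""
    return ItemCatalog()


def binarize(likert: LikertMatrix) -> BinaryMatrix:
    """Dichotomize Likert responses at the moderate-distress boundary.

    Categories 1-2 (absent or mild distress) map to 0; categories 3-5
    (moderate, severe, extreme) map to 1.  Shape, item order and group
    labels are preserved.
    """
    values = np.asarray(likert.values)
    bad = (values < 1) | (values > 5)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise InvalidResponseError(
            f"response {values[r, c]} at subject {r}, item "
            f"{likert.item_codes[c]!r} outside 1-5"
        )
    return BinaryMatrix(
        (values >= 3).astype(np.int8), list(likert.item_codes), group=likert.group
    )


def endorsement_frequencies(
    binary: BinaryMatrix, by_group: bool = False
) -> pd.DataFrame:
    """Per-item endorsement proportions (column means of the binary matrix).

    With ``by_group=True`` and group labels present, one row per group.
    """
    df = pd.DataFrame(binary.values, columns=binary.item_codes)
    if by_group and binary.group is not None:
        out = df.groupby(pd.Series(binary.group, name="group")).mean()
        return out
    return df.mean().to_frame(name="endorsement").T.set_axis(["all"])


def select_items(likert: LikertMatrix, catalog: ItemCatalog) -> LikertMatrix:
    """Restrict and reorder columns to the catalog items, in catalog order."""
    missing = [c for c in catalog.codes if c not in likert.item_codes]
    if missing:
        raise MissingItemError(f"catalog items absent from data: {missing}")
    idx = [likert.item_codes.index(c) for c in catalog.codes]
    return LikertMatrix(likert.values[:, idx], list(catalog.codes), group=likert.group)
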