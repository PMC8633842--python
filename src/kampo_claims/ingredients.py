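"""Formula-to-crude-drug mapping for cautionary-ingredient flagging.

Several crude drugs are contraindicated or to be used cautiously in
pregnancy: rhubarb, peach kernel, moutan bark, safflower, achyranthes root,
and anhydrous sodium sulfate may provoke miscarriage, and processed aconite
root carries an elevated risk of adverse effects.  The shipped map records,
for each formula it knows, only its *cautionary* constituents — it is not a
full composition table — and any formula absent from the map is reported as
having unknown ingredients rather than silently passing unflagged.  The map
is user-editable via YAML.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

CAUTIONARY_INGREDIENTS = frozenset({
    "rhubarb",
    "peach kernel",
    "moutan bark",
    "safflower",
    "achyranthes root",
    "anhydrous sodium sulfate",
    "processed aconite root",
})

# cautionary constituents of commonly dispensed formulas
DEFAULT_FORMULA_INGREDIENTS: dict[str, frozenset[str]] = {
    "mashiningan": frozenset({"rhubarb"}),
    "daiokanzoto": frozenset({"rhubarb"}),
    "otsujito": frozenset({"rhubarb"}),
    "bofutsushosan": frozenset({"rhubarb", "anhydrous sodium sulfate"}),
    "tokakujokito": frozenset({"rhubarb", "peach kernel", "anhydrous sodium sulfate"}),
    "junchoto": frozenset({"rhubarb", "peach kernel"}),
    "keishibukuryogan": frozenset({"peach kernel", "moutan bark"}),
    "kyukichoketsuin": frozenset({"peach kernel", "moutan bark", "safflower"}),
    "unkeito": frozenset({"moutan bark"}),
    "kamishoyosan": frozenset({"moutan bark"}),
    "maobushisaishinto": frozenset({"processed aconite root"}),
}


@dataclass(frozen=True)
class IngredientMap:
    formula_ingredients: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_FORMULA_INGREDIENTS))
    cautionary: frozenset[str] = CAUTIONARY_INGREDIENTS

    def flags(self, formula_name: str) -> frozenset[str] | None:
        """Cautionary ingredients of a formula; ``None`` when unknown."""
        ingredients = self.formula_ingredients.get(formula_name.lower())
        if ingredients is None:
            return None
        return frozenset(ingredients) & self.cautionary

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IngredientMap":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mapping = {name.lower(): frozenset(items)
                   for name, items in (raw.get("formulas") or {}).items()}
        cautionary = frozenset(raw.get("cautionary", CAUTIONARY_INGREDIENTS))
        return cls(mapping, cautionary)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "cautionary": sorted(self.cautionary),
            "formulas": {name: sorted(items)
                         for name, items in sorted(self.formula_ingredients.items())},
        }, sort_keys=False))
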