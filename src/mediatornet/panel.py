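"""The 27-plex serum soluble-mediator panel.

The analyses in this package operate on a fixed multiplex bead-array panel of
27 serum analytes split into four functional categories:

* chemokines (``C``) — CXCL8, CCL11, CCL3, CCL4, CCL2, CCL5, CXCL10
* pro-inflammatory cytokines (``PROc``) — IL-1β, IL-6, TNF-α, IL-12, IFN-γ,
  IL-15, IL-17
* regulatory cytokines (``REGc``) — IL-1Ra, IL-4, IL-5, IL-9, IL-10, IL-13
* growth factors (``GF``) — FGF-basic, PDGF, VEGF, G-CSF, GM-CSF, IL-2, IL-7

Each analyte carries a fixed 1..27 display index (the node numbering used in
network figures). Input tables may spell analyte names with ASCII stand-ins
for Greek letters ("TNF-alpha", "IL1b"); :func:`MediatorPanel.normalize`
maps such variants onto the canonical spellings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

CHEMOKINES = ("CXCL8", "CCL11", "CCL3", "CCL4", "CCL2", "CCL5", "CXCL10")
PRO_INFLAMMATORY = ("IL-1β", "IL-6", "TNF-α", "IL-12", "IFN-γ", "IL-15", "IL-17")
REGULATORY = ("IL-1Ra", "IL-4", "IL-5", "IL-9", "IL-10", "IL-13")
GROWTH_FACTORS = ("FGF-basic", "PDGF", "VEGF", "G-CSF", "GM-CSF", "IL-2", "IL-7")

CATEGORIES = ("C", "PROc", "REGc", "GF")

_GREEK_ASCII = {"β": ("beta", "b"), "α": ("alpha", "a"), "γ": ("gamma", "g")}


def _squash(name: str) -> str:
    """Lower-case and strip every non-alphanumeric character."""
    return re.sub(r"[^0-9a-zA-Zβαγ]+", "", name).lower()


def _alias_keys(canonical: str) -> set[str]:
    keys = {_squash(canonical)}
    for greek, subs in _GREEK_ASCII.items():
        if greek in canonical:
            for sub in subs:
                keys.add(_squash(canonical.replace(greek, sub)))
    return keys


@dataclass(frozen=True)
class MediatorPanel:
    """Ordered analyte panel with category labels and display numbering.

    Attributes
    ----------
    mediators:
        The 27 analyte names in display order.
    category:
        Map analyte -> one of ``C``, ``PROc``, ``REGc``, ``GF``.
    display_index:
        Map analyte -> 1..27, a bijection following the panel order.
    """

    mediators: tuple[str, ...]
    category: dict[str, str]
    display_index: dict[str, int]
    _aliases: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.mediators) != 27 or len(set(self.mediators)) != 27:
            raise ValueError("panel must contain exactly 27 distinct analytes")
        if set(self.category) != set(self.mediators):
            raise ValueError("category map must cover exactly the panel analytes")
        sizes = {c: sum(1 for a in self.mediators if self.category[a] == c)
                 for c in CATEGORIES}
        if sizes != {"C": 7, "PROc": 7, "REGc": 6, "GF": 7}:
            raise ValueError(f"category sizes must be C=7/PROc=7/REGc=6/GF=7, got {sizes}")
        if sorted(self.display_index.values()) != list(range(1, 28)):
            raise ValueError("display_index must be a bijection onto 1..27")
        if set(self.display_index) != set(self.mediators):
            raise ValueError("display_index must cover exactly the panel analytes")
        if not self._aliases:
            aliases: dict[str, str] = {}
            for name in self.mediators:
                for key in _alias_keys(name):
                    aliases[key] = name
            object.__setattr__(self, "_aliases", aliases)

    @classmethod
    def bioplex27(cls) -> "MediatorPanel":
        """The default 27-plex panel in figure display order."""
        ordered = CHEMOKINES + PRO_INFLAMMATORY + REGULATORY + GROWTH_FACTORS
        category = {}
        for group, label in ((CHEMOKINES, "C"), (PRO_INFLAMMATORY, "PROc"),
                             (REGULATORY, "REGc"), (GROWTH_FACTORS, "GF")):
            for a in group:
                category[a] = label
        display = {a: i + 1 for i, a in enumerate(ordered)}
        return cls(mediators=ordered, category=category, display_index=display)

    def normalize(self, name: str) -> str:
        """Map an analyte spelling variant onto its canonical panel name.

        Raises
        ------
        KeyError
            If the name does not resolve to any panel analyte.
        """
        key = _squash(name)
        try:
            return self._aliases[key]
        except KeyError:
            raise KeyError(f"analyte {name!r} is not in the 27-plex panel") from None

    def members(self, category: str) -> tuple[str, ...]:
        """Analytes belonging to one category, in display order."""
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
        return tuple(a for a in self.mediators if self.category[a] == category)


DEFAULT_PANEL = MediatorPanel.bioplex27()
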