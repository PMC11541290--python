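"""Canonical water-quality parameter vocabulary.

The monitoring programme this package targets reports twelve physicochemical
and microbiological parameters per station-month.  All tabular inputs are
normalised to the canonical names below; common synonyms from agency exports
are resolved through :data:`ALIASES`.
"""

from __future__ import annotations

#: Canonical parameter keys, with conventional reporting units.
PARAMETERS: dict[str, str] = {
    "nitrate": "mg/L",
    "nitrite": "mg/L",
    "ammonia": "mg/L",          # NH3-N
    "fecal_coliform": "CFU/100mL",
    "chlorophyll_a": "ug/L",
    "orthophosphate": "mg/L",
    "doc": "mg/L",              # dissolved organic carbon
    "temperature": "degC",
    "do": "mg/L",               # dissolved oxygen
    "ph": "pH units",
    "salinity": "ppt",
    "tss": "mg/L",              # total suspended solids
}

#: Case-insensitive alias table mapping export spellings to canonical keys.
ALIASES: dict[str, str] = {
    "no3": "nitrate", "nitrate-n": "nitrate", "no3-n": "nitrate",
    "no2": "nitrite", "nitrite-n": "nitrite", "no2-n": "nitrite",
    "nh3": "ammonia", "nh3-n": "ammonia", "ammonia-n": "ammonia",
    "f.coli": "fecal_coliform", "fcoli": "fecal_coliform",
    "fecal coliform": "fecal_coliform", "f. coli": "fecal_coliform",
    "chl-a": "chlorophyll_a", "chla": "chlorophyll_a",
    "chlorophyll-a": "chlorophyll_a", "chlorophyll a": "chlorophyll_a",
    "ortho-p": "orthophosphate", "orthop": "orthophosphate",
    "po4": "orthophosphate", "ortho phosphate": "orthophosphate",
    "dissolved organic carbon": "doc",
    "temp": "temperature", "water temperature": "temperature",
    "dissolved oxygen": "do", "d.o.": "do",
    "ph units": "ph",
    "sal": "salinity",
    "total suspended solids": "tss",
}
# identity aliases so canonical names always resolve
ALIASES.update({name: name for name in PARAMETERS})


def resolve_parameter(name: str) -> str | None:
    """Map a raw parameter label to its canonical key, or None if unknown."""
    return ALIASES.get(str(name).strip().lower())
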