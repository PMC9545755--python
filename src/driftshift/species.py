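"""Species vocabulary and foraging-strategy guilds.

Seven wintering waterfowl species are tracked, grouped into three foraging
strategies: generalists (medium-bodied dabbling ducks), grubbing/browsing
foragers (large-bodied geese), and wetland-obligate foragers (small-bodied
ducks whose diets depend on open-water wetlands).
"""

from __future__ import annotations

#: Four-letter species codes accepted everywhere in the package.
SPECIES_CODES = ("MALL", "GWTE", "GADW", "NOPI", "NSHO", "GWFG", "SNGO")

#: eBird-style common names -> species code (case-insensitive match at ingest).
COMMON_NAME_TO_CODE = {
    "mallard": "MALL",
    "green-winged teal": "GWTE",
    "gadwall": "GADW",
    "northern pintail": "NOPI",
    "northern shoveler": "NSHO",
    "greater white-fronted goose": "GWFG",
    "snow goose": "SNGO",
}

CODE_TO_COMMON_NAME = {
    "MALL": "Mallard",
    "GWTE": "Green-winged Teal",
    "GADW": "Gadwall",
    "NOPI": "Northern Pintail",
    "NSHO": "Northern Shoveler",
    "GWFG": "Greater White-fronted Goose",
    "SNGO": "Snow Goose",
}

#: Foraging-strategy guild per species.
STRATEGY_BY_SPECIES = {
    "MALL": "generalist",
    "NOPI": "generalist",
    "GWTE": "generalist",
    "SNGO": "grubbing",
    "GWFG": "grubbing",
    "NSHO": "wetland_obligate",
    "GADW": "wetland_obligate",
}

STRATEGIES = ("generalist", "grubbing", "wetland_obligate")

#: Canonical flyway order; also the tie-break order for boundary points.
FLYWAYS = ("Atlantic", "Mississippi", "Central", "Pacific")


def normalize_species(value: str) -> str | None:
    """Map a species code or common name to the canonical code.

    Returns ``None`` for species outside the seven-species vocabulary.
    """
    v = value.strip()
    if v.upper() in SPECIES_CODES:
        return v.upper()
    return COMMON_NAME_TO_CODE.get(v.lower().replace("‐", "-").replace("‑", "-"))
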