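"""Built-in country -> region table for the 13 registry countries.

Four regions are used for the region-specific mortality tests: North
America, Northern Europe, Southern Europe, and Japan.  Country codes are
ISO-3166 alpha-2 except ``EW`` (England and Wales, which the registry
tracks as a unit).
"""

from __future__ import annotations

REGIONS: dict[str, str] = {
    "CA": "North America",
    "US": "North America",
    "BE": "Northern Europe",
    "DE": "Northern Europe",
    "DK": "Northern Europe",
    "EW": "Northern Europe",
    "FI": "Northern Europe",
    "NO": "Northern Europe",
    "SE": "Northern Europe",
    "AT": "Southern Europe",
    "ES": "Southern Europe",
    "FR": "Southern Europe",
    "JP": "Japan",
}

REGION_NAMES = ("North America", "Northern Europe", "Southern Europe", "Japan")


def region_of(country: str) -> str:
    try:
        return REGIONS[country]
    except KeyError:
        raise KeyError(
            f"country {country!r} has no region assignment; known codes: "
            f"{sorted(REGIONS)}"
        ) from None
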