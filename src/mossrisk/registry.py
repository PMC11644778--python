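"""Element registry for moss-biomonitoring surveys.

The registry carries the 15 element symbols routinely quantified in national
moss surveys (ICP-AES panel plus Hg from a direct mercury analyzer), the
default Hakanson toxic-response factors, and the nine-element set entering
the Pollution Load Index.
"""

from __future__ import annotations

#: All measured element symbols, in conventional (alphabetical) order.
ELEMENTS: tuple[str, ...] = (
    "Al", "Ba", "Cd", "Co", "Cr", "Cu", "Fe", "Hg",
    "Mn", "Ni", "Pb", "S", "Sr", "V", "Zn",
)

#: Hakanson toxic-response factors (dimensionless toxicity weights).
#: Only these nine elements participate in PERI/ERI.
DEFAULT_TRF: dict[str, float] = {
    "Mn": 1.0,
    "Zn": 1.0,
    "Cr": 2.0,
    "V": 2.0,
    "Cu": 5.0,
    "Pb": 5.0,
    "Ni": 5.0,
    "Cd": 30.0,
    "Hg": 40.0,
}

#: Element set of the Pollution Load Index (geometric mean of nine CFs).
PLI_ELEMENTS: tuple[str, ...] = ("Al", "Cd", "Cr", "Cu", "Fe", "Ni", "Pb", "V", "Zn")

#: Moss species encountered in Caucasus-region surveys, with typical
#: sampling proportions (pleurocarpous Hypnum cupressiforme dominates).
SPECIES: tuple[str, ...] = (
    "Hypnum cupressiforme",
    "Abietinella abietina",
    "Hylocomium splendens",
    "Pleurozium schreberi",
)
SPECIES_WEIGHTS: tuple[float, ...] = (70 / 95, 14 / 95, 6 / 95, 5 / 95)

_CANONICAL = {symbol.lower(): symbol for symbol in ELEMENTS}


def canonical_element(name: str) -> str:
    """Return the registry spelling for ``name`` (case-insensitive).

    Symbols not in the registry are returned stripped but otherwise
    unchanged, so surveys carrying extra columns still load.
    """
    return _CANONICAL.get(name.strip().lower(), name.strip())
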