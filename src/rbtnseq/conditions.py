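"""Closed vocabulary of experimental conditions.

The screen compares a Time0 inoculum against bacteria recovered from two
compartments (rhizosphere, root) of five plant species seven days after
inoculation.  A condition label is ``Time0`` or ``"<species>:<compartment>"``.
"""

from __future__ import annotations

__all__ = [
    "TIME0",
    "SPECIES",
    "COMPARTMENTS",
    "CONDITIONS",
    "condition_label",
    "parse_condition",
    "is_valid_condition",
]

TIME0 = "Time0"
SPECIES = ("pea", "lentil", "Lathyrus", "alfalfa", "barley")
COMPARTMENTS = ("rhizosphere", "root")


def condition_label(species: str, compartment: str) -> str:
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}; expected one of {COMPARTMENTS}")
    return f"{species}:{compartment}"


CONDITIONS = (TIME0,) + tuple(
    condition_label(sp, cp) for sp in SPECIES for cp in COMPARTMENTS
)


def parse_condition(label: str) -> tuple[str, str] | None:
    """Split a non-Time0 condition into (species, compartment); None for Time0."""
    if label == TIME0:
        return None
    species, _, compartment = label.partition(":")
    if species not in SPECIES or compartment not in COMPARTMENTS:
        raise ValueError(f"invalid condition label {label!r}")
    return species, compartment


def is_valid_condition(label: str) -> bool:
    return label in CONDITIONS
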