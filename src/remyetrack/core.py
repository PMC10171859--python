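"""Shared vocabulary for lesion classification.

Focal inflammatory demyelinating white-matter lesions are assigned to one of
three stages, both radiologically (serial proton density-weighted MRI plus
terminal gadolinium-enhanced T1) and histologically (myelin stains and
oligodendrocyte-lineage markers):

``early_active``
    Ongoing inflammatory demyelination: persistently hyperintense on PDw,
    enhancing after gadolinium at the terminal scan, prominent microglial
    infiltration and large unstained (demyelinated) area on PLP/LFB.
``chronic_demyelinated``
    Chronic, at least partially demyelinated: persistent PDw hyperintensity
    without terminal enhancement, loss of oligodendrocytes, large unstained
    area.
``remyelinated``
    Initially hyperintense, returning to isointensity on PDw over weeks,
    no terminal enhancement, near-normal myelin staining and repopulated
    mature oligodendrocytes.
"""

from __future__ import annotations

import enum


class LesionClass(str, enum.Enum):
    """Three-level lesion stage used for both MRI and histology labels."""

    EARLY_ACTIVE = "early_active"
    CHRONIC_DEMYELINATED = "chronic_demyelinated"
    REMYELINATED = "remyelinated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes that count as "demyelinated" when lesions are grouped by
#: myelination status only (binary concordance analyses).
DEMYELINATED_CLASSES = frozenset(
    {LesionClass.EARLY_ACTIVE, LesionClass.CHRONIC_DEMYELINATED}
)


def as_lesion_class(value: "str | LesionClass") -> LesionClass:
    """Coerce a string or enum member to :class:`LesionClass`."""
    if isinstance(value, LesionClass):
        return value
    return LesionClass(str(value))
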