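"""Region vocabulary for regional morphometrics.

The cortical parcellation is the 34-region Desikan-Killiany atlas (per
hemisphere).  Subcortical structures default to a 9-name list covering the
common FreeSurfer segmentation targets; the exact set is configurable because
different studies report slightly different selections.  Gross measures are
the three per-hemisphere totals used to normalize cortical volume: gray
matter (GM), white matter (WM), and lateral ventricle (LV).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: Desikan-Killiany cortical regions, FreeSurfer aparc order.
DESIKAN_KILLIANY: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: Default 9 subcortical structures (per hemisphere).
SUBCORTICAL_DEFAULT: tuple[str, ...] = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
    "ventral_dc",
    "cerebellum_cortex",
)

#: Gross per-hemisphere volumes: gray matter, white matter, lateral ventricle.
GROSS_MEASURES: tuple[str, ...] = ("GM", "WM", "LV")

#: Measure names for cortical regions.
CORTICAL_MEASURES: tuple[str, ...] = ("thickness", "area", "volume")

#: All measure names appearing in a morphometric table.
MEASURES: tuple[str, ...] = CORTICAL_MEASURES + ("subcortical_volume", "gross_volume")

HEMISPHERES: tuple[str, ...] = ("LH", "RH")

# FreeSurfer spellings that differ from the canonical lower_snake names.
_FS_ALIASES: dict[str, str] = {
    "thalamus_proper": "thalamus",
    "accumbens_area": "accumbens",
    "ventraldc": "ventral_dc",
    "lateral_ventricle": "LV",
    "inf_lat_vent": "LV",
}


def normalize_region_name(name: str) -> str:
    """Map a region/structure label to the canonical lower_snake spelling.

    Strips FreeSurfer ``Left-``/``Right-``/``lh_``/``rh_`` prefixes, lowers the
    case, converts separators to underscores, and resolves known FreeSurfer
    aliases (``Thalamus-Proper`` -> ``thalamus``, ``Accumbens-area`` ->
    ``accumbens``, ...).
    """
    s = name.strip()
    s = re.sub(r"^(Left|Right)[-_]", "", s, flags=re.IGNORECASE)
    s = re.sub(r"^(lh|rh)[-_.]", "", s, flags=re.IGNORECASE)
    s = re.sub(r"[-\s.]+", "_", s).lower()
    return _FS_ALIASES.get(s, s)


@dataclass(frozen=True)
class RegionVocabulary:
    """The set of valid region names, by compartment.

    Invariants: exactly 34 unique cortical names, exactly 9 unique subcortical
    names, and the three gross measures GM/WM/LV.
    """

    cortical: tuple[str, ...] = DESIKAN_KILLIANY
    subcortical: tuple[str, ...] = SUBCORTICAL_DEFAULT
    gross: tuple[str, ...] = GROSS_MEASURES

    def __post_init__(self) -> None:
        if len(self.cortical) != 34 or len(set(self.cortical)) != 34:
            raise ValueError("cortical vocabulary must contain 34 unique names")
        if len(self.subcortical) != 9 or len(set(self.subcortical)) != 9:
            raise ValueError("subcortical vocabulary must contain 9 unique names")
        if set(self.gross) != set(GROSS_MEASURES):
            raise ValueError(f"gross measures must be {GROSS_MEASURES}")

    @property
    def all_regions(self) -> tuple[str, ...]:
        return self.cortical + self.subcortical + self.gross

    def compartment(self, region: str) -> str | None:
        """Return 'cortical', 'subcortical' or 'gross', or None if unknown."""
        if region in self.cortical:
            return "cortical"
        if region in self.subcortical:
            return "subcortical"
        if region in self.gross:
            return "gross"
        return None

    def valid_measures(self, region: str) -> tuple[str, ...]:
        comp = self.compartment(region)
        if comp == "cortical":
            return CORTICAL_MEASURES
        if comp == "subcortical":
            return ("subcortical_volume",)
        if comp == "gross":
            return ("gross_volume",)
        return ()
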