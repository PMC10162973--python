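"""Desikan-Killiany cortical parcellation labels.

The analysis operates on the 68 cortical parcels of the Desikan-Killiany
atlas (34 per hemisphere).  ROI identifiers follow the FreeSurfer naming
convention ``<parcel>-lh`` / ``<parcel>-rh``.
"""

from __future__ import annotations

_DK_PARCELS = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
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
    "temporalpole",
    "transversetemporal",
)

#: The 68 ROI labels, left hemisphere first, each hemisphere alphabetical.
DK_ROI_NAMES: tuple[str, ...] = tuple(
    f"{parcel}-{hemi}" for hemi in ("lh", "rh") for parcel in _DK_PARCELS
)

N_ROIS: int = len(DK_ROI_NAMES)  # 68

_INDEX = {name: i for i, name in enumerate(DK_ROI_NAMES)}


def roi_index(name: str) -> int:
    """Return the row index of an ROI label, raising ``KeyError`` with a hint."""
    try:
        return _INDEX[name]
    except KeyError:
        raise KeyError(
            f"unknown ROI {name!r}; expected one of the 68 Desikan-Killiany "
            "labels such as 'lateraloccipital-rh'"
        ) from None


def roi_indices(names) -> list[int]:
    return [roi_index(n) for n in names]
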