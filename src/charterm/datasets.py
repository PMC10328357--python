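"""Published fragment counts for the Pit 16 charcoal assemblage (Perdigoes).

The printed count table is an input of the quantification stage: 754
charcoal fragments from the two stratigraphic units holding the cremated
remains (SU72 and SU74), identified to 8 taxon labels, plus the recorded
anatomical-feature counts and size-class observations.
"""

from __future__ import annotations

import pandas as pd

from .anthraco import TaxonCountTable

__all__ = ["pit16_counts"]

_COUNTS = {
    #                 SU72  SU74
    "Olea europaea":   (33, 215),
    "Quercus spp.":    (66, 162),
    "Pinus pinaster":  (99, 57),
    "Fraxinus cf. angustifolia": (0, 10),
    "Cistus sp.":      (8, 33),
    "Fabaceae":        (2, 14),
    "Arbutus unedo":   (0, 7),
    "Angiosperm":      (0, 48),
}

# fragments of the taxon showing the feature (out of its total count)
_FEATURES = {
    ("Quercus spp.", "vitrification"): 85,
    ("Pinus pinaster", "radial cracks"): 90,
    ("Pinus pinaster", "radial groves"): 27,
}

# recorded size-class counts (largest classes only; the table is partial)
_SIZE_CLASSES = {
    "Olea europaea": {"1-1.99 cm": 71, "2-2.99 cm": 9},
}


def pit16_counts() -> TaxonCountTable:
    """The Pit 16 taxon x SU fragment-count table with feature records."""
    counts = pd.DataFrame.from_dict(_COUNTS, orient="index", columns=["SU72", "SU74"])
    sizes = pd.DataFrame.from_dict(_SIZE_CLASSES, orient="index").fillna(0).astype(int)
    return TaxonCountTable(
        counts,
        indeterminate_labels={"Angiosperm"},
        size_classes=sizes,
        feature_counts=dict(_FEATURES),
    )
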