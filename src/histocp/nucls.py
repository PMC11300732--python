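"""Class inventory of the NuCLS breast-cancer nucleus datasets.

The published census of the Corrected Single-Rater Dataset (CSRD, the
training/validation pool) and the Inferred P-truth Evaluation Multi-Rater
Dataset (IPEMRD, the test set), plus the two class-grouping configurations
used for evaluation:

* configuration 1 collapses every label into a single ``nuclei`` class
  (detection only);
* configuration 2 merges the five rarest morphologies into ``other_nuclei``
  and the two uncertain labels into ``ambiguous``, keeping the six
  well-populated classes as they are.
"""

from __future__ import annotations

from .formats import ClassMap

#: The 13 NuCLS labels in descending CSRD frequency.
LABELS: tuple[str, ...] = (
    "tumor",
    "lymphocyte",
    "fibroblast",
    "unlabeled",
    "plasma_cell",
    "macrophage",
    "vascular_endothelium",
    "ductal_epithelium",
    "apoptotic_body",
    "mitotic_figure",
    "myoepithelium",
    "neutrophil",
    "eosinophil",
)

#: Published per-class instance counts.
CSRD_COUNTS: dict[str, int] = {
    "tumor": 21088,
    "lymphocyte": 13575,
    "fibroblast": 8639,
    "unlabeled": 7518,
    "plasma_cell": 5557,
    "macrophage": 1353,
    "vascular_endothelium": 514,
    "ductal_epithelium": 498,
    "apoptotic_body": 391,
    "mitotic_figure": 229,
    "myoepithelium": 55,
    "neutrophil": 45,
    "eosinophil": 3,
}

IPEMRD_COUNTS: dict[str, int] = {
    "tumor": 510,
    "lymphocyte": 207,
    "fibroblast": 230,
    "unlabeled": 150,
    "plasma_cell": 161,
    "macrophage": 42,
    "vascular_endothelium": 48,
    "ductal_epithelium": 0,
    "apoptotic_body": 13,
    "mitotic_figure": 5,
    "myoepithelium": 0,
    "neutrophil": 6,
    "eosinophil": 0,
}

#: Configuration 1: detection only, one merged class.
CONFIG1_GROUPING: dict[str, str] = {label: "nuclei" for label in LABELS}

#: Configuration 2: minority-class merging. "Normal epithelium" is the
#: dataset's ductal_epithelium label (the only epithelium class present).
CONFIG2_GROUPING: dict[str, str] = {
    "tumor": "tumor",
    "lymphocyte": "lymphocyte",
    "fibroblast": "fibroblast",
    "plasma_cell": "plasma_cell",
    "macrophage": "macrophage",
    "vascular_endothelium": "vascular_endothelium",
    "mitotic_figure": "other_nuclei",
    "myoepithelium": "other_nuclei",
    "neutrophil": "other_nuclei",
    "ductal_epithelium": "other_nuclei",
    "eosinophil": "other_nuclei",
    "apoptotic_body": "ambiguous",
    "unlabeled": "ambiguous",
}

GROUPINGS: dict[str, dict[str, str]] = {
    "config1": CONFIG1_GROUPING,
    "config2": CONFIG2_GROUPING,
}


def default_class_map() -> ClassMap:
    """Label <-> intensity <-> category-id map over the 13 NuCLS labels.

    Red-channel intensities in real NuCLS masks are dataset-defined; this
    default assigns 1..13 in inventory order and is what the synthetic
    fixtures use.
    """
    return ClassMap.from_labels(LABELS)
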