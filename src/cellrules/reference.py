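"""Published per-class cell counts of the metastatic lung adenocarcinoma
single-cell atlas (GSE131907) after the >100-cell class-size filter.

32 tissue x cell-type classes across six tissues (mBrain, mLN, nLN, nLung,
PE, tLung); 180,035 cells in total. Used for offline bookkeeping checks and
as realistic size templates for the synthetic generator.
"""

from cellrules.datamodel import ClassSizeTable

LUNG_ATLAS_CLASS_SIZES: dict[str, int] = {
    "mBrain B lymphocytes": 1311,
    "mBrain Endothelial cells": 159,
    "mBrain Epithelial cells": 15463,
    "mBrain Fibroblasts": 444,
    "mBrain MAST cells": 508,
    "mBrain Myeloid cells": 5657,
    "mBrain T/NK cells": 2683,
    "mLN B lymphocytes": 6062,
    "mLN Epithelial cells": 3053,
    "mLN Myeloid cells": 5442,
    "mLN T/NK cells": 5069,
    "nLN B lymphocytes": 10584,
    "nLN Myeloid cells": 1288,
    "nLN T/NK cells": 19478,
    "nLung B lymphocytes": 634,
    "nLung Endothelial cells": 1295,
    "nLung Epithelial cells": 3703,
    "nLung Fibroblasts": 1585,
    "nLung MAST cells": 1079,
    "nLung Myeloid cells": 16672,
    "nLung T/NK cells": 11413,
    "PE B lymphocytes": 3285,
    "PE Epithelial cells": 396,
    "PE Myeloid cells": 3063,
    "PE T/NK cells": 9192,
    "tLung B lymphocytes": 5781,
    "tLung Endothelial cells": 645,
    "tLung Epithelial cells": 13852,
    "tLung Fibroblasts": 1739,
    "tLung MAST cells": 1809,
    "tLung Myeloid cells": 10123,
    "tLung T/NK cells": 16568,
}


def lung_atlas_size_table() -> ClassSizeTable:
    """The published 32-class size table as a ClassSizeTable."""
    return ClassSizeTable(dict(LUNG_ATLAS_CLASS_SIZES))
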