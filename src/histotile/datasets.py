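"""Published data-setting tables of the two public colorectal tile datasets.

These are the per-class train/validation/test counts as published for the
Kather texture 2016 collection (8 classes, 5,000 tiles of 150x150 px;
Zenodo record 53169) and for NCT-CRC-HE-100K (9 classes, 100,000 tiles of
224x224 px; Zenodo record 1214456) under the 60-20-20 stratified hold-out.
They are bookkeeping inputs (e.g. for checking split arithmetic), not
anything this package computes.  Note that a few published NCT rows are
internally inconsistent with their own totals; the counts are kept exactly
as printed.
"""

from __future__ import annotations

KATHER_2016_CLASSES = (
    "TUMOR", "STROMA", "COMPLEX", "LYMPHO", "DEBRIS", "MUCOSA", "ADIPOSE", "BACK",
)

#: per class: (train, validation, test)
KATHER_2016_SPLITS = {name: (375, 125, 125) for name in KATHER_2016_CLASSES}

NCT_CRC_HE_100K_SPLITS = {
    "TUM": (8591, 2863, 2863),
    "STR": (6268, 2089, 2089),
    "NORM": (5258, 1753, 1753),
    "MUS": (8122, 2707, 2707),
    "MUC": (5338, 1779, 1752),
    "LYM": (6935, 2311, 2311),
    "DEB": (6908, 2302, 2302),
    "BACK": (6340, 2113, 2113),
    "ADI": (6245, 2081, 2081),
}


def split_table_totals(table: dict[str, tuple[int, int, int]]) -> dict[str, int]:
    """Column sums and the grand sum of a per-class split table."""
    train = sum(v[0] for v in table.values())
    val = sum(v[1] for v in table.values())
    test = sum(v[2] for v in table.values())
    return {"train": train, "val": val, "test": test,
            "overall": train + val + test}
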