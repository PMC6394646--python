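"""Published worked example of three-source fusion, bundled for verification.

One fully worked end-to-end computation accompanies the fusion method this
package implements: three Bayesian belief rows over the 15-activity frame —
one each from the wearer's knowledge table, the image-tag classifier, and the
sensor classifier — and the resulting three-source PCR6 combination, all
printed to four decimal places.  The rows are reproduced here verbatim so the
implementation can be checked against a known answer (`adlfuse fuse
reproduce-table6` and the acceptance script both replay it).

Because the published rows are rounded to 4 decimals they sum to ≈1 ± 2e-4
and must be renormalized before combination; after renormalization the fused
row agrees with the published one to a few parts in 1e-5 per cell.

A second fragment covers knowledge-row normalization: the printed integer
scores of one time-period row (nine of its fifteen cells are printed, the
rest elided in the source table) and the corresponding printed belief values,
which equal score/41 for an implied row total of 41.
"""

from __future__ import annotations

import numpy as np

from adlfuse.dsmt import BBA
from adlfuse.frame import DEFAULT_FRAME

# Frame order: CN CU ET EM LD MT RD SP TK TU TP WO WU TV WT
KNOWLEDGE_ROW = (0.1860, 0.0233, 0.2326, 0.1163, 0.0, 0.0, 0.0233, 0.0,
                 0.1163, 0.1860, 0.0, 0.0698, 0.0233, 0.0233, 0.0)
IMAGE_ROW = (0.0401, 0.0260, 0.0, 0.4452, 0.0, 0.1526, 0.0610, 0.0,
             0.0939, 0.1505, 0.0, 0.0, 0.0, 0.0, 0.0308)
SENSOR_ROW = (0.0041, 0.0303, 0.0078, 0.0558, 0.0338, 0.0076, 0.0077, 0.0229,
              0.1781, 0.0264, 0.0101, 0.0174, 0.0178, 0.5602, 0.0200)
FUSED_ROW = (0.0565, 0.0057, 0.0754, 0.2561, 0.0031, 0.0427, 0.0103, 0.0015,
             0.1017, 0.0960, 0.0003, 0.0106, 0.0022, 0.3341, 0.0037)
FUSED_ARGMAX = "TV"  # watching TV

#: Printed integer scores of the worked knowledge row ("21:01-22:00"); the six
#: elided cells (SP, TK, TU, TP, WO, WU) are None.
KNOWLEDGE_SCORES_PARTIAL: dict[str, int | None] = {
    "CN": 2, "CU": 10, "ET": 1, "EM": 0, "LD": 0, "MT": 0, "RD": 3,
    "SP": None, "TK": None, "TU": None, "TP": None, "WO": None, "WU": None,
    "TV": 9, "WT": 2,
}
#: Row total implied by the printed belief values (0.2439 = 10/41 etc.).
KNOWLEDGE_ROW_TOTAL = 41
#: Printed belief values for the printed cells of the same row.
KNOWLEDGE_BBA_PARTIAL: dict[str, float] = {
    "CN": 0.0488, "CU": 0.2439, "ET": 0.0244, "EM": 0.0, "LD": 0.0,
    "MT": 0.0, "RD": 0.0732, "TV": 0.2195, "WT": 0.0488,
}


def source_bbas() -> tuple[BBA, BBA, BBA]:
    """The three worked-example source rows as renormalized BBAs
    (knowledge, image, sensors)."""
    frame = DEFAULT_FRAME
    rows = (KNOWLEDGE_ROW, IMAGE_ROW, SENSOR_ROW)
    return tuple(
        BBA.from_masses(
            frame, dict(zip(frame.labels, row)), normalize=True
        )
        for row in rows
    )


def fused_reference() -> np.ndarray:
    """The published fused row as a vector in frame order."""
    return np.asarray(FUSED_ROW)
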