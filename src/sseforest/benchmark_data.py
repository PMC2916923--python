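"""Published benchmark confusion matrices for the SCOP inter-version
evaluation strategies (training on release 1.69, testing on pairs unique to
1.73), used as regression inputs for the metric pipeline.

Strategy 1 trains on all 6,929 pairs of the 1.69 set and tests on the 6,606
pairs unique to 1.73 (five classes, NA included); strategy 2 removes
NA-pairs from both sides (4,071 training / 4,114 test pairs, four classes).
Rows are actual labels, columns predicted, in CL/FO/SF/FA/NA order.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix

STRATEGY1_CLASSES: tuple[str, ...] = ("CL", "FO", "SF", "FA", "NA")
STRATEGY2_CLASSES: tuple[str, ...] = ("CL", "FO", "SF", "FA")

STRATEGY1_CONFUSION = ConfusionMatrix(
    STRATEGY1_CLASSES,
    np.array(
        [
            [2813, 10, 0, 12, 511],
            [92, 125, 1, 30, 30],
            [21, 2, 56, 23, 0],
            [30, 5, 13, 336, 4],
            [216, 3, 0, 9, 2264],
        ]
    ),
)

STRATEGY2_CONFUSION = ConfusionMatrix(
    STRATEGY2_CLASSES,
    np.array(
        [
            [3327, 4, 1, 14],
            [134, 115, 6, 23],
            [21, 1, 56, 24],
            [44, 3, 12, 329],
        ]
    ),
)

#: Published training (test) set sizes of the four strategies.
STRATEGY_SET_SIZES = {
    1: (6929, 6606),
    2: (4071, 4114),
    3: (4071, 2858),
    4: (4071, 4653),
}
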