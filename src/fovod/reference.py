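"""Reference benchmark numbers for this detector family on PASCAL VOC 2007.

Per-class percent-AP values reported for the full-scale sliding-window
baseline (SW) and the foveated detector with a center-start
maximum-a-posteriori saccade strategy (MAP-C) after 1, 3 and 5 fixations,
together with their relative computational cost (SW normalized to 100).
These are inputs for report arithmetic and regression checks; desk-scale
synthetic experiments do not reproduce them.
"""

from __future__ import annotations

import numpy as np

from .evaluation import mean_ap

VOC2007_CLASSES = (
    "aeroplane", "bike", "bird", "boat", "bottle", "bus", "car", "cat",
    "chair", "cow", "dining-table", "dog", "horse", "motorbike", "person",
    "potted-plant", "sheep", "sofa", "train", "tv-monitor",
)

# per-class percent AP on the VOC 2007 test set
SW_AP = np.array([
    17.5, 28.6, 9.7, 10.4, 17.3, 29.8, 36.7, 7.9, 11.2, 21.0,
    2.3, 2.7, 30.9, 21.1, 19.7, 3.0, 9.2, 13.7, 23.5, 25.2,
])

MAP_C_AP = {
    1: np.array([17.0, 21.1, 4.9, 9.8, 9.3, 27.4, 27.9, 8.5, 3.7, 12.8,
                 2.0, 4.3, 29.7, 19.7, 18.2, 1.2, 10.7, 14.0, 26.2, 21.8]),
    3: np.array([17.4, 27.7, 10.1, 10.6, 10.4, 30.8, 31.6, 8.4, 10.4, 17.2,
                 2.1, 3.4, 33.3, 21.1, 18.7, 3.4, 7.6, 15.4, 26.4, 23.5]),
    5: np.array([17.0, 28.6, 10.0, 10.7, 11.2, 31.0, 34.0, 8.3, 10.6, 18.2,
                 2.1, 3.4, 34.2, 21.8, 19.7, 2.8, 8.1, 15.1, 27.8, 24.0]),
}

# relative computational cost, sliding window normalized to 100
RELATIVE_COST = {"SW": 100.0, ("MAP-C", 1): 11.5, ("MAP-C", 3): 31.2,
                 ("MAP-C", 5): 49.6}


def sw_mean_ap() -> float:
    """Mean AP of the sliding-window baseline over the 20 classes."""
    return mean_ap(SW_AP)


def map_c_mean_ap(n_fixations: int) -> float:
    return mean_ap(MAP_C_AP[n_fixations])


def relative_performance(n_fixations: int) -> float:
    """MAP-C mean AP as a percentage of the SW baseline's mean AP.

    Follows the report convention: the ratio is taken between the
    tabulated mean APs, which are printed at one-decimal precision.
    """
    return 100.0 * round(map_c_mean_ap(n_fixations), 1) / round(sw_mean_ap(), 1)


def sw_gap(n_fixations: int = 5) -> float:
    """Mean-AP gap between the SW baseline and MAP-C at ``n_fixations``,
    at the one-decimal precision of the tabulated mean APs."""
    return round(sw_mean_ap(), 1) - round(map_c_mean_ap(n_fixations), 1)
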