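"""Bundled reference measurements.

Published benchmark measurements of six individually labeled mouse
thalamocortical neurons (axonal classes 1–3), each quantified by three methods
on the same serial 50 µm sections: direct 3D reconstruction (the reference),
camera-lucida projection with per-class correction factor, and virtual-plane
stereology (step 75 µm, plane spacing 5 µm, sampling box 50×50×10 µm³).  All
lengths in µm.  These rows drive the expected-error arithmetic comparing the
practical performance of the two estimation methods.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["practical_measurements"]

_ROWS = [
    # class, direct, projection_estimate, sections/intersections, ce, planes_estimate
    (1, 28162.0, 35980.0, "26/834", 0.036, 28770.0),
    (1, 27855.0, 22842.0, "13/304", 0.066, 24663.0),
    (2, 60388.0, 53301.0, "31/593", 0.043, 66712.0),
    (2, 58049.0, 57755.0, "7/244", 0.067, 54900.0),
    (2, 78062.0, 68526.0, "10/398", 0.053, 71640.0),
    (3, 44393.0, 44684.0, "24/525", 0.048, 41211.0),
]


def practical_measurements() -> pd.DataFrame:
    """Six-neuron laboratory comparison table (lengths in µm).

    Columns: ``class_label``, ``direct_um`` (Neurolucida 3D reconstruction),
    ``projection_um`` (camera-lucida 2D length × class alpha),
    ``sections_intersections`` (stereology sampling effort), ``ce``
    (coefficient of error of the stereological estimate) and ``planes_um``
    (virtual-plane fractionator estimate).
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "class_label",
            "direct_um",
            "projection_um",
            "sections_intersections",
            "ce",
            "planes_um",
        ],
    )
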