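"""Bundled reference measurements.

``load_hela_cohort`` returns the published surface-modelling measurements of
seven HeLa cell nuclei imaged by serial block-face SEM (source volumes at
EMPIAR, accession EMPIAR-10094): nuclear volume, Jaccard index against the
equal-volume spheroid, and the mean, standard deviation and range of the
ray-traced surface map, one row per cell.  The table is used to study how
the spheroid Jaccard index co-varies with surface roughness across cells.
"""

from __future__ import annotations

import pandas as pd

_HELA_COHORT = {
    "volume_um3": [393.0, 442.0, 454.0, 487.0, 502.0, 580.0, 600.0],
    "ji_spheroid": [0.5538, 0.6610, 0.6989, 0.7084, 0.6643, 0.5991, 0.5801],
    "mean_mu": [-23.424, -17.018, -11.013, -16.467, -27.290, -27.882, -29.894],
    "std_sigma": [142.47, 105.11, 96.968, 98.528, 116.11, 135.57, 163.80],
    "range_": [681.0, 517.0, 553.0, 577.0, 544.0, 703.0, 894.0],
    "pixel_ratio_above": [0.16, 0.13, 0.12, 0.15, 0.13, 0.19, 0.17],
    "pixel_ratio_below": [0.19, 0.18, 0.17, 0.15, 0.19, 0.18, 0.15],
}


def load_hela_cohort() -> pd.DataFrame:
    """Surface-modelling metrics of the seven reference HeLa nuclei."""
    return pd.DataFrame(_HELA_COHORT)
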