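"""Bundled reference values from a published eight-parent white maize
half-diallel evaluated under three plant densities at two locations.

These small printed tables serve as worked examples and regression
fixtures: per-locus SSR allele counts consistent with the published
major-allele frequencies and gene diversities, the pairwise genetic
distance matrix of the eight inbred lines, the GCA/SCA mean squares of the
combined analysis, and the per-density trait means.
"""

from __future__ import annotations

import numpy as np

from .ssr import DistanceMatrix

__all__ = [
    "REFERENCE_LINES",
    "REFERENCE_LOCUS_ALLELE_COUNTS",
    "REFERENCE_COMBINING_MEAN_SQUARES",
    "REFERENCE_GCA_SCA_RATIOS",
    "REFERENCE_DENSITY_MEANS",
    "reference_distance_matrix",
]

REFERENCE_LINES = ("L1", "L2", "L3", "L4", "L5", "L6", "L7", "L8")

#: Allele counts over the 8 inbred lines per SSR locus. Counts were
#: reconstructed so that both the printed major-allele frequency and the
#: printed gene diversity are reproduced exactly (e.g. the three-allele
#: loci with major count 4/8 must split (4, 3, 1), since (4, 2, 2) gives
#: gene diversity 0.625 rather than the printed 0.59).
REFERENCE_LOCUS_ALLELE_COUNTS: dict[str, tuple[int, ...]] = {
    "phi308707": (5, 3),
    "phi96100": (7, 1),
    "phi453121": (4, 4),
    "phi072": (6, 2),
    "phi024": (4, 4),
    "umc1014": (4, 3, 1),
    "phi112": (4, 3, 1),
    "phi015": (4, 3, 1),
    "umc1033": (2, 2, 1, 1, 1, 1),
    "phi301654": (7, 1),
}

#: (MS_GCA, MS_SCA) per trait from the combined split-plot analysis.
REFERENCE_COMBINING_MEAN_SQUARES: dict[str, tuple[float, float]] = {
    "DTS": (57.16, 17.85),
    "ASI": (12.03, 6.44),
    "PLHT": (11397.27, 5247.69),
    "EHT": (2447.44, 1920.08),
    "LANG": (836.14, 282.20),
    "CHLC": (162.00, 104.38),
    "ED": (1.07, 0.99),
    "NRPE": (16.50, 6.04),
    "NKPR": (41.59, 62.24),
    "TKW": (12835.71, 10282.17),
    "GYPP": (13527.67, 8686.11),
    "GYPH": (67.17, 42.93),
}

#: Printed MS_GCA / MS_SCA ratios (2 decimals).
REFERENCE_GCA_SCA_RATIOS: dict[str, float] = {
    "DTS": 3.20, "ASI": 1.87, "PLHT": 2.17, "EHT": 1.27,
    "LANG": 2.96, "CHLC": 1.55, "ED": 1.08, "NRPE": 2.73,
    "NKPR": 0.67, "TKW": 1.25, "GYPP": 1.56, "GYPH": 1.57,
}

#: Trait means over all crosses/locations/reps per density level.
REFERENCE_DENSITY_MEANS: dict[str, dict[str, float]] = {
    "DTS": {"D1": 58.22, "D2": 61.19, "D3": 64.80},
    "ASI": {"D1": 3.26, "D2": 3.68, "D3": 4.56},
    "PLHT": {"D1": 240.12, "D2": 249.20, "D3": 263.52},
    "EHT": {"D1": 117.86, "D2": 125.68, "D3": 133.02},
    "LANG": {"D1": 34.03, "D2": 32.00, "D3": 30.21},
    "CHLC": {"D1": 50.34, "D2": 47.59, "D3": 44.23},
    "ED": {"D1": 5.16, "D2": 4.76, "D3": 4.44},
    "NRPE": {"D1": 14.83, "D2": 13.91, "D3": 13.37},
    "NKPR": {"D1": 40.28, "D2": 37.31, "D3": 33.12},
    "TKW": {"D1": 356.00, "D2": 333.24, "D3": 309.26},
    "GYPP": {"D1": 170.11, "D2": 153.78, "D3": 135.09},
    "GYPH": {"D1": 10.12, "D2": 10.98, "D3": 11.26},
}

_GD_UPPER = [
    # L1    L2    L3    L4    L5    L6    L7    L8
    [0.00, 0.43, 0.53, 0.31, 0.71, 0.71, 0.71, 0.78],  # L1
    [0.00, 0.00, 0.43, 0.53, 0.78, 0.78, 0.71, 0.78],  # L2
    [0.00, 0.00, 0.00, 0.43, 0.63, 0.63, 0.63, 0.71],  # L3
    [0.00, 0.00, 0.00, 0.00, 0.63, 0.71, 0.63, 0.71],  # L4
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.63, 0.43, 0.71],  # L5
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.43, 0.63],  # L6
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.53],  # L7
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],  # L8
]


def reference_distance_matrix() -> DistanceMatrix:
    """Published pairwise SSR genetic distances among the eight lines."""
    u = np.array(_GD_UPPER)
    return DistanceMatrix(REFERENCE_LINES, u + u.T)
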