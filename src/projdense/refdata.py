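"""Bundled reference dataset: per-animal counts and densitometry from the
mouse mPFC→NAc / mPFC→VTA tracing study this package models.

These are transcribed published per-animal measurements (cell counts by
subregion/layer/Bregma bin, marker co-labeling counts, double-tracer
counts, and per-stack axon length / volume / density values), not synthetic
data. They power the ``reproduce`` command and the reproduction test suite:
every summary statistic the study reports can be recomputed from them.

Known quirks of the source tables, consumed here as-is:

* the per-animal density columns are not equal to the printed length
  divided by the printed same-region volume (the printed volumes appear
  transposed between the two regions, and all values are rounded) — the
  densities are therefore taken as the authoritative per-animal values;
* the double-tracing "total" column differs slightly from the sum of its
  component counts; both are kept, and the total-based ratio uses the
  printed totals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .image_io import validate_cell_table

ANIMALS = ("A1", "A2", "A3")

#: Per-animal cell counts by mPFC subregion for each tracer population.
SUBREGION_COUNTS = {
    "nac": {
        "Cg2": (0, 0, 0),
        "Cg1": (2, 26, 4),
        "PrL": (49, 194, 54),
        "IL": (10, 35, 14),
        "MO": (135, 404, 82),
        "DP": (2, 16, 0),
        "DTT": (0, 15, 0),
    },
    "vta": {
        "Cg2": (26, 16, 22),
        "Cg1": (53, 42, 73),
        "PrL": (95, 257, 153),
        "IL": (20, 67, 88),
        "MO": (71, 128, 199),
        "DP": (68, 111, 130),
        "DTT": (64, 86, 109),
    },
}

#: Per-animal cell counts by cortical layer.
LAYER_COUNTS = {
    "nac": {
        "L1": (1, 4, 1),
        "L2/3": (71, 221, 32),
        "L5a": (92, 360, 119),
        "L5b": (25, 83, 1),
        "L6": (9, 22, 1),
    },
    "vta": {
        "L1": (1, 0, 0),
        "L2/3": (30, 9, 9),
        "L5a": (10, 7, 5),
        "L5b": (194, 434, 466),
        "L6": (162, 257, 294),
    },
}

#: Pooled (all-animal) counts per anteroposterior Bregma bin, rostral to
#: caudal; per-animal Bregma assignments were not published.
AP_POOLED_COUNTS = {
    "nac": (7, 271, 513, 238, 13, 0),
    "vta": (23, 221, 530, 864, 115, 125),
}

#: Representative Bregma level (mm) used when materializing each bin.
AP_BIN_REPRESENTATIVE = (3.00, 2.50, 2.20, 1.80, 1.50, 1.30)

#: Marker co-labeling counts: population -> marker -> layer-group label ->
#: (per-animal tracer+ tested denominators, per-animal marker+ numerators).
#: Group labels match DEFAULT_LAYER_GROUPS in cell_stats.
COLABEL_COUNTS = {
    "nac": {
        "calb1": {
            "L2/3": ((128, 101, 60), (84, 71, 42)),
            "L5a-5b-6": ((287, 200, 168), (7, 4, 7)),
        },
        "ctip2": {
            "L2/3-5a": ((62, 356, 349), (9, 9, 27)),
            "L5b-6": ((37, 29, 138), (22, 20, 88)),
        },
        "foxp2": {
            "L2/3-5a-5b": ((288, 357, 173), (5, 10, 0)),
            "L6": ((20, 24, 0), (4, 3, 0)),
        },
    },
    "vta": {
        "calb1": {
            "L2/3": ((4, 2, 5), (4, 2, 2)),
            "L5a-5b-6": ((371, 452, 331), (3, 2, 2)),
        },
        "ctip2": {
            "L2/3-5a": ((1, 2, 1), (1, 0, 0)),
            "L5b-6": ((152, 163, 187), (144, 158, 178)),
        },
        "foxp2": {
            "L2/3-5a-5b": ((162, 347, 411), (17, 22, 38)),
            "L6": ((393, 283, 275), (347, 219, 195)),
        },
    },
}

#: Representative layer used when materializing each co-labeling group.
COLABEL_GROUP_LAYER = {
    "L2/3": "L2/3",
    "L5a-5b-6": "L5a",
    "L2/3-5a": "L2/3",
    "L5b-6": "L5b",
    "L2/3-5a-5b": "L5a",
    "L6": "L6",
}

#: Double retrograde tracing, per animal. The *_incl counts include
#: double-labeled cells; ``total_printed`` is the independently tallied
#: total column of the source table.
OVERLAP_COUNTS = {
    "nac_incl": (269, 2995, 2621),
    "vta_incl": (111, 544, 840),
    "double": (0, 55, 70),
    "total_printed": (380, 3374, 3251),
}

#: Axon densitometry per animal: (NAc value, VTA value) triplets per group.
RAD_TABLE = {
    "mPFC_NAc": {
        "axon_length_mm": [(907.58, 30.80), (1385.42, 24.23), (401.99, 9.70)],
        "volume_mm3": [(0.0068, 0.018), (0.0060, 0.020), (0.0028, 0.019)],
        "density_mm_per_mm3": [
            (49215.43, 4539.63),
            (69073.73, 4042.84),
            (20991.09, 3519.42),
        ],
        "relative_density_printed": (0.092, 0.059, 0.17),
    },
    "mPFC_VTA": {
        "axon_length_mm": [(130.72, 196.69), (129.94, 161.77), (46.42, 63.91)],
        "volume_mm3": [(0.0067, 0.017), (0.0061, 0.016), (0.0064, 0.014)],
        "density_mm_per_mm3": [
            (7578.49, 29542.50),
            (7954.40, 26648.57),
            (3206.06, 9953.67),
        ],
        "relative_density_printed": (3.90, 3.35, 3.10),
    },
    "mPFC_Rbp4": {
        "axon_length_mm": [(597.27, 299.93), (617.26, 353.48), (1323.86, 99.42)],
        "volume_mm3": [(0.0069, 0.019), (0.0059, 0.0089), (0.0032, 0.016)],
        "density_mm_per_mm3": [
            (31674.39, 43542.44),
            (69696.59, 60044.90),
            (80501.53, 31307.55),
        ],
        "relative_density_printed": (1.37, 0.86, 0.39),
    },
    "mPFC_Thy1": {
        "axon_length_mm": [(1708.58, 517.52), (2719.73, 459.37), (2807.45, 398.95)],
        "volume_mm3": [(0.0058, 0.016), (0.0068, 0.016), (0.0057, 0.013)],
        "density_mm_per_mm3": [
            (104685.07, 88715.34),
            (166781.92, 67511.08),
            (210241.59, 69900.41),
        ],
        "relative_density_printed": (0.85, 0.40, 0.33),
    },
}

RAD_GROUPS = tuple(RAD_TABLE)


def _allocate_pooled(pooled: tuple[int, ...], animal_totals: tuple[int, ...]) -> list[list[int]]:
    """Greedy north-west-corner allocation of pooled bin counts to animals.

    Produces any per-animal x bin matrix with the given row (animal) and
    column (bin) marginals; only the marginals are meaningful downstream.
    """
    remaining = list(animal_totals)
    alloc = [[0] * len(pooled) for _ in animal_totals]
    for b, count in enumerate(pooled):
        left = count
        for a in range(len(animal_totals)):
            take = min(left, remaining[a])
            alloc[a][b] = take
            remaining[a] -= take
            left -= take
        if left:
            raise ValueError("pooled counts exceed animal totals")
    if any(remaining):
        raise ValueError("animal totals exceed pooled counts")
    return alloc


def distribution_cell_table(population: str) -> pd.DataFrame:
    """Materialize a cell table matching the published per-animal subregion
    and layer marginals and the pooled Bregma-bin marginals.

    The joint assignment (which subregion pairs with which layer within an
    animal) was not published; rows pair the expanded attribute lists in a
    fixed order, which preserves every published marginal exactly.
    """
    subs = SUBREGION_COUNTS[population]
    lays = LAYER_COUNTS[population]
    totals = tuple(sum(v[a] for v in subs.values()) for a in range(len(ANIMALS)))
    ap_alloc = _allocate_pooled(AP_POOLED_COUNTS[population], totals)
    rows = []
    for a, animal in enumerate(ANIMALS):
        sub_list = [s for s, counts in subs.items() for _ in range(counts[a])]
        lay_list = [l for l, counts in lays.items() for _ in range(counts[a])]
        breg_list = [
            AP_BIN_REPRESENTATIVE[b]
            for b in range(len(AP_BIN_REPRESENTATIVE))
            for _ in range(ap_alloc[a][b])
        ]
        if not len(sub_list) == len(lay_list) == len(breg_list):
            raise AssertionError("inconsistent reference marginals")
        for sub, lay, breg in zip(sub_list, lay_list, breg_list):
            rows.append(
                {
                    "animal": animal,
                    "bregma_mm": breg,
                    "subregion": sub,
                    "layer": lay,
                    "tracer_nac": int(population == "nac"),
                    "tracer_vta": int(population == "vta"),
                    "calb1": pd.NA,
                    "ctip2": pd.NA,
                    "foxp2": pd.NA,
                }
            )
    return validate_cell_table(pd.DataFrame(rows))


def colabel_cell_table(population: str, marker: str) -> pd.DataFrame:
    """Materialize the marker co-labeling cohort for one population/marker."""
    rows = []
    for group, (dens, nums) in COLABEL_COUNTS[population][marker].items():
        layer = COLABEL_GROUP_LAYER[group]
        for animal, den, num in zip(ANIMALS, dens, nums):
            for i in range(den):
                row = {
                    "animal": animal,
                    "bregma_mm": 2.0,
                    "subregion": "PrL",
                    "layer": layer,
                    "tracer_nac": int(population == "nac"),
                    "tracer_vta": int(population == "vta"),
                    "calb1": pd.NA,
                    "ctip2": pd.NA,
                    "foxp2": pd.NA,
                }
                row[marker] = int(i < num)
                rows.append(row)
    return validate_cell_table(pd.DataFrame(rows))


def overlap_cell_table() -> pd.DataFrame:
    """Materialize the double-retrograde cohort (singles derived from the
    tracer-inclusive counts minus the double-labeled counts)."""
    rows = []
    nac_incl = OVERLAP_COUNTS["nac_incl"]
    vta_incl = OVERLAP_COUNTS["vta_incl"]
    dbl = OVERLAP_COUNTS["double"]
    for a, animal in enumerate(ANIMALS):
        specs = [
            (nac_incl[a] - dbl[a], 1, 0),
            (vta_incl[a] - dbl[a], 0, 1),
            (dbl[a], 1, 1),
        ]
        for count, t_nac, t_vta in specs:
            for _ in range(count):
                rows.append(
                    {
                        "animal": animal,
                        "bregma_mm": 2.0,
                        "subregion": "PrL",
                        "layer": "L5a",
                        "tracer_nac": t_nac,
                        "tracer_vta": t_vta,
                        "calb1": pd.NA,
                        "ctip2": pd.NA,
                        "foxp2": pd.NA,
                    }
                )
    return validate_cell_table(pd.DataFrame(rows))


def rad_ratios_from_densities() -> dict[str, tuple[float, ...]]:
    """Per-animal RAD_VTA / RAD_NAc ratios from the per-animal densities."""
    out = {}
    for group, tab in RAD_TABLE.items():
        out[group] = tuple(
            vta / nac for nac, vta in tab["density_mm_per_mm3"]
        )
    return out


def rad_ratios_printed() -> dict[str, tuple[float, ...]]:
    """The published per-animal relative-density column."""
    return {g: tab["relative_density_printed"] for g, tab in RAD_TABLE.items()}
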