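"""Count statistics for retrogradely labeled projection neurons.

Three analyses over a cell table (one row per counted neuron):

* distributions — per-animal percentages of a tracer population across
  anteroposterior (Bregma) bins, mPFC subregions, or cortical layers,
  summarized as mean ± SD over animals;
* marker co-labeling — the per-animal proportion of tracer-labeled cells
  expressing Calb1 / Ctip2 / FoxP2 within layer groups, with a small-count
  suppression rule;
* double-tracer overlap — per-animal proportions of cells projecting to
  both targets, relative to each single-labeled population and to the total.

All summary percentages use the sample (n-1) standard deviation across
animals, matching how mean ± SD values are conventionally reported for
per-animal proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .image_io import LAYERS, MARKERS, SUBREGIONS
from .group_stats import mean_sd

#: Anteroposterior Bregma bins (label, low, high), inclusive at both printed
#: endpoints, rostral to caudal. Values are first rounded to 2 decimals
#: (the precision the bin edges are defined at).
AP_BINS = (
    (">2.80 mm", 2.81, float("inf")),
    ("2.80–2.35 mm", 2.35, 2.80),
    ("2.34–1.99 mm", 1.99, 2.34),
    ("1.98–1.71 mm", 1.71, 1.98),
    ("1.70–1.42 mm", 1.42, 1.70),
    ("<1.42 mm", -float("inf"), 1.41),
)

#: Minimum pooled co-labeled count / per-animal denominator below which a
#: co-labeling percentage is suppressed rather than reported.
SUPPRESSION_MIN_COUNT = 10

#: Default layer groupings used for co-labeling summaries, per marker: the
#: marker-rich laminae versus the rest.
DEFAULT_LAYER_GROUPS = {
    "calb1": (("L2/3", ("L2/3",)), ("L5a-5b-6", ("L5a", "L5b", "L6"))),
    "ctip2": (("L2/3-5a", ("L1", "L2/3", "L5a")), ("L5b-6", ("L5b", "L6"))),
    "foxp2": (("L2/3-5a-5b", ("L1", "L2/3", "L5a", "L5b")), ("L6", ("L6",))),
}


@dataclass(frozen=True)
class ProportionSummary:
    """Per-stratum co-labeling proportions with the suppression flag."""

    stratum: str
    animals: tuple[str, ...]
    numerators: tuple[int, ...]
    denominators: tuple[int, ...]
    pooled_numerator: int
    pooled_denominator: int
    suppressed: bool
    per_animal_pct: tuple | None  # None entries where denominator is 0
    mean_pct: float | None
    sd_pct: float | None


@dataclass(frozen=True)
class OverlapSummary:
    """Double-retrograde overlap counts and the three ratio summaries."""

    animals: tuple[str, ...]
    nac_single: tuple[int, ...]
    vta_single: tuple[int, ...]
    double: tuple[int, ...]
    totals: tuple[int, ...]
    ratios: dict  # name -> {"per_animal_pct": [...], "mean_pct": m, "sd_pct": s}


def assign_ap_bin(bregma_mm: float) -> str:
    """Map a Bregma level (mm) to its anteroposterior bin label.

    Bin edges are printed to 2 decimals with closed endpoints; values are
    rounded to that precision first, so every finite input lands in
    exactly one bin.
    """
    if not np.isfinite(bregma_mm):
        raise ValueError("bregma must be finite")
    v = round(float(bregma_mm), 2)
    for label, lo, hi in AP_BINS:
        if lo <= v <= hi:
            return label
    # Rounded values fall between two adjacent closed bins only if they sit
    # in the 0.01-wide gaps of the printed edges; assign to the upper bin.
    for label, lo, hi in AP_BINS:
        if v >= lo:
            return label
    return AP_BINS[-1][0]


def _population_mask(cells: pd.DataFrame, population: str) -> pd.Series:
    if population not in ("nac", "vta"):
        raise ValueError(f"population must be 'nac' or 'vta', got {population!r}")
    return cells[f"tracer_{population}"] == 1


def _strata(cells: pd.DataFrame, axis: str) -> tuple[pd.Series, tuple[str, ...]]:
    if axis == "ap_bin":
        values = cells["bregma_mm"].map(assign_ap_bin)
        order = tuple(label for label, _, _ in AP_BINS)
    elif axis == "subregion":
        values = cells["subregion"]
        order = SUBREGIONS
    elif axis == "layer":
        values = cells["layer"]
        order = LAYERS
    else:
        raise ValueError(f"axis must be ap_bin, subregion or layer, got {axis!r}")
    return values, order


def distribution_table(
    cells: pd.DataFrame, population: str, axis: str
) -> pd.DataFrame:
    """Stratum-by-stratum distribution of a tracer population.

    Returns one row per stratum with per-animal counts, the pooled count,
    the pooled percentage, and the mean ± SD of per-animal percentages
    (denominator: each animal's total cell count in the population).
    Animals with zero cells in the population are dropped with a warning.
    Within each animal the stratum percentages sum to 100.
    """
    sub = cells[_population_mask(cells, population)].copy()
    if sub.empty:
        raise ValueError(f"no cells in population {population!r}")
    strata, order = _strata(sub, axis)
    sub = sub.assign(_stratum=strata.to_numpy())
    animals = sorted(sub["animal"].unique())
    totals = sub.groupby("animal").size()
    empty = [a for a in animals if totals.get(a, 0) == 0]
    if empty:
        warnings.warn(f"animals with zero cells excluded: {empty}", stacklevel=2)
        animals = [a for a in animals if a not in empty]
    counts = (
        sub.groupby(["_stratum", "animal"]).size().unstack(fill_value=0)
        .reindex(index=order, columns=animals, fill_value=0)
    )
    pct = 100.0 * counts / totals.reindex(animals)
    rows = []
    grand_total = int(totals.reindex(animals).sum())
    for stratum in order:
        per_animal = counts.loc[stratum]
        pooled = int(per_animal.sum())
        m, s = mean_sd(pct.loc[stratum].to_numpy())
        rows.append(
            {
                "stratum": stratum,
                **{f"n_{a}": int(per_animal[a]) for a in animals},
                "pooled_count": pooled,
                "pooled_pct": 100.0 * pooled / grand_total,
                "mean_pct": m,
                "sd_pct": s,
            }
        )
    return pd.DataFrame(rows)


def colabel_proportions(
    cells: pd.DataFrame,
    population: str,
    marker: str,
    layer_groups: Sequence[tuple[str, Sequence[str]]] | None = None,
    include_total: bool = True,
) -> list[ProportionSummary]:
    """Proportion of tracer-labeled cells expressing a marker, per layer group.

    Cells untested for the marker (NA) enter neither numerator nor
    denominator. A group summary is suppressed — reported without a
    percentage — when the pooled marker-positive count is below
    :data:`SUPPRESSION_MIN_COUNT` or any contributing animal's denominator
    is, since a mean of per-animal percentages over so few cells is noise.
    """
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}")
    if layer_groups is None:
        layer_groups = DEFAULT_LAYER_GROUPS[marker]
    sub = cells[_population_mask(cells, population)]
    tested = sub[sub[marker].notna()].copy()
    if tested.empty:
        raise ValueError(f"marker {marker!r} entirely untested in population {population!r}")
    tested[marker] = tested[marker].astype(int)
    animals = tuple(sorted(tested["animal"].unique()))
    groups = list(layer_groups)
    if include_total:
        groups.append(("Total", tuple(LAYERS)))
    out = []
    for label, layers in groups:
        grp = tested[tested["layer"].isin(tuple(layers))]
        dens, nums = [], []
        for a in animals:
            ga = grp[grp["animal"] == a]
            dens.append(int(len(ga)))
            nums.append(int(ga[marker].sum()))
        pooled_num, pooled_den = sum(nums), sum(dens)
        suppressed = pooled_num < SUPPRESSION_MIN_COUNT or any(
            d < SUPPRESSION_MIN_COUNT for d in dens
        )
        per_pct = tuple(
            (100.0 * n / d) if d > 0 else None for n, d in zip(nums, dens)
        )
        if suppressed or any(p is None for p in per_pct):
            mean_pct = sd_pct = None
        else:
            mean_pct, sd_pct = mean_sd([p for p in per_pct if p is not None])
        out.append(
            ProportionSummary(
                stratum=label,
                animals=animals,
                numerators=tuple(nums),
                denominators=tuple(dens),
                pooled_numerator=pooled_num,
                pooled_denominator=pooled_den,
                suppressed=suppressed,
                per_animal_pct=per_pct,
                mean_pct=mean_pct,
                sd_pct=sd_pct,
            )
        )
    return out


def overlap_from_counts(
    animals: Sequence[str],
    nac_single: Sequence[int],
    vta_single: Sequence[int],
    double: Sequence[int],
    totals: Sequence[int] | None = None,
) -> OverlapSummary:
    """Overlap ratios from per-animal counts.

    ``totals`` defaults to ``nac_single + vta_single + double``; an explicit
    value supports source tables whose printed totals were tallied
    independently of the component counts.
    """
    nac = np.asarray(nac_single, dtype=float)
    vta = np.asarray(vta_single, dtype=float)
    dbl = np.asarray(double, dtype=float)
    tot = nac + vta + dbl if totals is None else np.asarray(totals, dtype=float)
    ratios = {}
    for name, den in (
        ("double_over_vta", vta),
        ("double_over_nac", nac),
        ("double_over_total", tot),
    ):
        ok = den > 0
        if not ok.all():
            bad = [a for a, keep in zip(animals, ok) if not keep]
            if np.any(dbl[~ok] > 0):
                warnings.warn(
                    f"{name}: undefined for animals {bad} (zero denominator); excluded",
                    stacklevel=2,
                )
            elif not np.any(ok):
                warnings.warn(f"{name}: no animal with nonzero denominator", stacklevel=2)
        pcts = 100.0 * dbl[ok] / den[ok]
        m, s = mean_sd(pcts) if len(pcts) else (float("nan"), float("nan"))
        ratios[name] = {
            "per_animal_pct": [float(p) for p in pcts],
            "mean_pct": m,
            "sd_pct": s,
        }
    return OverlapSummary(
        animals=tuple(animals),
        nac_single=tuple(int(x) for x in nac),
        vta_single=tuple(int(x) for x in vta),
        double=tuple(int(x) for x in dbl),
        totals=tuple(int(x) for x in tot),
        ratios=ratios,
    )


def overlap_statistics(cells: pd.DataFrame) -> OverlapSummary:
    """Double-retrograde overlap statistics from a cell table.

    Per animal: cells carrying only the NAc tracer, only the VTA tracer, or
    both; the three ratio summaries are double/VTA-single, double/NAc-single
    and double/(singles + doubles), each x100 and summarized mean ± SD.
    """
    if not ((cells["tracer_nac"] == 1).any() and (cells["tracer_vta"] == 1).any()):
        raise ValueError("table must contain both tracer populations")
    animals = sorted(cells["animal"].unique())
    nac_s, vta_s, dbl = [], [], []
    for a in animals:
        g = cells[cells["animal"] == a]
        both = (g["tracer_nac"] == 1) & (g["tracer_vta"] == 1)
        nac_s.append(int(((g["tracer_nac"] == 1) & ~both).sum()))
        vta_s.append(int(((g["tracer_vta"] == 1) & ~both).sum()))
        dbl.append(int(both.sum()))
    return overlap_from_counts(animals, nac_s, vta_s, dbl)
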