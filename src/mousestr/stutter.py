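"""Stutter-ratio statistics: filter derivation and cross-instrument analysis.

A stutter ratio is the height of the stutter peak divided by the height of
its parent allelic peak.  Filter recommendations are the mean ratio plus
three (sample) standard deviations, computed per marker (pooling alleles) or
per allele; only minus-stutter observations from normal diploid samples feed
filter derivation, because aneuploid lines carry unrepresentative peak
balance.

The instrument comparison normalizes each ratio by the mean of its
(marker, allele) group — repeat length being the dominant source of variation
— averages normalized ratios per (marker, instrument), and applies a Friedman
rank test with markers as blocks and instruments as treatments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import Allele


class StutterStatsError(ValueError):
    pass


@dataclass(frozen=True)
class StutterObservation:
    marker: str
    parent_allele: Allele
    position: int  # -1 or +1 repeats from the parent
    ratio: float
    instrument: str = ""
    lab_id: str = ""
    run_id: str = ""
    ploidy: Literal["diploid", "aneuploid"] = "diploid"

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise StutterStatsError(f"negative stutter ratio: {self.ratio}")
        if self.position not in (-1, +1):
            raise StutterStatsError(f"position must be -1 or +1: {self.position}")


@dataclass
class StutterFilterSet:
    marker_filters: dict[str, float] = field(default_factory=dict)
    allele_filters: dict[tuple[str, Allele], float] = field(default_factory=dict)
    marker_counts: dict[str, int] = field(default_factory=dict)
    allele_counts: dict[tuple[str, Allele], int] = field(default_factory=dict)
    low_n: set = field(default_factory=set)


def stutter_ratio(stutter_height: float, parent_height: float) -> float:
    """Stutter peak height divided by parent allelic peak height."""
    if parent_height <= 0:
        raise StutterStatsError(
            f"parent peak height must be positive, got {parent_height}"
        )
    return stutter_height / parent_height


def _filter_from_ratios(ratios: np.ndarray) -> tuple[float, bool]:
    """mean + 3*sample SD; single observations return the mean, flagged."""
    if ratios.size == 0:
        raise StutterStatsError("no observations")
    if ratios.size == 1:
        return float(ratios[0]), True
    return float(ratios.mean() + 3.0 * ratios.std(ddof=1)), False


def _diploid_minus(obs: Sequence[StutterObservation]) -> list[StutterObservation]:
    return [o for o in obs if o.position == -1 and o.ploidy == "diploid"]


def marker_filter(obs: Sequence[StutterObservation]) -> float:
    """Marker-level filter: mean of all (diploid, minus-position) stutter
    ratios at the locus plus three standard deviations."""
    usable = _diploid_minus(obs)
    if not usable:
        raise StutterStatsError("no diploid minus-stutter observations")
    value, _ = _filter_from_ratios(np.array([o.ratio for o in usable]))
    return value


def allele_filter(obs: Sequence[StutterObservation]) -> float:
    """Allele-level filter: as :func:`marker_filter` but the SD is taken over
    observations of one specific allele."""
    return marker_filter(obs)


def derive_filters(obs: Sequence[StutterObservation]) -> StutterFilterSet:
    """Derive marker- and allele-specific filter recommendations."""
    usable = _diploid_minus(obs)
    fs = StutterFilterSet()
    by_marker: dict[str, list[StutterObservation]] = {}
    by_allele: dict[tuple[str, Allele], list[StutterObservation]] = {}
    for o in usable:
        by_marker.setdefault(o.marker, []).append(o)
        by_allele.setdefault((o.marker, o.parent_allele), []).append(o)
    for marker, group in by_marker.items():
        ratios = np.array([o.ratio for o in group])
        fs.marker_filters[marker], low = _filter_from_ratios(ratios)
        fs.marker_counts[marker] = len(group)
        if low:
            fs.low_n.add(marker)
    for key, group in by_allele.items():
        ratios = np.array([o.ratio for o in group])
        fs.allele_filters[key], low = _filter_from_ratios(ratios)
        fs.allele_counts[key] = len(group)
        if low:
            fs.low_n.add(key)
    return fs


def normalize_ratios(obs: Sequence[StutterObservation]) -> list[float]:
    """Divide each ratio by the mean of its (marker, allele) group.

    Group means of the output are exactly 1; singleton groups normalize to 1.
    Groups whose mean is 0 are excluded with a warning (their entries are NaN).
    """
    import warnings

    groups: dict[tuple[str, Allele], list[int]] = {}
    for i, o in enumerate(obs):
        groups.setdefault((o.marker, o.parent_allele), []).append(i)
    out = [float("nan")] * len(obs)
    for key, idx in groups.items():
        mean = float(np.mean([obs[i].ratio for i in idx]))
        if mean == 0:
            warnings.warn(f"group {key} has zero mean stutter ratio; excluded")
            continue
        for i in idx:
            out[i] = obs[i].ratio / mean
    return out


# ---------------------------------------------------------------------------
# Friedman rank test (markers = blocks, instruments = treatments)
# ---------------------------------------------------------------------------


def friedman_statistic(table: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square for an (n blocks x k treatments)
    table.  Implemented in-package because the analysis needs the k = 2 case.
    """
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    if n < 1 or k < 2:
        raise StutterStatsError("need >=1 block and >=2 treatments")
    ranks = np.apply_along_axis(stats.rankdata, 1, table)
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    denom = float((ranks**2).sum()) - n * k * (k + 1) ** 2 / 4.0
    if denom == 0:
        return 0.0  # all ranks tied everywhere
    return num / denom


def friedman_exact_pvalue(table: np.ndarray) -> float:
    """Exact permutation p-value: permute treatments within each block and
    count statistics at least as large as observed.  Feasible for <=5
    treatments and <=12 blocks."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    if k > 5 or n > 12:
        raise StutterStatsError(
            "exact permutation p-value limited to <=5 treatments, <=12 blocks"
        )
    observed = friedman_statistic(table)
    perms = list(itertools.permutations(range(k)))
    count = 0
    total = 0
    for combo in itertools.product(perms, repeat=n):
        permuted = np.vstack([table[i, list(p)] for i, p in enumerate(combo)])
        if friedman_statistic(permuted) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def instrument_effect(
    obs: Sequence[StutterObservation],
    instruments: Sequence[str] | None = None,
    exact: bool = False,
) -> tuple[float, float, pd.DataFrame]:
    """Test whether instruments shift stutter ratios.

    Ratios are first normalized for allele length, then averaged per
    (marker, instrument); the Friedman test runs on the resulting blocks.
    Returns ``(statistic, p_value, table)`` where the table holds the average
    normalized ratio and within-marker rank per cell.
    """
    if instruments is None:
        instruments = sorted({o.instrument for o in obs})
    if len(instruments) < 2:
        raise StutterStatsError("need at least 2 instruments")
    normalized = normalize_ratios(obs)

    cells: dict[tuple[str, str], list[float]] = {}
    for o, z in zip(obs, normalized):
        if o.instrument in instruments and not np.isnan(z):
            cells.setdefault((o.marker, o.instrument), []).append(z)

    markers = sorted({m for (m, _) in cells})
    data = np.empty((len(markers), len(instruments)))
    for i, m in enumerate(markers):
        for j, ins in enumerate(instruments):
            vals = cells.get((m, ins))
            if not vals:
                raise StutterStatsError(
                    f"no observations for marker {m!r} on instrument {ins!r}"
                )
            data[i, j] = float(np.mean(vals))

    statistic = friedman_statistic(data)
    k = len(instruments)
    if exact:
        p_value = friedman_exact_pvalue(data)
    else:
        p_value = float(stats.chi2.sf(statistic, df=k - 1)) if statistic > 0 else 1.0

    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    table = pd.DataFrame(data, index=markers, columns=list(instruments))
    rank_table = pd.DataFrame(ranks, index=markers, columns=list(instruments))
    out = pd.concat({"mean_normalized_ratio": table, "rank": rank_table}, axis=1)
    return statistic, p_value, out


def read_observations(path) -> list[StutterObservation]:
    """Read observations CSV:
    ``marker,parent_allele,position,ratio,instrument,lab_id,run_id,ploidy``."""
    from .panel import _normalize_marker_name, parse_allele

    df = pd.read_csv(path, comment="#", dtype={"parent_allele": str})
    required = {"marker", "parent_allele", "position", "ratio"}
    missing = required - set(df.columns)
    if missing:
        raise StutterStatsError(f"observations missing column(s): {sorted(missing)}")
    obs = []
    for row in df.itertuples(index=False):
        obs.append(
            StutterObservation(
                marker=_normalize_marker_name(str(row.marker)),
                parent_allele=parse_allele(str(row.parent_allele)),
                position=int(row.position),
                ratio=float(row.ratio),
                instrument=str(getattr(row, "instrument", "") or ""),
                lab_id=str(getattr(row, "lab_id", "") or ""),
                run_id=str(getattr(row, "run_id", "") or ""),
                ploidy=str(getattr(row, "ploidy", "diploid") or "diploid"),
            )
        )
    return obs


def write_filters(fs: StutterFilterSet, path, header_lines=()) -> None:
    rows = [
        {"scope": "marker", "marker": m, "allele": "", "filter": f,
         "n": fs.marker_counts[m], "low_n": m in fs.low_n}
        for m, f in sorted(fs.marker_filters.items())
    ] + [
        {"scope": "allele", "marker": m, "allele": str(a), "filter": f,
         "n": fs.allele_counts[(m, a)], "low_n": (m, a) in fs.low_n}
        for (m, a), f in sorted(fs.allele_filters.items(), key=lambda kv: (kv[0][0], kv[0][1]))
    ]
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
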