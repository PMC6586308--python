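"""Interlaboratory concordance scoring.

Each allele call made by a laboratory gets an *agreement proportion*: the
fraction of the other participating labs whose call set at that marker also
contains the allele.  Marker- and cell-line-level scores are averages of
these proportions over all calls made.  A cell line is *concordant* when
every lab reports the identical allele set at every scored marker.

Worked example (12 labs, one marker): all 12 call allele 17 and 11 of the 12
also call allele 19.  Each allele-17 call agrees with 11/11 = 1 of the other
labs; each allele-19 call with 10/11 = 0.909.  The marker score averages over
the 23 calls made: (12*1 + 11*(10/11)) / 23 = 22/23 = 0.957.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .panel import Allele

#: Discordance reason codes: a. low fluorescent signal, b. error in stutter-
#: ratio calculation, c. stutter ratio at the threshold, d. missed allele
#: (not labeled), e. artifact (pull-up, dye blob, spike).
REASON_CODES = frozenset("abcde")


class ConcordanceError(ValueError):
    pass


@dataclass
class LabCallSet:
    """One laboratory's allele calls for one cell line."""

    cell_line: str
    lab_id: str
    calls: dict[str, frozenset[Allele]] = field(default_factory=dict)

    def alleles(self, marker: str) -> frozenset[Allele]:
        return self.calls.get(marker, frozenset())


@dataclass
class AgreementReport:
    cell_line: str
    per_call: dict[tuple[str, str, Allele], float]
    per_marker: dict[str, float]
    per_line_mean: float
    concordant: bool
    discordant_marker_count: int
    discordant_markers: list[str]
    total_calls: int
    reasons: frozenset[str] = frozenset()


def _markers_in_play(
    call_sets: Sequence[LabCallSet], markers: Sequence[str] | None
) -> list[str]:
    if markers is not None:
        return list(markers)
    seen: list[str] = []
    for cs in call_sets:
        for m in cs.calls:
            if m not in seen:
                seen.append(m)
    return seen


def call_agreement(
    lab_id: str,
    marker: str,
    allele: Allele,
    all_calls: Sequence[LabCallSet],
) -> float:
    """Fraction of the *other* labs whose call set contains ``allele``."""
    if len(all_calls) < 2:
        raise ConcordanceError("agreement needs at least 2 laboratories")
    others = [cs for cs in all_calls if cs.lab_id != lab_id]
    agreeing = sum(1 for cs in others if allele in cs.alleles(marker))
    return agreeing / len(others)


def marker_agreement(marker: str, all_calls: Sequence[LabCallSet]) -> float:
    """Average agreement proportion over every call made at the marker.

    The denominator is the total number of allele calls made across labs
    (23 in the worked example above), not the number of distinct alleles.
    """
    total = 0.0
    n_calls = 0
    for cs in all_calls:
        for allele in cs.alleles(marker):
            total += call_agreement(cs.lab_id, marker, allele, all_calls)
            n_calls += 1
    if n_calls == 0:
        raise ConcordanceError(f"no calls made at marker {marker}")
    return total / n_calls


def consensus_profile(
    all_calls: Sequence[LabCallSet], markers: Sequence[str] | None = None
) -> dict[str, frozenset[Allele]]:
    """Majority-rule consensus: alleles called by more than half the labs."""
    markers = _markers_in_play(all_calls, markers)
    n = len(all_calls)
    consensus: dict[str, frozenset[Allele]] = {}
    for m in markers:
        counts: dict[Allele, int] = {}
        for cs in all_calls:
            for a in cs.alleles(m):
                counts[a] = counts.get(a, 0) + 1
        kept = frozenset(a for a, c in counts.items() if c > n / 2)
        if kept:
            consensus[m] = kept
    return consensus


def line_agreement(
    all_calls: Sequence[LabCallSet], markers: Sequence[str] | None = None
) -> AgreementReport:
    """Score one cell line across laboratories.

    Returns per-call agreement proportions, per-marker scores, their overall
    mean, the concordant/discordant classification, and the number of markers
    at which at least two labs differ.
    """
    if len(all_calls) < 2:
        raise ConcordanceError("agreement needs at least 2 laboratories")
    cell_lines = {cs.cell_line for cs in all_calls}
    if len(cell_lines) != 1:
        raise ConcordanceError(
            f"line_agreement expects one cell line, got {sorted(cell_lines)}"
        )
    markers = _markers_in_play(all_calls, markers)

    per_call: dict[tuple[str, str, Allele], float] = {}
    per_marker: dict[str, float] = {}
    discordant: list[str] = []
    total = 0.0
    n_calls = 0
    for m in markers:
        marker_total = 0.0
        marker_calls = 0
        call_sets_at_m = {cs.lab_id: cs.alleles(m) for cs in all_calls}
        for cs in all_calls:
            for allele in cs.alleles(m):
                p = call_agreement(cs.lab_id, m, allele, all_calls)
                per_call[(cs.lab_id, m, allele)] = p
                marker_total += p
                marker_calls += 1
        if marker_calls:
            per_marker[m] = marker_total / marker_calls
            total += marker_total
            n_calls += marker_calls
        if len(set(call_sets_at_m.values())) > 1:
            discordant.append(m)

    mean = total / n_calls if n_calls else float("nan")
    return AgreementReport(
        cell_line=next(iter(cell_lines)),
        per_call=per_call,
        per_marker=per_marker,
        per_line_mean=mean,
        concordant=not discordant,
        discordant_marker_count=len(discordant),
        discordant_markers=discordant,
        total_calls=n_calls,
    )


def concordance_report(
    lines: dict[str, Sequence[LabCallSet]],
    markers: Sequence[str] | None = None,
    reasons: dict[str, Iterable[str]] | None = None,
    expected_labs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per cell line: mean agreement (3 decimals), discordant-marker
    count, concordance flag, and optional reason codes (restricted to a-e)."""
    reasons = reasons or {}
    for line, codes in reasons.items():
        bad = set(codes) - REASON_CODES
        if bad:
            raise ConcordanceError(
                f"invalid discordance reason code(s) {sorted(bad)} for {line};"
                f" allowed: {sorted(REASON_CODES)}"
            )
    rows = []
    for line, call_sets in lines.items():
        rep = line_agreement(list(call_sets), markers)
        incomplete = False
        if expected_labs is not None:
            incomplete = {cs.lab_id for cs in call_sets} != set(expected_labs)
        rows.append(
            {
                "cell_line": line,
                "mean_agreement": round(rep.per_line_mean, 3),
                "markers_discordant": rep.discordant_marker_count,
                "concordant": rep.concordant,
                "reasons": ",".join(sorted(reasons.get(line, ()))),
                "incomplete": incomplete,
            }
        )
    return pd.DataFrame(rows)
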