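"""Allele calling: peak table -> STR profile.

Pipeline per marker: drop sub-threshold peaks (default floor 100 RFU), pair
candidate stutter peaks one repeat (4 bp) below/above a taller parent, apply
the consensus stutter rules — a peak in the -4 stutter position is an allele
only when its stutter ratio exceeds 20%, a +4 peak only above 10% (strict
inequalities) — then map surviving peak sizes to alleles through the
calibrant-anchored bin set.  A mixture of cell lines invalidates stutter
ratios, so gross sister-peak height imbalance is flagged, never resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .panel import REPEAT_UNIT_BP, BinSet, Panel, size_to_allele
from .peakio import Peak, PeakTable, STRProfile


@dataclass(frozen=True)
class CallConfig:
    """Interpretation thresholds for allele calling.

    ``min_height_rfu`` applies both to allele eligibility and to the peaks
    entering stutter-ratio computation (set ``min_height_for_alleles=False``
    to restrict the floor to ratio computation only).
    """

    min_height_rfu: float = 100.0
    minus_stutter_threshold: float = 0.20
    plus_stutter_threshold: float = 0.10
    stutter_match_tol_bp: float = 0.5
    panel_version: Literal["full19", "core18"] = "core18"
    allow_off_ladder: bool = True
    min_height_for_alleles: bool = True
    imbalance_ratio: float = 0.3

    def __post_init__(self) -> None:
        for name in ("minus_stutter_threshold", "plus_stutter_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.min_height_rfu < 0:
            raise ValueError("min_height_rfu must be >= 0")


@dataclass(frozen=True)
class CandidateStutterPair:
    parent: Peak
    candidate: Peak
    position: int  # -1: one repeat below the parent, +1: one repeat above
    ratio: float


def pair_stutter_candidates(
    peaks: Sequence[Peak], tol: float = 0.5
) -> list[CandidateStutterPair]:
    """Pair each peak sitting one repeat (4 bp) from a taller peak with that
    parent.  A peak may appear as both parent and candidate.  When a candidate
    has several parents at the same position, the tallest parent governs (the
    smaller resulting ratio is the conservative, more-filterable one)."""
    ordered = sorted(peaks, key=lambda p: p.size_bp)
    best: dict[tuple[int, int], CandidateStutterPair] = {}
    for i, cand in enumerate(ordered):
        for j, parent in enumerate(ordered):
            if i == j or parent.height_rfu <= cand.height_rfu:
                continue
            for position in (-1, +1):
                expected = parent.size_bp + position * REPEAT_UNIT_BP
                if abs(cand.size_bp - expected) <= tol and parent.height_rfu > 0:
                    pair = CandidateStutterPair(
                        parent=parent,
                        candidate=cand,
                        position=position,
                        ratio=cand.height_rfu / parent.height_rfu,
                    )
                    key = (i, position)
                    prev = best.get(key)
                    if prev is None or parent.height_rfu > prev.parent.height_rfu:
                        best[key] = pair
    return sorted(
        best.values(), key=lambda p: (p.candidate.size_bp, p.position)
    )


def apply_stutter_rules(
    pairs: Sequence[CandidateStutterPair],
    config: CallConfig,
    peaks: Sequence[Peak] | None = None,
) -> dict[int, str]:
    """Dispose each peak as ``"allele"`` or ``"filtered_stutter"``.

    Keyed by ``id(peak)``.  A candidate is kept as an allele only when its
    ratio strictly exceeds the threshold for *every* stutter position it
    occupies; peaks in no stutter position are alleles by default.
    """
    disposition: dict[int, str] = {}
    if peaks is not None:
        for p in peaks:
            disposition[id(p)] = "allele"
    for pair in pairs:
        disposition.setdefault(id(pair.parent), "allele")
        thresh = (
            config.minus_stutter_threshold
            if pair.position == -1
            else config.plus_stutter_threshold
        )
        current = disposition.get(id(pair.candidate), "allele")
        if pair.ratio <= thresh:
            disposition[id(pair.candidate)] = "filtered_stutter"
        elif current != "filtered_stutter":
            disposition[id(pair.candidate)] = "allele"
    return disposition


@dataclass
class CallReport:
    """Full accounting of a called sample: every input peak lands in exactly
    one disposition bucket."""

    profile: STRProfile
    dispositions: dict[str, list[tuple[Peak, str]]] = field(default_factory=dict)

    def count(self, disposition: str) -> int:
        return sum(
            1
            for entries in self.dispositions.values()
            for _, d in entries
            if d == disposition
        )


def call_sample(
    table: PeakTable,
    binset: BinSet,
    config: CallConfig = CallConfig(),
    panel: Panel | None = None,
) -> STRProfile:
    return call_sample_report(table, binset, config, panel).profile


def call_sample_report(
    table: PeakTable,
    binset: BinSet,
    config: CallConfig = CallConfig(),
    panel: Panel | None = None,
) -> CallReport:
    """Call a peak table against a bin set, with per-peak accounting.

    Dispositions: ``allele``, ``filtered_stutter``, ``sub_threshold``,
    ``off_panel``, and ``off_ladder`` (when ``allow_off_ladder`` is false the
    peak is dropped; otherwise the nearest allele is called and flagged).
    Markers whose every peak falls below the RFU floor are flagged
    ``low_signal``; markers missing from the bin set get a ``marker_error``
    flag rather than aborting the sample.
    """
    profile = STRProfile(sample_id=table.sample_id)
    report = CallReport(profile=profile)
    panel_markers = set(panel.marker_names) if panel is not None else None

    for marker in table.markers:
        peaks = table.marker_peaks(marker)
        entries: list[tuple[Peak, str]] = []
        flags: set[str] = set()

        if panel_markers is not None and marker not in panel_markers:
            warnings.warn(f"peaks at off-panel marker {marker!r} not called")
            report.dispositions[marker] = [(p, "off_panel") for p in peaks]
            profile.flags[marker] = frozenset({"off_panel"})
            continue
        if config.panel_version == "core18" and marker == "11-1":
            report.dispositions[marker] = [(p, "off_panel") for p in peaks]
            profile.flags[marker] = frozenset({"excluded_marker"})
            continue
        if marker not in binset:
            report.dispositions[marker] = [(p, "off_panel") for p in peaks]
            profile.flags[marker] = frozenset({"marker_error"})
            continue

        tall = [p for p in peaks if p.height_rfu >= config.min_height_rfu]
        entries.extend(
            (p, "sub_threshold")
            for p in peaks
            if p.height_rfu < config.min_height_rfu
        )
        if peaks and not tall:
            flags.add("low_signal")

        ratio_pool = tall if config.min_height_for_alleles else peaks
        pairs = pair_stutter_candidates(ratio_pool, config.stutter_match_tol_bp)
        disposition = apply_stutter_rules(pairs, config, peaks=tall)
        in_stutter_pos = {id(p.candidate) for p in pairs}

        alleles = set()
        heights: dict[object, float] = {}
        for p in tall:
            d = disposition.get(id(p), "allele")
            if d == "filtered_stutter":
                entries.append((p, "filtered_stutter"))
                continue
            allele, call_flag = size_to_allele(binset, marker, p.size_bp)
            if call_flag == "off_ladder":
                if config.allow_off_ladder:
                    alleles.add(allele)
                    heights[allele] = max(heights.get(allele, 0.0), p.height_rfu)
                    flags.add("off_ladder")
                    entries.append((p, "off_ladder"))
                else:
                    entries.append((p, "off_ladder"))
                continue
            alleles.add(allele)
            heights[allele] = max(heights.get(allele, 0.0), p.height_rfu)
            if call_flag == "extrapolated":
                flags.add("extrapolated")
            if id(p) in in_stutter_pos:
                flags.add("stutter_overlap")
            entries.append((p, "allele"))

        if marker == "11-1":
            flags.add("shoulder_risk")
        if len(heights) >= 2:
            hs = list(heights.values())
            if min(hs) / max(hs) < config.imbalance_ratio:
                flags.add("imbalance")

        if alleles:
            profile.calls[marker] = frozenset(alleles)
        if flags:
            profile.flags[marker] = frozenset(flags)
        report.dispositions[marker] = entries
    return report


def screen_human_contamination(
    profile: STRProfile, panel: Panel
) -> tuple[Literal["clean", "human_detected"], dict[str, frozenset]]:
    """Check the two human STR markers for called alleles.

    Any call at D8S1106 or D4S2408 means human DNA amplified: the sample is
    flagged ``human_detected`` with the offending markers and alleles as
    evidence.
    """
    evidence = {
        m: profile.alleles(m) for m in panel.human_markers if profile.alleles(m)
    }
    status: Literal["clean", "human_detected"] = (
        "human_detected" if evidence else "clean"
    )
    return status, evidence
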