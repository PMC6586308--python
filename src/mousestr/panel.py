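"""Marker panels, allele nomenclature, and calibrant-anchored size-to-allele bins.

The mouse authentication assay targets tetranucleotide short tandem repeats
(STRs): every full repeat unit adds 4 bp to the amplicon.  Alleles are named
by repeat count, with microvariants carrying extra bases beyond full repeats
written as ``R.m`` (e.g. ``20.3`` = 20 full repeats plus 3 bases).

Genotyping converts imprecise capillary-electrophoresis fragment sizes into
alleles through *bins*: size windows anchored on calibrants (sequenced diploid
DNA of known repeat count) and extrapolated in +/-4 bp steps to alleles the
calibrants do not cover.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

REPEAT_UNIT_BP = 4

DYES = ("6FAM", "VIC", "NED", "PET")

#: The marker dropped from the assay for its +/-1 bp "shoulder" artifact
#: (incomplete adenylation); the core panel keeps the remaining 18 mouse loci.
SHOULDER_MARKER = "11-1"

HUMAN_MARKERS = ("D8S1106", "D4S2408")


class AlleleParseError(ValueError):
    """Malformed allele designation."""


class PanelError(ValueError):
    """Inconsistent panel or bin-set construction input."""


@dataclass(frozen=True, order=False)
class Allele:
    """STR allele: full tetranucleotide repeats plus a 0-3 base microvariant."""

    repeats: int
    microvariant: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 0:
            raise AlleleParseError(f"negative repeat count: {self.repeats}")
        if self.microvariant not in (0, 1, 2, 3):
            raise AlleleParseError(
                f"microvariant must be 0-3 bases, got {self.microvariant}"
            )

    @property
    def length_bp(self) -> int:
        """Implied repeat-region length: 4*repeats + microvariant bases."""
        return REPEAT_UNIT_BP * self.repeats + self.microvariant

    def shift(self, k: int) -> "Allele":
        """Shift by ``k`` full repeats, preserving the microvariant class."""
        if self.repeats + k < 0:
            raise PanelError(
                f"shift of {k} repeats takes allele {self} below zero repeats"
            )
        return Allele(self.repeats + k, self.microvariant)

    def __str__(self) -> str:
        if self.microvariant == 0:
            return str(self.repeats)
        return f"{self.repeats}.{self.microvariant}"

    def __lt__(self, other: "Allele") -> bool:
        return self.length_bp < other.length_bp

    def __le__(self, other: "Allele") -> bool:
        return self.length_bp <= other.length_bp

    def __gt__(self, other: "Allele") -> bool:
        return self.length_bp > other.length_bp

    def __ge__(self, other: "Allele") -> bool:
        return self.length_bp >= other.length_bp


def parse_allele(text: str) -> Allele:
    """Parse an allele designation like ``"19"`` or ``"20.3"``.

    Raises :class:`AlleleParseError` on anything else (empty, negative,
    microvariant outside 1-3, stray characters).
    """
    token = text.strip()
    if not token:
        raise AlleleParseError("empty allele designation")
    head, dot, tail = token.partition(".")
    try:
        repeats = int(head)
    except ValueError:
        raise AlleleParseError(f"bad repeat count in allele {token!r}") from None
    if repeats < 0 or head.startswith(("+", "-")):
        raise AlleleParseError(f"negative repeat count in allele {token!r}")
    micro = 0
    if dot:
        if not tail.isdigit():
            raise AlleleParseError(f"bad microvariant in allele {token!r}")
        micro = int(tail)
        if micro not in (1, 2, 3):
            raise AlleleParseError(
                f"microvariant {micro} out of range 1-3 in allele {token!r}"
                " (a tetranucleotide microvariant carries 1-3 extra bases)"
            )
    return Allele(repeats, micro)


def format_allele(a: Allele) -> str:
    return str(a)


def allele_shift(a: Allele, k: int) -> Allele:
    """Move an allele by ``k`` full repeats (+/-4 bp each); microvariant kept."""
    return a.shift(k)


@dataclass(frozen=True)
class MarkerDef:
    """One STR locus of the multiplex assay."""

    name: str
    species: Literal["mouse", "human"]
    chromosome: str
    dye: str
    known_allele_range: tuple[Allele, Allele] | None = None
    repeat_unit_bp: int = REPEAT_UNIT_BP

    def __post_init__(self) -> None:
        if self.dye not in DYES:
            raise PanelError(f"unknown dye label {self.dye!r} for marker {self.name}")
        if self.species not in ("mouse", "human"):
            raise PanelError(f"unknown species {self.species!r} for {self.name}")
        if self.repeat_unit_bp != REPEAT_UNIT_BP:
            raise PanelError("all assay loci are tetranucleotide repeats (4 bp)")


@dataclass(frozen=True)
class Panel:
    """Ordered marker collection; ``full19`` or the ``core18`` revision.

    ``core18`` drops marker 11-1 (shoulder-peak morphology); the two human
    contamination-screen markers are carried in both versions but never
    contribute to mouse profiles or matching.
    """

    markers: tuple[MarkerDef, ...]
    version: Literal["full19", "core18"] = "full19"

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelError(f"duplicate marker name(s): {sorted(dupes)}")

    @property
    def mouse_markers(self) -> list[str]:
        return [m.name for m in self.markers if m.species == "mouse"]

    @property
    def human_markers(self) -> list[str]:
        return [m.name for m in self.markers if m.species == "human"]

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def marker(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"marker {name!r} not in panel")

    def __contains__(self, name: object) -> bool:
        return any(m.name == name for m in self.markers)


def _normalize_marker_name(name: str) -> str:
    # tolerate the typographic en-dash used in print
    return name.strip().replace("–", "-")


def _parse_range(text: str) -> tuple[Allele, Allele] | None:
    text = text.strip()
    if not text:
        return None
    lo_txt, sep, hi_txt = text.partition("-")
    if not sep:
        raise PanelError(f"bad allele range {text!r} (expected 'lo-hi')")
    lo, hi = parse_allele(lo_txt), parse_allele(hi_txt)
    if hi < lo:
        raise PanelError(f"inverted allele range {text!r}")
    return lo, hi


def load_panel(
    config: str | Path | None = None, version: Literal["full19", "core18"] = "full19"
) -> Panel:
    """Load a marker panel from a CSV config; default is the packaged assay.

    The config has columns ``marker,species,chromosome,dye,known_allele_range``
    (range as ``lo-hi``, empty allowed).  ``version="core18"`` drops marker
    11-1.
    """
    if config is None:
        config = Path(__file__).parent / "fixtures" / "panel_full19.csv"
    path = Path(config)
    markers: list[MarkerDef] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"marker", "species", "chromosome", "dye"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise PanelError(f"panel config missing column(s): {sorted(missing)}")
        for row in reader:
            markers.append(
                MarkerDef(
                    name=_normalize_marker_name(row["marker"]),
                    species=row["species"].strip(),  # type: ignore[arg-type]
                    chromosome=row["chromosome"].strip(),
                    dye=row["dye"].strip(),
                    known_allele_range=_parse_range(row.get("known_allele_range", "")),
                )
            )
    if version == "core18":
        markers = [m for m in markers if m.name != SHOULDER_MARKER]
    elif version != "full19":
        raise PanelError(f"unknown panel version {version!r}")
    return Panel(markers=tuple(markers), version=version)


# ---------------------------------------------------------------------------
# Bins: calibrant anchors and +/-4 bp extrapolation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrantAnchor:
    """A sequenced calibrant allele with its measured fragment size."""

    marker: str
    allele: Allele
    measured_size_bp: float

    def __post_init__(self) -> None:
        if self.measured_size_bp <= 0:
            raise PanelError(
                f"anchor size must be positive: {self.marker} {self.allele}"
            )


@dataclass(frozen=True)
class Bin:
    marker: str
    allele: Allele
    center_bp: float
    half_width_bp: float
    provenance: Literal["anchored", "extrapolated"]

    def __post_init__(self) -> None:
        if self.half_width_bp <= 0:
            raise PanelError("bin half-width must be positive")


@dataclass
class BinSet:
    """Per-marker allele bins, anchored on calibrants then ladder-extended."""

    bins: dict[tuple[str, Allele], Bin] = field(default_factory=dict)
    extension_limit: int = 10

    def marker_bins(self, marker: str) -> list[Bin]:
        out = [b for (m, _), b in self.bins.items() if m == marker]
        out.sort(key=lambda b: b.center_bp)
        return out

    @property
    def markers(self) -> list[str]:
        return sorted({m for (m, _) in self.bins})

    def __contains__(self, marker: object) -> bool:
        return any(m == marker for (m, _) in self.bins)


def read_anchor_file(path: str | Path) -> list[CalibrantAnchor]:
    """Read a calibrant anchor CSV with header ``marker,allele,size_bp``."""
    anchors: list[CalibrantAnchor] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"marker", "allele", "size_bp"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise PanelError(f"anchor file missing column(s): {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                size = float(row["size_bp"])
            except ValueError:
                raise PanelError(
                    f"non-numeric size_bp at line {i}: {row['size_bp']!r}"
                ) from None
            anchors.append(
                CalibrantAnchor(
                    _normalize_marker_name(row["marker"]),
                    parse_allele(row["allele"]),
                    size,
                )
            )
    return anchors


def _check_anchor_consistency(marker: str, anchors: list[CalibrantAnchor]) -> None:
    ordered = sorted(anchors, key=lambda a: a.allele.length_bp)
    sizes = [a.measured_size_bp for a in ordered]
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise PanelError(
            f"anchors for marker {marker} are not strictly increasing in size"
            " with allele order"
        )


def _local_spacing(anchors: list[CalibrantAnchor], at: CalibrantAnchor) -> float:
    """Per-repeat bp spacing near ``at``: mean spacing of the two nearest
    anchors when >=2 exist, else the nominal 4.0 bp."""
    others = [a for a in anchors if a is not at]
    if not others:
        return float(REPEAT_UNIT_BP)
    nearest = min(
        others, key=lambda a: abs(a.measured_size_bp - at.measured_size_bp)
    )
    d_len = nearest.allele.length_bp - at.allele.length_bp
    if d_len == 0:
        return float(REPEAT_UNIT_BP)
    per_bp = (nearest.measured_size_bp - at.measured_size_bp) / d_len
    return per_bp * REPEAT_UNIT_BP


def build_binset(
    panel: Panel,
    anchors: Sequence[CalibrantAnchor],
    half_width_bp: float = 0.5,
    extension_limit: int = 10,
) -> BinSet:
    """Construct allele bins from calibrant anchors.

    Anchored bins sit at measured calibrant sizes.  Extrapolated bins are
    ladder-extended from the nearest anchor in 4 bp-per-repeat steps (locally
    calibrated when two anchors bracket the region), covering the marker's
    known allele range plus ``extension_limit`` repeats beyond the outermost
    anchor.  Each microvariant class present in the anchors gets its own
    ladder; classes appearing only in the known range are offset from an
    anchored ladder by the microvariant base difference.
    """
    binset = BinSet(extension_limit=extension_limit)
    by_marker: dict[str, list[CalibrantAnchor]] = {}
    for a in anchors:
        by_marker.setdefault(a.marker, []).append(a)

    for marker, marker_anchors in by_marker.items():
        if marker not in panel:
            warnings.warn(f"anchors for off-panel marker {marker!r} ignored")
            continue
        _check_anchor_consistency(marker, marker_anchors)
        mdef = panel.marker(marker)

        rep_lo = min(a.allele.repeats for a in marker_anchors)
        rep_hi = max(a.allele.repeats for a in marker_anchors)
        if mdef.known_allele_range is not None:
            lo, hi = mdef.known_allele_range
            rep_lo = min(rep_lo, lo.repeats)
            rep_hi = max(rep_hi, hi.repeats)
        rep_lo = max(0, min(rep_lo, min(a.allele.repeats for a in marker_anchors)
                            - extension_limit))
        rep_hi = max(rep_hi, max(a.allele.repeats for a in marker_anchors)
                     + extension_limit)

        micro_classes = {a.allele.microvariant for a in marker_anchors}
        if mdef.known_allele_range is not None:
            micro_classes |= {
                mdef.known_allele_range[0].microvariant,
                mdef.known_allele_range[1].microvariant,
            }

        for mv in sorted(micro_classes):
            class_anchors = [
                a for a in marker_anchors if a.allele.microvariant == mv
            ]
            for rep in range(rep_lo, rep_hi + 1):
                allele = Allele(rep, mv)
                anchor_hit = next(
                    (a for a in class_anchors if a.allele == allele), None
                )
                if anchor_hit is not None:
                    center = anchor_hit.measured_size_bp
                    prov: Literal["anchored", "extrapolated"] = "anchored"
                else:
                    # project from the nearest anchor (same class preferred)
                    pool = class_anchors or marker_anchors
                    ref = min(
                        pool, key=lambda a: abs(a.allele.length_bp - allele.length_bp)
                    )
                    spacing = _local_spacing(marker_anchors, ref)
                    d_repeats = allele.repeats - ref.allele.repeats
                    d_micro = allele.microvariant - ref.allele.microvariant
                    center = (
                        ref.measured_size_bp
                        + d_repeats * spacing
                        + d_micro * (spacing / REPEAT_UNIT_BP)
                    )
                    prov = "extrapolated"
                if center <= 0:
                    continue
                binset.bins[(marker, allele)] = Bin(
                    marker, allele, center, half_width_bp, prov
                )
    return binset


def size_to_allele(
    binset: BinSet, marker: str, size_bp: float
) -> tuple[Allele, Literal["anchored", "extrapolated", "off_ladder"]]:
    """Map a fragment size to the nearest allele bin of a marker.

    Returns ``(allele, flag)``: the bin's provenance when the size falls
    inside the bin window, else ``off_ladder`` with the nearest allele as a
    suggestion.  An exact tie between two bins resolves to the smaller allele
    with a warning.
    """
    bins = binset.marker_bins(marker)
    if not bins:
        raise KeyError(f"marker {marker!r} has no bins in this bin set")
    best = min(
        bins, key=lambda b: (abs(size_bp - b.center_bp), b.allele.length_bp)
    )
    dist = abs(size_bp - best.center_bp)
    ties = [
        b
        for b in bins
        if math.isclose(abs(size_bp - b.center_bp), dist, abs_tol=1e-12)
        and b is not best
    ]
    if ties:
        warnings.warn(
            f"size {size_bp} equidistant between bins at marker {marker};"
            f" resolved to smaller allele {best.allele}"
        )
    if dist <= best.half_width_bp:
        return best.allele, best.provenance
    return best.allele, "off_ladder"


def synthetic_anchor_sizes(
    panel: Panel, base_offsets: dict[str, float] | None = None
) -> dict[str, float]:
    """Synthetic per-marker base offsets for fragment-size models.

    The assay's true amplicon flank lengths are instrument- and primer-
    specific and are not part of this package's inputs; this deterministic
    synthetic stand-in assigns each marker a distinct flank so that
    ``size = offset + 4*repeats + microvariant`` yields plausible,
    non-overlapping CE sizes.
    """
    if base_offsets is not None:
        return dict(base_offsets)
    return {
        m.name: 70.0 + 9.0 * i for i, m in enumerate(panel.markers)
    }


def allele_size(marker_offset: float, allele: Allele) -> float:
    """Nominal fragment size under the synthetic linear size model."""
    return marker_offset + float(allele.length_bp)


def anchors_from_profile(
    calls: dict[str, Iterable[Allele]],
    offsets: dict[str, float],
) -> list[CalibrantAnchor]:
    """Build anchors for every allele of a calibrant profile using the
    synthetic size model (fixture plumbing for tests and simulations)."""
    anchors = []
    for marker, alleles in calls.items():
        for a in alleles:
            anchors.append(CalibrantAnchor(marker, a, allele_size(offsets[marker], a)))
    return anchors
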