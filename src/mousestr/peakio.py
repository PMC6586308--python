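"""Peak-table and STR-profile I/O.

Peak tables emulate the CSV exports of CE fragment-analysis software
(GeneMapper / GeneMarker): one sized, height-annotated peak per row.  Profile
tables carry called alleles per sample and marker, in either a *long* dialect
(``sample_id,marker,alleles,flags``) or a *wide* dialect (one row per marker,
one column per sample — the layout used for published multi-sample profile
tables).  Multiple alleles inside one cell are ``;``-separated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .panel import Allele, _normalize_marker_name, parse_allele

_FIXTURE_DIR = Path(__file__).parent / "fixtures"

_FIXTURE_FILES = {
    "table2": "table2_stutter_filters.csv",
    "table5": "table5_nih3t3_lab_calls.csv",
    "table6": "table6_concordant_profiles.csv",
    "table8": "table8_related_pairs.csv",
    "table10": "table10_calibrant1.csv",
    "table11": "panel_full19.csv",
}


class SchemaError(ValueError):
    """Input file does not match the expected column layout."""


@dataclass(frozen=True)
class Peak:
    marker: str
    dye: str
    size_bp: float
    height_rfu: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError(f"peak size must be positive, got {self.size_bp}")
        if self.height_rfu < 0:
            raise ValueError(f"peak height must be >= 0, got {self.height_rfu}")


@dataclass
class PeakTable:
    sample_id: str
    lab_id: str | None = None
    instrument: str | None = None
    peaks: list[Peak] = field(default_factory=list)

    def marker_peaks(self, marker: str) -> list[Peak]:
        return sorted(
            (p for p in self.peaks if p.marker == marker), key=lambda p: p.size_bp
        )

    @property
    def markers(self) -> list[str]:
        seen: list[str] = []
        for p in self.peaks:
            if p.marker not in seen:
                seen.append(p.marker)
        return seen


@dataclass
class STRProfile:
    """Called alleles per marker for one sample, with QC flags."""

    sample_id: str
    calls: dict[str, frozenset[Allele]] = field(default_factory=dict)
    flags: dict[str, frozenset[str]] = field(default_factory=dict)

    def alleles(self, marker: str) -> frozenset[Allele]:
        return self.calls.get(marker, frozenset())

    def total_alleles(self, markers: Iterable[str]) -> int:
        return sum(len(self.calls.get(m, ())) for m in markers)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, STRProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and {m: s for m, s in self.calls.items() if s}
            == {m: s for m, s in other.calls.items() if s}
        )


def read_peak_table(path: str | Path) -> list[PeakTable]:
    """Read a peak CSV: ``sample_id,lab_id,instrument,marker,dye,size_bp,
    height_rfu[,label]``; one :class:`PeakTable` per (sample_id, lab_id)."""
    tables: dict[tuple[str, str | None], PeakTable] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "marker", "dye", "size_bp", "height_rfu"}
        have = set(reader.fieldnames or [])
        if not required <= have:
            raise SchemaError(
                f"peak file missing column(s): {sorted(required - have)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                size = float(row["size_bp"])
                height = float(row["height_rfu"])
            except ValueError:
                raise SchemaError(
                    f"non-numeric size/height at line {lineno}"
                ) from None
            key = (row["sample_id"], row.get("lab_id") or None)
            table = tables.get(key)
            if table is None:
                table = tables[key] = PeakTable(
                    sample_id=key[0],
                    lab_id=key[1],
                    instrument=row.get("instrument") or None,
                )
            table.peaks.append(
                Peak(
                    marker=_normalize_marker_name(row["marker"]),
                    dye=row["dye"],
                    size_bp=size,
                    height_rfu=height,
                    label=row.get("label") or None,
                )
            )
    return list(tables.values())


def write_peak_table(
    tables: Iterable[PeakTable], path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "lab_id", "instrument", "marker", "dye", "size_bp",
             "height_rfu", "label"]
        )
        for t in tables:
            for p in t.peaks:
                writer.writerow(
                    [t.sample_id, t.lab_id or "", t.instrument or "", p.marker,
                     p.dye, f"{p.size_bp:.2f}", f"{p.height_rfu:.1f}",
                     p.label or ""]
                )


def _parse_allele_cell(cell: str, where: str) -> frozenset[Allele]:
    alleles = set()
    for tok in cell.split(";"):
        tok = tok.strip()
        if not tok:
            continue
        try:
            alleles.add(parse_allele(tok))
        except ValueError as e:
            raise SchemaError(f"unparseable allele {tok!r} at {where}: {e}") from None
    return frozenset(alleles)


def read_profile_table(
    path: str | Path, dialect: Literal["long", "wide"] = "long"
) -> list[STRProfile]:
    """Read STR profiles from CSV.

    ``long``: columns ``sample_id,marker,alleles[,flags]``.
    ``wide``: first column ``marker``, remaining columns one sample each.
    Empty allele cells leave the marker uncalled and record a ``no_call``
    flag.  Leading ``#`` comment lines are skipped.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows:
        raise SchemaError(f"empty profile table: {path}")
    header, data = rows[0], rows[1:]

    profiles: dict[str, STRProfile] = {}
    if dialect == "long":
        try:
            i_sample = header.index("sample_id")
            i_marker = header.index("marker")
            i_alleles = header.index("alleles")
        except ValueError as e:
            raise SchemaError(f"long profile table missing column: {e}") from None
        i_flags = header.index("flags") if "flags" in header else None
        for lineno, row in enumerate(data, start=2):
            sid = row[i_sample]
            prof = profiles.setdefault(sid, STRProfile(sample_id=sid))
            marker = _normalize_marker_name(row[i_marker])
            alleles = _parse_allele_cell(row[i_alleles], f"line {lineno}")
            flags: set[str] = set()
            if i_flags is not None and len(row) > i_flags and row[i_flags]:
                flags = set(row[i_flags].split(";"))
            if alleles:
                prof.calls[marker] = alleles
            else:
                flags.add("no_call")
            if flags:
                prof.flags[marker] = frozenset(flags)
    elif dialect == "wide":
        if _normalize_marker_name(header[0]).lower() != "marker":
            raise SchemaError("wide profile table must start with a 'marker' column")
        samples = header[1:]
        for sid in samples:
            profiles[sid] = STRProfile(sample_id=sid)
        for r, row in enumerate(data, start=2):
            marker = _normalize_marker_name(row[0])
            for c, sid in enumerate(samples, start=1):
                cell = row[c] if c < len(row) else ""
                alleles = _parse_allele_cell(cell, f"row {r}, column {c + 1}")
                if alleles:
                    profiles[sid].calls[marker] = alleles
                else:
                    profiles[sid].flags[marker] = frozenset({"no_call"})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return list(profiles.values())


def write_profile_table(
    profiles: Iterable[STRProfile],
    path: str | Path,
    dialect: Literal["long", "wide"] = "long",
    header_lines: Iterable[str] = (),
) -> None:
    """Write profiles; lossless round-trip with :func:`read_profile_table`
    (the wide dialect does not carry flags)."""
    profiles = list(profiles)
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        if dialect == "long":
            writer.writerow(["sample_id", "marker", "alleles", "flags"])
            for prof in profiles:
                markers = sorted(set(prof.calls) | set(prof.flags))
                for m in markers:
                    alleles = ";".join(
                        str(a) for a in sorted(prof.calls.get(m, frozenset()))
                    )
                    flags = ";".join(
                        sorted(prof.flags.get(m, frozenset()) - {"no_call"})
                    )
                    writer.writerow([prof.sample_id, m, alleles, flags])
        elif dialect == "wide":
            markers: list[str] = []
            for prof in profiles:
                for m in prof.calls:
                    if m not in markers:
                        markers.append(m)
            writer.writerow(["marker"] + [p.sample_id for p in profiles])
            for m in markers:
                writer.writerow(
                    [m]
                    + [
                        ";".join(str(a) for a in sorted(p.calls.get(m, frozenset())))
                        for p in profiles
                    ]
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_lab_calls(path: str | Path) -> list["LabCallSet"]:
    """Read per-lab call sets: ``cell_line,lab_id,marker,alleles``."""
    from .concord import LabCallSet

    sets: dict[tuple[str, str], LabCallSet] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#"))
        )
        required = {"cell_line", "lab_id", "marker", "alleles"}
        have = set(reader.fieldnames or [])
        if not required <= have:
            raise SchemaError(
                f"lab-calls file missing column(s): {sorted(required - have)}"
            )
        for lineno, row in enumerate(reader, start=2):
            key = (row["cell_line"], row["lab_id"])
            lcs = sets.get(key)
            if lcs is None:
                lcs = sets[key] = LabCallSet(
                    cell_line=key[0], lab_id=key[1], calls={}
                )
            alleles = _parse_allele_cell(row["alleles"], f"line {lineno}")
            if alleles:
                lcs.calls[_normalize_marker_name(row["marker"])] = alleles
    return list(sets.values())


def load_fixture(name: str):
    """Load a packaged reference table, parsed and typed.

    ========  ====================================================
    name      content
    ========  ====================================================
    table2    marker-level stutter-filter recommendations (DataFrame)
    table5    NIH/3T3 12-laboratory call sets (list of LabCallSet)
    table6    21 concordant cell-line profiles (list of STRProfile)
    table8    known parental/derivative percent-match pairs (DataFrame)
    table10   Calibrant 1 profile (single STRProfile)
    table11   the 21-marker assay panel (Panel)
    ========  ====================================================
    """
    import pandas as pd

    if name not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURE_FILES)}"
        )
    path = _FIXTURE_DIR / _FIXTURE_FILES[name]
    if name == "table2":
        df = pd.read_csv(path)
        df["stutter_ratio"] = df["stutter_ratio_pct"] / 100.0
        return df
    if name == "table5":
        return read_lab_calls(path)
    if name == "table6":
        return read_profile_table(path, dialect="wide")
    if name == "table8":
        return pd.read_csv(path)
    if name == "table10":
        (profile,) = read_profile_table(path, dialect="wide")
        return profile
    if name == "table11":
        from .panel import load_panel

        return load_panel(path)
    raise AssertionError("unreachable")


def fixture_path(name: str) -> Path:
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}")
    return _FIXTURE_DIR / _FIXTURE_FILES[name]
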