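"""Pairwise STR profile comparison.

Master's algorithm: percent match = 100 x (number of alleles shared between
the questioned and reference profiles) / (total number of alleles in the
*questioned* profile).  Shared alleles are counted marker by marker with set
semantics — a homozygous locus contributes one allele — so the measure is
asymmetric whenever the two profiles carry different allele counts.

A profile matched against itself always scores 100%.  Known derivatives of a
parental line score above 85%; lines from the same inbred strain can exceed
80% without being the same line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .peakio import STRProfile


class MatchError(ValueError):
    pass


@dataclass(frozen=True)
class MatchResult:
    questioned: str
    reference: str
    shared_alleles: int
    questioned_total: int
    reference_total: int
    percent_match: float
    markers_used: tuple[str, ...]

    @property
    def percent_rounded(self) -> int:
        """Report-style nearest-integer percent."""
        return int(round(self.percent_match))


def masters_match(
    questioned: STRProfile,
    reference: STRProfile,
    markers: Sequence[str],
) -> MatchResult:
    """Master's-algorithm percent match of ``questioned`` against
    ``reference`` over the given markers (human screen markers excluded by
    passing only mouse loci)."""
    shared = 0
    q_total = 0
    r_total = 0
    for m in markers:
        q = questioned.alleles(m)
        r = reference.alleles(m)
        shared += len(q & r)
        q_total += len(q)
        r_total += len(r)
    if q_total == 0:
        raise MatchError(
            f"questioned profile {questioned.sample_id!r} has no alleles"
            " at the requested markers"
        )
    return MatchResult(
        questioned=questioned.sample_id,
        reference=reference.sample_id,
        shared_alleles=shared,
        questioned_total=q_total,
        reference_total=r_total,
        percent_match=100.0 * shared / q_total,
        markers_used=tuple(markers),
    )


def pairwise_matrix(
    profiles: Sequence[STRProfile], markers: Sequence[str]
) -> pd.DataFrame:
    """Percent-match matrix: entry (i, j) treats profile i as questioned and
    profile j as reference.  Diagonal is 100; the matrix is generally
    asymmetric."""
    if len(profiles) < 2:
        raise MatchError("pairwise comparison needs at least 2 profiles")
    ids = [p.sample_id for p in profiles]
    mat = np.empty((len(profiles), len(profiles)))
    for i, q in enumerate(profiles):
        for j, r in enumerate(profiles):
            mat[i, j] = masters_match(q, r, markers).percent_match
    return pd.DataFrame(mat, index=ids, columns=ids)


def allele_distance(
    a: STRProfile, b: STRProfile, markers: Sequence[str]
) -> int:
    """Symmetric difference count: alleles present in one profile but not the
    other, summed over markers."""
    return sum(
        len(a.alleles(m) ^ b.alleles(m)) for m in markers
    )


def nearest_neighbor(
    profiles: Sequence[STRProfile], markers: Sequence[str]
) -> pd.DataFrame:
    """Each sample's nearest neighbor under the allele symmetric-difference
    distance; distance ties resolve to the earlier sample_id and are flagged."""
    if len(profiles) < 2:
        raise MatchError("nearest-neighbor search needs at least 2 profiles")
    rows = []
    for i, p in enumerate(profiles):
        dists = [
            (allele_distance(p, q, markers), j)
            for j, q in enumerate(profiles)
            if j != i
        ]
        best_d = min(d for d, _ in dists)
        hits = [j for d, j in dists if d == best_d]
        rows.append(
            {
                "sample_id": p.sample_id,
                "neighbor_id": profiles[hits[0]].sample_id,
                "distance": best_d,
                "tie": len(hits) > 1,
            }
        )
    return pd.DataFrame(rows)


def classify_relatedness(
    percent_match: float,
    derivative_threshold: float = 85.0,
    related_threshold: float = 80.0,
) -> Literal["same_or_derivative", "related", "unrelated"]:
    """Bucket a percent match: >85 same line or derivative, >80 related
    (e.g. same inbred strain), else unrelated."""
    if not 0 <= percent_match <= 100:
        raise MatchError(f"percent match out of range: {percent_match}")
    if percent_match > derivative_threshold:
        return "same_or_derivative"
    if percent_match > related_threshold:
        return "related"
    return "unrelated"
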