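"""Synthetic fragment-analysis data with the statistical structure the
pipeline assumes.

The generator emulates, per true allele: a sized peak (Gaussian sizing noise
around the nominal fragment size, lognormal height), minus- and plus-stutter
peaks whose ratio is linear in repeat count with Gaussian noise and an
additive per-instrument offset, allele dropout, marker-level low signal, and
the common CE artifacts (pull-up, dye blob, spike, and the +/-1 bp shoulder
peculiar to marker 11-1).  Multi-laboratory call sets are derived from true
profiles by injecting interpretation errors tagged with the standard
discordance reason codes (a: low signal, b: stutter-ratio error, c: ratio at
threshold, d: missed allele, e: artifact).

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .concord import LabCallSet
from .panel import (
    Allele,
    Panel,
    allele_size,
    load_panel,
    synthetic_anchor_sizes,
)
from .peakio import Peak, PeakTable, STRProfile
from .stutter import StutterObservation

#: Default instrument classes and their additive stutter-ratio offsets: the
#: capillary-array platforms read roughly one percentage point apart.
DEFAULT_INSTRUMENT_OFFSETS = {
    "ABI 3130xl": -0.01,
    "ABI 3500xl": -0.01,
    "ABI 3730": 0.0,
    "ABI 3730xl": 0.0,
}


@dataclass(frozen=True)
class StutterModel:
    """Linear stutter-ratio model: ratio = intercept + slope*repeats + noise."""

    intercept: float
    slope_per_repeat: float
    noise_sd: float

    def mean_ratio(self, repeats: int) -> float:
        return self.intercept + self.slope_per_repeat * repeats


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    panel: Panel = field(default_factory=load_panel)
    anchor_sizes: dict[str, float] | None = None
    minus_stutter: StutterModel = StutterModel(0.01, 0.005, 0.01)
    plus_stutter: StutterModel = StutterModel(0.005, 0.001, 0.004)
    mean_height_rfu: float = 2000.0
    height_cv: float = 0.25
    size_noise_sd_bp: float = 0.15
    dropout_prob: float = 0.0
    low_signal_prob: float = 0.0
    low_signal_factor: float = 0.03
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: {"pullup": 0.0, "dye_blob": 0.0, "spike": 0.0,
                                 "shoulder": 0.0}
    )
    instrument_offsets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INSTRUMENT_OFFSETS)
    )
    n_labs: int = 12
    ploidy: Literal["diploid", "aneuploid"] = "diploid"

    def __post_init__(self) -> None:
        for name in ("dropout_prob", "low_signal_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for k, v in self.artifact_rates.items():
            if not 0 <= v <= 1:
                raise ValueError(f"artifact rate {k}={v} out of [0,1]")

    def offsets(self) -> dict[str, float]:
        if self.anchor_sizes is not None:
            return dict(self.anchor_sizes)
        return synthetic_anchor_sizes(self.panel)


def noiseless(config: SyntheticConfig) -> SyntheticConfig:
    """Copy of the config with every stochastic mechanism switched off
    (identity-loop testing: generate -> call returns the input profile)."""
    return replace(
        config,
        minus_stutter=StutterModel(0.0, 0.0, 0.0),
        plus_stutter=StutterModel(0.0, 0.0, 0.0),
        size_noise_sd_bp=0.0,
        height_cv=0.0,
        dropout_prob=0.0,
        low_signal_prob=0.0,
        artifact_rates={k: 0.0 for k in config.artifact_rates},
        instrument_offsets={k: 0.0 for k in config.instrument_offsets},
    )


def _lognormal_height(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _stutter_ratio_draw(
    rng: np.random.Generator, model: StutterModel, repeats: int, offset: float
) -> float:
    noise = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
    return float(np.clip(model.mean_ratio(repeats) + noise + offset, 0.0, 1.0))


def simulate_peak_table(
    profile: STRProfile,
    config: SyntheticConfig,
    instrument: str | None = None,
    lab_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> PeakTable:
    """Render a true STR profile as a synthetic CE peak table."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    offsets = config.offsets()
    instr_offset = (
        config.instrument_offsets.get(instrument, 0.0) if instrument else 0.0
    )
    table = PeakTable(
        sample_id=profile.sample_id, lab_id=lab_id, instrument=instrument
    )
    dyes = {m.name: m.dye for m in config.panel.markers}

    for marker, alleles in profile.calls.items():
        if marker not in offsets:
            raise ValueError(f"no anchor size model for marker {marker!r}")
        dye = dyes.get(marker, "6FAM")
        low_signal = rng.random() < config.low_signal_prob
        scale = config.low_signal_factor if low_signal else 1.0
        for allele in sorted(alleles):
            if rng.random() < config.dropout_prob:
                continue
            center = allele_size(offsets[marker], allele)
            size = center + (
                rng.normal(0.0, config.size_noise_sd_bp)
                if config.size_noise_sd_bp > 0
                else 0.0
            )
            height = scale * _lognormal_height(
                rng, config.mean_height_rfu, config.height_cv
            )
            table.peaks.append(Peak(marker, dye, size, height, label=str(allele)))

            for position, model in ((-1, config.minus_stutter),
                                    (+1, config.plus_stutter)):
                ratio = _stutter_ratio_draw(
                    rng, model, allele.repeats, instr_offset
                )
                if ratio <= 0:
                    continue
                s_size = size + position * 4.0
                if s_size <= 0:
                    continue
                table.peaks.append(
                    Peak(marker, dye, s_size, ratio * height, label=None)
                )

            if rng.random() < config.artifact_rates.get("shoulder", 0.0):
                side = -1.0 if rng.random() < 0.5 else 1.0
                table.peaks.append(
                    Peak(marker, dye, size + side, 0.4 * height, label=None)
                )
            if rng.random() < config.artifact_rates.get("pullup", 0.0):
                victims = [m for m in dyes if dyes[m] != dye and m in offsets]
                if victims:
                    victim = victims[int(rng.integers(len(victims)))]
                    table.peaks.append(
                        Peak(victim, dyes[victim], size, 0.05 * height, label=None)
                    )

        # morphology (blob width, spike narrowness) is not modeled, only
        # an off-bin placement with modest height
        for kind in ("dye_blob", "spike"):
            if rng.random() < config.artifact_rates.get(kind, 0.0):
                lo = offsets[marker] + 20.0
                hi = offsets[marker] + 20.0 + 100.0
                table.peaks.append(
                    Peak(
                        marker,
                        dye,
                        float(rng.uniform(lo, hi)),
                        float(rng.uniform(50.0, 400.0)),
                        label=None,
                    )
                )
    table.peaks.sort(key=lambda p: (p.marker, p.size_bp))
    return table


# ---------------------------------------------------------------------------
# Interlaboratory study simulation
# ---------------------------------------------------------------------------

#: Reason code assigned to each injected interpretation error.
ERROR_REASONS = {
    "missed_allele": "d",
    "bin_error": "b",
    "stutter_miscall": "b",
    "low_signal": "a",
    "artifact": "e",
}


@dataclass(frozen=True)
class InjectedError:
    cell_line: str
    lab_id: str
    marker: str
    kind: str
    reason: str


def simulate_interlab_study(
    true_profiles: Sequence[STRProfile],
    n_labs: int,
    error_profile: dict[str, float] | None = None,
    config: SyntheticConfig | None = None,
) -> tuple[dict[str, list[LabCallSet]], list[InjectedError]]:
    """Derive per-laboratory call sets from true profiles with injected
    interpretation errors.

    ``error_profile`` gives per-call (or per-marker, for ``low_signal``)
    Bernoulli rates for {missed_allele, bin_error, stutter_miscall,
    low_signal, artifact}.  Ground truth is retained in the returned error
    log.  Deterministic given ``config.seed``.
    """
    if n_labs < 2:
        raise ValueError("an interlaboratory study needs at least 2 labs")
    config = config or SyntheticConfig()
    rates = {k: 0.0 for k in ERROR_REASONS}
    rates.update(error_profile or {})
    unknown = set(rates) - set(ERROR_REASONS)
    if unknown:
        raise ValueError(f"unknown error kind(s): {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)

    lines: dict[str, list[LabCallSet]] = {}
    log: list[InjectedError] = []
    for profile in true_profiles:
        call_sets = []
        for lab in range(1, n_labs + 1):
            lab_id = str(lab)
            calls: dict[str, frozenset[Allele]] = {}
            for marker, truth in profile.calls.items():
                if rng.random() < rates["low_signal"]:
                    log.append(
                        InjectedError(profile.sample_id, lab_id, marker,
                                      "low_signal", "a")
                    )
                    continue
                kept = set(truth)
                for allele in sorted(truth):
                    if rng.random() < rates["missed_allele"]:
                        kept.discard(allele)
                        log.append(
                            InjectedError(profile.sample_id, lab_id, marker,
                                          "missed_allele", "d")
                        )
                    elif rng.random() < rates["bin_error"]:
                        kept.discard(allele)
                        shift = 1 if rng.random() < 0.5 else -1
                        if allele.repeats + shift >= 0:
                            kept.add(allele.shift(shift))
                        log.append(
                            InjectedError(profile.sample_id, lab_id, marker,
                                          "bin_error", "b")
                        )
                if truth and rng.random() < rates["stutter_miscall"]:
                    lowest = min(truth)
                    if lowest.repeats >= 1:
                        kept.add(lowest.shift(-1))
                        log.append(
                            InjectedError(profile.sample_id, lab_id, marker,
                                          "stutter_miscall", "b")
                        )
                if rng.random() < rates["artifact"]:
                    base = max(truth) if truth else Allele(15)
                    kept.add(base.shift(+2))
                    log.append(
                        InjectedError(profile.sample_id, lab_id, marker,
                                      "artifact", "e")
                    )
                if kept:
                    calls[marker] = frozenset(kept)
            call_sets.append(
                LabCallSet(cell_line=profile.sample_id, lab_id=lab_id, calls=calls)
            )
        lines[profile.sample_id] = call_sets
    return lines, log


def drop_call(
    call_sets: Sequence[LabCallSet], lab_id: str, marker: str, allele: Allele
) -> list[LabCallSet]:
    """Deterministically remove one allele call from one lab (construction
    helper mirroring a single missed-allele discordance)."""
    out = []
    for cs in call_sets:
        calls = dict(cs.calls)
        if cs.lab_id == lab_id and marker in calls:
            reduced = calls[marker] - {allele}
            if reduced:
                calls[marker] = reduced
            else:
                del calls[marker]
        out.append(LabCallSet(cs.cell_line, cs.lab_id, calls))
    return out


# ---------------------------------------------------------------------------
# Stutter observation simulation
# ---------------------------------------------------------------------------


def simulate_stutter_observations(
    config: SyntheticConfig,
    n_per_allele: int = 10,
    markers: Sequence[str] | None = None,
    positions: tuple[int, ...] = (-1,),
) -> list[StutterObservation]:
    """Draw stutter observations across the panel's known allele ranges.

    For every (marker, allele, instrument) cell, ``n_per_allele`` ratios are
    drawn from the configured linear model, tagged with a cycling lab id and
    the configured ploidy.  Deterministic given ``config.seed``.
    """
    if n_per_allele < 1:
        raise ValueError("n_per_allele must be >= 1")
    rng = np.random.default_rng(config.seed)
    if markers is None:
        markers = [
            m.name
            for m in config.panel.markers
            if m.species == "mouse" and m.known_allele_range is not None
        ]
    obs: list[StutterObservation] = []
    instruments = list(config.instrument_offsets) or [""]
    for marker in markers:
        mdef = config.panel.marker(marker)
        if mdef.known_allele_range is None:
            raise ValueError(f"marker {marker!r} has no known allele range")
        lo, hi = mdef.known_allele_range
        alleles = [Allele(r, lo.microvariant) for r in range(lo.repeats, hi.repeats + 1)]
        for allele in alleles:
            for instrument in instruments:
                offset = config.instrument_offsets.get(instrument, 0.0)
                for i in range(n_per_allele):
                    for position in positions:
                        model = (
                            config.minus_stutter
                            if position == -1
                            else config.plus_stutter
                        )
                        obs.append(
                            StutterObservation(
                                marker=marker,
                                parent_allele=allele,
                                position=position,
                                ratio=_stutter_ratio_draw(
                                    rng, model, allele.repeats, offset
                                ),
                                instrument=instrument,
                                lab_id=str(1 + i % max(config.n_labs, 1)),
                                run_id=str(i),
                                ploidy=config.ploidy,
                            )
                        )
    return obs
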