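"""Somatic expansion index from a calibrated fragment trace.

The HTT repeat PCR yields, for the expanded allele, a dominant "main" peak at
the inherited (reference) CAG length flanked by a ladder of minor peaks at
3-bp spacing.  Peaks left of the main peak mix polymerase-slippage stutter
with any somatic contractions and are discarded; peaks to the right can only
come from somatically expanded molecules.  The expansion index (EI) is

    EI = sum_i  (h_i / h_main) * i

over right-hand peaks at offset i CAG units from the main peak, keeping only
peaks whose height ratio reaches a relative threshold (default 3% of the main
peak, boundary inclusive).  An EI of 0 means no detectable mosaicism.  The EI
is invariant to uniform rescaling of all heights and to the presence of
sub-threshold or off-ladder peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .trace_io import FragmentTrace, Peak

__all__ = [
    "EIConfig",
    "ExpandedAlleleProfile",
    "ExpansionIndexResult",
    "CalibrationError",
    "NoExpandedAlleleError",
    "calibrate_repeats",
    "identify_main_peak",
    "compute_expansion_index",
    "mutant_allele_distribution",
    "ei_from_trace",
]


class CalibrationError(ValueError):
    """No usable anchor to convert peak sizes to repeat lengths."""


class NoExpandedAlleleError(ValueError):
    """The trace holds no peak at or above the expanded-allele repeat cutoff."""


@dataclass(frozen=True)
class EIConfig:
    """Tunable parameters of the EI pipeline.

    threshold
        Relative height threshold; right-hand peaks with ratio >= threshold
        are retained (peaks *below* 3% of the main peak are excluded).
    min_expanded_repeat
        Smallest repeat length considered an expanded allele; separates the
        expanded allele from the normal allele (normal range tops out near
        35; pathological alleles start at 36).
    bp_per_repeat
        Ladder spacing, 3 bp per CAG unit.
    off_ladder_tolerance_bp
        Maximum deviation from the nearest ladder rung before a peak is
        flagged off-ladder and excluded.
    """

    threshold: float = 0.03
    min_expanded_repeat: int = 36
    bp_per_repeat: float = 3.0
    off_ladder_tolerance_bp: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")


@dataclass
class ExpandedAlleleProfile:
    """Main expanded-allele peak plus right-hand expansion peaks as height ratios.

    ``right_ratios`` maps offset i (CAG units beyond the main peak, i >= 1)
    to height_i / main_height.  The main peak itself (offset 0) is implicit.
    """

    cag_main: int
    main_height: float
    right_ratios: dict[int, float]

    def __post_init__(self) -> None:
        if not self.main_height > 0:
            raise ValueError("main peak height must be positive")
        for offset, ratio in self.right_ratios.items():
            if int(offset) != offset or offset <= 0:
                raise ValueError(f"offsets must be positive integers, got {offset}")
            if ratio < 0:
                raise ValueError(f"ratio at offset {offset} is negative")


@dataclass(frozen=True)
class ExpansionIndexResult:
    ei: float
    threshold: float
    retained_offsets: tuple[int, ...]
    cag_main: int


def calibrate_repeats(
    trace: FragmentTrace,
    anchor_cag: int | None = None,
    anchor_size_bp: float | None = None,
    bp_per_repeat: float = 3.0,
    tolerance_bp: float = 1.0,
) -> FragmentTrace:
    """Assign a CAG repeat length to every peak.

    Either every peak already carries a called allele (``repeat_length`` set,
    e.g. from the export's Allele column), in which case the trace is returned
    unchanged, or an anchor (a known CAG count at a known fragment size, such
    as the per-plate internal standard) is supplied and each peak is snapped
    to the nearest rung of the 3-bp ladder through that anchor.  Peaks whose
    size deviates from the nearest rung by more than ``tolerance_bp`` are
    flagged off-ladder; they keep their nearest-rung assignment but are
    excluded by all downstream steps.
    """
    if anchor_cag is None and anchor_size_bp is None:
        if all(p.repeat_length is not None for p in trace.peaks):
            return trace
        raise CalibrationError(
            f"trace {trace.sample_id!r}: peaks lack called alleles and no anchor was supplied"
        )
    if anchor_cag is None or anchor_size_bp is None:
        raise CalibrationError("anchor requires both anchor_cag and anchor_size_bp")
    if bp_per_repeat <= 0:
        raise CalibrationError("bp_per_repeat must be positive")
    peaks: list[Peak] = []
    for p in trace.peaks:
        rung = round((p.size_bp - anchor_size_bp) / bp_per_repeat)
        repeat = anchor_cag + rung
        deviation = abs(p.size_bp - (anchor_size_bp + rung * bp_per_repeat))
        if repeat <= 0:
            peaks.append(replace(p, repeat_length=None, off_ladder=True))
        else:
            peaks.append(replace(p, repeat_length=repeat, off_ladder=deviation > tolerance_bp))
    return FragmentTrace(sample_id=trace.sample_id, peaks=peaks, plate_id=trace.plate_id)


def identify_main_peak(trace: FragmentTrace, min_expanded_repeat: int = 36) -> ExpandedAlleleProfile:
    """Locate the expanded-allele main peak and collect right-hand expansion peaks.

    The main peak is the tallest calibrated on-ladder peak with repeat length
    >= ``min_expanded_repeat``; ties break toward the larger repeat.  All
    peaks left of it (the normal allele, its cluster, and PCR stutter) are
    discarded.  Right-hand peaks are indexed by offset = repeat - cag_main;
    should several peaks calibrate to one rung their heights are summed.
    """
    usable = [p for p in trace.peaks if p.repeat_length is not None and not p.off_ladder]
    candidates = [p for p in usable if p.repeat_length >= min_expanded_repeat]
    if not candidates:
        raise NoExpandedAlleleError(
            f"trace {trace.sample_id!r}: no on-ladder peak with repeat length >= {min_expanded_repeat}"
        )
    main = max(candidates, key=lambda p: (p.height, p.repeat_length))
    heights: dict[int, float] = {}
    for p in usable:
        offset = p.repeat_length - main.repeat_length
        if offset > 0:
            heights[offset] = heights.get(offset, 0.0) + p.height
    ratios = {i: h / main.height for i, h in sorted(heights.items())}
    return ExpandedAlleleProfile(cag_main=main.repeat_length, main_height=main.height, right_ratios=ratios)


def compute_expansion_index(profile: ExpandedAlleleProfile, threshold: float = 0.03) -> ExpansionIndexResult:
    """Sum of retained height ratios weighted by their CAG offset."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    retained = tuple(i for i in sorted(profile.right_ratios) if profile.right_ratios[i] >= threshold)
    ei = sum(profile.right_ratios[i] * i for i in retained)
    return ExpansionIndexResult(ei=ei, threshold=threshold, retained_offsets=retained, cag_main=profile.cag_main)


def mutant_allele_distribution(profile: ExpandedAlleleProfile, threshold: float = 0.03) -> dict[int, float]:
    """Percent of mutant alleles at each retained expansion length.

    Offset 0 is the main (inherited) expanded allele.  Percentages are
    height shares over the main peak plus retained right-hand peaks and sum
    to 100.
    """
    retained = compute_expansion_index(profile, threshold).retained_offsets
    heights = {0: profile.main_height}
    for i in retained:
        heights[i] = profile.right_ratios[i] * profile.main_height
    total = sum(heights.values())
    return {i: 100.0 * h / total for i, h in heights.items()}


def ei_from_trace(
    trace: FragmentTrace,
    config: EIConfig = EIConfig(),
    anchor_cag: int | None = None,
    anchor_size_bp: float | None = None,
) -> ExpansionIndexResult:
    """Full pipeline: calibrate, identify the main peak, compute the EI."""
    calibrated = calibrate_repeats(
        trace,
        anchor_cag=anchor_cag,
        anchor_size_bp=anchor_size_bp,
        bp_per_repeat=config.bp_per_repeat,
        tolerance_bp=config.off_ladder_tolerance_bp,
    )
    profile = identify_main_peak(calibrated, min_expanded_repeat=config.min_expanded_repeat)
    return compute_expansion_index(profile, threshold=config.threshold)
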