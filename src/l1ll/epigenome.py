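"""Peak-set integration with L1 promoters.

Two analyses share this module: calling active L1 promoters from H3K4me3
peaks (a promoter is "marked" when a significant peak overlaps its first
900 bp), and classifying dCas9 CUT&RUN peaks from a CRISPRi experiment
into on-target (overlapping a full-length young L1) and off-target binding
sites, after removing peaks shared with the non-targeting control — those
are technical artifacts of the crosslinked dCas9 CUT&RUN, not gRNA
binding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotations import PromoterWindow, TELocus
from .intervals import GenomicInterval, expand_interval, intersect_sets


@dataclass(frozen=True)
class Peak:
    peak_id: str
    interval: GenomicInterval
    p_value: float
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.peak_id}: p-value must be in (0, 1], got {self.p_value}")


def read_peaks_bed(path: str | Path) -> list[Peak]:
    """Read peaks from BED6+1 (name, score, strand, p-value)."""
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
                p_value = float(fields[6]) if len(fields) > 6 else 1.0
                peaks.append(
                    Peak(name, GenomicInterval(chrom, start, end, "."), p_value, score)
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for peak in peaks:
            iv = peak.interval
            score = peak.score if peak.score is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peak.peak_id}\t{score}\t.\t{peak.p_value}\n"
            )


def significant_peaks(peaks: Sequence[Peak], alpha: float = 0.05) -> list[Peak]:
    """Peaks with caller-reported p-value strictly below ``alpha``."""
    return [p for p in peaks if p.p_value < alpha]


@dataclass
class PromoterMarkTable:
    """Per-locus promoter marking: marked iff supported by >= 1 peak."""

    support: dict[str, list[str]]

    @property
    def marked(self) -> set[str]:
        return {locus for locus, peaks in self.support.items() if peaks}

    def is_marked(self, locus_id: str) -> bool:
        return bool(self.support.get(locus_id))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": list(self.support),
                "marked": [bool(v) for v in self.support.values()],
                "supporting_peaks": [",".join(v) for v in self.support.values()],
            }
        )


def mark_promoters(
    peaks: Sequence[Peak],
    promoters: Sequence[PromoterWindow],
    flank: int = 0,
) -> PromoterMarkTable:
    """Mark each promoter overlapped >= 1 bp by a (flank-expanded) peak."""
    peak_ivs = [expand_interval(p.interval, flank) for p in peaks]
    prom_ivs = [p.interval for p in promoters]
    support: dict[str, list[str]] = {p.locus_id: [] for p in promoters}
    for pi, qi in intersect_sets(peak_ivs, prom_ivs):
        support[promoters[qi].locus_id].append(peaks[pi].peak_id)
    return PromoterMarkTable(support)


@dataclass
class Dcas9Classification:
    on_target: list[Peak]
    off_target: list[Peak]
    #: treatment peaks dropped because they overlap a control peak — the
    #: artifact class shared with non-targeting cells.
    n_control_dropped: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": ["on_target", "off_target", "control_shared_dropped"],
                "n_peaks": [len(self.on_target), len(self.off_target), self.n_control_dropped],
            }
        )


def classify_dcas9_peaks(
    treatment_peaks: Sequence[Peak],
    control_peaks: Sequence[Peak],
    fl_young_loci: Sequence[TELocus],
    flank: int = 100,
    expand_control: bool = False,
) -> Dcas9Classification:
    """Classify dCas9 CRISPRi peaks as on- or off-target gRNA binding sites.

    Treatment peaks are expanded by ``flank`` bp on both sides; any peak
    overlapping a control peak (expanded too when ``expand_control``) is
    discarded as a shared technical artifact. Survivors overlapping the
    body of a full-length young L1 are on-target; the rest are off-target.
    Inputs are expected to be significance-filtered already.
    """
    expanded = [expand_interval(p.interval, flank) for p in treatment_peaks]
    ctrl_ivs = [
        expand_interval(p.interval, flank) if expand_control else p.interval
        for p in control_peaks
    ]
    shared = {i for i, _ in intersect_sets(expanded, ctrl_ivs)}
    survivor_idx = [i for i in range(len(treatment_peaks)) if i not in shared]
    locus_ivs = [l.interval for l in fl_young_loci]
    survivor_ivs = [expanded[i] for i in survivor_idx]
    on_positions = {pos for pos, _ in intersect_sets(survivor_ivs, locus_ivs)}
    on = [treatment_peaks[i] for pos, i in enumerate(survivor_idx) if pos in on_positions]
    off = [treatment_peaks[i] for pos, i in enumerate(survivor_idx) if pos not in on_positions]
    return Dcas9Classification(on, off, len(shared))
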