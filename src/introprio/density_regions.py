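"""Window-based variant densities and highly polymorphic region calls.

Variant counts are tallied in non-overlapping windows (1 Mb by default) and
windows whose SNP or InDel count strictly exceeds its threshold are merged
into labelled regions ("p{chrom}_{k}").  Thresholds are either absolute
per-window counts or a fold over the genome-wide mean window count; runs of
qualifying windows separated by at most ``merge_gap_windows`` quiet windows
are merged, which absorbs single noisy windows inside a real introgression.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CoordinateError, InputError
from .variant_io import INDEL, SNP, VariantRecord

DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # inclusive
    snp_count: int
    indel_count: int


@dataclass(frozen=True)
class PolymorphicRegion:
    label: str
    chrom: str
    start: int
    end: int
    snp_total: int
    indel_total: int
    trigger: str  # snp | indel | both


@dataclass(frozen=True)
class RegionConfig:
    """Detection settings.

    ``threshold_mode="fold_mean"`` (default) interprets the thresholds as a
    multiple of the genome-wide mean per-window count for each variant
    class; ``"absolute"`` takes them as per-window counts directly.
    """

    window_bp: int = DEFAULT_WINDOW_BP
    snp_threshold: float = 3.0
    indel_threshold: float = 3.0
    threshold_mode: str = "fold_mean"
    merge_gap_windows: int = 1

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if self.snp_threshold <= 0 or self.indel_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.threshold_mode not in ("fold_mean", "absolute"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.merge_gap_windows < 0:
            raise ValueError("merge_gap_windows must be >= 0")


def count_in_windows(
    variants: Iterable[VariantRecord],
    chrom_lengths: dict[str, int],
    cfg: RegionConfig | None = None,
) -> list[Window]:
    """Tile every chromosome with non-overlapping windows and count
    SNP/InDel records per window.  Window i covers [(i-1)W+1, iW], clipped
    to the chromosome end."""
    cfg = cfg or RegionConfig()
    W = cfg.window_bp
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, length in chrom_lengths.items():
        n = max(1, -(-length // W))
        per_chrom[chrom] = (np.zeros(n, dtype=int), np.zeros(n, dtype=int))
    for v in variants:
        if v.chrom not in per_chrom:
            raise CoordinateError(f"variant chromosome {v.chrom!r} has no declared length")
        length = chrom_lengths[v.chrom]
        if v.pos > length:
            raise CoordinateError(f"{v.chrom}:{v.pos} beyond chromosome length {length}")
        idx = (v.pos - 1) // W
        snp, indel = per_chrom[v.chrom]
        if v.vclass == SNP:
            snp[idx] += 1
        else:
            indel[idx] += 1
    windows = []
    for chrom, length in chrom_lengths.items():
        snp, indel = per_chrom[chrom]
        for i in range(len(snp)):
            start = i * W + 1
            end = min((i + 1) * W, length)
            windows.append(Window(chrom, start, end, int(snp[i]), int(indel[i])))
    return windows


def _chrom_tag(chrom: str) -> str:
    """'chr07'/'SL4.0ch07' -> '7'; anything else passes through."""
    m = re.search(r"(\d+)$", chrom)
    return str(int(m.group(1))) if m else chrom


def resolve_thresholds(windows: Sequence[Window], cfg: RegionConfig) -> tuple[float, float]:
    if cfg.threshold_mode == "absolute":
        return cfg.snp_threshold, cfg.indel_threshold
    snp_mean = float(np.mean([w.snp_count for w in windows])) if windows else 0.0
    indel_mean = float(np.mean([w.indel_count for w in windows])) if windows else 0.0
    return cfg.snp_threshold * snp_mean, cfg.indel_threshold * indel_mean


def detect_polymorphic_regions(
    windows: Sequence[Window], cfg: RegionConfig | None = None
) -> list[PolymorphicRegion]:
    """Call highly polymorphic regions from tiled, sorted windows.

    A window qualifies when its SNP count strictly exceeds the SNP
    threshold or its InDel count strictly exceeds the InDel threshold.
    """
    cfg = cfg or RegionConfig()
    snp_thr, indel_thr = resolve_thresholds(windows, cfg)
    by_chrom: dict[str, list[Window]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    regions: list[PolymorphicRegion] = []
    for chrom, ws in by_chrom.items():
        prev_end = 0
        for w in ws:
            if w.start <= prev_end:
                raise InputError(f"{chrom}: windows unsorted or overlapping at {w.start}")
            prev_end = w.end
        qual = [
            (w.snp_count > snp_thr, w.indel_count > indel_thr) for w in ws
        ]
        runs: list[list[int]] = []  # index runs of qualifying windows incl. tolerated gaps
        current: list[int] | None = None
        gap = 0
        for i, (qs, qi) in enumerate(qual):
            if qs or qi:
                if current is None:
                    current = [i]
                else:
                    current.extend(range(current[-1] + 1, i + 1))
                gap = 0
            elif current is not None:
                gap += 1
                if gap > cfg.merge_gap_windows:
                    runs.append(current)
                    current = None
                    gap = 0
        if current is not None:
            runs.append(current)
        tag = _chrom_tag(chrom)
        for k, run in enumerate(runs, start=1):
            sub = [ws[i] for i in run]
            snp_trig = any(qual[i][0] for i in run)
            indel_trig = any(qual[i][1] for i in run)
            trigger = "both" if snp_trig and indel_trig else ("snp" if snp_trig else "indel")
            regions.append(
                PolymorphicRegion(
                    label=f"p{tag}_{k}",
                    chrom=chrom,
                    start=sub[0].start,
                    end=sub[-1].end,
                    snp_total=sum(w.snp_count for w in sub),
                    indel_total=sum(w.indel_count for w in sub),
                    trigger=trigger,
                )
            )
    return regions


# ---------------------------------------------------------------------------
# Tabular I/O (TSV round-trips; BED export is 0-based half-open)

def windows_to_frame(windows: Iterable[Window]) -> pd.DataFrame:
    return pd.DataFrame(
        [(w.chrom, w.start, w.end, w.snp_count, w.indel_count) for w in windows],
        columns=["chrom", "start", "end", "snp_count", "indel_count"],
    )


def write_windows_tsv(windows: Iterable[Window], path: str | Path) -> None:
    windows_to_frame(windows).to_csv(path, sep="\t", index=False)


def read_windows_tsv(path: str | Path) -> list[Window]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [Window(r.chrom, int(r.start), int(r.end), int(r.snp_count), int(r.indel_count))
            for r in df.itertuples(index=False)]


def regions_to_frame(regions: Iterable[PolymorphicRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.label, r.chrom, r.start, r.end, r.snp_total, r.indel_total, r.trigger) for r in regions],
        columns=["label", "chrom", "start", "end", "snp_total", "indel_total", "trigger"],
    )


def write_regions_tsv(regions: Iterable[PolymorphicRegion], path: str | Path) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)


def read_regions_tsv(path: str | Path) -> list[PolymorphicRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        PolymorphicRegion(r.label, r.chrom, int(r.start), int(r.end),
                          int(r.snp_total), int(r.indel_total), r.trigger)
        for r in df.itertuples(index=False)
    ]


def write_regions_bed(regions: Iterable[PolymorphicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label}\n")
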