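"""Variant-allele-frequency windows and loss-of-heterozygosity scan.

In a triploid clone, reads at a reference-heterozygous site carry the
alternative allele with expected frequency dosage/3 (1/3 or 2/3). Loss of
heterozygosity converts a region to homozygosity and shifts the windowed
mean VAF away from that expectation. The scan averages per-site VAF over
consecutive windows of a fixed number of heterozygous positions (not base
pairs), compares each window mean with its reference-dosage expectation,
and flags windows whose absolute deviation exceeds a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VafConfig",
    "VafWindow",
    "VafTrack",
    "select_het_positions",
    "vaf",
    "windowed_vaf",
    "loh_scan",
    "sample_read_arrays",
]


@dataclass(frozen=True)
class VafConfig:
    min_quality: float = 30.0  # strict >
    min_depth: int = 5  # strict >
    window_size: int = 10_000  # heterozygous positions per window
    loh_delta: float = 0.10  # |observed - expected| flag threshold

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not 0 < self.loh_delta < 0.5:
            raise ValueError("loh_delta must be in (0, 0.5)")


def select_het_positions(ref, cfg: VafConfig) -> np.ndarray:
    """Indices of usable reference-heterozygous sites.

    Sites with reference dosage 1 or 2, quality strictly above
    cfg.min_quality and depth strictly above cfg.min_depth, in
    (contig, position) order (the profile's storage order).
    """
    mask = ref.het_mask & (ref.quality > cfg.min_quality) & (ref.depth > cfg.min_depth)
    return np.flatnonzero(mask)


def vaf(alt_reads: int, depth: int) -> float:
    """Per-site variant allele frequency, alt reads / total reads."""
    if depth <= 0:
        raise ValueError("VAF undefined at zero depth")
    if not 0 <= alt_reads <= depth:
        raise ValueError("alt_reads outside [0, depth]")
    return alt_reads / depth


@dataclass(frozen=True)
class VafWindow:
    contig: str
    start: int  # 1-based position of first site
    end: int  # 1-based position of last site
    n_sites: int
    mean_vaf: float
    expected_vaf: float
    partial: bool  # fewer sites than the window size


@dataclass
class VafTrack:
    sample_id: str
    windows: list[VafWindow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": self.sample_id,
                    "contig": w.contig,
                    "start": w.start,
                    "end": w.end,
                    "n_sites": w.n_sites,
                    "mean_vaf": w.mean_vaf,
                    "expected_vaf": w.expected_vaf,
                    "partial": w.partial,
                }
                for w in self.windows
            ]
        )

    def global_mean(self) -> float:
        """Site-weighted mean of window means (= global mean VAF)."""
        n = sum(w.n_sites for w in self.windows)
        return sum(w.mean_vaf * w.n_sites for w in self.windows) / n


def windowed_vaf(
    sample_id: str,
    contigs: np.ndarray,
    positions: np.ndarray,
    alt_reads: np.ndarray,
    depths: np.ndarray,
    ref_dosage: np.ndarray,
    cfg: VafConfig,
) -> VafTrack:
    """Average VAF over consecutive blocks of het positions.

    Inputs are aligned arrays over the selected het positions, ordered by
    (contig, position). Windows never span contig boundaries; the final
    partial block of each contig is retained and flagged. Sites with zero
    depth are skipped (they contribute to neither mean). The expected VAF
    of a window is the mean of dosage/3 over its usable sites.
    """
    contigs = np.asarray(contigs)
    positions = np.asarray(positions)
    alt_reads = np.asarray(alt_reads, dtype=float)
    depths = np.asarray(depths, dtype=float)
    ref_dosage = np.asarray(ref_dosage, dtype=float)

    windows: list[VafWindow] = []
    if positions.size == 0:
        warnings.warn("no valid het positions: empty VAF track", stacklevel=2)
        return VafTrack(sample_id=sample_id, windows=windows)

    for contig in pd.unique(contigs):
        sel = np.flatnonzero(contigs == contig)
        for block_start in range(0, sel.size, cfg.window_size):
            block = sel[block_start : block_start + cfg.window_size]
            usable = block[depths[block] > 0]
            if usable.size == 0:
                continue
            v = alt_reads[usable] / depths[usable]
            expected = float(np.mean(ref_dosage[usable] / 3.0))
            windows.append(
                VafWindow(
                    contig=str(contig),
                    start=int(positions[block[0]]),
                    end=int(positions[block[-1]]),
                    n_sites=int(usable.size),
                    mean_vaf=float(v.mean()),
                    expected_vaf=expected,
                    partial=block.size < cfg.window_size,
                )
            )
    return VafTrack(sample_id=sample_id, windows=windows)


def loh_scan(track: VafTrack, cfg: VafConfig) -> pd.DataFrame:
    """Flag windows whose mean VAF deviates from expectation by > loh_delta.

    Returns the full window table with deviation, direction ("loss" when
    the observed mean moves toward 0 or 1 away from the heterozygous
    expectation) and a boolean flag.
    """
    if not track.windows:
        raise ValueError("empty VAF track")
    df = track.to_frame()
    df["deviation"] = df["mean_vaf"] - df["expected_vaf"]
    df["flagged"] = df["deviation"].abs() > cfg.loh_delta
    df["direction"] = np.where(df["deviation"] > 0, "up", "down")
    return df


def sample_read_arrays(sites, sample_id: str, ref, het_indices: np.ndarray):
    """Extract aligned (contig, pos, alt, depth, ref dosage) arrays for one
    sample at the selected reference-het positions, from parsed VCF sites.

    Sites absent from the VCF (not emitted or filtered) get zero depth and
    are skipped by the windowing stage.
    """
    lookup = {(s.contig, s.position): s for s in sites}
    contigs = ref.contigs[het_indices]
    positions = ref.positions[het_indices]
    alt = np.zeros(het_indices.size)
    depth = np.zeros(het_indices.size)
    for k, (c, p) in enumerate(zip(contigs, positions)):
        site = lookup.get((str(c), int(p)))
        if site is None:
            continue
        call = site.calls.get(sample_id)
        if call is None:
            continue
        alt[k] = call.alt_reads
        depth[k] = call.depth
    return contigs, positions, alt, depth, ref.dosage[het_indices]
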