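"""Sliding-window heterozygosity analysis.

Variants in the immediate vicinity of a rare inherited dominant trait
variant tend to show a heterozygote excess: if f is the minor population
allele frequency of a nearby variant, carriers are heterozygous there with
probability exceeding 1 - f, against a population heterozygosity of only
2f(1 - f).  Scanning each individual's chromosome with a window of 2m + 1
adjacent variants and computing the window-average heterozygosity
H = h/(g + h) (h heterozygous, g homozygous genotypes in the window)
therefore produces local peaks of H around dominant disease variants.

For each individual the scan extracts runs of increasing H up to a maximum
H_max followed by decreasing H; the positions of the H_max peaks are that
individual's candidate disease-variant locations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import HET, HOM, CandidateSet, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class HProfile:
    """Window-average heterozygosity along one chromosome of one individual.

    ``h_values[i]`` is H for the window centred on variant i, NaN for the
    first and last m variants and wherever the window contains no called
    genotypes (g + h = 0).
    """

    individual: str
    chrom: str
    pos: np.ndarray
    h_values: np.ndarray
    m: int


@dataclass
class HmaxSegment:
    """A rising-then-falling run of window heterozygosity with its peak."""

    individual: str
    chrom: str
    start_pos: int
    end_pos: int
    peak_pos: int
    peak_h: float


def _window_counts(indicator: np.ndarray, m_lo: np.ndarray, m_hi: np.ndarray) -> np.ndarray:
    """Sum of ``indicator`` over index windows [i - m, i + m], via cumsums."""
    cs = np.concatenate(([0], np.cumsum(indicator, dtype=np.int64)))
    idx = np.arange(len(indicator))
    return cs[idx + m_hi + 1] - cs[idx - m_lo]


def window_heterozygosity(
    gm: GenotypeMatrix, individual: str, m: int | np.ndarray = 50
) -> list[HProfile]:
    """Compute H = h/(g + h) in a sliding window of 2m + 1 variants.

    The window slides one variant at a time; H is defined for variant
    indices m..M-1-m of each chromosome, with missing genotypes excluded
    from both h and g.  Chromosomes shorter than 2m + 1 variants are
    skipped with a warning.  Returns one :class:`HProfile` per (retained)
    chromosome.

    ``m`` may also be a per-variant vector of half-widths (length equal to
    the total variant count), an extension hook for dynamically chosen
    window sizes; H is then defined where the per-position window fits on
    the chromosome.
    """
    row = gm.codes[gm.individual_index(individual)]
    m_arr = np.asarray(m)
    scalar_m = m_arr.ndim == 0
    if scalar_m:
        if int(m_arr) < 1:
            raise ValueError(f"window half-width m must be >= 1, got {m}")
    elif len(m_arr) != gm.n_variants:
        raise ValueError("per-position m vector must match the variant count")
    profiles: list[HProfile] = []
    for c in gm.variants.chromosomes:
        sl = gm.variants.block(c)
        codes = row[sl]
        M = len(codes)
        mv = np.broadcast_to(m_arr if scalar_m else m_arr[sl], (M,)).astype(np.int64)
        idx = np.arange(M)
        fits = (idx - mv >= 0) & (idx + mv <= M - 1)
        if not fits.any():
            warnings.warn(
                f"chromosome {c}: {M} variants, window 2m+1 does not fit; skipped"
            )
            continue
        mv_c = np.where(fits, mv, 0)
        h = _window_counts((codes == HET).astype(np.int64), mv_c, mv_c)
        g = _window_counts((codes == HOM).astype(np.int64), mv_c, mv_c)
        denom = g + h
        H = np.full(M, np.nan)
        ok = fits & (denom > 0)
        H[ok] = h[ok] / denom[ok]
        profiles.append(
            HProfile(individual, c, gm.variants.pos[sl].copy(), H, int(mv.max()))
        )
    return profiles


def detect_hmax_segments(
    hp: HProfile,
    min_rise: int = 3,
    min_fall: int = 3,
    min_prominence: float = 0.1,
) -> list[HmaxSegment]:
    """Extract maximal rising-then-falling runs of H and their peaks.

    A segment runs non-decreasing from its start to a peak and
    non-increasing from the peak to its end (plateaus allowed), and is kept
    if it contains at least ``min_rise`` strict increases before the peak,
    at least ``min_fall`` strict decreases after it, and its peak exceeds
    the larger endpoint H by at least ``min_prominence``.  When the peak is
    a plateau, ``peak_pos`` is the first variant of the maximal-H plateau.
    Consecutive segments may share their boundary variant (the valley).

    Positions where H is undefined are excluded from the analysis; the
    defined values are treated as one contiguous sequence.
    """
    defined = np.flatnonzero(~np.isnan(hp.h_values))
    H = hp.h_values[defined]
    n = len(H)
    segments: list[HmaxSegment] = []
    i = 0
    while i < n - 1:
        if H[i + 1] < H[i]:
            i += 1
            continue
        start = i
        j = i
        while j + 1 < n and H[j + 1] >= H[j]:
            j += 1
        peak_end = j
        while j + 1 < n and H[j + 1] <= H[j]:
            j += 1
        end = j
        rises = int(np.count_nonzero(H[start + 1 : peak_end + 1] > H[start:peak_end]))
        falls = int(np.count_nonzero(H[peak_end + 1 : end + 1] < H[peak_end:end]))
        peak_h = float(H[peak_end])
        prominence = peak_h - max(float(H[start]), float(H[end]))
        if rises >= min_rise and falls >= min_fall and prominence >= min_prominence:
            # H is non-decreasing on [start, peak_end], so the first index
            # attaining the maximum is the first variant of the peak plateau
            peak_first = start + int(np.argmax(H[start : peak_end + 1] == peak_h))
            segments.append(
                HmaxSegment(
                    individual=hp.individual,
                    chrom=hp.chrom,
                    start_pos=int(hp.pos[defined[start]]),
                    end_pos=int(hp.pos[defined[end]]),
                    peak_pos=int(hp.pos[defined[peak_first]]),
                    peak_h=peak_h,
                )
            )
        i = end
    return segments


def scan_all(
    gm: GenotypeMatrix,
    m: int | np.ndarray = 50,
    min_rise: int = 3,
    min_fall: int = 3,
    min_prominence: float = 0.1,
) -> list[CandidateSet]:
    """Run the heterozygosity scan for every individual.

    Returns one :class:`CandidateSet` per individual (in matrix order)
    holding the H_max peak positions across all chromosomes, and logs the
    per-individual candidate counts k and their total.
    """
    out: list[CandidateSet] = []
    total = 0
    for individual in gm.individuals:
        positions: list[tuple[str, int]] = []
        peak_h: list[float] = []
        for hp in window_heterozygosity(gm, individual, m):
            for seg in detect_hmax_segments(hp, min_rise, min_fall, min_prominence):
                positions.append((seg.chrom, seg.peak_pos))
                peak_h.append(seg.peak_h)
        cs = CandidateSet(individual, positions, peak_h)
        logger.info("individual %s: k = %d candidate positions", individual, cs.k)
        total += cs.k
        out.append(cs)
    logger.info(
        "scan complete: %d individuals, %d candidate positions in total",
        len(out),
        total,
    )
    return out
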