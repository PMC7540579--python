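"""Runs of consecutive variants shared by significantly many individuals.

Once a run-inclusion threshold N_crit(d) is known — the smallest N_f whose
empirical p-value falls below 0.05, floored at 3 — the variants with
N_f >= N_crit cluster into maximal runs of consecutive variants.  These
runs are the method's deliverable: a short list of genomic regions
expected to harbor the shared susceptibility variants, summarized by run
count N_r, span lengths, the total N_var of significant variants, and
overlap with a region of interest (e.g. a gene with a 1 Mb flank on each
side).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DataError
from .sharing import SharingProfile, SignificanceTable

logger = logging.getLogger(__name__)


@dataclass
class SignificantRun:
    """Maximal stretch of consecutive variants with N_f >= N_crit."""

    chrom: str
    start_pos: int
    end_pos: int
    n_variants: int
    max_nf: int
    overlaps_roi: bool = False

    @property
    def length_kb(self) -> float:
        """Span from first to last variant in kb (0 for single-variant runs)."""
        return (self.end_pos - self.start_pos) / 1000.0


@dataclass
class RegionOfInterest:
    """A target genomic interval, 1-based closed (e.g. gene +/- flank)."""

    chrom: str
    start_pos: int
    end_pos: int

    def __post_init__(self) -> None:
        if not self.start_pos < self.end_pos:
            raise ValueError(
                f"ROI start must be < end, got {self.start_pos}..{self.end_pos}"
            )

    @classmethod
    def parse(cls, text: str) -> "RegionOfInterest":
        """Parse 'chrom:start-end' (1-based closed), e.g. 'chr17:41196312-43277500'."""
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", text.strip())
        if not m:
            raise DataError(f"cannot parse region {text!r}; expected chrom:start-end")
        return cls(m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))

    def with_flank(self, flank_bp: int) -> "RegionOfInterest":
        """The region extended by ``flank_bp`` at either end (floored at 1)."""
        return RegionOfInterest(
            self.chrom, max(1, self.start_pos - flank_bp), self.end_pos + flank_bp
        )


@dataclass
class RunSummary:
    """All significant runs for one d, with Table-style aggregates."""

    runs: list[SignificantRun]
    n_crit: int
    n_var: int  # total variants with N_f >= n_crit

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def l_avg_kb(self) -> float:
        """Mean run span in kb (NaN when there are no runs)."""
        if not self.runs:
            return float("nan")
        return float(np.mean([r.length_kb for r in self.runs]))


def find_runs(profile: SharingProfile, n_crit: int) -> RunSummary:
    """Find maximal runs of consecutive variants with N_f >= n_crit.

    A run breaks at any variant with N_f < n_crit and at chromosome
    boundaries.  ``n_var`` counts all variants with N_f >= n_crit and
    always equals the sum of run sizes.
    """
    if n_crit < 1:
        raise ValueError(f"n_crit must be >= 1, got {n_crit}")
    runs: list[SignificantRun] = []
    for c in profile.variants.chromosomes:
        sl = profile.variants.block(c)
        nf = profile.nf[sl]
        pos = profile.variants.pos[sl]
        mask = (nf >= n_crit).astype(np.int8)
        edges = np.diff(np.concatenate(([0], mask, [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for a, b in zip(starts, ends):
            runs.append(
                SignificantRun(
                    chrom=c,
                    start_pos=int(pos[a]),
                    end_pos=int(pos[b - 1]),
                    n_variants=int(b - a),
                    max_nf=int(nf[a:b].max()),
                )
            )
    n_var = int(np.count_nonzero(profile.nf >= n_crit))
    return RunSummary(runs=runs, n_crit=int(n_crit), n_var=n_var)


def select_n_crit(sig_table: SignificanceTable, d_kb: float, floor: int = 3) -> int:
    """Run-inclusion threshold: smallest t with p(t, d) < alpha, floored.

    Errors if no threshold reaches significance at this d (too few
    individuals or too large a d).
    """
    return sig_table.n_crit(d_kb, floor=floor)


def overlap_regions(
    runs: Sequence[SignificantRun], roi: RegionOfInterest
) -> list[SignificantRun]:
    """Flag runs whose closed interval intersects the ROI; return the hits.

    Touching endpoints count as overlapping (closed-interval convention).
    """
    hits: list[SignificantRun] = []
    for r in runs:
        r.overlaps_roi = (
            r.chrom == roi.chrom
            and r.start_pos <= roi.end_pos
            and roi.start_pos <= r.end_pos
        )
        if r.overlaps_roi:
            hits.append(r)
    return hits


def run_table(summary: RunSummary, roi: RegionOfInterest | None = None) -> pd.DataFrame:
    """Tabulate runs (1-based run index, coordinates, N = max N_f, ROI flag)."""
    if roi is not None:
        overlap_regions(summary.runs, roi)
    return pd.DataFrame(
        {
            "run": np.arange(1, summary.n_runs + 1),
            "chrom": [r.chrom for r in summary.runs],
            "start_pos": [r.start_pos for r in summary.runs],
            "end_pos": [r.end_pos for r in summary.runs],
            "n_variants": [r.n_variants for r in summary.runs],
            "N": [r.max_nf for r in summary.runs],
            "length_kb": [r.length_kb for r in summary.runs],
            "in_roi": [bool(r.overlaps_roi) for r in summary.runs],
        }
    )


def write_runs_tsv(
    summary: RunSummary, path, roi: RegionOfInterest | None = None
) -> None:
    run_table(summary, roi).to_csv(path, sep="\t", index=False)


def write_runs_bed(summary: RunSummary, path) -> None:
    """Write runs as BED (0-based half-open): start-1, end; score = max N_f."""
    with open(path, "w") as fh:
        for i, r in enumerate(summary.runs, start=1):
            fh.write(
                f"{r.chrom}\t{r.start_pos - 1}\t{r.end_pos}\trun{i}\t{r.max_nf}\n"
            )


def plot_runs(
    summary: RunSummary,
    roi: RegionOfInterest | None = None,
    ax=None,
):
    """Bar chart of run index vs N (max N_f per run), ROI runs highlighted.

    Cosmetic companion to :func:`run_table`; returns the matplotlib axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    table = run_table(summary, roi)
    colors = ["#d62728" if flag else "#1f77b4" for flag in table["in_roi"]]
    ax.bar(table["run"], table["N"], color=colors, width=0.8)
    ax.set_xlabel("run index $n_r$")
    ax.set_ylabel("individuals $N$")
    ax.set_title(f"Runs of variants with $N_f \\geq$ {summary.n_crit}")
    return ax
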