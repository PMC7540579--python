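"""Model/results interface for shared-genomic-segment analysis.

:class:`SharedSegmentModel` bundles a variant universe with per-individual
candidate positions and a testing configuration (d grid, permutation
count); :meth:`SharedSegmentModel.fit` runs the sharing statistic and its
permutation null for every d and returns a
:class:`SharedSegmentResults` carrying the N_f profiles, null tables,
empirical p-values, the p(N_f, d) significance table, and lazy access to
significant-run summaries and plots.

Typical use::

    gm = read_genotypes("cohort.vcf.gz")
    model = SharedSegmentModel.from_genotypes(gm, m=50, maf_max=0.05,
                                              d_grid=(10, 50, 100), n_perm=10_000)
    res = model.fit(seed=1)
    print(res.summary())
    res.runs(50)          # RunSummary at d = 50 kb
    res.pvalues(50)       # per-variant empirical p-values
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CandidateSet,
    FilterReport,
    GenotypeMatrix,
    VariantTable,
    candidate_summary,
    filter_variants,
)
from .runs import RegionOfInterest, RunSummary, find_runs, plot_runs, run_table
from .scan import scan_all
from .sharing import (
    NullTable,
    SharingProfile,
    SignificanceTable,
    count_sharing,
    empirical_pvalues,
    format_pvalue,
    permutation_null,
)

logger = logging.getLogger(__name__)

DEFAULT_D_GRID: tuple[float, ...] = (2, 5, 10, 20, 50, 100, 200, 500)


class SharedSegmentModel:
    """Equivalence test for sharing of candidate disease-variant positions.

    Parameters
    ----------
    candidates
        One :class:`CandidateSet` per individual (H_max peak positions).
    variants
        The variant universe the candidates were estimated on; permuted
        candidate positions are re-drawn from these positions.
    d_grid
        Half-widths d in kb at which sharing is evaluated.
    n_perm
        Number of permutation samples, including the observed data when
        ``fit(include_observed=True)`` (the default); the smallest
        attainable p is then 1/n_perm.
    n_crit_floor
        Minimum run-inclusion threshold N_crit (default 3).
    null_mode
        ``"pooled"`` (one p per (N_f, d), pooled over variants) or
        ``"per_variant"``.
    """

    def __init__(
        self,
        candidates: Sequence[CandidateSet],
        variants: VariantTable,
        d_grid: Sequence[float] = DEFAULT_D_GRID,
        n_perm: int = 10_000,
        n_crit_floor: int = 3,
        alpha: float = 0.05,
        null_mode: str = "pooled",
    ):
        self.candidates = list(candidates)
        self.variants = variants
        self.d_grid = tuple(float(d) for d in d_grid)
        if len(set(self.d_grid)) != len(self.d_grid):
            raise ValueError("d_grid contains duplicates")
        self.n_perm = int(n_perm)
        self.n_crit_floor = int(n_crit_floor)
        self.alpha = float(alpha)
        self.null_mode = null_mode
        self.filter_report: FilterReport | None = None
        self.scan_params: dict | None = None

    @classmethod
    def from_genotypes(
        cls,
        gm: GenotypeMatrix,
        m: int = 50,
        maf_max: float = 0.05,
        min_rise: int = 3,
        min_fall: int = 3,
        min_prominence: float = 0.1,
        **kwargs,
    ) -> "SharedSegmentModel":
        """Build the model from genotypes: filter variants, scan for H_max peaks.

        Applies the monomorphic and MAF > ``maf_max`` filters, runs the
        sliding-window heterozygosity scan per individual, and uses the
        peak positions as candidates over the filtered variant universe.
        """
        filtered, report = filter_variants(gm, maf_max=maf_max)
        candidates = scan_all(
            filtered,
            m=m,
            min_rise=min_rise,
            min_fall=min_fall,
            min_prominence=min_prominence,
        )
        model = cls(candidates, filtered.variants, **kwargs)
        model.filter_report = report
        model.scan_params = {
            "m": m,
            "maf_max": maf_max,
            "min_rise": min_rise,
            "min_fall": min_fall,
            "min_prominence": min_prominence,
        }
        return model

    @property
    def n_individuals(self) -> int:
        return len(self.candidates)

    def fit(self, seed: int = 0, include_observed: bool = True) -> "SharedSegmentResults":
        """Compute N_f profiles and permutation nulls over the d grid."""
        k_list = [cs.k for cs in self.candidates]
        sharing: dict[float, SharingProfile] = {}
        nulls: dict[float, NullTable] = {}
        for d in self.d_grid:
            logger.info("d = %g kb: counting sharing and permuting", d)
            prof = count_sharing(self.variants, self.candidates, d)
            nulls[d] = permutation_null(
                self.variants,
                k_list,
                d,
                self.n_perm,
                seed,
                observed=prof if include_observed else None,
                mode=self.null_mode,
                target_index=None if self.null_mode == "pooled" else 0,
            )
            sharing[d] = prof
        return SharedSegmentResults(self, sharing, nulls, seed)


class SharedSegmentResults:
    """Fitted sharing statistics, nulls, p-values and run summaries."""

    def __init__(
        self,
        model: SharedSegmentModel,
        sharing: dict[float, SharingProfile],
        nulls: dict[float, NullTable],
        seed: int,
    ):
        self.model = model
        self.sharing = sharing
        self.nulls = nulls
        self.seed = int(seed)
        self._sig_table: SignificanceTable | None = None

    # -- low-level accessors -------------------------------------------------

    def _d(self, d_kb: float) -> float:
        for d in self.model.d_grid:
            if abs(d - float(d_kb)) < 1e-9:
                return d
        raise KeyError(f"d = {d_kb} kb not in the fitted grid {self.model.d_grid}")

    @property
    def sig_table(self) -> SignificanceTable:
        """The p(N_f, d) significance table pooled over variants."""
        if self._sig_table is None:
            self._sig_table = SignificanceTable.from_nulls(
                self.nulls, alpha=self.model.alpha
            )
        return self._sig_table

    def pvalues(self, d_kb: float) -> np.ndarray:
        d = self._d(d_kb)
        return empirical_pvalues(self.sharing[d], self.nulls[d])

    def n_crit(self, d_kb: float, floor: int | None = None) -> int:
        d = self._d(d_kb)
        if floor is None:
            floor = self.model.n_crit_floor
        return self.sig_table.n_crit(d, floor=floor)

    def runs(
        self,
        d_kb: float,
        roi: RegionOfInterest | None = None,
        n_crit: int | None = None,
    ) -> RunSummary:
        """Significant runs at d; N_crit taken from the significance table."""
        d = self._d(d_kb)
        if n_crit is None:
            n_crit = self.n_crit(d)
        summary = find_runs(self.sharing[d], n_crit)
        if roi is not None:
            from .runs import overlap_regions

            overlap_regions(summary.runs, roi)
        return summary

    def run_table(
        self, d_kb: float, roi: RegionOfInterest | None = None
    ) -> pd.DataFrame:
        return run_table(self.runs(d_kb), roi)

    def plot_runs(self, d_kb: float, roi: RegionOfInterest | None = None, ax=None):
        return plot_runs(self.runs(d_kb), roi, ax=ax)

    # -- summaries ------------------------------------------------------------

    def run_overview(self, roi: RegionOfInterest | None = None) -> pd.DataFrame:
        """Per-d overview: N_crit, number of runs N_r, mean span, N_var.

        Grid entries where no N_f threshold reaches significance are
        reported with N_crit = NaN and no runs.
        """
        rows = []
        for d in self.model.d_grid:
            try:
                nc = self.n_crit(d)
            except Exception:
                rows.append((d, np.nan, 0, np.nan, 0, np.nan))
                continue
            summary = self.runs(d, roi=roi)
            roi_lengths = [r.length_kb for r in summary.runs if r.overlaps_roi]
            rows.append(
                (
                    d,
                    nc,
                    summary.n_runs,
                    summary.l_avg_kb,
                    summary.n_var,
                    roi_lengths[0] if roi_lengths else np.nan,
                )
            )
        return pd.DataFrame(
            rows, columns=["d_kb", "N_crit", "N_r", "L_avg_kb", "N_var", "L_roi_kb"]
        )

    def summary(self, roi: RegionOfInterest | None = None) -> str:
        """Human-readable report: cohort accounting, p(N_f, d) table, runs."""
        m = self.model
        cs = candidate_summary(m.candidates)
        lines = [
            "Shared genomic segment analysis (equivalence test)",
            "=" * 58,
            f"Individuals:          {cs.n_individuals}",
            (
                f"Candidate positions:  {cs.total_k} total "
                f"(k from {cs.min_k} to {cs.max_k}, mean {cs.mean_k:.1f})"
            ),
            f"Variant universe:     {len(m.variants)} positions on "
            f"{len(m.variants.chromosomes)} chromosome(s)",
            f"Permutation samples:  {m.n_perm} (seed {self.seed}; "
            f"min attainable p = {1.0 / m.n_perm:g})",
            f"Null mode:            {m.null_mode}",
        ]
        if m.filter_report is not None:
            fr = m.filter_report
            lines.append(
                f"Variant filtering:    {fr.n_input} loaded, "
                f"{fr.n_monomorphic_removed} monomorphic removed, "
                f"{fr.n_common_removed} common removed, {fr.n_retained} kept"
            )
        lines += [
            "",
            f"Empirical significance levels p(N_f, d)  [p at {1.0 / m.n_perm:g} "
            f"means < {1.0 / m.n_perm:g}]",
        ]
        tbl = self.sig_table.table
        shown = tbl.map(lambda p: format_pvalue(p, m.n_perm))
        shown.columns = [f"d={c:g}kb" for c in tbl.columns]
        lines.append(shown.to_string())
        lines += ["", "Significant runs per d (N_crit floored at "
                  f"{m.n_crit_floor}):"]
        ov = self.run_overview(roi=roi)
        lines.append(ov.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SharedSegmentResults: N={self.model.n_individuals}, "
            f"M={len(self.model.variants)}, d_grid={self.model.d_grid}, "
            f"n_perm={self.model.n_perm}>"
        )
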