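"""The N_f sharing statistic and its permutation null.

Given per-individual candidate disease-variant positions, the test
statistic at a DNA variant v is N_f(v): the number of individuals having at
least one candidate position within +/- d kb of v (closed interval, each
individual counted at most once).  Under the null hypothesis of
heterogeneity — a candidate position can fall anywhere in the variant
universe — the chance that several individuals' candidates co-locate is
small, so large N_f is evidence of a shared susceptibility locus.  This is
an equivalence-testing setup: homogeneity (sharing) is the *alternative*.

The null is realised by permutation: each individual's k candidate
positions are re-drawn uniformly without replacement from the variant
positions, independently across individuals, and pseudo-N_f values are
computed exactly as for the observed data.  The empirical p-value of an
observed count t is the proportion of pseudo-N_f values >= t.  Two modes
are provided:

* ``pooled`` (default): pseudo-N_f values are pooled over all variants and
  permutation samples, giving one p per (N_f, d) — the shape of the
  published significance tables.
* ``per_variant``: one pseudo-N_f per permutation sample, evaluated at a
  single target variant; with n_perm samples including the observed data
  the smallest attainable p is exactly 1/n_perm.

In both modes reported p-values are floored at 1/n_perm (a p at the floor
is to be read as "< 1/n_perm").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CandidateSet, DataError, VariantTable

logger = logging.getLogger(__name__)


@dataclass
class SharingProfile:
    """Per-variant N_f counts for one half-width d."""

    variants: VariantTable
    d_kb: float
    nf: np.ndarray  # int32, aligned to variants
    n_individuals: int

    def __post_init__(self) -> None:
        self.nf = np.asarray(self.nf, dtype=np.int32)
        if len(self.nf) != len(self.variants):
            raise ValueError("nf length != variant count")


def _merge_windows(positions: np.ndarray, half_width: float) -> list[tuple[float, float]]:
    """Merge the closed intervals [p - hw, p + hw] of sorted positions."""
    lo = positions - half_width
    hi = positions + half_width
    merged: list[tuple[float, float]] = []
    cur_lo, cur_hi = lo[0], hi[0]
    for left, right in zip(lo[1:], hi[1:]):
        if left <= cur_hi:
            cur_hi = max(cur_hi, right)
        else:
            merged.append((cur_lo, cur_hi))
            cur_lo, cur_hi = left, right
    merged.append((cur_lo, cur_hi))
    return merged


class _IntervalStamper:
    """Adds +1 over variant-index ranges covered by candidate windows.

    Precomputes per-chromosome position arrays so that repeated stamping
    (one pass per individual per permutation sample) costs O(k log M).
    """

    def __init__(self, variants: VariantTable, half_width_bp: float):
        self.variants = variants
        self.hw = half_width_bp
        self.chroms = variants.chromosomes
        self.slices = {c: variants.block(c) for c in self.chroms}
        self.pos = {c: variants.pos[variants.block(c)] for c in self.chroms}
        self.stops = np.array([self.slices[c].stop for c in self.chroms])

    def stamp_positions(self, chrom: str, positions: np.ndarray, delta: np.ndarray) -> None:
        """Stamp merged windows around sorted ``positions`` on ``chrom``."""
        sl = self.slices[chrom]
        p = self.pos[chrom]
        for lo, hi in _merge_windows(positions, self.hw):
            a = int(np.searchsorted(p, lo, side="left"))
            b = int(np.searchsorted(p, hi, side="right"))
            if a < b:
                delta[sl.start + a] += 1
                delta[sl.start + b] -= 1

    def stamp_indices(self, idx_sorted: np.ndarray, delta: np.ndarray) -> None:
        """Stamp windows around variants given by sorted global indices."""
        blocks = np.searchsorted(self.stops, idx_sorted, side="right")
        for blk in np.unique(blocks):
            c = self.chroms[blk]
            sl = self.slices[c]
            local = idx_sorted[blocks == blk] - sl.start
            self.stamp_positions(c, self.pos[c][local], delta)


def count_sharing(
    variants: VariantTable, candidates: Sequence[CandidateSet], d_kb: float
) -> SharingProfile:
    """Count, per variant, the individuals with a candidate within +/- d kb.

    The interval is closed: a candidate exactly d_kb * 1000 bp away still
    counts.  Each individual contributes at most 1 at any variant, which is
    enforced by merging that individual's overlapping windows before
    stamping.  Candidates on chromosomes absent from the variant table are
    an error.
    """
    if d_kb <= 0:
        raise ValueError(f"d_kb must be positive, got {d_kb}")
    vchroms = set(variants.chromosomes)
    unmatched = sorted(
        {c for cs in candidates for c, _ in cs.positions if c not in vchroms}
    )
    if unmatched:
        raise DataError(
            "candidate chromosome labels absent from the variant table: "
            + ", ".join(unmatched)
        )
    stamper = _IntervalStamper(variants, d_kb * 1000.0)
    delta = np.zeros(len(variants) + 1, dtype=np.int32)
    for cs in candidates:
        for chrom, positions in cs.positions_by_chrom().items():
            stamper.stamp_positions(chrom, positions, delta)
    nf = np.cumsum(delta[:-1], dtype=np.int32)
    return SharingProfile(variants, float(d_kb), nf, len(candidates))


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


@dataclass
class NullTable:
    """Empirical null distribution of pseudo-N_f for one half-width d.

    ``sample_counts[s, v]`` is the number of pooled positions in sample s
    whose pseudo-N_f equals v (``n_pool`` positions per sample: all M
    variants in pooled mode, 1 in per-variant mode).  Exceedance
    probabilities and their Monte-Carlo standard errors derive from it.
    """

    d_kb: float
    n_perm: int
    n_individuals: int
    sample_counts: np.ndarray  # (n_perm, n_individuals + 1)
    n_pool: int
    mode: str
    includes_observed: bool

    def __post_init__(self) -> None:
        self.sample_counts = np.asarray(self.sample_counts, dtype=np.int64)
        # per-sample counts of pseudo-N_f >= t, t = 0..N
        self._ge = np.cumsum(self.sample_counts[:, ::-1], axis=1)[:, ::-1]

    @property
    def floor(self) -> float:
        """Smallest attainable p-value, 1/n_perm."""
        return 1.0 / self.n_perm

    def p_of(self, t) -> np.ndarray | float:
        """Empirical P(pseudo-N_f >= t), floored at 1/n_perm.

        Accepts scalars or arrays; t <= 0 gives 1, t beyond the tabulated
        range gives the floor value.
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=np.int64))
        total_ge = self._ge.sum(axis=0)
        denom = float(self.n_perm * self.n_pool)
        p = np.empty(t_arr.shape, dtype=float)
        below = t_arr <= 0
        beyond = t_arr > self.n_individuals
        inside = ~below & ~beyond
        p[below] = 1.0
        p[beyond] = self.floor
        p[inside] = total_ge[t_arr[inside]] / denom
        p = np.maximum(p, self.floor)
        return p if np.ndim(t) else float(p[0])

    def mc_se(self, t: int) -> float:
        """Monte-Carlo s.e. of p_of(t), clustering by permutation sample.

        Pseudo-N_f values within one sample are correlated across variants,
        so the s.e. treats the per-sample exceedance proportions as the
        i.i.d. replicates.
        """
        if not 0 < t <= self.n_individuals:
            return 0.0
        frac = self._ge[:, t] / self.n_pool
        if len(frac) < 2:
            return float("nan")
        return float(np.std(frac, ddof=1) / np.sqrt(self.n_perm))


def _draw_indices(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct indices uniform in [0, n); rejection sampling for k << n."""
    if k > n:
        raise DataError(f"cannot draw {k} distinct positions from {n} variants")
    if k * 20 >= n:
        return rng.choice(n, size=k, replace=False)
    idx = rng.integers(0, n, size=k)
    uniq = np.unique(idx)
    while len(uniq) < k:
        extra = rng.integers(0, n, size=k - len(uniq))
        uniq = np.unique(np.concatenate([uniq, extra]))
    return uniq


def permutation_null(
    variants: VariantTable,
    k_per_individual: Sequence[int],
    d_kb: float,
    n_perm: int,
    seed: int,
    observed: SharingProfile | None = None,
    mode: str = "pooled",
    target_index: int | None = None,
) -> NullTable:
    """Build the permutation null of pseudo-N_f for one half-width d.

    Each permutation sample re-draws, for every individual independently,
    k candidate positions uniformly without replacement from the variant
    table (the permutation of position labels the null hypothesis implies),
    and evaluates pseudo-N_f exactly as :func:`count_sharing` does.

    If ``observed`` is given, it is counted as one of the ``n_perm``
    samples (so n_perm includes the observed data and the smallest p is
    1/n_perm); otherwise all ``n_perm`` samples are random draws.

    Randomness is drawn from per-(individual, sample) streams derived from
    ``seed``, so results do not depend on evaluation order.
    """
    if n_perm < 2:
        raise ValueError(f"n_perm must be >= 2, got {n_perm}")
    if mode not in ("pooled", "per_variant"):
        raise ValueError(f"unknown null mode {mode!r}")
    if mode == "per_variant" and target_index is None:
        raise ValueError("per_variant mode requires target_index")
    M = len(variants)
    ks = [int(k) for k in k_per_individual]
    if any(k < 0 for k in ks):
        raise ValueError("negative candidate count")
    if any(k > M for k in ks):
        raise DataError(f"candidate count exceeds variant count M={M}")
    if observed is not None:
        if abs(observed.d_kb - d_kb) > 1e-9:
            raise ValueError("observed profile computed with a different d_kb")
        if observed.n_individuals != len(ks):
            raise ValueError("observed profile has a different number of individuals")
    N = len(ks)
    seed = int(seed) % (2**31)
    stamper = _IntervalStamper(variants, d_kb * 1000.0)

    if mode == "per_variant":
        sl_t, pos_t = None, None
        for c in variants.chromosomes:
            sl = variants.block(c)
            if sl.start <= target_index < sl.stop:
                sl_t, pos_t = sl, variants.pos[target_index]
                break
        assert sl_t is not None, "target_index out of range"
        hw = d_kb * 1000.0
        p_chrom = variants.pos[sl_t]
        a = sl_t.start + int(np.searchsorted(p_chrom, pos_t - hw, side="left"))
        b = sl_t.start + int(np.searchsorted(p_chrom, pos_t + hw, side="right"))

    counts = np.zeros((n_perm, N + 1), dtype=np.int64)
    s0 = 0
    if observed is not None:
        if mode == "pooled":
            counts[0] = np.bincount(observed.nf, minlength=N + 1)
        else:
            counts[0, int(observed.nf[target_index])] = 1
        s0 = 1

    delta = np.zeros(M + 1, dtype=np.int32)
    for s in range(s0, n_perm):
        if mode == "pooled":
            delta[:] = 0
            for i, k in enumerate(ks):
                if k == 0:
                    continue
                rng = np.random.default_rng((seed, i, s))
                idx = np.sort(_draw_indices(rng, M, k))
                stamper.stamp_indices(idx, delta)
            nf = np.cumsum(delta[:-1])
            counts[s] = np.bincount(nf, minlength=N + 1)
        else:
            hits = 0
            for i, k in enumerate(ks):
                if k == 0:
                    continue
                rng = np.random.default_rng((seed, i, s))
                idx = _draw_indices(rng, M, k)
                if np.any((idx >= a) & (idx < b)):
                    hits += 1
            counts[s, hits] = 1

    n_pool = M if mode == "pooled" else 1
    return NullTable(
        d_kb=float(d_kb),
        n_perm=n_perm,
        n_individuals=N,
        sample_counts=counts,
        n_pool=n_pool,
        mode=mode,
        includes_observed=observed is not None,
    )


def empirical_pvalues(profile: SharingProfile, null: NullTable) -> np.ndarray:
    """Per-variant empirical p-values p(v) = P(pseudo-N_f >= N_f(v))."""
    if abs(profile.d_kb - null.d_kb) > 1e-9:
        raise ValueError(
            f"profile d={profile.d_kb} kb but null built for d={null.d_kb} kb"
        )
    return np.asarray(null.p_of(profile.nf), dtype=float)


def format_pvalue(p: float, n_perm: int) -> str:
    """Render a p-value, writing values at the floor as '< 1/n_perm'."""
    floor = 1.0 / n_perm
    if p <= floor + 1e-15:
        return f"<{floor:g}"
    return f"{p:.4f}"


# ---------------------------------------------------------------------------
# Significance table (one p per N_f threshold and d)
# ---------------------------------------------------------------------------


class SignificanceTable:
    """Matrix of p-values by N_f threshold (rows) and half-width d (columns).

    For each d the smallest threshold t with p < alpha is flagged; the
    run-inclusion threshold N_crit(d) is that t floored at a configurable
    minimum (default 3).
    """

    def __init__(self, table: pd.DataFrame, alpha: float = 0.05):
        self.table = table.sort_index(axis=1)
        self.alpha = float(alpha)

    @classmethod
    def from_nulls(
        cls, nulls: Mapping[float, NullTable], alpha: float = 0.05
    ) -> "SignificanceTable":
        if not nulls:
            raise ValueError("no null tables supplied")
        n_max = max(nt.n_individuals for nt in nulls.values())
        t_values = np.arange(1, n_max + 1)
        data = {
            float(d): np.asarray(nt.p_of(t_values), dtype=float)
            for d, nt in nulls.items()
        }
        table = pd.DataFrame(data, index=pd.Index(t_values, name="N_f"))
        return cls(table, alpha)

    @property
    def d_grid(self) -> list[float]:
        return [float(c) for c in self.table.columns]

    def _column(self, d_kb: float) -> pd.Series:
        for c in self.table.columns:
            if abs(float(c) - float(d_kb)) < 1e-9:
                return self.table[c]
        raise KeyError(f"no significance column for d = {d_kb} kb")

    def flagged_t(self, d_kb: float) -> int | None:
        """Smallest threshold t with p < alpha for this d, or None."""
        col = self._column(d_kb)
        sig = col[col < self.alpha]
        return int(sig.index.min()) if len(sig) else None

    def n_crit(self, d_kb: float, floor: int = 3) -> int:
        t = self.flagged_t(d_kb)
        if t is None:
            raise DataError(
                f"no N_f threshold reaches p < {self.alpha} at d = {d_kb} kb; "
                "consider more individuals or a smaller d"
            )
        return max(int(floor), t)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, alpha: float = 0.05) -> "SignificanceTable":
        df = pd.read_csv(path, sep="\t", index_col="N_f")
        df.columns = [float(c) for c in df.columns]
        return cls(df, alpha)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SignificanceTable(d_grid={self.d_grid}, alpha={self.alpha})"


def significance_table(
    nulls: Mapping[float, NullTable], alpha: float = 0.05
) -> SignificanceTable:
    """Build the p(t, d) table from per-d permutation nulls."""
    return SignificanceTable.from_nulls(nulls, alpha)


def write_sharing(
    profile: SharingProfile, path, pvalues: np.ndarray | None = None
) -> None:
    """Write per-variant sharing counts (and optional p-values) as TSV."""
    df = profile.variants.to_dataframe()
    df["nf"] = profile.nf
    if pvalues is not None:
        df["p"] = pvalues
    df.to_csv(path, sep="\t", index=False)


def read_sharing(path, d_kb: float, n_individuals: int | None = None) -> SharingProfile:
    """Read a sharing TSV back into a :class:`SharingProfile`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing = {"chrom", "pos", "id", "maf", "nf"} - set(df.columns)
    if missing:
        raise DataError(f"sharing table {path} lacks columns {sorted(missing)}")
    variants = VariantTable.from_dataframe(df)
    nf = df["nf"].to_numpy(dtype=np.int32)
    n = int(n_individuals) if n_individuals is not None else int(nf.max(initial=0))
    return SharingProfile(variants, float(d_kb), nf, n)
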