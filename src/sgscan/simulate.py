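"""Synthetic genotype and candidate-set generation.

The generator emulates the statistical structure the method assumes for
carriers of a rare dominant disease variant: at background variants with
minor allele frequency f, a carrier is heterozygous with the population
probability 2f(1 - f); at variants within a halo of +/- w bp around the
disease position, heterozygosity is elevated to p_het_near, which must
exceed 1 - f (the heterozygote-excess inequality that motivates the scan).
Genotypes are i.i.d. across variants — the method works one variant at a
time and does not appeal to linkage disequilibrium, so none is simulated.
Only carriers are generated (the sharing stage uses carriers only).

A second generator draws candidate-position sets directly (bypassing the
genotype scan) for null-calibration and sharing-stage tests: each
individual receives k candidate positions uniformly without replacement
from the variant grid, and a chosen number of individuals additionally
receive one candidate near a designated true position.

Default configuration: M = 20,000 variants on a 20 Mb uniform grid, 5
carriers, fixed f = 0.01, disease position at mid-chromosome with a 1 Mb
elevation half-width and p_het_near = 1 — the deterministic-core recovery
setting under which the implanted signal is fully penetrant in the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import HET, HOM, MISSING, CandidateSet, GenotypeMatrix, VariantTable


@dataclass
class SimConfig:
    """Parameters of the carrier-genotype simulation.

    ``maf_dist`` selects how per-variant minor allele frequencies f are
    drawn: ``("fixed", f)``, ``("uniform", low, high)`` or
    ``("loguniform", low, high)``, all constrained to (0, 0.05] by default
    use.  ``p_het_far`` defaults to the population heterozygosity
    2f(1 - f) of each variant; ``p_het_near`` applies within
    +/- ``elevation_halfwidth_bp`` of ``disease_pos`` and must exceed
    1 - max(f) (the heterozygote-excess condition near a dominant variant).
    """

    n_variants: int = 20_000
    chrom_length_bp: int = 20_000_000
    spacing: str = "uniform_grid"  # or "uniform_random"
    n_carriers: int = 5
    maf_dist: tuple = ("fixed", 0.01)
    disease_pos: int | None = None  # default: mid-chromosome
    elevation_halfwidth_bp: int = 1_000_000
    p_het_near: float = 1.0
    p_het_far: float | None = None  # default: 2f(1-f) per variant
    missing_rate: float = 0.0
    chrom: str = "chr1"
    seed: int = 0

    def resolved_disease_pos(self) -> int:
        return (
            self.chrom_length_bp // 2 if self.disease_pos is None else self.disease_pos
        )

    def validate(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.n_variants > self.chrom_length_bp:
            raise ValueError("more variants than base pairs")
        if self.spacing not in ("uniform_grid", "uniform_random"):
            raise ValueError(f"unknown spacing {self.spacing!r}")
        if not 0 < self.elevation_halfwidth_bp < self.chrom_length_bp:
            raise ValueError("elevation_halfwidth_bp must be in (0, chrom_length_bp)")
        if not 0 <= self.p_het_near <= 1:
            raise ValueError("p_het_near must be a probability")
        if self.p_het_far is not None and not 0 <= self.p_het_far <= 1:
            raise ValueError("p_het_far must be a probability")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 1 <= self.resolved_disease_pos() <= self.chrom_length_bp:
            raise ValueError("disease_pos outside the chromosome")
        f_max = float(np.max(self._maf_bounds()))
        if not 0 < f_max <= 0.5:
            raise ValueError("allele frequencies must lie in (0, 0.5]")
        # no-signal configs (p_het_near not above the background rate) are
        # legitimate for null-calibration runs; only an *implanted* signal
        # must satisfy the heterozygote-excess inequality
        no_signal = self.p_het_far is not None and self.p_het_near <= self.p_het_far
        if not no_signal and self.p_het_near <= 1 - f_max:
            raise ValueError(
                f"p_het_near={self.p_het_near} must exceed 1 - f = {1 - f_max:.4g} "
                "(heterozygote-excess condition near a dominant variant)"
            )

    def _maf_bounds(self) -> tuple[float, float]:
        kind = self.maf_dist[0]
        if kind == "fixed":
            (f,) = self.maf_dist[1:]
            return (f, f)
        if kind in ("uniform", "loguniform"):
            low, high = self.maf_dist[1:]
            return (low, high)
        raise ValueError(f"unknown maf_dist kind {kind!r}")


def _draw_positions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    M, L = cfg.n_variants, cfg.chrom_length_bp
    if cfg.spacing == "uniform_grid":
        return np.linspace(1, L, num=M, dtype=np.int64) if M > 1 else np.array([L // 2])
    pos = np.sort(rng.choice(L, size=M, replace=False)) + 1
    return pos.astype(np.int64)


def _draw_maf(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    kind = cfg.maf_dist[0]
    M = cfg.n_variants
    if kind == "fixed":
        return np.full(M, float(cfg.maf_dist[1]))
    low, high = float(cfg.maf_dist[1]), float(cfg.maf_dist[2])
    if kind == "uniform":
        return rng.uniform(low, high, size=M)
    return np.exp(rng.uniform(np.log(low), np.log(high), size=M))


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, dict]:
    """Simulate carrier genotypes with an implanted heterozygosity halo.

    Returns the genotype matrix and a truth record with the implanted
    disease position and halo half-width, so downstream tests never
    re-derive ground truth from outputs.  Deterministic given cfg.seed.
    """
    cfg.validate()
    rng = np.random.default_rng(int(cfg.seed) % (2**31))
    pos = _draw_positions(cfg, rng)
    # grid rounding may collide at extreme densities; enforce uniqueness
    if len(np.unique(pos)) != len(pos):
        raise ValueError("variant grid produced duplicate positions; reduce density")
    f = _draw_maf(cfg, rng)
    disease_pos = cfg.resolved_disease_pos()
    near = np.abs(pos - disease_pos) <= cfg.elevation_halfwidth_bp
    p_far = 2.0 * f * (1.0 - f) if cfg.p_het_far is None else np.full_like(f, cfg.p_het_far)
    p_het = np.where(near, cfg.p_het_near, p_far)
    u = rng.random((cfg.n_carriers, cfg.n_variants))
    codes = np.where(u < p_het, HET, HOM).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(codes.shape) < cfg.missing_rate
        codes[miss] = MISSING
    variants = VariantTable(
        np.full(cfg.n_variants, cfg.chrom, dtype=object),
        pos,
        np.array([f"v{i}" for i in range(cfg.n_variants)], dtype=object),
        f,
    )
    individuals = [f"carrier{i}" for i in range(cfg.n_carriers)]
    truth = {
        "chrom": cfg.chrom,
        "disease_pos": int(disease_pos),
        "elevation_halfwidth_bp": int(cfg.elevation_halfwidth_bp),
        "window_start": int(max(1, disease_pos - cfg.elevation_halfwidth_bp)),
        "window_end": int(disease_pos + cfg.elevation_halfwidth_bp),
        "p_het_near": float(cfg.p_het_near),
        "seed": int(cfg.seed),
    }
    return GenotypeMatrix(variants, individuals, codes), truth


def simulate_candidates(
    n_individuals: int,
    k_range: tuple[int, int],
    variants: VariantTable,
    n_true_shared: int = 0,
    true_pos: int | None = None,
    seed: int = 0,
    true_halfwidth_bp: int = 0,
) -> list[CandidateSet]:
    """Draw candidate-position sets directly on an existing variant grid.

    Each individual receives k ~ uniform over [k_range[0], k_range[1]]
    candidates at variant positions drawn without replacement; the first
    ``n_true_shared`` individuals additionally receive one candidate at the
    variant nearest ``true_pos`` (or uniformly among variants within
    +/- ``true_halfwidth_bp`` of it).  Deterministic given seed.
    """
    if n_true_shared > n_individuals:
        raise ValueError(
            f"n_true_shared={n_true_shared} exceeds n_individuals={n_individuals}"
        )
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    M = len(variants)
    if not 0 <= k_lo <= k_hi <= M:
        raise ValueError(f"k_range {k_range} outside [0, {M}]")
    if n_true_shared > 0 and true_pos is None:
        raise ValueError("true_pos required when n_true_shared > 0")
    rng = np.random.default_rng(int(seed) % (2**31))
    out: list[CandidateSet] = []
    for i in range(n_individuals):
        k = int(rng.integers(k_lo, k_hi + 1))
        idx = rng.choice(M, size=k, replace=False) if k else np.empty(0, np.int64)
        positions = [
            (str(variants.chrom[j]), int(variants.pos[j])) for j in np.sort(idx)
        ]
        peak_h = list(np.round(rng.uniform(0.2, 1.0, size=len(positions)), 4))
        if i < n_true_shared:
            lo, hi = true_pos - true_halfwidth_bp, true_pos + true_halfwidth_bp
            in_win = np.flatnonzero((variants.pos >= lo) & (variants.pos <= hi))
            if len(in_win):
                j = int(rng.choice(in_win)) if true_halfwidth_bp else int(
                    in_win[np.argmin(np.abs(variants.pos[in_win] - true_pos))]
                )
            else:  # no variant inside the window: take the nearest one
                j = int(np.argmin(np.abs(variants.pos - true_pos)))
            positions.append((str(variants.chrom[j]), int(variants.pos[j])))
            peak_h.append(1.0)
        out.append(CandidateSet(f"ind{i}", positions, peak_h))
    return out
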