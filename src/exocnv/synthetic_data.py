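"""Simulated sequencing batches with known copy-number truth.

Counts are drawn as gamma-mixed Poisson (negative binomial): the mean at
sample *s*, target *t* is ``depth * sample_effect_s * target_effect_t *
m_st`` where the copy-number multiplier is ``m = 1 + f (c - 2) / 2`` for a
spike of copy number ``c`` present in a cell fraction ``f`` (1.0 =
constitutive).  The generator is deliberately *not* the caller's
beta-binomial likelihood, so recovery tests exercise robustness rather than
self-confirmation.  All entry points take an explicit seed; the same seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import BATCH_SIZES, CountMatrix, TargetGrid, ValidationError

# Study batch/depth conditions: 32-sample exome batches at ~200 reads per
# target with mild sample- and strong target-level capture variability.
DEFAULT_N_TARGETS = 1000
DEFAULT_DEPTH = 200.0
DEFAULT_SAMPLE_SD = 0.1
DEFAULT_TARGET_SD = 0.5
DEFAULT_RHO = 0.01


@dataclass
class Spike:
    """One planted CNV: a target range in one sample."""

    sample: int            # row index in the batch
    first_target: int
    last_target: int       # inclusive
    copy_number: int       # in {0, 1, 3, 4}
    mosaic_fraction: float = 1.0

    def multiplier(self) -> float:
        return 1.0 + self.mosaic_fraction * (self.copy_number - 2) / 2.0


@dataclass
class SimSpec:
    """Conditions for one simulated batch."""

    seed: int
    n_samples: int | None = None   # defaults to the library's batch size
    n_targets: int = DEFAULT_N_TARGETS
    targets_per_gene: int = 10
    mean_depth: float = DEFAULT_DEPTH
    sample_sd: float = DEFAULT_SAMPLE_SD    # lognormal sigma of sample effects
    target_sd: float = DEFAULT_TARGET_SD    # lognormal sigma of target effects
    rho: float = DEFAULT_RHO                # NB overdispersion: var = mu + rho mu^2
    library_kind: str = "ES"
    spikes: list[Spike] = field(default_factory=list)
    #: optional per-target depth multipliers shared by the whole batch
    #: (e.g. a poorly captured exon); length n_targets.
    target_scaling: np.ndarray | None = None

    def __post_init__(self):
        if self.n_samples is None:
            self.n_samples = BATCH_SIZES[self.library_kind]
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if min(self.n_samples, self.n_targets) <= 0 or self.mean_depth <= 0:
            raise ValidationError("sizes and depth must be positive")
        if not (0 < self.rho < 1):
            raise ValidationError("rho must lie in (0, 1)")
        for sp in self.spikes:
            if sp.copy_number not in (0, 1, 3, 4):
                raise ValidationError(f"spike copy_number {sp.copy_number} not in {{0,1,3,4}}")
            if not (0 <= sp.first_target <= sp.last_target < self.n_targets):
                raise ValidationError("spike outside the target grid")
            if not (0 <= sp.sample < self.n_samples):
                raise ValidationError("spike sample outside the batch")
            if not (0 <= sp.mosaic_fraction <= 1):
                raise ValidationError("mosaic fraction must lie in [0, 1]")


@dataclass
class SimResult:
    batch: CountMatrix
    grid: TargetGrid
    truth: pd.DataFrame  # sample, chrom, first_target, last_target, start, end, copy_number, mosaic_fraction


def make_grid(n_targets: int, targets_per_gene: int = 10,
              chrom: str = "1", target_len: int = 120,
              spacing: int = 1000) -> TargetGrid:
    """A regular single-chromosome exon lattice for simulations."""
    starts = np.arange(n_targets) * spacing
    df = pd.DataFrame({
        "chrom": chrom,
        "start": starts,
        "end": starts + target_len,
        "gene": [f"G{i // targets_per_gene:04d}" for i in range(n_targets)],
        "exon_index": [i % targets_per_gene + 1 for i in range(n_targets)],
    })
    return TargetGrid(df)


def _negbin(rng: np.random.Generator, mu: np.ndarray, rho: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + rho mu^2 (elementwise)."""
    out = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    shape = 1.0 / rho
    lam = rng.gamma(shape, mu[pos] * rho)
    out[pos] = rng.poisson(lam)
    return out


def simulate_batch(spec: SimSpec) -> SimResult:
    """Draw one batch of per-target counts with the planted CNVs."""
    rng = np.random.default_rng(spec.seed)
    grid = make_grid(spec.n_targets, spec.targets_per_gene)
    sample_eff = rng.lognormal(0.0, spec.sample_sd, size=spec.n_samples)
    target_eff = rng.lognormal(0.0, spec.target_sd, size=spec.n_targets)
    if spec.target_scaling is not None:
        target_eff = target_eff * np.asarray(spec.target_scaling, dtype=float)
    mu = spec.mean_depth * np.outer(sample_eff, target_eff)
    for sp in spec.spikes:
        mu[sp.sample, sp.first_target:sp.last_target + 1] *= sp.multiplier()
    counts = _negbin(rng, mu, spec.rho)
    sample_ids = [f"S{i:03d}" for i in range(spec.n_samples)]
    batch = CountMatrix(sample_ids, counts, library_kind=spec.library_kind,
                        override_batch_size=spec.n_samples != BATCH_SIZES[spec.library_kind])
    starts = grid.df["start"].to_numpy()
    ends = grid.df["end"].to_numpy()
    truth = pd.DataFrame([
        {
            "sample": sample_ids[sp.sample],
            "chrom": grid.df["chrom"].iloc[0],
            "first_target": sp.first_target,
            "last_target": sp.last_target,
            "start": int(starts[sp.first_target]),
            "end": int(ends[sp.last_target]),
            "copy_number": sp.copy_number,
            "mosaic_fraction": sp.mosaic_fraction,
        }
        for sp in spec.spikes
    ], columns=["sample", "chrom", "first_target", "last_target", "start",
                "end", "copy_number", "mosaic_fraction"])
    return SimResult(batch=batch, grid=grid, truth=truth)


# Re-exported here so batch simulation and bundled study tables share one
# module surface.
from .fixtures import make_paper_fixtures  # noqa: E402,F401
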