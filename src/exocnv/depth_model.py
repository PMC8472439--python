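"""Batch read-depth copy-number calling.

A test sample's per-target read counts are compared with an aggregate of
well-correlated samples from the same sequencing batch.  At each capture
target the observed fraction ``o_t / (o_t + r_t)`` of test reads among
test-plus-reference reads is modelled as beta-binomial around the fraction
expected under each candidate copy number ``c``:

    p_c = (c/2 * N_s) / (c/2 * N_s + N_r)

where ``N_s`` and ``N_r`` are the test and reference library totals.  A
deletion halves the test sample's share of reads at the affected targets, a
duplication raises it by half, independently of per-target capture
efficiency, which cancels between test and reference.  The beta-binomial
intra-class correlation ``rho`` absorbs the technical overdispersion of
capture sequencing.  Copy states 0-4 are segmented along each chromosome by
a Viterbi pass with a strong stay-diploid prior, and each emitted call is
scored by the log10 likelihood ratio of its copy state against diploid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import betabinom

from .io_formats import CountMatrix, TargetGrid, ValidationError

#: Copy states considered by the segmenter; the most extreme event expected
#: in diagnostic exomes is a quadruplication.
COPY_STATES = (0, 1, 2, 3, 4)
DIPLOID = 2
#: Depth-ratio floor standing in for c/2 at c=0 (residual mismapped reads).
ZERO_COPY_EPS = 0.01
#: State preference for Viterbi tie-breaks: less extreme states first.
_TIE_ORDER = sorted(range(len(COPY_STATES)), key=lambda i: (abs(COPY_STATES[i] - 2), COPY_STATES[i]))

RHO_FLOOR = 1e-6
RHO_CEIL = 0.3


@dataclass
class ReferenceModel:
    """Aggregated reference for one test sample within its batch."""

    test_sample: str
    reference_ids: list[str]
    ref_counts: np.ndarray  # per-target summed reference counts r_t
    n_test: int             # N_s: total test reads over the grid
    n_ref: int              # N_r: total reference reads
    rho: float              # beta-binomial intra-class correlation

    def __post_init__(self):
        if self.test_sample in self.reference_ids:
            raise ValidationError("test sample cannot be its own reference")
        if not self.reference_ids:
            raise ValidationError("reference set is empty")
        if self.n_test <= 0 or self.n_ref <= 0:
            raise ValidationError("test and reference totals must be positive")
        if not (0 < self.rho < 1):
            raise ValidationError("rho must lie in (0, 1)")


@dataclass
class CnvCall:
    """A contiguous run of targets assigned a non-diploid copy state."""

    sample: str
    chrom: str
    first_target: int
    last_target: int
    start: int
    end: int
    copy_number: int
    n_targets: int
    mean_ratio: float   # observed / expected-diploid depth over the segment
    quality: float      # log10 likelihood ratio vs all-diploid
    mosaic_fraction: float | None = None

    def __post_init__(self):
        if self.copy_number == DIPLOID:
            raise ValidationError("a CNV call cannot be diploid")
        if self.end <= self.start:
            raise ValidationError("call has non-positive size")
        if self.n_targets < 1 or self.last_target < self.first_target:
            raise ValidationError("call spans no targets")

    @property
    def type(self) -> str:
        return "loss" if self.copy_number < DIPLOID else "gain"

    @property
    def size(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Reference selection
# ---------------------------------------------------------------------------

def estimate_rho(obs: np.ndarray, ref: np.ndarray, p: float | None = None) -> float:
    """Method-of-moments intra-class correlation of per-target fractions.

    Under the beta-binomial, E[(f_t - p)^2] = p(1-p)[rho + (1-rho)/n_t]
    with f_t = o_t/n_t; solving target-wise and averaging gives rho.
    """
    n = obs + ref
    keep = n > 0
    o, n = obs[keep].astype(float), n[keep].astype(float)
    if p is None:
        p = o.sum() / n.sum()
    if not (0 < p < 1):
        return RHO_FLOOR
    f = o / n
    num = (f - p) ** 2 - p * (1 - p) / n
    den = p * (1 - p) * (1 - 1 / n)
    ok = den > 0
    if not ok.any():
        return RHO_FLOOR
    rho = float(np.mean(num[ok] / den[ok]))
    return float(np.clip(rho, RHO_FLOOR, RHO_CEIL))


def _predicted_fraction_variance(obs: np.ndarray, ref: np.ndarray) -> float:
    """Mean beta-binomial variance of the per-target aggregate fraction."""
    n = obs + ref
    keep = n > 0
    tot_o, tot_n = obs[keep].sum(), n[keep].sum()
    if tot_n == 0 or tot_o == 0 or tot_o == tot_n:
        return np.inf
    p = tot_o / tot_n
    rho = estimate_rho(obs, ref, p)
    return float(np.mean(p * (1 - p) * (rho + (1 - rho) / n[keep])))


def select_reference(test: str, batch: CountMatrix, max_refs: int = 10) -> ReferenceModel:
    """Choose the reference aggregate for one sample of a batch.

    Other batch samples are ranked by Pearson correlation of their count
    profiles with the test sample, then added greedily in rank order while
    the predicted beta-binomial variance of the aggregate observed fraction
    keeps decreasing (capped at ``max_refs``).
    """
    if batch.n_samples < 2:
        raise ValidationError("reference set requires a batch of >=2 samples")
    obs = batch.row(test).astype(float)
    if obs.sum() == 0:
        raise ValidationError(f"test sample {test!r} has zero total counts")
    others = [s for s in batch.sample_ids if s != test]
    cors = []
    for s in others:
        r = batch.row(s).astype(float)
        if r.std() == 0 or obs.std() == 0:
            cors.append(-np.inf)
        else:
            cors.append(float(np.corrcoef(obs, r)[0, 1]))
    order = sorted(range(len(others)), key=lambda i: -cors[i])

    chosen: list[str] = []
    agg = np.zeros_like(obs)
    best_var = np.inf
    for i in order[:max_refs * 2]:
        cand = batch.row(others[i]).astype(float)
        var = _predicted_fraction_variance(obs, agg + cand)
        if var < best_var:
            chosen.append(others[i])
            agg = agg + cand
            best_var = var
            if len(chosen) >= max_refs:
                break
        elif chosen:
            break
    if not chosen:  # fall back to the single best-correlated sample
        chosen = [others[order[0]]]
        agg = batch.row(chosen[0]).astype(float)
    ref_counts = agg.astype(np.int64)
    rho = estimate_rho(batch.row(test), ref_counts)
    return ReferenceModel(
        test_sample=test,
        reference_ids=chosen,
        ref_counts=ref_counts,
        n_test=int(batch.row(test).sum()),
        n_ref=int(ref_counts.sum()),
        rho=rho,
    )


# ---------------------------------------------------------------------------
# Likelihood model
# ---------------------------------------------------------------------------

def expected_fraction(c: int, n_s: float, n_r: float) -> float:
    """Expected test-read fraction at a target under copy number ``c``."""
    if n_s <= 0 or n_r <= 0:
        raise ValidationError("library totals must be positive")
    half = ZERO_COPY_EPS if c == 0 else c / 2.0
    return (half * n_s) / (half * n_s + n_r)


def _bb_params(p: float, rho: float) -> tuple[float, float]:
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    return a, b


def target_loglik(o: int, r: int, p: float, rho: float) -> float:
    """Beta-binomial log pmf of ``o`` test reads among ``o + r`` total.

    Mean ``p``, intra-class correlation ``rho``; reduces to the binomial as
    rho -> 0.  A target with no reads at all carries no information and
    contributes 0.
    """
    n = o + r
    if n == 0:
        return 0.0
    if not (0 < p < 1 and 0 < rho < 1):
        raise ValidationError("p and rho must lie in (0, 1)")
    a, b = _bb_params(p, rho)
    return float(betabinom.logpmf(o, n, a, b))


def _emission_matrix(obs: np.ndarray, ref: np.ndarray, model: ReferenceModel) -> np.ndarray:
    """Log-likelihood of each target under each copy state: shape (T, S)."""
    n = obs + ref
    out = np.zeros((len(obs), len(COPY_STATES)))
    informative = n > 0
    for j, c in enumerate(COPY_STATES):
        p = expected_fraction(c, model.n_test, model.n_ref)
        a, b = _bb_params(p, model.rho)
        out[informative, j] = betabinom.logpmf(obs[informative], n[informative], a, b)
    return out


# ---------------------------------------------------------------------------
# Viterbi segmentation
# ---------------------------------------------------------------------------

def transition_log_matrix(transition_prob: float, n_states: int = len(COPY_STATES),
                          diploid: int = DIPLOID) -> np.ndarray:
    """Stochastic transition matrix with a stay-diploid prior.

    Entering any non-diploid state costs ``log t``.  From the diploid state
    the remaining mass stays diploid; from a non-diploid state the remaining
    mass is split evenly between staying and returning to diploid, so both
    extending and closing a CNV segment are cheap — only the entry is
    penalised, and the segment-level quality threshold does the final
    filtering.
    """
    t = transition_prob
    A = np.empty((n_states, n_states))
    for i in range(n_states):
        for j in range(n_states):
            if j != diploid and j != i:
                A[i, j] = t
        if i == diploid:
            A[i, i] = 1.0 - (n_states - 1) * t
        else:
            rest = 1.0 - (n_states - 2) * t
            A[i, i] = rest / 2.0
            A[i, diploid] = rest / 2.0
    return np.log(A)


def viterbi(emissions: np.ndarray, log_trans: np.ndarray,
            log_init: np.ndarray, tie_order: Sequence[int] | None = None) -> np.ndarray:
    """Most probable state path for one chromosome.

    ``emissions`` is (T, S) log-likelihood; ties are broken toward the first
    state in ``tie_order`` (by default, states closest to diploid).
    """
    T, S = emissions.shape
    order = list(tie_order) if tie_order is not None else list(range(S))
    score = log_init + emissions[0]
    back = np.zeros((T, S), dtype=np.intp)
    for t in range(1, T):
        cand = score[:, None] + log_trans  # (from, to)
        # argmax over `from` with tie-break preferring states in `order`
        best_from = np.empty(S, dtype=np.intp)
        best_val = np.empty(S)
        for j in range(S):
            col = cand[:, j]
            m = col.max()
            for i in order:
                if col[i] >= m - 1e-12:
                    best_from[j] = i
                    best_val[j] = col[i]
                    break
        back[t] = best_from
        score = best_val + emissions[t]
    path = np.empty(T, dtype=np.intp)
    m = score.max()
    for i in order:
        if score[i] >= m - 1e-12:
            path[-1] = i
            break
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def brute_force_path(emissions: np.ndarray, log_trans: np.ndarray,
                     log_init: np.ndarray, tie_order: Sequence[int] | None = None) -> np.ndarray:
    """Exhaustive enumeration of all state paths (oracle for tiny instances)."""
    from itertools import product

    T, S = emissions.shape
    order = list(tie_order) if tie_order is not None else list(range(S))
    rank = {s: k for k, s in enumerate(order)}
    best, best_score = None, -np.inf
    for path in product(range(S), repeat=T):
        score = log_init[path[0]] + emissions[0, path[0]]
        for t in range(1, T):
            score += log_trans[path[t - 1], path[t]] + emissions[t, path[t]]
        key = tuple(rank[s] for s in path)
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12 and best is not None
            and key < tuple(rank[s] for s in best)
        ):
            best, best_score = path, max(score, best_score)
    return np.array(best, dtype=np.intp)


def call_segments(
    test: str,
    batch: CountMatrix,
    ref_model: ReferenceModel,
    grid: TargetGrid,
    transition_prob: float = 1e-4,
    call_threshold: float = 3.0,
) -> list[CnvCall]:
    """Segment one sample's depth profile into CNV calls.

    Runs a per-chromosome Viterbi pass over copy states 0-4 and emits every
    maximal non-diploid run whose log10 likelihood ratio against the
    all-diploid path reaches ``call_threshold``.
    """
    if batch.n_targets != len(grid):
        raise ValidationError(
            f"count matrix has {batch.n_targets} targets but grid has {len(grid)}"
        )
    obs_all = batch.row(test)
    log_trans = transition_log_matrix(transition_prob)
    log_init = log_trans[DIPLOID].copy()
    p_diploid = expected_fraction(DIPLOID, ref_model.n_test, ref_model.n_ref)
    calls: list[CnvCall] = []
    for chrom in grid.chroms:
        rows = grid.chrom_rows(chrom)
        obs, ref = obs_all[rows], ref_model.ref_counts[rows]
        em = _emission_matrix(obs, ref, ref_model)
        path = viterbi(em, log_trans, log_init, tie_order=_TIE_ORDER)
        states = np.array(COPY_STATES)[path]
        starts = grid.df["start"].to_numpy()[rows]
        ends = grid.df["end"].to_numpy()[rows]
        t = 0
        while t < len(states):
            if states[t] == DIPLOID:
                t += 1
                continue
            u = t
            while u + 1 < len(states) and states[u + 1] != DIPLOID:
                u += 1
            seg = slice(t, u + 1)
            seg_states = states[seg]
            vals, cnts = np.unique(seg_states, return_counts=True)
            # modal state; ties toward less extreme copy numbers
            modal = int(sorted(
                vals[cnts == cnts.max()], key=lambda c: (abs(c - 2), c)
            )[0])
            ll_called = float(em[seg, :][np.arange(u + 1 - t), path[seg]].sum())
            ll_diploid = float(em[seg, list(COPY_STATES).index(DIPLOID)].sum())
            # path likelihood includes the transitions: entry from diploid,
            # within-segment moves, and the exit back to diploid (if any)
            dip = list(COPY_STATES).index(DIPLOID)
            prev_state = dip  # segment is entered from diploid by construction
            tr_called = log_trans[prev_state, path[t]]
            tr_diploid = log_trans[dip, dip]
            for k in range(t + 1, u + 1):
                tr_called += log_trans[path[k - 1], path[k]]
                tr_diploid += log_trans[dip, dip]
            if u + 1 < len(states):
                tr_called += log_trans[path[u], dip]
                tr_diploid += log_trans[dip, dip]
            quality = (ll_called + tr_called - ll_diploid - tr_diploid) / math.log(10)
            # diploid expectation of o_t given the (CNV-free) reference
            # counts: e_t = r_t * N_s / N_r
            e_diploid = ref[seg] * (ref_model.n_test / ref_model.n_ref)
            mean_ratio = float(obs[seg].sum() / e_diploid.sum()) if e_diploid.sum() > 0 else 1.0
            if quality >= call_threshold:
                call = CnvCall(
                    sample=test, chrom=chrom,
                    first_target=int(t), last_target=int(u),
                    start=int(starts[t]), end=int(ends[u]),
                    copy_number=modal, n_targets=int(u - t + 1),
                    mean_ratio=mean_ratio, quality=quality,
                )
                if modal in (1, 3):
                    call = replace(call, mosaic_fraction=estimate_mosaic(call))
                calls.append(call)
            t = u + 1
    return calls


# ---------------------------------------------------------------------------
# Mosaicism
# ---------------------------------------------------------------------------

def estimate_mosaic(call: CnvCall) -> float:
    """Cell fraction carrying a single-copy gain or loss.

    The depth ratio of a segment present in a fraction ``f`` of cells is
    ``1 + f (c - 2) / 2``, so ``f = 2 (r - 1)`` for a duplication and
    ``f = 2 (1 - r)`` for a heterozygous deletion, clamped to [0, 1].
    Calls with ``f >= 0.95`` are treated as constitutive downstream (no
    mosaic annotation in reports).
    """
    if call.copy_number not in (1, 3):
        raise ValidationError(
            "mosaic fraction is only estimated for single-copy gains/losses"
        )
    r = call.mean_ratio
    f = 2.0 * (r - 1.0) if call.copy_number == 3 else 2.0 * (1.0 - r)
    return float(np.clip(f, 0.0, 1.0))


def is_constitutive(fraction: float, cutoff: float = 0.95) -> bool:
    return fraction >= cutoff
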