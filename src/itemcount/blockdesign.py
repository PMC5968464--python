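"""Assignment of control items to blocks to avoid ceiling/floor exposure.

A list-experiment block leaks the sensitive answer whenever a respondent's
count is extreme: a count of 0 reveals "false" and a count of J+1 reveals
"true" for every item in the block.  Good instruments therefore assign
control items to blocks so that the probability of an extreme count is
small — most respondents should affirm one to three of the four controls.

Under the design assumption that items are answered independently, the
block count is Poisson-binomial and the extreme-count probability has an
exact value computed here by convolving the J+1 Bernoulli distributions
(:func:`extreme_prob_exact`).  :func:`search_assignment` reproduces the
design-by-simulation workflow — draw random partitions of the control pool
into blocks, score each, keep the argmin — with either the exact oracle
(default) or Monte-Carlo scoring, plus an exhaustive mode for small pools.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .design import DesignError, ItemBlock, SurveyDesign

__all__ = [
    "block_count_pmf",
    "extreme_prob_exact",
    "extreme_prob_simulated",
    "AssignmentCandidate",
    "search_assignment",
    "assign_positions",
]


def block_count_pmf(probs) -> np.ndarray:
    """Exact pmf of the sum of independent Bernoulli(p_i) variables.

    Convolves the two-point distributions one item at a time; returns an
    array of length ``len(probs) + 1`` over counts 0..m.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or probs.size == 0:
        raise DesignError("probs must be a non-empty 1-d sequence")
    if (probs < 0).any() or (probs > 1).any():
        raise DesignError(f"probabilities outside [0, 1]: {probs}")
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def extreme_prob_exact(block: ItemBlock | "np.ndarray | list") -> float:
    """Exact probability that a block's count is extreme (0 or J+1).

    Accepts an :class:`ItemBlock` (controls plus sensitive item) or a bare
    probability vector.
    """
    probs = block.all_probs if isinstance(block, ItemBlock) else block
    pmf = block_count_pmf(probs)
    return float(pmf[0] + pmf[-1])


def extreme_prob_simulated(probs, n_sims: int, rng: np.random.Generator) -> float:
    """Monte-Carlo estimate of the extreme-count probability."""
    probs = np.asarray(probs, dtype=float)
    counts = (rng.random((n_sims, probs.size)) < probs).sum(axis=1)
    return float(((counts == 0) | (counts == probs.size)).mean())


@dataclass(frozen=True)
class AssignmentCandidate:
    """One partition of the control pool into blocks, with its scores.

    ``groups[i]`` lists the control item ids assigned to the i-th block
    stub; ``block_probs[i]`` is that block's extreme-count probability and
    ``score`` the aggregate (sum or max over blocks).
    """

    groups: tuple[tuple[str, ...], ...]
    block_probs: tuple[float, ...]
    score: float


def _score_partition(groups, pool_probs, sensitive, exact, n_sims, rng, aggregate):
    block_probs = []
    for grp, blk in zip(groups, sensitive):
        probs = [pool_probs[item] for item in grp] + [blk.sensitive_prob]
        if exact:
            block_probs.append(extreme_prob_exact(probs))
        else:
            block_probs.append(extreme_prob_simulated(probs, n_sims, rng))
    agg = sum(block_probs) if aggregate == "sum" else max(block_probs)
    return tuple(block_probs), agg


def _all_partitions(items: tuple[str, ...], group_size: int):
    """All ordered partitions of ``items`` into consecutive groups of
    ``group_size`` (blocks are distinguishable by their sensitive item)."""
    if not items:
        yield ()
        return
    for combo in itertools.combinations(items, group_size):
        rest = tuple(i for i in items if i not in combo)
        for tail in _all_partitions(rest, group_size):
            yield (combo,) + tail


def search_assignment(
    pool: dict,
    sensitive: "list[ItemBlock]",
    n_candidates: int = 1000,
    n_sims: int = 10000,
    seed: int = 0,
    *,
    exact: bool = True,
    exhaustive: bool = False,
    aggregate: str = "sum",
) -> AssignmentCandidate:
    """Find a low-leakage assignment of control items to blocks.

    Parameters
    ----------
    pool
        ``control_item_id -> assumed affirmative probability``; its size
        must equal ``B * J`` for B block stubs of J controls each.
    sensitive
        One :class:`ItemBlock` stub per block; only ``sensitive_prob`` (and
        id fields) are read — the stubs' control lists are ignored.
    n_candidates
        Number of random partitions scored (ignored in exhaustive mode).
    n_sims
        Monte-Carlo draws per block when ``exact=False``.
    seed
        Drives both partition sampling and Monte-Carlo scoring.
    exact
        Score with the convolution oracle (default) instead of simulation.
    exhaustive
        Enumerate every ordered partition; feasible only for small pools.
    aggregate
        Combine per-block probabilities by ``"sum"`` (default) or ``"max"``.

    Returns the argmin candidate; ties keep the earliest partition
    considered, so the result is deterministic given the seed.
    """
    B = len(sensitive)
    if aggregate not in ("sum", "max"):
        raise DesignError(f"aggregate must be 'sum' or 'max', got {aggregate!r}")
    items = tuple(pool)
    if B == 0 or len(items) % B != 0:
        raise DesignError(f"pool of {len(items)} items cannot fill {B} blocks")
    J = len(items) // B
    rng = np.random.default_rng(seed)

    best: AssignmentCandidate | None = None
    if exhaustive:
        candidates = _all_partitions(items, J)
    else:
        def _random_partitions():
            arr = np.array(items, dtype=object)
            for _ in range(n_candidates):
                perm = rng.permutation(len(arr))
                yield tuple(
                    tuple(arr[perm[i * J:(i + 1) * J]]) for i in range(B)
                )
        candidates = _random_partitions()

    for groups in candidates:
        block_probs, agg = _score_partition(
            groups, pool, sensitive, exact, n_sims, rng, aggregate
        )
        if best is None or agg < best.score:
            best = AssignmentCandidate(groups=groups, block_probs=block_probs, score=agg)
    assert best is not None
    return best


def assign_positions(
    design: SurveyDesign, n: int, seed: int = 0
) -> np.ndarray:
    """Randomized sensitive-item positions, one per respondent per block.

    Returns an ``(n, B)`` integer array with entries uniform on 1..J+1,
    independent across respondents and blocks, deterministic given seed.
    """
    if n < 1:
        raise DesignError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return rng.integers(1, design.n_controls + 2, size=(n, design.n_blocks))
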