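"""Synthetic test images with controllable multimodal histograms, and the
exhaustive-search oracle that certifies optimizer output on small instances.

Real high-bit-depth scans (12-bit MRI, promoted benchmark photographs) have
smooth histograms with a handful of modes — background, soft tissue, bright
structures.  The generator emulates exactly that: pixels are drawn i.i.d.
from a Gaussian mixture over the gray range, rounded and clipped.  What it
deliberately does *not* emulate is spatial structure (anatomy, texture,
noise correlation): histogram-based thresholding only sees the gray-level
distribution, so mixture images exercise the optimizers under realistic
objective landscapes while remaining fully reproducible from a seed.

The exhaustive oracle enumerates every strictly increasing threshold tuple
and returns the certified global optimum of the Kapur objective.  It refuses
instances beyond its combinatorial budget rather than subsampling; callers
rebin the histogram (4096 -> 256 levels, say) to bring an instance within
budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, islice
from math import comb
from typing import Sequence

import numpy as np

from .histogram import GrayHistogram, GrayImage, KapurObjective, ThresholdSet

__all__ = [
    "MixtureSpec",
    "OracleBudgetError",
    "generate_synthetic_image",
    "random_mixture_spec",
    "exhaustive_optimal_thresholds",
    "rebin_histogram",
    "upscale_thresholds",
]


class OracleBudgetError(ValueError):
    """The exhaustive enumeration would exceed the combinatorial budget."""


@dataclass(frozen=True)
class MixtureSpec:
    """A Gaussian-mixture recipe for a synthetic grayscale image.

    ``modes`` is a sequence of ``(mean, sd, weight)`` triples in gray-level
    units; weights must be positive and sum to 1.  The default shape
    (256 x 256) gives 65k pixel samples — enough for the empirical histogram
    to track the analytic mixture closely.
    """

    modes: tuple[tuple[float, float, float], ...]
    bit_depth: int = 12
    shape: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        modes = tuple((float(m), float(s), float(w)) for m, s, w in self.modes)
        if not modes:
            raise ValueError("need at least one mode")
        weights = np.array([w for _, _, w in modes])
        if np.any(weights <= 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("mode weights must be positive and sum to 1")
        top = 2**self.bit_depth - 1
        if any(not 0 <= m <= top for m, _, _ in modes):
            raise ValueError(f"mode means must lie in [0, {top}]")
        if any(s < 0 for _, s, _ in modes):
            raise ValueError("mode standard deviations must be non-negative")
        object.__setattr__(self, "modes", modes)

    @property
    def levels(self) -> int:
        return 2**self.bit_depth

    def to_dict(self) -> dict:
        return {
            "modes": [list(m) for m in self.modes],
            "bit_depth": self.bit_depth,
            "shape": list(self.shape),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureSpec":
        return cls(
            modes=tuple(tuple(m) for m in d["modes"]),
            bit_depth=int(d["bit_depth"]),
            shape=tuple(d["shape"]),
            seed=int(d["seed"]),
        )

    def analytic_bin_probs(self) -> np.ndarray:
        """Exact per-level probabilities of the rounded, clipped mixture."""
        from scipy.stats import norm

        edges = np.arange(self.levels + 1) - 0.5  # level v <- (v-0.5, v+0.5]
        probs = np.zeros(self.levels)
        for mean, sd, w in self.modes:
            if sd == 0:
                probs[int(np.clip(np.floor(mean + 0.5), 0, self.levels - 1))] += w
                continue
            cdf = norm.cdf(edges, loc=mean, scale=sd)
            p = np.diff(cdf)
            p[0] += cdf[0]  # clipped tails fold into the end bins
            p[-1] += 1.0 - cdf[-1]
            probs += w * p
        return probs


def generate_synthetic_image(spec: MixtureSpec) -> GrayImage:
    """Sample an image from the mixture; a fixed seed gives bit-identical output."""
    rng = np.random.default_rng(spec.seed)
    n_pix = spec.shape[0] * spec.shape[1]
    means = np.array([m for m, _, _ in spec.modes])
    sds = np.array([s for _, s, _ in spec.modes])
    weights = np.array([w for _, _, w in spec.modes])
    component = rng.choice(len(spec.modes), size=n_pix, p=weights)
    values = rng.normal(means[component], sds[component])
    pixels = np.clip(np.floor(values + 0.5), 0, spec.levels - 1).astype(np.int64)
    return GrayImage(pixels=pixels.reshape(spec.shape), bit_depth=spec.bit_depth)


def random_mixture_spec(
    seed: int,
    n_modes: int = 4,
    bit_depth: int = 12,
    shape: tuple[int, int] = (256, 256),
) -> MixtureSpec:
    """A seeded random multimodal recipe emulating high-bit-depth scans.

    Mode means are spread over the central 80% of the gray range (evenly
    spaced anchors with ±5%-of-range jitter, so modes stay separated), mode
    widths are 1.5-4% of the range, and weights are Dirichlet(2) draws —
    smooth histograms with 2-5 well-defined peaks, the regime where
    multilevel thresholding at 4-8 thresholds is meaningful.
    """
    rng = np.random.default_rng(seed)
    top = 2**bit_depth - 1
    anchors = np.linspace(0.1, 0.9, n_modes) * top
    means = anchors + rng.uniform(-0.05, 0.05, n_modes) * top
    sds = rng.uniform(0.015, 0.04, n_modes) * top
    weights = rng.dirichlet(np.full(n_modes, 2.0))
    modes = tuple(
        (float(np.clip(m, 0, top)), float(s), float(w))
        for m, s, w in zip(means, sds, weights)
    )
    return MixtureSpec(modes=modes, bit_depth=bit_depth, shape=shape, seed=seed)


def exhaustive_optimal_thresholds(
    hist: GrayHistogram,
    n_thresholds: int,
    budget_cap: int = 10**7,
    chunk_size: int = 100_000,
) -> tuple[ThresholdSet, float]:
    """Certified global optimum of the Kapur objective by full enumeration.

    Enumerates all ``C(L - 1, n)`` strictly increasing tuples over
    ``[1, L - 1]`` in lexicographic order and returns the first argmax (so
    ties break to the lexicographically smallest tuple).  Raises
    :class:`OracleBudgetError` when the tuple count exceeds ``budget_cap``.
    """
    levels = hist.levels
    total = comb(levels - 1, n_thresholds)
    if total == 0:
        raise ValueError("no feasible threshold tuple at this dimension")
    if total > budget_cap:
        raise OracleBudgetError(
            f"C({levels - 1}, {n_thresholds}) = {total} exceeds the budget of "
            f"{budget_cap}; rebin the histogram or lower n_thresholds"
        )
    objective = KapurObjective(hist)
    gen = combinations(range(1, levels), n_thresholds)
    best_val = -np.inf
    best_tuple: tuple[int, ...] | None = None
    while True:
        block = np.array(list(islice(gen, chunk_size)), dtype=np.int64)
        if block.size == 0:
            break
        vals = objective.evaluate_many(block)
        i = int(np.argmax(vals))
        if vals[i] > best_val:  # strict: keeps the lexicographically first argmax
            best_val = float(vals[i])
            best_tuple = tuple(int(v) for v in block[i])
    assert best_tuple is not None
    return ThresholdSet(values=best_tuple, levels=levels), best_val


def rebin_histogram(hist: GrayHistogram, target_levels: int) -> GrayHistogram:
    """Aggregate adjacent bins down to ``target_levels`` (a divisor of L)."""
    if target_levels < 2 or hist.levels % target_levels != 0:
        raise ValueError(f"target_levels must divide {hist.levels}")
    factor = hist.levels // target_levels
    counts = hist.counts.reshape(target_levels, factor).sum(axis=1)
    return GrayHistogram(counts=counts, levels=target_levels)


def upscale_thresholds(thresholds: ThresholdSet, levels: int) -> ThresholdSet:
    """Map thresholds found on a rebinned histogram back to the full scale.

    A rebinned threshold ``t`` marks the left edge of coarse bin ``t``, i.e.
    original level ``t * (L / target_levels)``.
    """
    if levels % thresholds.levels != 0:
        raise ValueError("original levels must be a multiple of the rebinned levels")
    factor = levels // thresholds.levels
    return ThresholdSet(
        values=tuple(v * factor for v in thresholds.values), levels=levels
    )
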