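"""Distribution summaries and divergences for accuracy benchmarking.

Smoothed-simulation abundances are real-valued; they are rounded to the
nearest integer before histogramming so that exact and smoothed ensembles are
compared on the same integer support.  All information measures use natural
logarithms (the headline divergence/entropy ratio is base-invariant anyway).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiscretePDF",
    "empirical_pdf",
    "moments",
    "entropy",
    "kl_divergence",
    "jsd",
    "jsd_over_entropy",
]


@dataclass(frozen=True)
class DiscretePDF:
    """Probability mass function on ordered integer bins."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "support", np.asarray(self.support, dtype=int))
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if self.support.shape != self.probs.shape or self.support.ndim != 1:
            raise ValueError("support and probs must be matching 1-D arrays")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be nonnegative and sum to 1")
        if np.any(np.diff(self.support) <= 0):
            raise ValueError("support must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.support, "probability": self.probs})


def empirical_pdf(samples) -> DiscretePDF:
    """Histogram real-valued abundances on integer bins (round-to-nearest)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empirical_pdf needs at least one sample")
    vals = np.rint(samples).astype(int)
    support, counts = np.unique(vals, return_counts=True)
    return DiscretePDF(support, counts / counts.sum())


def moments(samples, max_order: int = 4) -> tuple[float, ...]:
    """Raw sample moments <m>, <m^2>, ... up to ``max_order``."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("moments of an empty sample")
    return tuple(float(np.mean(samples**k)) for k in range(1, max_order + 1))


def _aligned(p: DiscretePDF, q: DiscretePDF):
    """Zero-pad both PMFs onto the union of their supports."""
    support = np.union1d(p.support, q.support)
    pa = np.zeros(support.size)
    qa = np.zeros(support.size)
    pa[np.searchsorted(support, p.support)] = p.probs
    qa[np.searchsorted(support, q.support)] = q.probs
    return pa, qa


def entropy(p: DiscretePDF) -> float:
    """Shannon entropy in nats, with 0 log 0 = 0."""
    pr = p.probs[p.probs > 0]
    return float(-(pr * np.log(pr)).sum())


def kl_divergence(p: DiscretePDF, q: DiscretePDF) -> float:
    """KL divergence in nats on the union support; P>0 where Q=0 gives inf."""
    pa, qa = _aligned(p, q)
    mask = pa > 0
    if np.any(qa[mask] == 0):
        return float("inf")
    return float((pa[mask] * np.log(pa[mask] / qa[mask])).sum())


def jsd(p: DiscretePDF, q: DiscretePDF) -> float:
    """Jensen-Shannon divergence in nats: always finite, bounded by ln 2."""
    pa, qa = _aligned(p, q)
    m = 0.5 * (pa + qa)

    def _kl(x):
        mask = x > 0
        return (x[mask] * np.log(x[mask] / m[mask])).sum()

    return float(0.5 * _kl(pa) + 0.5 * _kl(qa))


def jsd_over_entropy(p_dga: DiscretePDF, p_exact: DiscretePDF) -> float:
    """Divergence-to-entropy ratio JSD(p_dga || p_exact) / H(p_exact)."""
    h = entropy(p_exact)
    if h <= 0:
        raise ValueError("reference distribution has zero entropy")
    return jsd(p_dga, p_exact) / h
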