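"""Summary statistics for switched fire-vegetation dynamics.

Permanence ratios (fraction of years in each dynamic), the empirical two-state
fire chain, cover histograms split by dynamic, and the bimodality index

    B = | mu* - mu |

where mu is the mean tree cover and mu* the mean cover of the years (or
stationary mass) belonging to the more frequent dynamic.  Both means are
estimated from histograms with the same bins (sum c_k f_k / sum f_k over bin
centers c_k), so that B is free of the half-bin offset a raw mean would carry
against the binned estimator.  B >= 0.1 classifies
the cover distribution as bimodal: when the system mixes two well-separated
single-dynamic regimes, the dominant-dynamic mean pulls away from the overall
mean; when one dynamic dominates completely or the two overlap, mu* ~ mu.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .model_core import SimulationResult

__all__ = [
    "PermanenceSummary",
    "CoverHistogram",
    "FireChainEstimate",
    "BimodalityReport",
    "permanence_ratios",
    "estimate_fire_chain",
    "histogram_by_dynamic",
    "bimodality_index",
    "pooled_bimodality",
    "classify_bimodality",
]

#: default classification cutoff for the bimodality index
B_THRESHOLD = 0.1
#: default number of initial years discarded as influenced by the initial state
DEFAULT_BURN_IN = 100


@dataclass(frozen=True)
class PermanenceSummary:
    """Years spent in each dynamic over the analysis window."""

    V_f: int
    V_nf: int
    ratio_f: float
    ratio_nf: float
    window: tuple[int, int]


def permanence_ratios(fire_seq, burn_in: int = 0) -> PermanenceSummary:
    """Fraction of post-burn-in years spent in the fire / no-fire dynamic."""
    seq = np.asarray(fire_seq, dtype=int).ravel()
    if burn_in >= seq.size:
        raise ValueError(
            f"burn_in={burn_in} leaves no years out of {seq.size}"
        )
    window = seq[burn_in:]
    v_f = int(window.sum())
    v_nf = int(window.size - v_f)
    return PermanenceSummary(
        V_f=v_f,
        V_nf=v_nf,
        ratio_f=v_f / window.size,
        ratio_nf=v_nf / window.size,
        window=(burn_in, seq.size),
    )


@dataclass(frozen=True)
class FireChainEstimate:
    """Empirical 2x2 transition matrix of the fire indicator sequence.

    ``P[s, s']`` estimates the probability of moving from fire status s to s'.
    Rows never visited are NaN and flagged in ``undefined_rows`` rather than
    imputed.
    """

    P: np.ndarray
    counts: np.ndarray
    undefined_rows: tuple[int, ...]


def estimate_fire_chain(fire_seq) -> FireChainEstimate:
    seq = np.asarray(fire_seq, dtype=int).ravel()
    if seq.size < 2:
        raise ValueError("need at least two years to estimate transitions")
    counts = np.zeros((2, 2), dtype=int)
    np.add.at(counts, (seq[:-1], seq[1:]), 1)
    row_tot = counts.sum(axis=1)
    P = np.full((2, 2), np.nan)
    undefined = []
    for s in range(2):
        if row_tot[s] > 0:
            P[s] = counts[s] / row_tot[s]
        else:
            undefined.append(s)
    return FireChainEstimate(P=P, counts=counts, undefined_rows=tuple(undefined))


@dataclass(frozen=True)
class CoverHistogram:
    """Histogram of tree cover on [0, 1] with half-open bins [l, l+w) (last closed)."""

    bin_width: float
    edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def masses(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot > 0 else np.zeros_like(self.counts, dtype=float)

    @property
    def empty(self) -> bool:
        return self.counts.sum() == 0

    @property
    def mean(self) -> float:
        """Binned mean sum(c_k f_k) / sum(f_k); NaN for an empty histogram."""
        if self.empty:
            return float("nan")
        return float(self.centers @ self.masses)

    @classmethod
    def from_values(cls, values, bin_width: float, weights=None) -> "CoverHistogram":
        nb = int(round(1.0 / bin_width))
        if abs(nb * bin_width - 1.0) > 1e-9:
            raise ValueError(f"bin width {bin_width} does not partition [0, 1]")
        edges = np.linspace(0.0, 1.0, nb + 1)
        counts, _ = np.histogram(
            np.asarray(values, dtype=float), bins=edges, weights=weights
        )
        return cls(bin_width=bin_width, edges=edges, counts=counts)


def classify_bimodality(B: float, threshold: float = B_THRESHOLD) -> str:
    """Pure threshold rule: bimodal iff B >= threshold."""
    return "bimodal" if B >= threshold else "unimodal"


@dataclass(frozen=True)
class BimodalityReport:
    """Bimodality index of a cover distribution and its classification.

    ``mu`` and ``mu_star`` are the binned means (shared bins); ``mu_raw`` is
    the unbinned mean of the underlying covers, reported for reference.
    """

    mu: float
    mu_star: float
    mu_raw: float
    B: float
    threshold: float
    verdict: str
    dominant_dynamic: str
    tie: bool
    mode: str
    histogram_total: CoverHistogram
    histogram_dominant: CoverHistogram


def _report_from_pool(
    covers: np.ndarray,
    fires: np.ndarray,
    bin_width: float,
    threshold: float,
    mode: str,
) -> BimodalityReport:
    n_f = int(fires.sum())
    n_nf = fires.size - n_f
    tie = n_f == n_nf
    # ties broken toward no-fire
    dominant = "fire" if n_f > n_nf else "no_fire"
    hist_total = CoverHistogram.from_values(covers, bin_width)
    dom_covers = covers[fires == (1 if dominant == "fire" else 0)]
    hist_dom = CoverHistogram.from_values(dom_covers, bin_width)
    mu = hist_total.mean
    mu_star = hist_dom.mean
    B = abs(mu_star - mu)
    return BimodalityReport(
        mu=mu,
        mu_raw=float(covers.mean()),
        mu_star=mu_star,
        B=B,
        threshold=threshold,
        verdict=classify_bimodality(B, threshold),
        dominant_dynamic=dominant,
        tie=tie,
        mode=mode,
        histogram_total=hist_total,
        histogram_dominant=hist_dom,
    )


def histogram_by_dynamic(
    result: "SimulationResult", bin_width: float = 0.1, burn_in: int = DEFAULT_BURN_IN
) -> tuple[CoverHistogram, CoverHistogram, CoverHistogram]:
    """Cover histograms (total, fire years, no-fire years) with shared bins.

    Year t's cover is the pre-update state x(t), attributed to the dynamic
    indicated by F(t); the three histograms partition exactly.  "Cover" is
    the vegetation cover summed over the classes that count (the fire model's
    cover mask) — the total over all classes when no mask is set.
    """
    covers = result.effective_cover[burn_in : result.horizon]
    fires = result.fires[burn_in:]
    total = CoverHistogram.from_values(covers, bin_width)
    h_fire = CoverHistogram.from_values(covers[fires == 1], bin_width)
    h_nofire = CoverHistogram.from_values(covers[fires == 0], bin_width)
    return total, h_fire, h_nofire


def bimodality_index(
    obj,
    bin_width: float = 0.1,
    burn_in: int = DEFAULT_BURN_IN,
    threshold: float = B_THRESHOLD,
) -> BimodalityReport:
    """Bimodality index of a trajectory or of a discretized chain.

    Trajectory mode (``obj`` is a :class:`~firetree.model_core.SimulationResult`):
    the dominant dynamic is the fire status with more post-burn-in years; mu
    and mu* are the binned means of the full and the dominant-subset
    histograms.

    Chain mode (``obj`` is a :class:`~firetree.markov_chain.DiscretizedChain`):
    the state centers are binned with weights w_i (for mu) and with
    w_i p_i or w_i (1 - p_i) (for mu*), the stationary analogue of labelling
    years by F(t); dominance is decided by the stationary fire fraction
    phi = sum_i w_i p_i vs 1/2.
    """
    if hasattr(obj, "fires"):  # trajectory
        covers = obj.effective_cover[burn_in : obj.horizon]
        fires = np.asarray(obj.fires[burn_in:], dtype=int)
        if covers.size == 0:
            raise ValueError("burn-in leaves no years to analyse")
        return _report_from_pool(covers, fires, bin_width, threshold, mode="trajectory")
    if hasattr(obj, "p_state"):  # discretized chain
        w = obj.w
        covers = obj.state_covers
        p = obj.p_state
        phi = float(w @ p)
        tie = phi == 0.5
        dominant = "fire" if phi > 0.5 else "no_fire"
        dom_w = w * (p if dominant == "fire" else (1.0 - p))
        hist_total = CoverHistogram.from_values(covers, bin_width, weights=w)
        hist_dom = CoverHistogram.from_values(covers, bin_width, weights=dom_w)
        mu = hist_total.mean
        mu_star = hist_dom.mean
        B = abs(mu_star - mu)
        return BimodalityReport(
            mu=mu,
            mu_raw=float(w @ covers),
            mu_star=mu_star,
            B=B,
            threshold=threshold,
            verdict=classify_bimodality(B, threshold),
            dominant_dynamic=dominant,
            tie=tie,
            mode="chain",
            histogram_total=hist_total,
            histogram_dominant=hist_dom,
        )
    raise TypeError(f"cannot compute bimodality index of {type(obj).__name__}")


def pooled_bimodality(
    covers, fires, bin_width: float = 0.1, threshold: float = B_THRESHOLD
) -> BimodalityReport:
    """Bimodality index of a spatial pool of (cover, fire status) pairs.

    Same estimator as trajectory mode with site-years replaced by sites
    sampled at one instant; dominance by majority fire status in the pool.
    """
    c = np.asarray(covers, dtype=float).ravel()
    f = np.asarray(fires, dtype=int).ravel()
    if c.size == 0 or c.size != f.size:
        raise ValueError("pool must be nonempty with matching covers and fire statuses")
    return _report_from_pool(c, f, bin_width, threshold, mode="pooled")
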