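"""Replication, thresholding, significance, and ensemble refinement.

One species' suitability model is never a single fit: species with 5–29
deduplicated occurrences are replicated by leave-one-out (jackknife, n
replicates), species with >= 30 by 10-fold cross-validation. Each replicate
carries its own maximum-sensitivity-plus-specificity (MSS) threshold; the
ensemble is summarized by a "refined" mean map retaining only pixels deemed
suitable by at least 95% of replicates, then binarized at the mean MSS
threshold.

Small-sample significance follows the leave-one-out test: the number of
left-out points falling in their replicate's predicted-suitable area is
compared with the exact Poisson-binomial tail under the null that each point
lands in the suitable area with probability equal to that area's fraction of
the study region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .raster_core import AlignmentError, RasterLayer

__all__ = [
    "UndefinedResultError",
    "EvaluationResult",
    "ReplicateEnsemble",
    "choose_replication_mode",
    "mss_threshold",
    "poisson_binomial_tail",
    "jackknife_significance",
    "continuous_boyce_index",
    "refine_ensemble",
    "binarize_refined",
]


class UndefinedResultError(ValueError):
    """The requested statistic is undefined on these inputs."""


@dataclass
class EvaluationResult:
    """Per-species model quality: leave-one-out success rate q, its
    Poisson-binomial p-value, continuous Boyce index (None for small-sample
    species), and the MSS threshold used for binarization."""

    species_id: str
    n_occurrences: int
    mode: str
    success_rate: float
    jackknife_p: float
    cbi: float | None
    mss: float


@dataclass
class ReplicateEnsemble:
    """Replicate suitability maps for one species.

    ``maps`` maps scenario_id -> list of logistic RasterLayers (one per
    replicate); ``thresholds`` holds each replicate's own MSS threshold;
    for jackknife mode ``heldout_rowcol[i]`` is the grid cell of the point
    left out of replicate i (cross-validation: list of held-out cells).
    """

    mode: str
    maps: dict[str, list[RasterLayer]] = field(default_factory=dict)
    thresholds: list[float] = field(default_factory=list)
    heldout_rowcol: list = field(default_factory=list)
    models: list = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.thresholds)

    def _check(self, scenario: str) -> list[RasterLayer]:
        if scenario not in self.maps:
            raise KeyError(f"no replicate maps for scenario {scenario!r}")
        maps = self.maps[scenario]
        if len(maps) < 2:
            raise ValueError("need at least 2 replicates")
        spec = maps[0].spec
        for m in maps[1:]:
            if m.spec != spec:
                raise AlignmentError("replicate maps are misaligned")
        return maps


def choose_replication_mode(n_occurrences: int) -> tuple[str, int]:
    """('jackknife', n) for 5–29 occurrences, ('crossvalidation', 10) for
    >= 30, ('excluded', 0) below 5 (exclusion signal, not an error)."""
    if n_occurrences < 5:
        return "excluded", 0
    if n_occurrences <= 29:
        return "jackknife", n_occurrences
    return "crossvalidation", 10


def mss_threshold(
    presence_scores,
    background_scores,
    presence_weights=None,
    background_weights=None,
) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the unique observed scores (presence and background
    pooled); sensitivity(t) = weighted fraction of presences >= t,
    specificity(t) = weighted fraction of background < t; ties go to the
    smallest threshold. Weights (optional) allow the population-level
    version used for synthetic ground truth.
    """
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    if p.size == 0 or b.size == 0:
        raise ValueError("need at least one presence and one background score")
    wp = np.ones_like(p) if presence_weights is None else np.asarray(
        presence_weights, float
    )
    wb = np.ones_like(b) if background_weights is None else np.asarray(
        background_weights, float
    )
    cand = np.unique(np.concatenate([p, b]))
    # weighted fraction >= t via cumulative sums over sorted scores
    p_order = np.argsort(p)
    b_order = np.argsort(b)
    p_sorted, wp_sorted = p[p_order], wp[p_order]
    b_sorted, wb_sorted = b[b_order], wb[b_order]
    cp = np.concatenate([[0.0], np.cumsum(wp_sorted)])
    cb = np.concatenate([[0.0], np.cumsum(wb_sorted)])
    ip = np.searchsorted(p_sorted, cand, side="left")
    ib = np.searchsorted(b_sorted, cand, side="left")
    sens = (cp[-1] - cp[ip]) / cp[-1]
    spec = cb[ib] / cb[-1]
    total = sens + spec
    best = np.argmax(total)  # argmax takes the first maximum = smallest t
    return float(cand[best])


def poisson_binomial_tail(success_probs, s: int) -> float:
    """Exact upper tail P(S >= s) of a sum of independent Bernoulli(p_i),
    by dynamic programming over the count distribution."""
    p = np.asarray(success_probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    n = p.size
    if s > n:
        return 0.0
    if s <= 0:
        return 1.0
    dist = np.zeros(n + 1)
    dist[0] = 1.0
    for i, pi in enumerate(p):
        dist[1 : i + 2] = dist[1 : i + 2] * (1 - pi) + dist[: i + 1] * pi
        dist[0] *= 1 - pi
    return float(dist[s:].sum())


def jackknife_significance(
    ensemble: ReplicateEnsemble, scenario: str = "present"
) -> tuple[float, float]:
    """Leave-one-out success rate q and Poisson-binomial p-value.

    Replicate i (trained without point i) predicts its left-out point a
    success when the point's suitability reaches that replicate's MSS
    threshold; the null probability p_i is the fraction of valid area the
    replicate predicts suitable.
    """
    if ensemble.mode != "jackknife":
        raise ValueError(f"ensemble mode is {ensemble.mode!r}, not jackknife")
    maps = ensemble._check(scenario)
    successes = []
    null_probs = []
    for i, (lyr, thr) in enumerate(zip(maps, ensemble.thresholds)):
        row, col = ensemble.heldout_rowcol[i]
        valid = lyr.valid_mask
        vals = lyr.values
        successes.append(1 if vals[row, col] >= thr else 0)
        null_probs.append(float(np.mean(vals[valid] >= thr)))
    s = int(np.sum(successes))
    q = s / len(successes)
    return q, poisson_binomial_tail(null_probs, s)


def continuous_boyce_index(
    presence_scores,
    background_scores,
    n_windows: int = 101,
    window_width: float | None = None,
) -> float:
    """Continuous Boyce index: Spearman correlation between the
    predicted-to-expected ratio F and suitability.

    Windows of fixed width (default: a tenth of the observed score range)
    slide across the range at ``n_windows`` evenly spaced midpoints; for
    each, F = (fraction of presences inside) / (fraction of background
    inside). Windows with no background mass are undefined and dropped;
    windows with zero presence mass (F = 0) are also dropped, so the rank
    correlation is taken over the windows where the ratio is informative —
    the convention under which a model placing all presences in its top
    suitability decile scores near 1.
    """
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    lo = min(p.min(), b.min())
    hi = max(p.max(), b.max())
    if hi == lo:
        raise UndefinedResultError("degenerate suitability range")
    if window_width is None:
        window_width = (hi - lo) / 10.0
    mids = np.linspace(lo, hi, n_windows)
    f_vals, f_mids = [], []
    half = window_width / 2.0
    for mid in mids:
        in_p = np.mean((p >= mid - half) & (p <= mid + half))
        in_b = np.mean((b >= mid - half) & (b <= mid + half))
        if in_b == 0 or in_p == 0:
            continue
        f_vals.append(in_p / in_b)
        f_mids.append(mid)
    if len(f_vals) < 3:
        raise UndefinedResultError("too few usable windows for the Boyce index")
    rho = stats.spearmanr(f_mids, f_vals).statistic
    if np.isnan(rho):
        raise UndefinedResultError("Boyce ratio is constant across windows")
    return float(rho)


def refine_ensemble(ensemble: ReplicateEnsemble, scenario: str) -> RasterLayer:
    """Ensemble mean logistic map with low-agreement pixels removed.

    Each replicate is binarized at its own MSS threshold; a pixel keeps its
    mean value only where the fraction of replicates calling it suitable is
    at least 0.95 (with 10 replicates: all 10), else it is set to 0. Nodata
    propagates.
    """
    maps = ensemble._check(scenario)
    arr = np.stack([m.values for m in maps])
    thr = np.asarray(ensemble.thresholds)[:, None, None]
    nodata = maps[0].spec.nodata_value
    invalid = np.any(arr == nodata, axis=0)
    agreement = np.mean(arr >= thr, axis=0)
    mean_map = arr.mean(axis=0)
    refined = np.where(agreement >= 0.95, mean_map, 0.0)
    refined[invalid] = nodata
    return RasterLayer(maps[0].spec, refined, name=f"refined:{scenario}")


def binarize_refined(refined: RasterLayer, ensemble: ReplicateEnsemble) -> RasterLayer:
    """Presence/absence map: refined value >= mean replicate MSS threshold.
    Nodata propagates."""
    thr = float(np.mean(ensemble.thresholds))
    nodata = refined.spec.nodata_value
    binary = np.where(refined.values >= thr, 1.0, 0.0)
    binary[refined.values == nodata] = nodata
    return RasterLayer(refined.spec, binary, name=f"{refined.name}:binary")
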