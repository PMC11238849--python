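"""Classical flat-null cross-correlogram significance test.

The Perkel–Gerstein–Moore-style baseline analysis: assume the CC of an
unconnected pair is flat, estimate the expected per-bin count from the
far-lag region, and flag a connection when any bin in a short detection
window just off the origin escapes a two-sided Poisson confidence band
(Bonferroni-corrected over the window's bins).  A hump above the band is
labelled excitatory, a dip below it inhibitory.  Background co-modulation
violates the flat-null assumption, so this test is expected to report
spurious connections on common-input pairs — it is retained as the
baseline against which the GLM methods are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .correlogram import Correlogram

__all__ = ["ClassicalResult", "classical_test"]


@dataclass(frozen=True)
class ClassicalResult:
    """Outcome of the flat-null band test for one pair (both directions)."""

    baseline: float  # expected count per bin under the flat null
    band_low: float
    band_high: float
    decision_ij: str  # ref -> tgt, from positive-lag window
    decision_ji: str  # tgt -> ref, from mirrored negative lags
    extremal_bin_ij: float  # lag center (ms) of the largest deviation
    extremal_count_ij: int
    extremal_bin_ji: float
    extremal_count_ji: int


def _direction(counts, centers, lo, hi, baseline):
    """Label one direction from its detection-window bins."""
    if counts.size == 0:
        return "none", np.nan, 0
    dev_up = counts.max() - baseline
    dev_dn = baseline - counts.min()
    k_up = int(np.argmax(counts))
    k_dn = int(np.argmin(counts))
    above = counts[k_up] > hi
    below = counts[k_dn] < lo
    if above and (not below or dev_up >= dev_dn):
        return "excitatory", float(centers[k_up]), int(counts[k_up])
    if below:
        return "inhibitory", float(centers[k_dn]), int(counts[k_dn])
    k = k_up if dev_up >= dev_dn else k_dn
    return "none", float(centers[k]), int(counts[k])


def classical_test(cc: Correlogram, alpha: float = 1e-4,
                   detect_window: tuple = (1.0, 5.0),
                   baseline_min_lag: float = 10.0) -> ClassicalResult:
    """Two-sided Poisson band test on the detection window.

    The baseline is the mean count over bins with |lag| beyond
    *baseline_min_lag* ms; the band uses exact Poisson quantiles at level
    alpha, Bonferroni-corrected for the number of window bins per
    direction.  Direction ref→tgt is tested on positive lags within
    *detect_window* (ms), tgt→ref on the mirrored negative lags.
    """
    if cc.n_bins == 0:
        raise ValueError("empty correlogram")
    centers = cc.lag_centers
    base_sel = np.abs(centers) > baseline_min_lag
    if base_sel.sum() < 20:
        raise ValueError("need at least 20 baseline bins outside the window")
    baseline = float(cc.counts[base_sel].mean())
    pos_sel = (centers > 0) & (centers >= detect_window[0]) & (centers <= detect_window[1])
    neg_sel = (centers < 0) & (-centers >= detect_window[0]) & (-centers <= detect_window[1])
    m = max(int(pos_sel.sum()), 1)
    hi = float(poisson.ppf(1.0 - alpha / (2 * m), baseline))
    lo = float(poisson.ppf(alpha / (2 * m), baseline))
    dec_ij, bin_ij, cnt_ij = _direction(
        cc.counts[pos_sel], centers[pos_sel], lo, hi, baseline)
    dec_ji, bin_ji, cnt_ji = _direction(
        cc.counts[neg_sel], centers[neg_sel], lo, hi, baseline)
    return ClassicalResult(
        baseline=baseline, band_low=lo, band_high=hi,
        decision_ij=dec_ij, decision_ji=dec_ji,
        extremal_bin_ij=bin_ij, extremal_count_ij=cnt_ij,
        extremal_bin_ji=bin_ji, extremal_count_ji=cnt_ji,
    )
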