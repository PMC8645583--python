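"""Mass-univariate nonparametric condition comparison with FDR control.

The Wilcoxon rank-sum test is implemented directly: midranks for ties, and
either exact enumeration of all rank assignments (small samples,
n + m <= 12) or a normal approximation with tie-corrected variance and
continuity correction.  Multiplicity is handled by the Benjamini-Hochberg
step-up procedure.  A vectorized path applies the approximate test to
every (electrode, frequency-bin) cell of two single-trial spectrum sets
and pools all cells into one BH family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

from .spectral import SpectrumSet

__all__ = [
    "rank_sum_test",
    "fdr_bh",
    "SignificanceMap",
    "spectral_significance_map",
    "EXACT_MAX_N",
]

#: Largest pooled sample size for which the exact null distribution of the
#: rank sum is enumerated (C(12, 6) = 924 assignments at worst).
EXACT_MAX_N = 12


def _normal_approx_p(w: np.ndarray, n: int, m: int,
                     tie_term: np.ndarray) -> np.ndarray:
    """Two-sided p for rank sums ``w`` of the first sample (size n) under
    the null, with tie-corrected variance and continuity correction."""
    big_n = n + m
    mean = n * (big_n + 1) / 2.0
    var = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    dev = w - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(dev) - 0.5) / np.sqrt(var)
    z = np.where(np.abs(dev) <= 0.5, 0.0, z)      # continuity through zero
    p = 2.0 * ndtr(-z)
    p = np.where(var <= 0, 1.0, p)
    return np.minimum(p, 1.0)


def _exact_p(ranks: np.ndarray, n: int, w_obs: float) -> float:
    """Exact two-sided p by enumerating all C(n+m, n) rank assignments of
    the pooled midranks (valid under ties as a permutation test)."""
    big_n = ranks.size
    mean = n * (big_n + 1) / 2.0
    # under ties the permutation mean is n * mean(ranks); midranks always
    # sum to N(N+1)/2, so the two coincide
    dev_obs = abs(w_obs - mean) - 1e-9
    count = total = 0
    for comb in combinations(range(big_n), n):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mean) >= dev_obs:
            count += 1
    return count / total


def rank_sum_test(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(statistic, p)``.

    The statistic is the midrank sum of ``x`` in the pooled sample.  With
    ``method='auto'`` the exact permutation distribution is enumerated when
    n + m <= 12, otherwise the tie-corrected normal approximation with
    continuity correction is used.  Two identical flat samples give p = 1
    with the statistic at its null mean.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n].sum())
    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be 'auto', 'exact' or 'approx'")
    use_exact = method == "exact" or (method == "auto" and n + m <= EXACT_MAX_N)
    if np.ptp(pooled) == 0:
        return w, 1.0
    if use_exact:
        return w, _exact_p(ranks, n, w_obs=w)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    p = float(_normal_approx_p(np.array(w), n, m, np.array(tie_term)))
    return w, p


def rank_sum_test_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized approximate rank-sum test along axis 0.

    ``x`` (n x cells) vs ``y`` (m x cells); returns per-cell (statistic, p)
    identical to :func:`rank_sum_test` with ``method='approx'``.
    """
    n, m = x.shape[0], y.shape[0]
    pooled = np.concatenate([x, y], axis=0)
    ranks = rankdata(pooled, axis=0)
    w = ranks[:n].sum(axis=0)
    # ties: t_i = multiplicity of element i's value; sum over runs of
    # (t^3 - t) equals sum_i (t_i^2 - 1); chunked to bound the (N, N,
    # cells) comparison tensor
    n_cells = pooled.shape[1]
    tie_term = np.empty(n_cells)
    chunk = max(1, int(4e7) // max((n + m) ** 2, 1))
    for s in range(0, n_cells, chunk):
        block = pooled[:, s:s + chunk]
        eq = block[:, None, :] == block[None, :, :]
        tie_term[s:s + chunk] = (eq.sum(axis=1) ** 2 - 1).sum(axis=0)
    p = _normal_approx_p(w, n, m, tie_term)
    flat = np.ptp(pooled, axis=0) == 0
    return w, np.where(flat, 1.0, p)


def fdr_bh(pvals, q: float) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level ``q``.

    Sort p ascending, find the largest i with p(i) <= i q / m, reject every
    p <= p(i).  Returns the rejection mask in the original order and the
    realized threshold p(i) (0.0 when nothing is rejected).
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = q * np.arange(1, p.size + 1) / p.size
    passing = np.flatnonzero(ranked <= crit)
    if passing.size == 0:
        return np.zeros(p.size, dtype=bool), 0.0
    threshold = float(ranked[passing[-1]])
    return p <= threshold, threshold


@dataclass(frozen=True)
class SignificanceMap:
    """Electrode x frequency-bin test results for one comparison family."""

    channels: tuple[str, ...]
    freqs: np.ndarray
    p: np.ndarray               # electrodes x bins
    statistic: np.ndarray       # rank sum of the VR sample
    rejected: np.ndarray        # BH mask at level q
    q: float
    threshold: float            # realized BH threshold
    family: str = ""            # e.g. "subject 1, eyes_closed"

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        shape = (len(self.channels), self.freqs.size)
        for name in ("p", "statistic", "rejected"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must be electrodes x bins")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (electrode, freq_hz, statistic, p, rejected)."""
        ch_idx, bin_idx = np.meshgrid(
            np.arange(len(self.channels)), np.arange(self.freqs.size),
            indexing="ij")
        return pd.DataFrame({
            "electrode": np.array(self.channels)[ch_idx.ravel()],
            "freq_hz": self.freqs[bin_idx.ravel()],
            "statistic": self.statistic.ravel(),
            "p": self.p.ravel(),
            "rejected": self.rejected.ravel(),
        })


def spectral_significance_map(vr: SpectrumSet, novr: SpectrumSet,
                              q: float = 0.01, fmin: float = 1.0,
                              fmax: float | None = None,
                              family: str = "") -> SignificanceMap:
    """Compare single-trial spectral power between conditions, cell by cell.

    Runs the rank-sum test per (electrode, bin) on the single-trial powers
    of one eye state, restricted to [fmin, fmax] (default 1 Hz .. Nyquist),
    and pools ALL electrode x bin p-values into one BH family at level
    ``q``.
    """
    if vr.channels != novr.channels:
        raise ValueError("electrode sets differ between conditions")
    if vr.freqs.size != novr.freqs.size or not np.allclose(vr.freqs, novr.freqs):
        raise ValueError("frequency axes differ between conditions")
    if vr.n_trials < 2 or novr.n_trials < 2:
        raise ValueError("need at least 2 trials per condition")
    fmax = fmax if fmax is not None else float(vr.freqs[-1])
    vr_sel, novr_sel = vr.select(fmin, fmax), novr.select(fmin, fmax)
    n_ch, n_bins = len(vr.channels), vr_sel.freqs.size
    x = vr_sel.power.reshape(vr_sel.n_trials, n_ch * n_bins)
    y = novr_sel.power.reshape(novr_sel.n_trials, n_ch * n_bins)
    stat, p = rank_sum_test_matrix(x, y)
    mask, threshold = fdr_bh(p, q)
    return SignificanceMap(
        channels=vr.channels, freqs=vr_sel.freqs,
        p=p.reshape(n_ch, n_bins), statistic=stat.reshape(n_ch, n_bins),
        rejected=mask.reshape(n_ch, n_bins), q=q, threshold=threshold,
        family=family)
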