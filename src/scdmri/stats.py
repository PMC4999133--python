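"""ROI statistics: SNR, CNR, inter-/intra-subject CV, effect size,
two-sided Mann-Whitney U, Spearman rank correlation.

All standard deviations are sample (n-1) SDs.  The Mann-Whitney test
uses the exact null distribution (dynamic-programming count of U
arrangements) for small tie-free samples and the tie- and
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy import special
from scipy.stats import rankdata

__all__ = [
    "snr", "cnr", "cv_inter", "cv_intra", "effect_size",
    "mann_whitney", "spearman",
    "EXACT_MW_MAX_N",
]

#: exact Mann-Whitney enumeration is used when n + m <= this (tie-free)
EXACT_MW_MAX_N = 16


def _sd(x) -> float:
    return float(np.std(x, ddof=1))


def snr(volume: np.ndarray, tissue_mask: np.ndarray,
        background_mask: np.ndarray, min_background: int = 100) -> float:
    """Signal-to-noise ratio: mean tissue intensity over background SD."""
    volume = np.asarray(volume, dtype=float)
    tissue = volume[np.asarray(tissue_mask, dtype=bool)]
    bg = volume[np.asarray(background_mask, dtype=bool)]
    if tissue.size == 0:
        raise ValueError("tissue ROI is empty")
    if bg.size < min_background:
        raise ValueError(
            f"background ROI needs >= {min_background} voxels, got {bg.size}")
    sd_bg = _sd(bg)
    if sd_bg == 0:
        raise ValueError("zero background SD (noiseless image)")
    return float(tissue.mean()) / sd_bg


def cnr(metric_map: np.ndarray, wm_mask: np.ndarray,
        gm_mask: np.ndarray) -> float:
    """Signed WM/GM contrast-to-noise ratio of a parameter map:
    ``(M_WM - M_GM) / sqrt((SD_WM² + SD_GM²) / 2)``."""
    metric_map = np.asarray(metric_map, dtype=float)
    wm = metric_map[np.asarray(wm_mask, dtype=bool)]
    gm = metric_map[np.asarray(gm_mask, dtype=bool)]
    if wm.size < 2 or gm.size < 2:
        raise ValueError("both ROIs need >= 2 voxels")
    denom = np.sqrt((_sd(wm) ** 2 + _sd(gm) ** 2) / 2.0)
    if denom == 0:
        raise ValueError("zero SD in both ROIs")
    return float(wm.mean() - gm.mean()) / denom


def cv_inter(subject_means) -> float:
    """Inter-subject CV: sample SD of per-subject ROI means over their
    average."""
    x = np.asarray(subject_means, dtype=float)
    if x.size < 2:
        raise ValueError("at least 2 subjects are required")
    mean = x.mean()
    if mean == 0:
        raise ValueError("mean of subject means is zero; CV undefined")
    return _sd(x) / abs(mean)


def cv_intra(voxel_values_per_subject, return_per_subject: bool = False):
    """Intra-subject CV: per-subject within-ROI SD/mean, averaged.

    With ``return_per_subject=True`` also returns the individual CVs
    (used for between-protocol significance testing).
    """
    per_subject = []
    for i, values in enumerate(voxel_values_per_subject):
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"subject {i}: ROI needs >= 2 voxels")
        mean = v.mean()
        if mean == 0:
            raise ValueError(f"subject {i}: zero ROI mean; CV undefined")
        per_subject.append(_sd(v) / abs(mean))
    avg = float(np.mean(per_subject))
    if return_per_subject:
        return avg, np.asarray(per_subject)
    return avg


def effect_size(case_values, control_values) -> float:
    """Signed effect size: (case mean - control mean) / control SD."""
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    sd_control = _sd(control)
    if sd_control == 0:
        raise ValueError("control-group SD is zero; effect size undefined")
    return float(case.mean() - control.mean()) / sd_control


@functools.lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple:
    """Number of rank arrangements yielding each U value in [0, nm].

    Recurrence f(u; n, m) = f(u - m; n - 1, m) + f(u; n, m - 1).
    """
    if n == 0 or m == 0:
        return (1,)
    a = _u_counts(n - 1, m)   # largest observation in group x: U gains m
    b = _u_counts(n, m - 1)   # largest observation in group y
    out = [0] * (n * m + 1)
    for u, c in enumerate(a):
        out[u + m] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def _exact_two_sided_p(u: float, n: int, m: int) -> float:
    counts = np.array(_u_counts(n, m), dtype=float)
    total = counts.sum()
    u_min = min(u, n * m - u)
    # symmetric null: two-sided p = 2 P(U <= u_min), capped at 1
    p = 2.0 * counts[: int(np.floor(u_min)) + 1].sum() / total
    return float(min(1.0, p))


def mann_whitney(x, y):
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U is the statistic of the first sample.
    Tie-free samples with ``n + m <= 16`` use the exact permutation
    null (full U-distribution); larger or tied samples use the normal
    approximation with tie and continuity corrections.  An all-tied
    comparison (zero null variance) returns p = 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)          # midranks
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if not has_ties and n + m <= EXACT_MW_MAX_N:
        return u, _exact_two_sided_p(u, n, m)

    N = n + m
    mu = n * m / 2.0
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * special.ndtr(-z)))
    return u, max(p, np.finfo(float).tiny)


def spearman(x, y, exact: bool = False):
    """Spearman rank correlation with two-sided p-value.

    rho is the Pearson correlation of midranks.  The p-value uses the
    t approximation with n - 2 degrees of freedom by default, or exact
    enumeration over all permutations of one rank vector for n <= 8
    when ``exact=True``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("at least 3 observations are required")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if exact:
        if n > 8:
            raise ValueError("exact enumeration supported only for n <= 8")
        from itertools import permutations
        rx_c = rx - rx.mean()
        denom_x = np.sqrt((rx_c ** 2).sum())
        count = 0
        total = 0
        for perm in permutations(ry):
            ryp = np.asarray(perm)
            ry_c = ryp - ryp.mean()
            r = float(rx_c @ ry_c) / (denom_x * np.sqrt((ry_c ** 2).sum()))
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total

    if abs(rho) >= 1.0:
        return float(np.sign(rho)), np.finfo(float).tiny
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2.0 * special.stdtr(n - 2, -abs(t)))
    return rho, max(min(p, 1.0), np.finfo(float).tiny)
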