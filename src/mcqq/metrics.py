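"""Evaluation statistics for OEF maps.

Accuracy and precision of repeated reconstructions are summarized by the
mean signed error (ME) and the mean across-trial standard deviation (MSD):

    ME  = (1/Nv) sum_i (OEF_truth,i - OEF_avg,i)
    MSD = (1/Nv) sum_i OEF_std,i

with OEF_avg/OEF_std the per-voxel mean and population SD (divisor Nt) over
Nt noise trials.  Lesion abnormality is summarized by the ratio of lesion
mean OEF to contralateral normal-tissue mean OEF, and map similarity by
SSIM.  A Wilcoxon signed-rank test compares paired per-subject summaries
between two methods.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

__all__ = [
    "TrialStack",
    "mean_error",
    "mean_std",
    "oef_ratio",
    "ssim_map",
    "wilcoxon_signed_rank",
]


class TrialStack:
    """OEF maps from repeated noise trials, shape (n_trials, x, y, z)."""

    def __init__(self, maps: np.ndarray):
        maps = np.asarray(maps, dtype=float)
        if maps.ndim < 2 or maps.shape[0] < 1:
            raise ValueError("need at least one trial map")
        self.maps = maps

    @property
    def n_trials(self) -> int:
        return self.maps.shape[0]

    def average(self) -> np.ndarray:
        return self.maps.mean(axis=0)

    def std(self) -> np.ndarray:
        # population SD (divisor Nt), matching the printed definition
        return self.maps.std(axis=0, ddof=0)


def _check_mask(mask) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return mask


def mean_error(truth: np.ndarray, trials: TrialStack, mask) -> float:
    """Mean signed error of the trial-average map against truth (accuracy)."""
    mask = _check_mask(mask)
    return float((np.asarray(truth, float) - trials.average())[mask].mean())


def mean_std(trials: TrialStack, mask) -> float:
    """Mean across-trial per-voxel SD (precision); 0 for a single trial."""
    mask = _check_mask(mask)
    return float(trials.std()[mask].mean())


def oef_ratio(oef: np.ndarray, lesion_mask, contralateral_mask) -> float:
    """Ratio of lesion mean OEF to contralateral normal-tissue mean OEF."""
    lesion_mask = _check_mask(lesion_mask)
    contralateral_mask = _check_mask(contralateral_mask)
    oef = np.asarray(oef, dtype=float)
    normal = oef[contralateral_mask].mean()
    if normal == 0:
        raise ZeroDivisionError("contralateral mean OEF is zero")
    return float(oef[lesion_mask].mean() / normal)


def ssim_map(oef_a: np.ndarray, oef_b: np.ndarray, mask=None) -> float:
    """Mean structural similarity between two OEF maps over the mask.

    Standard constants (K1 = 0.01, K2 = 0.03); the dynamic range is the
    combined masked value range of the two maps.
    """
    oef_a = np.asarray(oef_a, dtype=float)
    oef_b = np.asarray(oef_b, dtype=float)
    if oef_a.shape != oef_b.shape:
        raise ValueError("maps must share a grid")
    if mask is None:
        mask = np.ones(oef_a.shape, dtype=bool)
    mask = _check_mask(mask)
    vals = np.concatenate([oef_a[mask], oef_b[mask]])
    drange = float(vals.max() - vals.min())
    if drange == 0:
        return 1.0
    _, smap = structural_similarity(oef_a, oef_b, data_range=drange, full=True)
    return float(smap[mask].mean())


def wilcoxon_signed_rank(a, b=None) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Call with paired differences, or with two equal-length sequences.  Uses
    the exact null distribution for n <= 25 and the normal approximation
    with continuity correction above.
    """
    a = np.asarray(a, dtype=float)
    diffs = a if b is None else a - np.asarray(b, dtype=float)
    if diffs.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.all(diffs == 0):
        raise ValueError("all differences are zero; test undefined")
    method = "exact" if diffs.size <= 25 and not np.any(diffs == 0) else "approx"
    res = stats.wilcoxon(diffs, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return float(res.pvalue)
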