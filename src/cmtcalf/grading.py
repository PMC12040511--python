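"""Ordinal MRI grading: modified Mercuri scale and STIR hyperintensity.

The modified Mercuri scale grades T1-weighted intramuscular fat
accumulation on a 6-point ordinal scale (0 normal appearance ... 5 end
stage, no residual muscle).  Grades 2-4 correspond to published fat
volume bands (<30%, 30-60%, >60% of muscle volume); the cut-offs for
grades 0/1 and 5 are set so that healthy-control fat fractions (~3%)
grade 0 and "no residual muscle" corresponds to near-total fat
replacement.

STIR hyperintensity (an oedema/denervation marker) is graded
0 none / 1 mild / 2 marked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: upper fat-fraction bound (exclusive) of each Mercuri grade 0..4;
#: grade 5 is everything at or above the last edge.
MERCURI_FF_EDGES = np.array([2.5, 15.0, 30.0, 60.0, 90.0])

#: STIR grade probabilities (none, mild, marked) by group
STIR_PROBS = {"patient": (0.90, 0.09, 0.01), "control": (0.94, 0.06, 0.0)}


def mercuri_from_ff(ff, rater_noise: float = 0.0, rng=None):
    """Map fat fraction (%) to modified Mercuri grade(s) 0-5.

    The mapping is a deterministic band lookup on the true fat
    fraction; with probability ``rater_noise`` the grade is moved one
    step up or down (equiprobably) and clipped to [0, 5], emulating
    inter-rater variability.

    Parameters
    ----------
    ff : float or array-like
        Fat fraction in percent, each value in [0, 100].
    rater_noise : float
        Probability of a +/-1-step misgrade, in [0, 1].
    rng : numpy Generator, optional
        Required when ``rater_noise > 0``.

    Returns
    -------
    int or ndarray of int
    """
    ff_arr = np.asarray(ff, dtype=float)
    if np.any((ff_arr < 0) | (ff_arr > 100)):
        raise ValueError("fat fraction must lie in [0, 100]")
    if not 0.0 <= rater_noise <= 1.0:
        raise ValueError("rater_noise must lie in [0, 1]")
    grade = np.searchsorted(MERCURI_FF_EDGES, ff_arr, side="right")
    if rater_noise > 0.0:
        if rng is None:
            raise ValueError("rater_noise > 0 requires an rng")
        flip = rng.random(grade.shape) < rater_noise
        step = rng.choice([-1, 1], size=grade.shape)
        grade = np.clip(grade + flip * step, 0, 5)
    grade = grade.astype(int)
    return grade if grade.ndim else int(grade)


def simulate_stir(n: int, group: str, rng) -> np.ndarray:
    """Draw per-muscle STIR grades {0,1,2} at the observed prevalences."""
    probs = STIR_PROBS[group]
    return rng.choice(3, size=n, p=probs)


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation with its significance and provenance."""

    rho: float
    p: float
    n: int
    method: str = "Spearman"
    note: str = ""

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.rho)

    def to_dict(self) -> dict:
        return {"rho": self.rho, "p": self.p, "n": self.n,
                "method": self.method, "note": self.note}


def grade_ff_agreement(grades, ffs) -> CorrelationResult:
    """Spearman agreement between Mercuri grades and quantitative FF.

    Accepts per-subject pairs (mean muscle grade vs whole-calf summary
    FF) or per-muscle pairs (single grade vs muscle FF).  Ties are
    handled by average ranks; the p-value is two-sided.  Constant input
    leaves rho undefined and is flagged rather than raised.
    """
    g = np.asarray(grades, dtype=float)
    f = np.asarray(ffs, dtype=float)
    if g.shape != f.shape or g.ndim != 1:
        raise ValueError("grades and ffs must be 1-D and the same length")
    keep = np.isfinite(g) & np.isfinite(f)
    g, f = g[keep], f[keep]
    if g.size < 5:
        raise ValueError(f"need >= 5 pairs, got {g.size}")
    if np.ptp(g) == 0 or np.ptp(f) == 0:
        return CorrelationResult(float("nan"), float("nan"), int(g.size),
                                 note="constant input, rho undefined")
    rho, p = stats.spearmanr(g, f)
    return CorrelationResult(float(rho), float(p), int(g.size))
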