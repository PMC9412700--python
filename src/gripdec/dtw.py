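"""Multivariate dynamic time warping, template selection and warp-resampling.

Movement sequences differ in duration and local tempo across repetitions and
subjects, so trials cannot be compared sample-by-sample.  Dynamic time
warping (DTW) finds the monotone, continuous warping path minimizing the
cumulative Euclidean distance between the c-dimensional samples of two
series (dependent/multivariate warping: all channels warp together).

A representative *template* trial is chosen from the training set by pairing
trial i with trial i + floor(n/2) and scoring each pairing with
s_i = rho_i * (1 - d_i), where rho_i is the Pearson correlation of the
path-aligned pair and d_i the DTW distance normalized so the largest pairing
distance is 1.  The first trial of the best-scoring pair becomes the
template; every trial is then warp-resampled to the template's length
(samples of a trial mapped onto one repeated template index are averaged),
yielding the fixed-size feature space a linear SVM requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .data import Trial


# ---------------------------------------------------------------------------
# Core dynamic program
# ---------------------------------------------------------------------------

@njit(cache=True)
def _accumulate(cost):  # pragma: no cover - exercised via dtw()
    t1, t2 = cost.shape
    D = np.empty((t1, t2))
    D[0, 0] = cost[0, 0]
    for j in range(1, t2):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, t1):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
        for j in range(1, t2):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost[i, j] + best
    return D


@njit(cache=True)
def _backtrace(D):  # pragma: no cover - exercised via dtw()
    t1, t2 = D.shape
    maxlen = t1 + t2 - 1
    pp = np.empty(maxlen, dtype=np.int64)
    qq = np.empty(maxlen, dtype=np.int64)
    i, j = t1 - 1, t2 - 1
    k = maxlen - 1
    pp[k] = i
    qq[k] = j
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            d_diag = D[i - 1, j - 1]
            d_up = D[i - 1, j]
            d_left = D[i, j - 1]
            # ties prefer the diagonal so identical inputs yield the
            # identity path, then the shorter-path predecessors
            if d_diag <= d_up and d_diag <= d_left:
                i -= 1
                j -= 1
            elif d_up <= d_left:
                i -= 1
            else:
                j -= 1
        k -= 1
        pp[k] = i
        qq[k] = j
    return pp[k:], qq[k:]


def dtw(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """DTW distance and optimal warping path between two (t x c) series.

    Point cost is the Euclidean distance between c-dimensional samples;
    admissible path steps are (1,0), (0,1), (1,1) with fixed endpoints.

    Returns
    -------
    distance : float
        Minimum cumulative point distance along an admissible path.
    path : (L, 2) int array
        Index pairs (p into x, q into y), 0-based, starting at (0, 0) and
        ending at (t_x - 1, t_y - 1); L <= t_x + t_y - 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.ndim != 2 or y.ndim != 2:
        raise ValueError("inputs must be 2-D (time x channel)")
    if x.shape[1] != y.shape[1]:
        raise ValueError(f"channel mismatch: {x.shape[1]} vs {y.shape[1]}")
    cost = cdist(x, y, metric="euclidean")
    D = _accumulate(cost)
    pp, qq = _backtrace(D)
    return float(D[-1, -1]), np.column_stack([pp, qq])


# ---------------------------------------------------------------------------
# Template selection
# ---------------------------------------------------------------------------

@dataclass
class TemplateScore:
    """Score of one template-candidate pairing: s = rho * (1 - d)."""

    index: int      # pairing index i (0-based): trial i vs trial i + n//2
    rho: float      # Pearson correlation of the path-aligned pair
    dist: float     # DTW distance, normalized so max over pairings is 1
    score: float


@dataclass
class Template:
    """The representative trial defining the fixed feature-space length."""

    values: np.ndarray
    sample_rate: float
    provenance: dict

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def _aligned_correlation(x: np.ndarray, y: np.ndarray,
                         path: np.ndarray) -> float:
    """Pearson correlation between two series expanded along a warping path,
    flattened across channels and path steps."""
    xa = x[path[:, 0]].ravel()
    ya = y[path[:, 1]].ravel()
    sx, sy = xa.std(), ya.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for constant aligned series")
    return float(np.corrcoef(xa, ya)[0, 1])


def select_template(trials: list[Trial]) -> tuple[Template, list[TemplateScore]]:
    """Pick the most representative trial as alignment template.

    Trial i is paired with trial i + floor(n/2) for i = 0 .. floor(n/2) - 2;
    this small subset of pairings suffices to find a series that is not an
    outlier.  Raw DTW distances are normalized so the largest is 1; the
    first trial of the pairing maximizing s_i = rho_i (1 - d_i) is returned
    (ties broken by lowest pairing index).
    """
    n = len(trials)
    if n < 4:
        raise ValueError("template selection needs at least 4 trials")
    half = n // 2
    raw, rhos = [], []
    for i in range(half - 1):
        x, y = trials[i].values, trials[i + half].values
        dist, path = dtw(x, y)
        raw.append(dist)
        rhos.append(_aligned_correlation(x, y, path))
    raw = np.array(raw)
    dmax = raw.max()
    # all pairings identical: distances stay 0 and scores reduce to rho
    norm = raw / dmax if dmax > 0 else raw
    scores = [TemplateScore(i, rhos[i], float(norm[i]),
                            rhos[i] * (1.0 - float(norm[i])))
              for i in range(half - 1)]
    best = max(range(half - 1), key=lambda i: (scores[i].score, -i))
    chosen = trials[best]
    template = Template(
        values=chosen.values.copy(),
        sample_rate=chosen.sample_rate,
        provenance={"subject_id": chosen.subject_id, "run": chosen.run,
                    "block": chosen.block, "trial_index": best},
    )
    return template, scores


# ---------------------------------------------------------------------------
# Warp-resampling
# ---------------------------------------------------------------------------

def warp_to_template(trial: Trial, template: Template) -> Trial:
    """Resample a trial to the template's length along the DTW path.

    All trial samples whose path steps map onto the same template index are
    averaged per channel; a template index paired with a single trial sample
    replicates that sample.  The output always has exactly the template's
    number of samples; warping the template's own series returns it exactly.
    """
    if trial.n_channels != template.n_channels:
        raise ValueError("trial/template channel mismatch")
    _, path = dtw(trial.values, template.values)
    t_T = template.n_samples
    sums = np.zeros((t_T, trial.n_channels))
    counts = np.zeros(t_T)
    np.add.at(sums, path[:, 1], trial.values[path[:, 0]])
    np.add.at(counts, path[:, 1], 1.0)
    aligned = sums / counts[:, None]
    return trial.with_values(aligned, stage="aligned",
                             sample_rate=template.sample_rate)


def align_dataset(train: list[Trial], test: list[Trial] | None = None,
                  ) -> tuple[Template, list[Trial], list[Trial]]:
    """Select a template from the training trials and warp both splits to it.

    The template is chosen from training trials only, so no information from
    the test split enters the feature-space definition.
    """
    template, _ = select_template(train)
    aligned_train = [warp_to_template(t, template) for t in train]
    aligned_test = [warp_to_template(t, template) for t in (test or [])]
    return template, aligned_train, aligned_test


def to_feature_matrix(trials: list[Trial]) -> np.ndarray:
    """Flatten aligned (t_T x c) trials into an (n x t_T*c) feature matrix."""
    if not trials:
        return np.empty((0, 0))
    return np.stack([t.values.ravel() for t in trials])
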