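"""Parameter-free Monte Carlo prediction of swap frequency.

Predicts how often a non-target item would be selected for report, given
only the empirically observed report errors for the cue-feature dimension.
For each trial, errors are resampled with replacement from the matching
error pool (same condition level), added to every item's cue feature, and
the item whose perturbed cue feature lands nearest the cue is "selected";
the trial simulates a swap whenever that item is a non-target.  Averaging
over many iterations per trial yields a predicted swap proportion that can
be compared directly with empirical estimates — no free parameters, no
distributional assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np

from .circular import wrap
from .taskgen import TrialArray

__all__ = ["ErrorPool", "predict_swaps", "pools_from_errors"]


@dataclass
class ErrorPool:
    """Report-dimension errors observed under one condition level.

    The pool should come from the condition in which the cue-feature
    dimension was itself reported (same source/participant, same stimulus
    level), so that its spread reflects memory variability for that feature.
    """

    level: str
    errors: np.ndarray

    def __post_init__(self):
        self.errors = np.atleast_1d(np.asarray(self.errors, dtype=float))
        if self.errors.size == 0:
            raise ValueError(f"empty error pool for level {self.level!r}")
        self.errors = wrap(self.errors)


def pools_from_errors(errors_by_level: Mapping[str, Sequence[float]]) -> Dict[str, ErrorPool]:
    return {lvl: ErrorPool(level=lvl, errors=np.asarray(e))
            for lvl, e in errors_by_level.items()}


def predict_swaps(trials: Sequence[TrialArray], pools: Mapping[str, ErrorPool],
                  n_iter: int = 1000, rng: np.random.Generator | None = None,
                  chunk: int = 200) -> Dict[str, dict]:
    """Predicted swap proportion per condition level.

    For each trial and iteration, one error per item is drawn independently
    with replacement from the trial's level pool and added to the item's cue
    feature; the trial counts as a swap iff the minimum absolute circular
    distance to the cue (the target's true cue feature) is achieved by a
    non-target.  Ties go to the target.  Returns, per level, the mean
    proportion over trials x iterations plus bookkeeping counts.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(trials) == 0:
        raise ValueError("no trials")
    levels = sorted({t.level for t in trials})
    missing = [lvl for lvl in levels if lvl not in pools]
    if missing:
        raise ValueError(f"no error pool for level(s) {missing}")

    out: Dict[str, dict] = {}
    for lvl in levels:
        sub = [t for t in trials if t.level == lvl]
        pool = pools[lvl].errors
        cue = np.stack([t.cue_feats for t in sub])            # (M, N)
        tgt = np.array([t.target for t in sub])
        m, n = cue.shape
        cue_val = cue[np.arange(m), tgt]                      # the cue itself
        swaps = 0
        total = 0
        for start in range(0, n_iter, chunk):
            c = min(chunk, n_iter - start)
            draws = rng.integers(0, pool.size, size=(m, c, n))
            perturbed = wrap(cue[:, None, :] + pool[draws])
            dist = np.abs(wrap(perturbed - cue_val[:, None, None]))
            idx = tgt[:, None, None].repeat(c, 1)
            d_t = np.take_along_axis(dist, idx, axis=2)[:, :, 0]
            dist_nt = dist.copy()
            np.put_along_axis(dist_nt, tgt[:, None, None].repeat(c, 1), np.inf,
                              axis=2)
            swaps += int((dist_nt.min(axis=2) < d_t).sum())
            total += m * c
        out[lvl] = {
            "predicted_proportion": swaps / total,
            "n_trials": m,
            "n_iter": n_iter,
        }
    return out
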