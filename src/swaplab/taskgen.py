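"""Synthetic cued-recall data generator.

Builds memory arrays with the structural constraints of three cued-recall
experiments and simulates responses from known generative processes, so that
every estimator downstream can be tested against ground truth:

* Exp-1 style: set size 6, orientation x location, minimum separations of
  30 deg in location and 15 deg in native orientation space (30 deg after the
  orientation space is doubled onto the full circle), three stimulus-quality
  levels (ellipse elongation).
* Exp-2 style: set size 4, motion direction x location, 60 deg minimum
  separation in both dimensions, three coherence levels.
* Exp-3 style: set size 6, orientation report with a spatial cue; locations
  fixed / rotated / random (36 deg minimum separation when random),
  orientations unconstrained.

All features are stored internally in radians on (-pi, pi] *after* any
orientation doubling.  Arrays are drawn by rejection sampling, i.e. uniformly
over the constraint-satisfying set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .circular import TWO_PI, circ_dist, wrap

__all__ = [
    "TrialArray",
    "ResponseRecord",
    "ExperimentConfig",
    "MixtureGenParams",
    "exp1_config",
    "exp2_config",
    "exp3_config",
    "generate_array",
    "generate_spatial_config",
    "generate_trials",
    "simulate_responses",
    "sample_min_sep",
    "make_error_sampler",
    "response_arrays",
    "records_to_frame",
    "frame_to_records",
    "write_responses",
    "read_responses",
]


@dataclass
class TrialArray:
    """One memory array: per-item cue and report features plus the target.

    ``cue_feats[i]`` is item i's value in the cueing dimension and
    ``rep_feats[i]`` its value in the reported dimension; ``target`` indexes
    the cued item.  ``cue_dim`` tags which physical dimension is the cue
    (location, orientation or direction) and ``level`` the stimulus-quality
    condition.
    """

    cue_feats: np.ndarray
    rep_feats: np.ndarray
    target: int
    level: str
    cue_dim: str

    def __post_init__(self):
        self.cue_feats = np.asarray(self.cue_feats, dtype=float)
        self.rep_feats = np.asarray(self.rep_feats, dtype=float)
        if self.cue_feats.shape != self.rep_feats.shape:
            raise ValueError("cue and report features must have equal length")
        if not (0 <= self.target < self.set_size):
            raise ValueError("target index out of range")

    @property
    def set_size(self) -> int:
        return len(self.cue_feats)

    @property
    def nontarget_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.set_size) if i != self.target])


@dataclass
class ResponseRecord:
    """A trial plus the observed response and derived circular deviations.

    ``ground_truth_selected`` is the item the generative process actually
    read out (-1 for a uniform/guess response); it is ``None`` for data whose
    generative origin is unknown.
    """

    trial: TrialArray
    response: float
    error_to_target: float = field(init=False)
    deviations_to_nontargets: np.ndarray = field(init=False)
    ground_truth_selected: Optional[int] = None

    def __post_init__(self):
        t = self.trial
        self.response = float(wrap(self.response))
        self.error_to_target = float(circ_dist(self.response, t.rep_feats[t.target]))
        self.deviations_to_nontargets = circ_dist(
            self.response, t.rep_feats[t.nontarget_indices]
        )


@dataclass
class ExperimentConfig:
    """Structural and generative description of one synthetic experiment."""

    set_size: int
    levels: Sequence[str]
    min_sep_cue: float  # radians, in the scaled (full-circle) space
    min_sep_rep: float
    n_trials_per_level: int
    cue_dim: str  # {"location", "orientation", "direction"}
    spatial_mode: str = "continuous"  # {"continuous", "fixed", "rotated", "random"}
    seed: int = 0

    def __post_init__(self):
        for name, sep in (("cue", self.min_sep_cue), ("rep", self.min_sep_rep)):
            if self.set_size * sep > TWO_PI + 1e-12:
                raise ValueError(
                    f"infeasible min_sep_{name}: {self.set_size} items with "
                    f"separation {sep:.4f} rad exceed the circle"
                )
        if self.spatial_mode not in ("continuous", "fixed", "rotated", "random"):
            raise ValueError(f"unknown spatial_mode {self.spatial_mode!r}")


def exp1_config(condition: str = "location-report", n_trials_per_level: int = 96,
                seed: int = 0) -> ExperimentConfig:
    """Six ellipses; 30 deg location separation, 15 deg native orientation
    separation (30 deg once doubled).  ``condition`` selects which dimension
    cues and which is reported."""
    sep = np.pi / 6.0
    if condition == "location-report":
        cue_dim = "orientation"
    elif condition == "orientation-report":
        cue_dim = "location"
    else:
        raise ValueError("condition must be 'location-report' or 'orientation-report'")
    return ExperimentConfig(
        set_size=6, levels=("low", "medium", "high"), min_sep_cue=sep,
        min_sep_rep=sep, n_trials_per_level=n_trials_per_level,
        cue_dim=cue_dim, seed=seed,
    )


def exp2_config(condition: str = "location-report", n_trials_per_level: int = 96,
                seed: int = 0) -> ExperimentConfig:
    """Four motion stimuli; 60 deg minimum separation in direction and location."""
    sep = np.pi / 3.0
    if condition == "location-report":
        cue_dim = "direction"
    elif condition == "direction-report":
        cue_dim = "location"
    else:
        raise ValueError("condition must be 'location-report' or 'direction-report'")
    return ExperimentConfig(
        set_size=4, levels=("low", "medium", "high"), min_sep_cue=sep,
        min_sep_rep=sep, n_trials_per_level=n_trials_per_level,
        cue_dim=cue_dim, seed=seed,
    )


def exp3_config(spatial_mode: str = "random", n_trials: int = 109,
                seed: int = 0) -> ExperimentConfig:
    """Orientation report with a spatial cue; six Gabors whose locations are
    fixed/rotated (equispaced, 60 deg apart) or random with a 36 deg minimum
    separation.  Orientations are unconstrained."""
    if spatial_mode not in ("fixed", "rotated", "random"):
        raise ValueError("spatial_mode must be 'fixed', 'rotated' or 'random'")
    min_sep_cue = np.deg2rad(36.0) if spatial_mode == "random" else 0.0
    return ExperimentConfig(
        set_size=6, levels=(spatial_mode,), min_sep_cue=min_sep_cue,
        min_sep_rep=0.0, n_trials_per_level=n_trials, cue_dim="location",
        spatial_mode=spatial_mode, seed=seed,
    )


def _min_adjacent_gap(sorted_angles: np.ndarray) -> np.ndarray:
    """Smallest circular gap between adjacent sorted angles, batched (B, n)."""
    gaps = np.diff(sorted_angles, axis=-1)
    wrap_gap = TWO_PI - (sorted_angles[..., -1] - sorted_angles[..., 0])
    return np.minimum(gaps.min(axis=-1), wrap_gap)


def sample_min_sep(n: int, min_sep: float, rng: np.random.Generator,
                   size: int = 1) -> np.ndarray:
    """Draw ``size`` sets of n angles, uniform over the configurations whose
    pairwise circular separations are all >= min_sep (rejection sampling).

    Returns an array of shape (size, n).  Raises if the constraint set is
    empty or has measure zero (n * min_sep >= 2 pi for n >= 2).
    """
    if n < 1:
        raise ValueError("need at least one item")
    if min_sep < 0:
        raise ValueError("min_sep must be nonnegative")
    if n == 1 or min_sep == 0.0:
        return wrap(rng.uniform(-np.pi, np.pi, size=(size, n)))
    if n * min_sep >= TWO_PI - 1e-12:
        raise ValueError("n * min_sep >= 2 pi: rejection sampling infeasible")
    out = np.empty((size, n))
    filled = 0
    batch = max(64, 2 * size)
    while filled < size:
        cand = rng.uniform(-np.pi, np.pi, size=(batch, n))
        ok = _min_adjacent_gap(np.sort(cand, axis=-1)) >= min_sep
        good = cand[ok]
        take = min(size - filled, len(good))
        out[filled:filled + take] = good[:take]
        filled += take
    return wrap(out)


def generate_spatial_config(mode: str, n_locations: int, min_sep: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Item locations for one trial under a spatial-configuration regime.

    fixed   -> the same equispaced set every call (2 pi / n apart);
    rotated -> equispaced set with a fresh uniform global rotation;
    random  -> rejection-sampled with the given minimum separation.
    """
    base = wrap(np.arange(n_locations) * TWO_PI / n_locations)
    if mode == "fixed":
        return base
    if mode == "rotated":
        return wrap(base + rng.uniform(-np.pi, np.pi))
    if mode == "random":
        return sample_min_sep(n_locations, min_sep, rng, size=1)[0]
    raise ValueError(f"unknown spatial mode {mode!r}")


def generate_array(config: ExperimentConfig, rng: np.random.Generator,
                   level: Optional[str] = None) -> TrialArray:
    """Draw one memory array satisfying the configuration's constraints."""
    level = level if level is not None else config.levels[0]
    if config.spatial_mode == "continuous":
        cue = sample_min_sep(config.set_size, config.min_sep_cue, rng, 1)[0]
    else:
        # Cue dimension is spatial in the structured-configuration designs.
        cue = generate_spatial_config(config.spatial_mode, config.set_size,
                                      config.min_sep_cue, rng)
    rep = sample_min_sep(config.set_size, config.min_sep_rep, rng, 1)[0]
    target = int(rng.integers(config.set_size))
    return TrialArray(cue_feats=cue, rep_feats=rep, target=target,
                      level=level, cue_dim=config.cue_dim)


def generate_trials(config: ExperimentConfig,
                    rng: Optional[np.random.Generator] = None) -> list[TrialArray]:
    """All trials for one synthetic session, levels interleaved.

    With no explicit ``rng``, per-trial substreams are derived from
    ``config.seed`` via SeedSequence spawning, so output is reproducible and
    independent of trial order.
    """
    n_total = config.n_trials_per_level * len(config.levels)
    if rng is None:
        children = np.random.SeedSequence(config.seed).spawn(n_total)
        rngs = [np.random.default_rng(c) for c in children]
    else:
        rngs = [rng] * n_total
    trials = []
    k = 0
    for level in config.levels:
        for _ in range(config.n_trials_per_level):
            trials.append(generate_array(config, rngs[k], level=level))
            k += 1
    return trials


# ---------------------------------------------------------------------------
# Response simulation


@dataclass
class MixtureGenParams:
    """Generating parameters for the three-component response process."""

    p_target: float
    p_nontarget: float
    p_uniform: float
    kappa: float = 8.0
    error: str = "vonmises"  # or "wrapped_laplace"
    scale: float = 0.4  # wrapped-Laplace scale, radians

    def __post_init__(self):
        total = self.p_target + self.p_nontarget + self.p_uniform
        if not np.isclose(total, 1.0):
            raise ValueError("mixture weights must sum to 1")
        if min(self.p_target, self.p_nontarget, self.p_uniform) < -1e-12:
            raise ValueError("mixture weights must be nonnegative")


def make_error_sampler(params: MixtureGenParams) -> Callable[[int, np.random.Generator], np.ndarray]:
    if params.error == "vonmises":
        return lambda n, rng: wrap(rng.vonmises(0.0, params.kappa, size=n))
    if params.error == "wrapped_laplace":
        return lambda n, rng: wrap(rng.laplace(0.0, params.scale, size=n))
    raise ValueError(f"unknown error family {params.error!r}")


def _simulate_mixture(trials, params: MixtureGenParams, rng) -> list[ResponseRecord]:
    sampler = make_error_sampler(params)
    m = len(trials)
    comp = rng.choice(3, size=m, p=[params.p_target, params.p_nontarget, params.p_uniform])
    errs = sampler(m, rng)
    records = []
    for trial, c, e in zip(trials, comp, errs):
        if c == 0:
            src = trial.target
            resp = trial.rep_feats[src] + e
        elif c == 1:
            src = int(rng.choice(trial.nontarget_indices))
            resp = trial.rep_feats[src] + e
        else:
            src = -1
            resp = rng.uniform(-np.pi, np.pi)
        records.append(ResponseRecord(trial=trial, response=float(wrap(resp)),
                                      ground_truth_selected=src))
    return records


def simulate_responses(trials: Sequence[TrialArray], model: str, params,
                       rng: np.random.Generator) -> list[ResponseRecord]:
    """Simulate one response per trial from a known generative process.

    ``model`` selects the process: ``"target_only"`` (von Mises noise around
    the target's report feature; ``params`` is the concentration),
    ``"mixture"`` (three-component process, :class:`MixtureGenParams`),
    ``"nbm"`` (neural binding model; params from :mod:`swaplab.nbm`) or
    ``"im"`` (interference model; params from :mod:`swaplab.interference`).
    """
    if model == "target_only":
        kappa = float(params)
        if kappa < 0:
            raise ValueError("kappa must be nonnegative")
        errs = wrap(rng.vonmises(0.0, kappa, size=len(trials)))
        return [
            ResponseRecord(trial=t, response=float(wrap(t.rep_feats[t.target] + e)),
                           ground_truth_selected=t.target)
            for t, e in zip(trials, errs)
        ]
    if model == "mixture":
        return _simulate_mixture(trials, params, rng)
    if model == "nbm":
        from . import nbm
        return [rec for rec, _ in nbm.simulate_trials(trials, params, rng)]
    if model == "im":
        from . import interference
        return interference.simulate_responses(trials, params, rng)
    raise ValueError(f"unknown generative model {model!r}")


# ---------------------------------------------------------------------------
# Tabular I/O and array views


def response_arrays(records: Sequence[ResponseRecord]) -> dict:
    """Columnar view of a homogeneous set of records (single set size)."""
    if len(records) == 0:
        raise ValueError("no records")
    n = records[0].trial.set_size
    if any(r.trial.set_size != n for r in records):
        raise ValueError("mixed set sizes are not supported in array form")
    return {
        "response": np.array([r.response for r in records]),
        "target": np.array([r.trial.target for r in records]),
        "cue": np.stack([r.trial.cue_feats for r in records]),
        "rep": np.stack([r.trial.rep_feats for r in records]),
        "level": np.array([r.trial.level for r in records]),
        "cue_dim": np.array([r.trial.cue_dim for r in records]),
        "error_to_target": np.array([r.error_to_target for r in records]),
        "set_size": n,
    }


def records_to_frame(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        t = r.trial
        row = {"trial_id": i, "level": t.level, "cue_dim": t.cue_dim,
               "set_size": t.set_size, "target_index": t.target}
        for j in range(t.set_size):
            row[f"cue_{j + 1}"] = round(float(t.cue_feats[j]), 6)
            row[f"rep_{j + 1}"] = round(float(t.rep_feats[j]), 6)
        row["response"] = round(float(r.response), 6)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[ResponseRecord]:
    records = []
    for _, row in frame.iterrows():
        n = int(row["set_size"])
        trial = TrialArray(
            cue_feats=np.array([row[f"cue_{j + 1}"] for j in range(n)], dtype=float),
            rep_feats=np.array([row[f"rep_{j + 1}"] for j in range(n)], dtype=float),
            target=int(row["target_index"]),
            level=str(row["level"]),
            cue_dim=str(row["cue_dim"]),
        )
        records.append(ResponseRecord(trial=trial, response=float(row["response"])))
    return records


def write_responses(records: Sequence[ResponseRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_responses(path) -> list[ResponseRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t"))
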