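"""Interference model of cued recall: density, likelihood and fitting.

Retrieval mixes three routes.  Cue-based retrieval selects each item with a
weight that decays exponentially with the circular distance between its cue
feature and the retrieval cue (the target has distance zero and weight one;
the cue-based weight scale A_c is fixed at 1).  Cue-independent retrieval
activates every item equally with weight A_a.  Background noise contributes
a uniform component with weight A_b.  One item is held in the focus of
attention; when that item is the target (probability 1/N under simultaneous
presentation), it is reported with enhanced precision kappa_f and the
noise weights A_a, A_b are reduced by the factor r.  Responses are von
Mises draws centred on the selected item's report feature (concentration
kappa outside the focus, kappa_f for the focused target).

Two variants are fit: the full model (6 free parameters per condition cell:
kappa, kappa_f, A_a, A_b, s, r) and a partial model with the
cue-independent weight A_a frozen at zero (5 parameters).  The model makes
no prediction linking report variability in one dimension to swap frequency
when that dimension cues, so it is fit to each report-condition x level
cell independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .circular import TWO_PI, vm_pdf, wrap
from .taskgen import ResponseRecord, TrialArray, response_arrays

__all__ = [
    "IMParams",
    "IMFitResult",
    "im_response_density",
    "im_loglik",
    "fit_im",
    "simulate_responses",
]

A_C = 1.0  # cue-based retrieval weight, fixed


@dataclass
class IMParams:
    """kappa/kappa_f: report precision outside/inside the focus of
    attention; A_a: cue-independent retrieval weight; A_b: background-noise
    weight; s: similarity scale of the exponential cue-matching kernel
    (radians); r: reduction of A_a and A_b when the target is focused."""

    kappa: float
    kappa_f: float
    A_a: float
    A_b: float
    s: float
    r: float
    p_focus_target: Optional[float] = None  # defaults to 1/set_size

    def __post_init__(self):
        if self.kappa <= 0 or self.kappa_f <= 0:
            raise ValueError("concentrations must be positive")
        if self.A_a < 0 or self.A_b < 0:
            raise ValueError("weights must be nonnegative")
        if self.s <= 0:
            raise ValueError("similarity scale s must be positive")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("focus reduction r must lie in [0, 1]")


def _state_weights(array: TrialArray, params: IMParams, focused: bool):
    """Per-item selection weights and uniform weight for one focus state."""
    cue_val = array.cue_feats[array.target]
    d = np.abs(wrap(array.cue_feats - cue_val))
    w = A_C * np.exp(-d / params.s)
    scale = params.r if focused else 1.0
    a = params.A_a * scale
    b = params.A_b * scale
    item_w = w + a
    z = item_w.sum() + b
    return item_w / z, b / z


def im_response_density(array: TrialArray, params: IMParams,
                        variant: str = "full",
                        x: Optional[np.ndarray] = None):
    """Response density for one trial, mixed over focus states.

    ``variant="partial"`` forces A_a = 0.  Evaluated at ``x`` (defaults to a
    720-point grid); integrates to 1 over the circle.
    """
    if variant not in ("full", "partial"):
        raise ValueError("variant must be 'full' or 'partial'")
    params = _apply_variant(params, variant)
    n = array.set_size
    p_focus = params.p_focus_target if params.p_focus_target is not None else 1.0 / n
    if x is None:
        x = -np.pi + (np.arange(720) + 0.5) * TWO_PI / 720
    x = np.asarray(x, dtype=float)

    dens = np.zeros_like(x)
    for focused, p_state in ((True, p_focus), (False, 1.0 - p_focus)):
        item_w, unif_w = _state_weights(array, params, focused)
        state = np.full_like(x, unif_w / TWO_PI)
        for j in range(n):
            kappa = (params.kappa_f
                     if focused and j == array.target else params.kappa)
            state += item_w[j] * vm_pdf(x - array.rep_feats[j], 0.0, kappa)
        dens += p_state * state
    return x, dens


def _apply_variant(params: IMParams, variant: str) -> IMParams:
    if variant == "partial" and params.A_a != 0.0:
        return IMParams(kappa=params.kappa, kappa_f=params.kappa_f, A_a=0.0,
                        A_b=params.A_b, s=params.s, r=params.r,
                        p_focus_target=params.p_focus_target)
    return params


def _check_single_cell(records: Sequence[ResponseRecord]):
    cells = {(r.trial.level, r.trial.cue_dim) for r in records}
    if len(cells) > 1:
        raise ValueError(
            f"records span multiple condition cells {sorted(cells)}; "
            "the interference model is fit per cell")


def im_loglik(records: Sequence[ResponseRecord], params: IMParams,
              variant: str = "full") -> float:
    """Sum of log response densities over one condition cell."""
    _check_single_cell(records)
    params = _apply_variant(params, variant)
    arr = response_arrays(records)
    x, rep, tgt, cue = (arr["response"], arr["rep"], arr["target"], arr["cue"])
    m, n = rep.shape
    p_focus = params.p_focus_target if params.p_focus_target is not None else 1.0 / n

    cue_val = cue[np.arange(m), tgt]
    d = np.abs(wrap(cue - cue_val[:, None]))
    w = A_C * np.exp(-d / params.s)
    vm_mat = vm_pdf(x[:, None] - rep, 0.0, params.kappa)       # (M, N)
    vm_tgt_f = vm_pdf(x - rep[np.arange(m), tgt], 0.0, params.kappa_f)

    total = np.zeros(m)
    for focused, p_state in ((True, p_focus), (False, 1.0 - p_focus)):
        scale = params.r if focused else 1.0
        item_w = w + params.A_a * scale
        z = item_w.sum(axis=1) + params.A_b * scale
        comp = vm_mat.copy()
        if focused:
            comp[np.arange(m), tgt] = vm_tgt_f
        state = ((item_w * comp).sum(axis=1)
                 + params.A_b * scale / TWO_PI) / z
        total += p_state * state
    return float(np.log(np.clip(total, 1e-300, None)).sum())


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class IMFitResult:
    variant: str
    cells: dict                      # (level, cue_dim) -> per-cell fit dict
    loglik: float = field(init=False)
    n_params: int = field(init=False)
    n_obs: int = field(init=False)
    aic: float = field(init=False)
    bic: float = field(init=False)
    converged: bool = field(init=False)

    def __post_init__(self):
        self.loglik = sum(c["loglik"] for c in self.cells.values())
        self.n_params = sum(c["n_params"] for c in self.cells.values())
        self.n_obs = sum(c["n_obs"] for c in self.cells.values())
        self.aic = 2.0 * self.n_params - 2.0 * self.loglik
        self.bic = sum(c["n_params"] * np.log(c["n_obs"])
                       - 2.0 * c["loglik"] for c in self.cells.values())
        self.converged = all(c["converged"] for c in self.cells.values())


_N_FREE = {"full": 6, "partial": 5}


def _pack_im(p: IMParams, variant: str) -> np.ndarray:
    logit = lambda v: np.log(np.clip(v, 1e-4, 1 - 1e-4)
                             / (1 - np.clip(v, 1e-4, 1 - 1e-4)))
    out = [np.log(p.kappa), np.log(p.kappa_f), np.log(max(p.A_b, 1e-6)),
           np.log(p.s), logit(p.r)]
    if variant == "full":
        out.insert(2, np.log(max(p.A_a, 1e-6)))
    return np.array(out)


def _unpack_im(theta: np.ndarray, variant: str) -> IMParams:
    expit = lambda v: 1.0 / (1.0 + np.exp(-v))
    i = 0
    kappa = float(np.exp(np.clip(theta[i], -2, 6))); i += 1
    kappa_f = float(np.exp(np.clip(theta[i], -2, 6))); i += 1
    if variant == "full":
        a_a = float(np.exp(np.clip(theta[i], -14, 4))); i += 1
    else:
        a_a = 0.0
    a_b = float(np.exp(np.clip(theta[i], -14, 4))); i += 1
    s = float(np.exp(np.clip(theta[i], -4, 3))); i += 1
    r = float(expit(theta[i]))
    return IMParams(kappa=kappa, kappa_f=kappa_f, A_a=a_a, A_b=a_b, s=s, r=r)


def fit_im(records: Sequence[ResponseRecord], variant: str = "full",
           n_restarts: int = 3, rng: Optional[np.random.Generator] = None,
           maxiter: int = 2000) -> IMFitResult:
    """Per-cell maximum-likelihood fits (Nelder-Mead) plus aggregate totals.

    Cells are (level, cue-dimension) combinations; each contributes 6
    (full) or 5 (partial) free parameters to the aggregate count — 36 vs 30
    for a three-level, two-condition experiment.
    """
    if variant not in _N_FREE:
        raise ValueError("variant must be 'full' or 'partial'")
    if rng is None:
        rng = np.random.default_rng(0)
    groups: dict = {}
    for r_ in records:
        groups.setdefault((r_.trial.level, r_.trial.cue_dim), []).append(r_)

    cells = {}
    for key, recs in sorted(groups.items()):
        def objective(theta):
            try:
                return -im_loglik(recs, _unpack_im(theta, variant), variant)
            except (ValueError, FloatingPointError):
                return 1e12
        init = IMParams(kappa=8.0, kappa_f=12.0, A_a=0.05, A_b=0.1,
                        s=0.5, r=0.5)
        x0 = _pack_im(init, variant)
        best, converged = None, False
        for i in range(n_restarts):
            start = x0 if i == 0 else x0 + rng.normal(0, 1.0, x0.size)
            res = optimize.minimize(objective, start, method="Nelder-Mead",
                                    options={"maxiter": maxiter,
                                             "xatol": 1e-5, "fatol": 1e-6,
                                             "adaptive": True})
            converged = converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        cells[key] = {
            "params": _unpack_im(best.x, variant),
            "loglik": float(-best.fun),
            "n_params": _N_FREE[variant],
            "n_obs": len(recs),
            "converged": converged,
        }
    return IMFitResult(variant=variant, cells=cells)


# ---------------------------------------------------------------------------
# Generative sampling (used by taskgen.simulate_responses)


def simulate_responses(trials: Sequence[TrialArray], params: IMParams,
                       rng: np.random.Generator,
                       variant: str = "full") -> list[ResponseRecord]:
    """Structural sampling from the model (focus state, route, item, noise)."""
    params = _apply_variant(params, variant)
    out = []
    for t in trials:
        n = t.set_size
        p_focus = (params.p_focus_target if params.p_focus_target is not None
                   else 1.0 / n)
        focused = rng.random() < p_focus
        item_w, unif_w = _state_weights(t, params, focused)
        probs = np.concatenate([item_w, [unif_w]])
        pick = rng.choice(n + 1, p=probs)
        if pick == n:
            resp = rng.uniform(-np.pi, np.pi)
            src = -1
        else:
            kappa = (params.kappa_f if focused and pick == t.target
                     else params.kappa)
            resp = t.rep_feats[pick] + rng.vonmises(0.0, kappa)
            src = int(pick)
        out.append(ResponseRecord(trial=t, response=float(wrap(resp)),
                                  ground_truth_selected=src))
    return out
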