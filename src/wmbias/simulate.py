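"""Synthetic cohorts for retro-cue orientation continuous-report experiments.

One simulated trial shows four orientations in sequence; a retro-cue then
selects one of them (the target) for reproduction.  The generated response
error is a three-part mixture:

* with probability ``p_guess`` a lapse: error uniform on (−90, 90];
* with probability ``p_swap`` a swap: the observer reports a uniformly
  chosen distractor instead of the target (error = distractor delta plus
  the usual report noise);
* otherwise a genuine report: Von Mises noise around the target, plus an
  additive DoG-shaped attraction toward each of the three distractors.

Report noise is parameterised on the doubled circle (orientations are
180°-periodic): a draw from VM(0, κ) in doubled-angle space is halved back
to the orientation scale, and quoted κ values refer to that doubled space.
Recall precision depends on the target's serial position (recency) via
``kappa_by_position``.

The experiment templates mirror four study designs: ``plain`` (no item
attributes), ``noise2level`` (high/low stimulus noise per item, plus a
confidence rating), ``colour_precue`` (two item colours, target colour
pre-cued → colour is task-relevant) and ``colour_nocue`` (two colours,
no cue → colour is task-irrelevant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circular import DoGParams, dog_value, orientation_diff, wrap_orientation
from .schema import CANONICAL_COLUMNS

__all__ = [
    "SimConfig",
    "SwapCell",
    "SwapStudyResult",
    "sample_response_error",
    "simulate_trials",
    "swap_confound_study",
]

TEMPLATES = ("plain", "noise2level", "colour_precue", "colour_nocue")

#: |error| cut-offs (degrees) mapping to confidence ratings 3 / 2 / 1.
CONFIDENCE_CUTOFFS = (10.0, 25.0)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic cohort.

    ``bias_params`` maps condition keys to DoG parameters: ``"default"``
    always applies; templates may override with ``"high"``/``"low"``
    (distractor noise level) or ``"same"``/``"different"`` (distractor vs
    target colour).  ``distance_weights`` scale the amplitude by temporal
    distance 1–3.  κ values are concentrations on the doubled circle.
    """

    n_observers: int = 40
    trials_per_observer: int = 100
    kappa_by_position: tuple[float, float, float, float] = (2.5, 3.0, 3.5, 5.0)
    bias_params: Mapping[str, DoGParams] = field(
        default_factory=lambda: {"default": DoGParams(a=2.0, w=0.03)}
    )
    p_guess: float = 0.1
    p_swap: float = 0.0
    conditions: str = "plain"
    seed: int = 0
    distance_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    direction_weights: tuple[float, float] = (1.0, 1.0)  # (forward, backward)
    target_noise_kappa_scale: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.7, "low": 1.4}
    )
    prev_response_bias: DoGParams | None = None
    keep_latent: bool = False

    def __post_init__(self):
        if self.conditions not in TEMPLATES:
            raise ValueError(f"unknown template {self.conditions!r}")
        if not (0.0 <= self.p_guess <= 1.0 and 0.0 <= self.p_swap <= 1.0):
            raise ValueError("p_guess and p_swap must lie in [0, 1]")
        if self.p_guess + self.p_swap > 1.0:
            raise ValueError("p_guess + p_swap must not exceed 1")
        if len(self.kappa_by_position) != 4 or any(
            k <= 0 for k in self.kappa_by_position
        ):
            raise ValueError("kappa_by_position needs 4 positive concentrations")
        if "default" not in self.bias_params:
            raise ValueError('bias_params must contain a "default" entry')

    def bias_for(self, key: str) -> DoGParams:
        """DoG parameters for a condition key, falling back to "default"."""
        return self.bias_params.get(key, self.bias_params["default"])


def _wrap_error(e):
    """Wrap signed errors onto (−90, 90]."""
    e = np.mod(np.asarray(e, dtype=float), 180.0)
    return np.where(e > 90.0, e - 180.0, e)


def _vm_noise_deg(rng: np.random.Generator, kappa, size=None):
    """Von Mises report noise: drawn on the doubled circle, halved back."""
    return np.rad2deg(rng.vonmises(0.0, kappa, size=size)) / 2.0


def sample_response_error(
    delta_list: Sequence[float],
    cfg: SimConfig,
    position: int,
    rng: np.random.Generator,
    *,
    param_keys: Sequence[str] = ("default", "default", "default"),
    distances: Sequence[int] = (1, 1, 1),
) -> float:
    """Draw one response error (degrees, in (−90, 90]) for a single trial.

    ``delta_list`` holds the three distractor deltas (distractor − target),
    ``position`` the target's serial position 1–4.  ``param_keys`` select
    the per-distractor bias condition and ``distances`` the temporal
    distances used for amplitude weighting.
    """
    if not 1 <= position <= 4:
        raise ValueError("position must be in 1..4")
    u = rng.random()
    if u < cfg.p_guess:
        return float(rng.uniform(-90.0, 90.0))
    kappa = cfg.kappa_by_position[position - 1]
    noise = float(_vm_noise_deg(rng, kappa))
    if u < cfg.p_guess + cfg.p_swap:
        j = rng.integers(0, len(delta_list))
        return float(_wrap_error(delta_list[j] + noise))
    bias = 0.0
    for d, key, dist in zip(delta_list, param_keys, distances):
        p = cfg.bias_for(key)
        eff = DoGParams(a=p.a * cfg.distance_weights[dist - 1], w=p.w)
        bias += dog_value(d, eff)
    return float(_wrap_error(bias + noise))


def _draw_attributes(rng, n, template):
    """Per-item noise levels, colours and the pre-cue for one cohort."""
    noise = np.full((n, 4), "none", dtype=object)
    colour = np.full((n, 4), "none", dtype=object)
    precue = np.full(n, "none", dtype=object)
    if template == "noise2level":
        noise = rng.choice(["high", "low"], size=(n, 4))
    elif template in ("colour_precue", "colour_nocue"):
        colour = rng.choice(["cyan", "yellow"], size=(n, 4))
    return noise, colour, precue


def simulate_trials(cfg: SimConfig) -> pd.DataFrame:
    """Generate a cohort of trials as a canonical-schema DataFrame.

    Reproducible: the same config (incl. seed) yields an identical table.
    Orientations are i.i.d. uniform on [0, 180); the target position is
    uniform on {1..4}; responses follow :func:`sample_response_error`
    (vectorised); a confidence rating (from |error| via the two cut-offs in
    :data:`CONFIDENCE_CUTOFFS`) is produced for the ``noise2level``
    template only, matching the study design that collected one.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_observers * cfg.trials_per_observer
    template = cfg.conditions

    ori = rng.uniform(0.0, 180.0, size=(n, 4))
    target_pos = rng.integers(1, 5, size=n)
    noise, colour, precue = _draw_attributes(rng, n, template)
    if template == "colour_precue":
        precue = colour[np.arange(n), target_pos - 1].copy()

    rows = np.arange(n)
    target_ori = ori[rows, target_pos - 1]
    # distractor slot -> stimulus position, ordered by serial position
    d_pos = np.stack(
        [np.sort(np.setdiff1d(np.arange(1, 5), [tp])) for tp in range(1, 5)]
    )[target_pos - 1]  # (n, 3)
    d_ori = ori[rows[:, None], d_pos - 1]
    delta = orientation_diff(d_ori, target_ori[:, None])
    distance = np.abs(d_pos - target_pos[:, None])

    # per-distractor bias parameters from condition keys
    a_eff = np.empty((n, 3))
    w_eff = np.empty((n, 3))
    for j in range(3):
        if template == "noise2level":
            keys = noise[rows, d_pos[:, j] - 1]
        elif template in ("colour_precue", "colour_nocue"):
            same = colour[rows, d_pos[:, j] - 1] == colour[rows, target_pos - 1]
            keys = np.where(same, "same", "different")
        else:
            keys = np.full(n, "default", dtype=object)
        for key in np.unique(keys):
            p = cfg.bias_for(str(key))
            m = keys == key
            a_eff[m, j] = p.a
            w_eff[m, j] = p.w
    a_eff *= np.asarray(cfg.distance_weights)[distance - 1]
    # forward = distractor shown before the target in the sequence
    a_eff *= np.where(
        d_pos < target_pos[:, None], cfg.direction_weights[0], cfg.direction_weights[1]
    )

    kappa = np.asarray(cfg.kappa_by_position)[target_pos - 1].astype(float)
    if template == "noise2level":
        t_noise = noise[rows, target_pos - 1]
        for lvl, s in cfg.target_noise_kappa_scale.items():
            kappa[t_noise == lvl] *= s

    from .circular import DOG_C  # local alias for the vectorised DoG sum

    bias = np.sum(delta * a_eff * w_eff * DOG_C * np.exp(-((w_eff * delta) ** 2)), axis=1)
    vm = _vm_noise_deg(rng, kappa)
    u = rng.random(n)
    is_guess = u < cfg.p_guess
    is_swap = (~is_guess) & (u < cfg.p_guess + cfg.p_swap)
    swap_pick = rng.integers(0, 3, size=n)

    error = _wrap_error(bias + vm)
    error[is_swap] = _wrap_error(delta[is_swap, swap_pick[is_swap]] + vm[is_swap])
    error[is_guess] = rng.uniform(-90.0, 90.0, size=int(is_guess.sum()))

    if cfg.prev_response_bias is not None:
        # sequential pass: attraction toward the previous trial's response
        pb = cfg.prev_response_bias
        core = ~(is_guess | is_swap)
        for o in range(cfg.n_observers):
            lo = o * cfg.trials_per_observer
            prev_resp = np.nan
            for i in range(lo, lo + cfg.trials_per_observer):
                if np.isfinite(prev_resp) and core[i]:
                    d_prev = orientation_diff(prev_resp, target_ori[i])
                    error[i] = _wrap_error(error[i] + dog_value(d_prev, pb))
                prev_resp = target_ori[i] + error[i]

    response = wrap_orientation(target_ori + error)

    if template == "noise2level":
        abs_err = np.abs(error)
        confidence = np.where(
            abs_err < CONFIDENCE_CUTOFFS[0], 3, np.where(abs_err < CONFIDENCE_CUTOFFS[1], 2, 1)
        )
        confidence = pd.array(confidence, dtype="Int64")
    else:
        confidence = pd.array([pd.NA] * n, dtype="Int64")

    obs_ids = np.repeat(
        [f"obs{k + 1:03d}" for k in range(cfg.n_observers)], cfg.trials_per_observer
    )
    df = pd.DataFrame(
        {
            "observer_id": obs_ids,
            "experiment_id": f"sim-{template}",
            "trial_index": np.tile(np.arange(cfg.trials_per_observer), cfg.n_observers),
            **{f"ori_{k+1}": ori[:, k] for k in range(4)},
            **{f"noise_{k+1}": noise[:, k] for k in range(4)},
            **{f"colour_{k+1}": colour[:, k] for k in range(4)},
            "precue_colour": precue,
            "target_position": target_pos,
            "response": response,
            "confidence": confidence,
            "attention_pass": True,
        }
    )
    df = df[list(CANONICAL_COLUMNS)]
    if cfg.keep_latent:
        df["gen_component"] = np.where(
            is_guess, "guess", np.where(is_swap, "swap", "core")
        )
    df.attrs["sim_metadata"] = {
        "seed": cfg.seed,
        "template": template,
        "kappa_convention": "doubled-circle",
        "kappa_by_position": list(cfg.kappa_by_position),
        "p_guess": cfg.p_guess,
        "p_swap": cfg.p_swap,
    }
    return df


@dataclass
class SwapCell:
    """Per-cell record of the swap-error confound study."""

    name: str
    true_params: DoGParams
    p_swap: float
    p_guess: float
    seed: int
    n_points: int
    fit_raw: "DoGFit"  # noqa: F821 - forward ref to wmbias.inference
    fit_removed: "DoGFit"  # noqa: F821


@dataclass
class SwapStudyResult:
    """Fitted amplitudes with/without large-error removal, per simulated cell.

    ``contrasts`` holds (name_a, name_b, true difference, estimated
    difference on raw data, estimated difference after removal).
    """

    cells: dict[str, SwapCell]
    contrasts: list[dict]
    removal_threshold: float


def swap_confound_study(
    configs: Mapping[str, SimConfig],
    removal_threshold: float = 45.0,
    contrast_pairs: Sequence[tuple[str, str]] = (),
) -> SwapStudyResult:
    """Quantify how swap errors inflate fitted bias amplitudes.

    For each named config the cohort is simulated, expanded to
    (target, distractor) data points and the DoG is fitted twice: on all
    points, and after dropping whole trials with |error| above
    ``removal_threshold``.  Swap trials track the distractor delta, so with
    no true bias they still produce a positive fitted amplitude; removal
    shrinks (but cannot fully undo) that inflation.  Condition *contrasts*
    (amplitude differences between cells with equal swap rates) are
    expected to stay honest or be slightly shrunk.  A fit that fails to
    converge is recorded in the cell (``converged`` flag), never raised.
    """
    from .inference import fit_dog
    from .preprocess import expand_to_datapoints, remove_large_errors

    cells: dict[str, SwapCell] = {}
    for name, cfg in configs.items():
        trials = simulate_trials(cfg)
        pts_raw = expand_to_datapoints(trials)
        pts_rem = expand_to_datapoints(remove_large_errors(trials, removal_threshold))
        cells[name] = SwapCell(
            name=name,
            true_params=cfg.bias_for("default"),
            p_swap=cfg.p_swap,
            p_guess=cfg.p_guess,
            seed=cfg.seed,
            n_points=len(pts_raw),
            fit_raw=fit_dog(pts_raw),
            fit_removed=fit_dog(pts_rem),
        )

    contrasts = []
    for a, b in contrast_pairs:
        ca, cb = cells[a], cells[b]
        contrasts.append(
            {
                "cell_a": a,
                "cell_b": b,
                "true_diff": ca.true_params.a - cb.true_params.a,
                "raw_diff": ca.fit_raw.params.a - cb.fit_raw.params.a,
                "removed_diff": ca.fit_removed.params.a - cb.fit_removed.params.a,
            }
        )
    return SwapStudyResult(
        cells=cells, contrasts=contrasts, removal_threshold=removal_threshold
    )


def replicate(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy a config with a new seed (convenience for replicate sweeps)."""
    return replace(cfg, seed=seed)
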