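"""Trial-table IO, observer exclusion and expansion into bias data points.

A *bias data point* pairs one target with one reference orientation: the
signed orientation difference delta = reference − target (in (−90, 90])
and the signed response error = response − target.  A standard trial
yields three such points (one per distractor); variants use the circular
mean of the distractors, or the previous trial's response/target, as the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .circular import (
    axial_circular_sd,
    axial_resultant_length,
    orientation_diff,
)
from .schema import (
    CANONICAL_COLUMNS,
    COLOURS,
    NOISE_LEVELS,
    ORIENTATION_COLUMNS,
    SCHEMA_VERSION,
)

__all__ = [
    "ValidationReport",
    "ExclusionReport",
    "read_trials",
    "write_trials",
    "trial_errors",
    "target_orientations",
    "exclude_flat_observers",
    "flag_first_last_similarity",
    "remove_large_errors",
    "expand_to_datapoints",
    "datapoints_circular_mean",
    "between_trial_datapoints",
]


@dataclass
class ValidationReport:
    """Outcome of validating a trial table: bad rows are kept, not hidden."""

    n_rows: int
    n_valid: int
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _row_errors(df: pd.DataFrame) -> list[tuple[int, str]]:
    errors: list[tuple[int, str]] = []
    ori = df[list(ORIENTATION_COLUMNS)].to_numpy(dtype=float)
    bad_ori = ~((ori >= 0.0) & (ori < 180.0)).all(axis=1) | ~np.isfinite(ori).all(axis=1)
    resp = pd.to_numeric(df["response"], errors="coerce").to_numpy(dtype=float)
    bad_resp = ~((resp >= 0.0) & (resp < 180.0)) | ~np.isfinite(resp)
    tp = pd.to_numeric(df["target_position"], errors="coerce").to_numpy()
    bad_tp = ~np.isin(tp, [1, 2, 3, 4])
    bad_noise = np.zeros(len(df), dtype=bool)
    for c in ("noise_1", "noise_2", "noise_3", "noise_4"):
        bad_noise |= ~df[c].astype(str).isin(NOISE_LEVELS).to_numpy()
    bad_colour = np.zeros(len(df), dtype=bool)
    for c in ("colour_1", "colour_2", "colour_3", "colour_4"):
        bad_colour |= ~df[c].astype(str).isin(COLOURS).to_numpy()
    # pre-cue consistency: the cued colour must match the target's colour
    colours = df[["colour_1", "colour_2", "colour_3", "colour_4"]].to_numpy(dtype=object)
    precue = df["precue_colour"].astype(str).to_numpy()
    has_cue = (precue != "none") & ~bad_tp
    rows = np.arange(len(df))
    bad_cue = np.zeros(len(df), dtype=bool)
    idx = np.where(has_cue)[0]
    if idx.size:
        bad_cue[idx] = colours[idx, tp[idx].astype(int) - 1] != precue[idx]
    for i in rows:
        reasons = []
        if bad_ori[i]:
            reasons.append("orientation outside [0, 180)")
        if bad_resp[i]:
            reasons.append("response outside [0, 180)")
        if bad_tp[i]:
            reasons.append("target_position not in 1..4")
        if bad_noise[i]:
            reasons.append("invalid noise level")
        if bad_colour[i]:
            reasons.append("invalid colour")
        if bad_cue[i]:
            reasons.append("precue_colour does not match target colour")
        if reasons:
            errors.append((int(i), "; ".join(reasons)))
    return errors


def read_trials(path, schema_version: str = SCHEMA_VERSION):
    """Read a canonical trial CSV.

    Returns ``(trials, report)``: validated rows as a DataFrame and a
    :class:`ValidationReport` listing rejected rows with reasons.  A
    missing required column raises ``ValueError`` (schema error).
    """
    if schema_version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {schema_version!r}")
    df = pd.read_csv(path, dtype={"observer_id": str, "experiment_id": str})
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = df[list(CANONICAL_COLUMNS)]
    errors = _row_errors(df)
    bad = {i for i, _ in errors}
    keep = df.index[~df.index.isin(bad)]
    out = df.loc[keep].reset_index(drop=True)
    out["confidence"] = pd.array(
        pd.to_numeric(out["confidence"], errors="coerce"), dtype="Int64"
    )
    out["attention_pass"] = out["attention_pass"].astype(bool)
    out["target_position"] = out["target_position"].astype(int)
    out["trial_index"] = out["trial_index"].astype(int)
    return out, ValidationReport(n_rows=len(df), n_valid=len(out), errors=errors)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table in canonical column order (UTF-8 CSV)."""
    trials[list(CANONICAL_COLUMNS)].to_csv(path, index=False)


def target_orientations(trials: pd.DataFrame) -> np.ndarray:
    """Presented orientation of the cued item, per trial."""
    ori = trials[list(ORIENTATION_COLUMNS)].to_numpy(dtype=float)
    tp = trials["target_position"].to_numpy(dtype=int)
    return ori[np.arange(len(trials)), tp - 1]


def trial_errors(trials: pd.DataFrame) -> np.ndarray:
    """Signed response error (response − target) per trial, in (−90, 90]."""
    return np.asarray(
        orientation_diff(trials["response"].to_numpy(dtype=float), target_orientations(trials))
    )


@dataclass
class ExclusionReport:
    """Per-observer exclusion decision with the statistics behind it.

    Statuses partition the observers: ``retained``, ``excluded_flat``
    (error distribution indistinguishable from uniform guessing),
    ``flagged_similarity`` (retained but suspicious: first- and last-target
    precision nearly identical) or ``insufficient`` (< ``min_trials``
    trials; retained, untestable).
    """

    table: pd.DataFrame  # index observer_id
    alpha: float
    n_bins: int
    min_trials: int = 20
    similarity_tolerance: float | None = None

    @property
    def retained_ids(self) -> list[str]:
        keep = self.table["status"] != "excluded_flat"
        return list(self.table.index[keep])

    def retained(self, trials: pd.DataFrame) -> pd.DataFrame:
        return trials[trials["observer_id"].isin(self.retained_ids)].reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_bins": self.n_bins,
            "min_trials": self.min_trials,
            "similarity_tolerance": self.similarity_tolerance,
            "observers": self.table.reset_index().to_dict(orient="records"),
        }


def exclude_flat_observers(
    trials: pd.DataFrame, alpha: float = 0.05, n_bins: int = 12, min_trials: int = 20
) -> ExclusionReport:
    """Exclude observers whose response errors look like random guessing.

    An observer is excluded when BOTH (a) a chi-square goodness-of-fit of
    their binned errors against the uniform distribution fails to reject
    at ``alpha`` and (b) the resultant length of the doubled errors is
    below 0.2.  Observers with fewer than ``min_trials`` trials are marked
    ``insufficient`` and retained.  All sub-statistics are reported.
    """
    records = []
    if len(trials):
        err_all = trial_errors(trials)
        for obs, idx in trials.groupby("observer_id", sort=True).indices.items():
            err = err_all[idx]
            n = len(err)
            if n < min_trials:
                records.append(
                    dict(observer_id=obs, n_trials=n, chi2_stat=np.nan, chi2_p=np.nan,
                         resultant_length=np.nan, status="insufficient")
                )
                continue
            counts, _ = np.histogram(err, bins=n_bins, range=(-90.0, 90.0))
            chi2, p = stats.chisquare(counts)
            r = axial_resultant_length(err)
            flat = (p > alpha) and (r < 0.2)
            records.append(
                dict(observer_id=obs, n_trials=n, chi2_stat=float(chi2), chi2_p=float(p),
                     resultant_length=float(r),
                     status="excluded_flat" if flat else "retained")
            )
    table = pd.DataFrame.from_records(
        records,
        columns=["observer_id", "n_trials", "chi2_stat", "chi2_p", "resultant_length", "status"],
    ).set_index("observer_id")
    return ExclusionReport(table=table, alpha=alpha, n_bins=n_bins, min_trials=min_trials)


def flag_first_last_similarity(
    trials: pd.DataFrame, tolerance: float, report: ExclusionReport | None = None
) -> pd.DataFrame:
    """Flag observers equally precise on the hardest and easiest target.

    Compares the circular SD of response errors for position-1 targets
    (encoded first, normally worst recalled) against position-4 targets
    (most recent, best recalled).  An absolute difference ≤ ``tolerance``
    degrees is suspicious — memory decay should show — so the observer is
    flagged, never auto-excluded.  If ``report`` is given, flagged retained
    observers get status ``flagged_similarity`` there.
    """
    err = trial_errors(trials) if len(trials) else np.array([])
    tp = trials["target_position"].to_numpy(dtype=int) if len(trials) else np.array([], int)
    records = []
    for obs, idx in trials.groupby("observer_id", sort=True).indices.items():
        e1 = err[idx][tp[idx] == 1]
        e4 = err[idx][tp[idx] == 4]
        if len(e1) == 0 or len(e4) == 0:
            records.append(dict(observer_id=obs, sd_first=np.nan, sd_last=np.nan,
                                abs_diff=np.nan, flagged=False))
            continue
        sd1 = axial_circular_sd(e1)
        sd4 = axial_circular_sd(e4)
        diff = abs(sd1 - sd4)
        records.append(dict(observer_id=obs, sd_first=sd1, sd_last=sd4,
                            abs_diff=diff, flagged=bool(diff <= tolerance)))
    flags = pd.DataFrame.from_records(
        records, columns=["observer_id", "sd_first", "sd_last", "abs_diff", "flagged"]
    )
    if report is not None:
        report.similarity_tolerance = tolerance
        for obs in flags.loc[flags["flagged"], "observer_id"]:
            if obs in report.table.index and report.table.loc[obs, "status"] == "retained":
                report.table.loc[obs, "status"] = "flagged_similarity"
    return flags


def remove_large_errors(trials: pd.DataFrame, threshold: float = 45.0) -> pd.DataFrame:
    """Drop whole trials with |response error| above ``threshold`` degrees.

    The standard swap-error mitigation: a swap (reporting a distractor)
    usually produces a large error, so trimming at 45° removes most swaps
    at large deltas.  Threshold 90 removes nothing.
    """
    if not (0.0 < threshold <= 90.0):
        raise ValueError("threshold must lie in (0, 90]")
    if not len(trials):
        return trials.copy()
    keep = np.abs(trial_errors(trials)) <= threshold
    return trials[keep].reset_index(drop=True)


_POINT_COLUMNS = [
    "observer_id", "experiment_id", "trial_index", "target_position",
    "distractor_position", "temporal_distance", "direction", "delta", "error",
    "distractor_noise", "target_noise", "colour_match", "confidence",
]


def expand_to_datapoints(trials: pd.DataFrame) -> pd.DataFrame:
    """Expand trials into (target, distractor) bias data points, 3 per trial.

    delta = distractor − target orientation (signed, axial); error =
    response − target.  ``direction`` is ``forward`` when the distractor
    was shown before the target, ``backward`` after; ``temporal_distance``
    is the absolute serial-position gap (1–3).
    """
    n = len(trials)
    if n == 0:
        return pd.DataFrame(columns=_POINT_COLUMNS)
    ori = trials[list(ORIENTATION_COLUMNS)].to_numpy(dtype=float)
    tp = trials["target_position"].to_numpy(dtype=int)
    rows = np.arange(n)
    t_ori = ori[rows, tp - 1]
    err = trial_errors(trials)
    noise = trials[["noise_1", "noise_2", "noise_3", "noise_4"]].to_numpy(dtype=object)
    colour = trials[["colour_1", "colour_2", "colour_3", "colour_4"]].to_numpy(dtype=object)
    t_noise = noise[rows, tp - 1]
    t_colour = colour[rows, tp - 1]

    d_pos = np.stack(
        [np.sort(np.setdiff1d(np.arange(1, 5), [p])) for p in range(1, 5)]
    )[tp - 1]  # (n, 3)
    frames = []
    for j in range(3):
        dp = d_pos[:, j]
        d_ori = ori[rows, dp - 1]
        d_noise = noise[rows, dp - 1]
        d_colour = colour[rows, dp - 1]
        has_colour = (d_colour != "none") & (t_colour != "none")
        colour_match = np.where(
            has_colour, np.where(d_colour == t_colour, "same", "different"), "none"
        )
        frames.append(
            pd.DataFrame(
                {
                    "observer_id": trials["observer_id"].to_numpy(),
                    "experiment_id": trials["experiment_id"].to_numpy(),
                    "trial_index": trials["trial_index"].to_numpy(),
                    "target_position": tp,
                    "distractor_position": dp,
                    "temporal_distance": np.abs(dp - tp),
                    "direction": np.where(dp < tp, "forward", "backward"),
                    "delta": orientation_diff(d_ori, t_ori),
                    "error": err,
                    "distractor_noise": d_noise,
                    "target_noise": t_noise,
                    "colour_match": colour_match,
                    "confidence": trials["confidence"].to_numpy(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["confidence"] = pd.array(out["confidence"], dtype="Int64")
    return out[_POINT_COLUMNS]


def datapoints_circular_mean(trials: pd.DataFrame) -> pd.DataFrame:
    """One data point per trial against the circular mean of its distractors.

    Trials with a degenerate axial mean (balanced distractors) are skipped;
    the count is recorded in ``result.attrs["n_degenerate_skipped"]``.
    """
    n = len(trials)
    cols = ["observer_id", "experiment_id", "trial_index", "target_position",
            "delta", "error", "confidence"]
    if n == 0:
        out = pd.DataFrame(columns=cols)
        out.attrs["n_degenerate_skipped"] = 0
        return out
    ori = trials[list(ORIENTATION_COLUMNS)].to_numpy(dtype=float)
    tp = trials["target_position"].to_numpy(dtype=int)
    rows = np.arange(n)
    t_ori = ori[rows, tp - 1]
    d_pos = np.stack(
        [np.sort(np.setdiff1d(np.arange(1, 5), [p])) for p in range(1, 5)]
    )[tp - 1]
    d_ori = ori[rows[:, None], d_pos - 1]
    z = np.exp(2j * np.deg2rad(d_ori)).mean(axis=1)
    ok = np.abs(z) >= 1e-9
    mean_ori = np.mod(np.rad2deg(np.angle(z)) / 2.0, 180.0)
    out = pd.DataFrame(
        {
            "observer_id": trials["observer_id"].to_numpy()[ok],
            "experiment_id": trials["experiment_id"].to_numpy()[ok],
            "trial_index": trials["trial_index"].to_numpy()[ok],
            "target_position": tp[ok],
            "delta": orientation_diff(mean_ori[ok], t_ori[ok]),
            "error": trial_errors(trials)[ok],
            "confidence": pd.array(trials["confidence"].to_numpy()[ok], dtype="Int64"),
        }
    )
    out.attrs["n_degenerate_skipped"] = int((~ok).sum())
    return out


def between_trial_datapoints(trials: pd.DataFrame):
    """Serial-dependence data points across consecutive trials.

    Returns ``(prev_response_points, prev_target_points)``: delta is the
    previous trial's response (resp. displayed target orientation) minus
    the current target; error is the current response error.  The first
    trial of each observer contributes nothing and observer boundaries are
    never crossed.  Trials are ordered by (observer_id, trial_index).
    """
    cols = ["observer_id", "experiment_id", "trial_index", "target_position",
            "delta", "error", "confidence"]
    if len(trials) == 0:
        empty = pd.DataFrame(columns=cols)
        return empty, empty.copy()
    t = trials.sort_values(["observer_id", "trial_index"], kind="stable").reset_index(drop=True)
    t_ori = target_orientations(t)
    err = trial_errors(t)
    resp = t["response"].to_numpy(dtype=float)
    same_obs = t["observer_id"].to_numpy()[1:] == t["observer_id"].to_numpy()[:-1]
    cur = np.where(same_obs)[0] + 1

    def build(prev_ref):
        return pd.DataFrame(
            {
                "observer_id": t["observer_id"].to_numpy()[cur],
                "experiment_id": t["experiment_id"].to_numpy()[cur],
                "trial_index": t["trial_index"].to_numpy()[cur],
                "target_position": t["target_position"].to_numpy()[cur],
                "delta": orientation_diff(prev_ref[cur - 1], t_ori[cur]),
                "error": err[cur],
                "confidence": pd.array(t["confidence"].to_numpy()[cur], dtype="Int64"),
            }
        )

    return build(resp), build(t_ori)
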