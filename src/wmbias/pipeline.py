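"""End-to-end analysis suites: confirmatory hypotheses, exploratory
analyses, the error-removal-threshold robustness sweep and report output.

Seeding: one master seed lives in the config; each permutation test gets a
seed derived deterministically from the master seed and the test's name,
so adding or reordering tests never perturbs another test's null
distribution.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (
    fit_dog,
    model_free_bias,
    permutation_test_amplitude,
    permutation_test_contrast,
)
from .preprocess import (
    between_trial_datapoints,
    datapoints_circular_mean,
    expand_to_datapoints,
    remove_large_errors,
)

__all__ = [
    "AnalysisConfig",
    "SuiteReport",
    "derive_seed",
    "run_confirmatory_suite",
    "run_exploratory_suite",
    "threshold_sweep",
    "write_report",
]


def derive_seed(master_seed: int, name: str) -> int:
    """Deterministic per-test seed below 2^31, stable across sessions."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis parameters with the study's defaults."""

    error_removal_threshold: float = 45.0
    n_perm: int = 10_000
    alpha: float = 0.05
    moving_average_fraction: float = 0.04
    seed: int = 0
    amplitude_sidedness: str = "two_sided"

    def __post_init__(self):
        if not (0.0 < self.error_removal_threshold <= 90.0):
            raise ValueError("error_removal_threshold must lie in (0, 90]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SuiteReport:
    """Structured results of one analysis suite with full provenance."""

    name: str
    config: dict
    entries: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "config": self.config,
            "entries": self.entries,
            "skipped": self.skipped,
            "provenance": self.provenance,
        }


def _amplitude_entry(points, cfg: AnalysisConfig, name: str) -> dict:
    """Fit + amplitude permutation test for one condition's points."""
    fit = fit_dog(points)
    perm = permutation_test_amplitude(
        points,
        n_perm=cfg.n_perm,
        seed=derive_seed(cfg.seed, name),
        sidedness=cfg.amplitude_sidedness,
    )
    return {"kind": "amplitude", "n_points": len(points), "fit": fit.to_dict(),
            "perm": perm.to_dict()}


def _contrast_entry(points, label_col, label_a, label_b, cfg, name, statistic="dog_amplitude"):
    contrast = permutation_test_contrast(
        points, label_col, label_a, label_b,
        n_perm=cfg.n_perm, seed=derive_seed(cfg.seed, name), statistic=statistic,
    )
    return {"kind": "contrast", "statistic": statistic, **contrast.to_dict()}


def _provenance(cfg: AnalysisConfig, trials: pd.DataFrame) -> dict:
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    return {
        "software_version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "master_seed": cfg.seed,
        "n_trials_in": int(len(trials)),
        "n_observers": int(trials["observer_id"].nunique()) if len(trials) else 0,
    }


def run_confirmatory_suite(trials: pd.DataFrame, cfg: AnalysisConfig) -> SuiteReport:
    """The four pre-registered hypothesis tests.

    After the configured large-error removal: H1 — forward and backward
    bias amplitudes (distractors shown before vs. after the target), each
    tested against a shuffled-delta null, plus their contrast; H2 —
    amplitude at temporal distance 1 and pooled distances 2–3; H3 —
    contrast of distance-1 vs. distance-2/3 bias; H4A — contrast of high-
    vs. low-noise *distractors*; H4B — contrast of high- vs. low-noise
    *targets*.  H4 sub-tests are skipped with a reason when the cohort has
    no noise attributes.  All serial positions enter every comparison.
    """
    report = SuiteReport(name="confirmatory", config=cfg.to_dict())
    report.provenance = _provenance(cfg, trials)
    kept = remove_large_errors(trials, cfg.error_removal_threshold)
    points = expand_to_datapoints(kept)
    report.provenance["n_trials_after_removal"] = int(len(kept))
    report.provenance["n_datapoints"] = int(len(points))

    for direction in ("forward", "backward"):
        sub = points[points["direction"] == direction]
        report.entries[f"H1_{direction}"] = _amplitude_entry(sub, cfg, f"H1_{direction}")
    report.entries["H1_contrast_forward_vs_backward"] = _contrast_entry(
        points, "direction", "forward", "backward", cfg, "H1_contrast"
    )

    points = points.assign(
        proximity=np.where(points["temporal_distance"] == 1, "near", "far")
    )
    report.entries["H2_distance_1"] = _amplitude_entry(
        points[points["proximity"] == "near"], cfg, "H2_distance_1"
    )
    report.entries["H2_distance_2_3"] = _amplitude_entry(
        points[points["proximity"] == "far"], cfg, "H2_distance_2_3"
    )
    report.entries["H3_contrast_near_vs_far"] = _contrast_entry(
        points, "proximity", "near", "far", cfg, "H3_contrast"
    )

    if set(points["distractor_noise"].unique()) >= {"high", "low"}:
        report.entries["H4A_contrast_distractor_noise"] = _contrast_entry(
            points, "distractor_noise", "high", "low", cfg, "H4A_contrast"
        )
        report.entries["H4B_contrast_target_noise"] = _contrast_entry(
            points, "target_noise", "high", "low", cfg, "H4B_contrast"
        )
    else:
        reason = "cohort has no per-item noise levels"
        report.skipped["H4A_contrast_distractor_noise"] = reason
        report.skipped["H4B_contrast_target_noise"] = reason
    return report


def run_exploratory_suite(trials: pd.DataFrame, cfg: AnalysisConfig) -> SuiteReport:
    """Exploratory analyses mirroring the study's secondary questions.

    Per target × distractor position fits (12 combinations); same- vs.
    different-colour bias (DoG and model-free) with contrasts; confidence
    2 vs. 3 contrast (self-reported guesses excluded); target position 1
    vs. 4 contrast; previous-trial response and previous-trial target bias
    with their contrast; circular-mean-of-distractors vs. individual-
    distractor contrast.  Suites whose attributes are absent from the
    cohort are skipped with a reason.
    """
    report = SuiteReport(name="exploratory", config=cfg.to_dict())
    report.provenance = _provenance(cfg, trials)
    kept = remove_large_errors(trials, cfg.error_removal_threshold)
    points = expand_to_datapoints(kept)

    for tp in range(1, 5):
        for dp in range(1, 5):
            if dp == tp:
                continue
            sub = points[
                (points["target_position"] == tp) & (points["distractor_position"] == dp)
            ]
            name = f"combo_t{tp}_d{dp}"
            try:
                report.entries[name] = _amplitude_entry(sub, cfg, name)
            except ValueError as exc:
                report.skipped[name] = str(exc)

    if set(points["colour_match"].unique()) >= {"same", "different"}:
        for match in ("same", "different"):
            sub = points[points["colour_match"] == match]
            report.entries[f"colour_{match}"] = _amplitude_entry(sub, cfg, f"colour_{match}")
            report.entries[f"colour_{match}_model_free"] = {
                "kind": "model_free",
                "n_points": len(sub),
                "value": model_free_bias(sub),
            }
        report.entries["colour_contrast"] = _contrast_entry(
            points, "colour_match", "same", "different", cfg, "colour_contrast"
        )
        report.entries["colour_contrast_model_free"] = _contrast_entry(
            points, "colour_match", "same", "different", cfg,
            "colour_contrast_model_free", statistic="model_free",
        )
    else:
        report.skipped["colour_contrast"] = "cohort has no item colours"

    conf = points[points["confidence"].notna() & (points["confidence"] != 1)]
    if len(conf) and set(conf["confidence"].unique()) >= {2, 3}:
        conf = conf.assign(confidence_label=conf["confidence"].map({2: "low", 3: "high"}))
        try:
            report.entries["confidence_contrast_low_vs_high"] = _contrast_entry(
                conf, "confidence_label", "low", "high", cfg, "confidence_contrast"
            )
        except ValueError as exc:
            report.skipped["confidence_contrast_low_vs_high"] = str(exc)
    else:
        report.skipped["confidence_contrast_low_vs_high"] = "no confidence ratings"

    pos14 = points[points["target_position"].isin([1, 4])].assign(
        position_label=lambda d: d["target_position"].map({1: "first", 4: "last"})
    )
    try:
        report.entries["target_position_first_vs_last"] = _contrast_entry(
            pos14, "position_label", "first", "last", cfg, "target_position_contrast"
        )
    except ValueError as exc:
        report.skipped["target_position_first_vs_last"] = str(exc)

    prev_resp, prev_targ = between_trial_datapoints(kept)
    if len(prev_resp) >= 50:
        report.entries["previous_response"] = _amplitude_entry(
            prev_resp, cfg, "previous_response"
        )
        report.entries["previous_target"] = _amplitude_entry(prev_targ, cfg, "previous_target")
        pooled = pd.concat(
            [prev_resp.assign(reference="prev_response"),
             prev_targ.assign(reference="prev_target")],
            ignore_index=True,
        )
        report.entries["previous_response_vs_target"] = _contrast_entry(
            pooled, "reference", "prev_response", "prev_target", cfg, "previous_contrast"
        )
    else:
        report.skipped["previous_response"] = "too few consecutive-trial pairs"

    cm = datapoints_circular_mean(kept)
    if len(cm) >= 50:
        report.entries["circular_mean"] = _amplitude_entry(cm, cfg, "circular_mean")
        pooled = pd.concat(
            [cm.assign(reference="circ_mean"),
             points[["delta", "error"]].assign(reference="individual")],
            ignore_index=True,
        )
        report.entries["circular_mean_vs_individual"] = _contrast_entry(
            pooled, "reference", "circ_mean", "individual", cfg, "circular_mean_contrast"
        )
        report.entries["circular_mean"]["n_degenerate_skipped"] = cm.attrs.get(
            "n_degenerate_skipped", 0
        )
    else:
        report.skipped["circular_mean"] = "too few non-degenerate circular means"
    return report


def threshold_sweep(
    trials: pd.DataFrame, cfg: AnalysisConfig, thresholds=(30.0, 45.0, 60.0, 75.0, 90.0)
) -> pd.DataFrame:
    """Robustness of the confirmatory p-values to the error-removal cut-off.

    Reruns the confirmatory suite at each threshold with the same master
    seed (so permutation nulls are comparable across columns) and returns a
    table of p-values, one row per hypothesis entry, one column per
    threshold, plus a row of retained trial counts.
    """
    for t in thresholds:
        if not (0.0 < t <= 90.0):
            raise ValueError("thresholds must lie in (0, 90]")
    columns: dict[float, dict] = {}
    for t in thresholds:
        rep = run_confirmatory_suite(trials, replace(cfg, error_removal_threshold=float(t)))
        col = {}
        for name, entry in rep.entries.items():
            col[name] = entry["perm"]["p_value"]
        col["n_trials"] = rep.provenance["n_trials_after_removal"]
        columns[float(t)] = col
    return pd.DataFrame(columns).rename_axis(index="entry", columns="threshold")


def write_report(report: SuiteReport, path) -> dict[str, Path]:
    """Write a suite report as machine-readable JSON plus a text summary.

    Returns the paths written.  Outputs are deterministic for a fixed
    config and seed (no timestamps).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    json_path = path / f"{report.name}.json"
    txt_path = path / f"{report.name}.txt"
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=_json_default)
    with open(txt_path, "w") as fh:
        fh.write(format_report(report))
    return {"json": json_path, "txt": txt_path}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def format_report(report: SuiteReport) -> str:
    """Human-readable one-line-per-result summary of a suite report."""
    lines = [f"=== {report.name} suite ==="]
    prov = report.provenance
    lines.append(
        f"version {prov.get('software_version')} | config {prov.get('config_hash')} | "
        f"seed {prov.get('master_seed')} | trials in {prov.get('n_trials_in')}"
    )
    for name, entry in report.entries.items():
        if entry["kind"] == "amplitude":
            fit = entry["fit"]
            perm = entry["perm"]
            lines.append(
                f"{name}: a={fit['a']:+.3f} w={fit['w']:.4f} "
                f"n={entry['n_points']} p={perm['p_display']}"
            )
        elif entry["kind"] == "contrast":
            perm = entry["perm"]
            lines.append(
                f"{name}: {entry['label_a']}={entry['amplitude_a']:+.3f} vs "
                f"{entry['label_b']}={entry['amplitude_b']:+.3f} "
                f"diff={entry['observed_diff']:+.3f} p={perm['p_display']}"
            )
        elif entry["kind"] == "model_free":
            lines.append(f"{name}: model-free bias={entry['value']:+.3f} n={entry['n_points']}")
    for name, reason in report.skipped.items():
        lines.append(f"{name}: SKIPPED ({reason})")
    return "\n".join(lines) + "\n"
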