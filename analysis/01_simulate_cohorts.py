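#!/usr/bin/env python
"""Generate the synthetic cohorts used by the downstream analyses.

Three cohorts mirror the study designs the pipeline targets:

* ``noise2level`` — two stimulus-noise levels per item plus confidence
  ratings; the main cohort for the confirmatory hypothesis suite.
* ``colour_precue`` — item colours with a target-colour pre-cue; same- vs
  different-colour distractors are generated with opposite-sign bias
  (attraction vs repulsion), the pattern expected when colour is
  task-relevant.
* ``colour_nocue`` — item colours but no cue; one shared bias amplitude,
  the null pattern expected when colour is task-irrelevant.

Writes canonical trial CSVs under results/data/.
"""

from pathlib import Path

from wmbias import DoGParams, SimConfig, simulate_trials, write_trials

OUT = Path(__file__).resolve().parents[1] / "results" / "data"

COHORTS = {
    "noise2level": SimConfig(
        n_observers=40, trials_per_observer=100, conditions="noise2level",
        kappa_by_position=(2.5, 3.0, 3.5, 5.0),
        bias_params={"default": DoGParams(a=2.0, w=0.03)},
        p_guess=0.1, seed=101,
    ),
    "colour_precue": SimConfig(
        n_observers=40, trials_per_observer=100, conditions="colour_precue",
        kappa_by_position=(2.5, 3.0, 3.5, 5.0),
        bias_params={
            "default": DoGParams(a=2.0, w=0.03),
            "same": DoGParams(a=2.0, w=0.03),
            "different": DoGParams(a=-2.0, w=0.03),
        },
        p_guess=0.1, seed=102,
    ),
    "colour_nocue": SimConfig(
        n_observers=40, trials_per_observer=100, conditions="colour_nocue",
        kappa_by_position=(2.5, 3.0, 3.5, 5.0),
        bias_params={"default": DoGParams(a=2.0, w=0.03)},
        p_guess=0.1, seed=103,
    ),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, cfg in COHORTS.items():
        trials = simulate_trials(cfg)
        path = OUT / f"{name}.csv"
        write_trials(trials, path)
        print(f"{name}: {len(trials)} trials -> {path}")
        print(f"  generator: {trials.attrs['sim_metadata']}")


if __name__ == "__main__":
    main()
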