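"""Canonical trial-table schema (version 1).

One CSV row per retro-cue trial.  Foreign layouts (e.g. a public data
deposit) are converted to this schema through a user-supplied adapter
before entering the pipeline; see :mod:`wmbias.preprocess`.
"""

from __future__ import annotations

SCHEMA_VERSION = "1"

ORIENTATION_COLUMNS = ("ori_1", "ori_2", "ori_3", "ori_4")
NOISE_COLUMNS = ("noise_1", "noise_2", "noise_3", "noise_4")
COLOUR_COLUMNS = ("colour_1", "colour_2", "colour_3", "colour_4")

CANONICAL_COLUMNS = (
    "observer_id",
    "experiment_id",
    "trial_index",
    *ORIENTATION_COLUMNS,
    *NOISE_COLUMNS,
    *COLOUR_COLUMNS,
    "precue_colour",
    "target_position",
    "response",
    "confidence",
    "attention_pass",
)

NOISE_LEVELS = ("high", "low", "none")
COLOURS = ("cyan", "yellow", "none")
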