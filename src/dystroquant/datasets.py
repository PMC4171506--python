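"""Reference reproducibility measurements bundled for validating the
precision statistics.

These are per-experiment average membrane dystrophin intensities (au,
MANDYS106 staining) of the same biopsies re-analyzed in independent
experiments on different days by different operators — once at 'control'
microscope settings (1% laser, healthy control vs BMD vs DMD samples)
and once at high laser settings (7%, DMD samples only).  The published
inter-assay CV% and ranking columns derived from them are recorded
alongside, so the package's own ``cv_percent`` and ``rank_samples`` can
be checked against an independent hand calculation.
"""

from __future__ import annotations

# 'control' settings: per-experiment biopsy means (au), experiments 1 and 2
CONTROL_SETTINGS_MEANS: dict[str, dict[str, float]] = {
    "Control 2": {"exp1": 929.0, "exp2": 768.0},
    "BMD 1": {"exp1": 415.0, "exp2": 367.0},
    "BMD 3": {"exp1": 387.0, "exp2": 412.0},
    "BMD 4": {"exp1": 359.0, "exp2": 323.0},
    "BMD 2": {"exp1": 200.0, "exp2": 213.0},
    "DMD 1": {"exp1": 58.0, "exp2": 82.0},
    "DMD 2": {"exp1": 44.0, "exp2": 82.0},
}

#: Published inter-assay CV% (integer percent) at 'control' settings.
CONTROL_SETTINGS_CV: dict[str, int] = {
    "Control 2": 13,
    "BMD 1": 9,
    "BMD 3": 4,
    "BMD 4": 7,
    "BMD 2": 4,
    "DMD 1": 24,
    "DMD 2": 43,
}

# high (7% laser) settings: DMD biopsies across three experiments
HIGH_SETTINGS_MEANS: dict[str, dict[str, float]] = {
    "DMD 3": {"exp3": 255.0, "exp4": 241.0, "exp7": 208.0},
    "DMD 1": {"exp3": 286.0, "exp4": 298.0, "exp7": 228.0},
    "DMD 4": {"exp5": 306.0, "exp6": 427.0, "exp7": 354.0},
    "DMD 5": {"exp5": 406.0, "exp7": 397.0},
}

#: Published inter-assay CV% (integer percent) at high settings.
HIGH_SETTINGS_CV: dict[str, int] = {
    "DMD 3": 10,
    "DMD 1": 14,
    "DMD 4": 17,
    "DMD 5": 2,
}

#: Published sample ranking at high settings (1 = highest intensity),
#: consistent across the three experiments.
HIGH_SETTINGS_RANKING: dict[str, int] = {
    "DMD 5": 1,
    "DMD 4": 2,
    "DMD 1": 3,
    "DMD 3": 4,
}
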