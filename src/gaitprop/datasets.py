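"""Bundled example data."""

from importlib import resources

import pandas as pd


def load_example_cohort() -> pd.DataFrame:
    """Demographics and per-condition treadmill speeds for a published
    35-person post-stroke cohort walking at slow / self-selected / fast
    speeds.

    Columns: id; analysis (which outcome analyses the participant entered);
    sex; age (years); le_fm (Lower-Extremity Fugl-Meyer, dataset 2 only);
    ss_sla (step length asymmetry at self-selected speed, positive = longer
    paretic steps); slow_speed / ss_speed / fast_speed (m/s, blank where a
    condition was not collected); slow_partially_excluded (1 where the slow
    trial was excluded from at least one analysis). Dataset-1 participants
    (le_fm blank) had the slow belt set to 50% of self-selected speed.
    """
    path = resources.files("gaitprop").joinpath("data/example_cohort.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)
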