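"""Synthetic behavioural cohorts with the structure of the mouse study.

Two generators produce trial-record tables in the shared schema (37
subjects by default: 8 GFP, 16 light-off, 21 light-on; 8 days x 10 trials
of initial learning and 12 days x 10 trials of reversal):

* ``mechanistic`` — each subject is a simulated agent whose (eta_ACh,
  eta_DA) pair is drawn from its group's sampling region (control vs
  reduced acetylcholine) and run through the full spiking-network session;
* ``glm`` — each trial outcome is Bernoulli with success probability given
  by the fixed-effects logistic model plus Gaussian subject-specific
  intercepts and trial slopes (the mixed-model structure).

Hidden truths (per-subject parameters or coefficients) are returned
separately from the data table so recovery tests cannot leak them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .arena import ProtocolSpec, default_protocol
from .fitting import GridSpec, ParameterRegion, default_regions, sample_group_parameters
from .plasticity import PlasticityParams
from .simulate import Network, run_session
from .stats import DESIGN_COLUMNS, TRIAL_COLUMNS, records_from_session, validate_records

__all__ = [
    "CohortSpec",
    "DEFAULT_GROUP_SIZES",
    "default_glm_coefficients",
    "generate_mechanistic_cohort",
    "generate_glm_cohort",
]

DEFAULT_GROUP_SIZES = {"GFP": 8, "light_off": 16, "light_on": 21}

#: which sampling region each group draws from in the mechanistic generator
DEFAULT_GROUP_REGIONS = {
    "GFP": "control",
    "light_off": "control",
    "light_on": "reduced_ach",
}


def default_glm_coefficients() -> dict:
    """Generating coefficients for the glm cohort, on the fixed-effects design scale.

    Chosen once so synthetic curves span the observed range: controls start
    near 50% and approach ceiling within a stage, reversal resets
    performance, and the group-by-stage interactions favour the controls.
    """
    return {
        "intercept": -0.2,
        "group_light_off": 0.15,
        "group_GFP": 0.10,
        "trial": 0.030,
        "stage": -1.6,
        "trial_x_stage": -0.004,
        "group_light_off_x_stage": 0.55,
        "group_GFP_x_stage": 0.50,
    }


@dataclass(frozen=True)
class CohortSpec:
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    generator: str = "mechanistic"          # or "glm"
    group_regions: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_REGIONS))
    regions: dict = field(default_factory=default_regions)
    beta: dict = field(default_factory=default_glm_coefficients)
    sd_b0: float = 0.5      # SD of subject-specific intercepts
    sd_b4: float = 0.008    # SD of subject-specific trial slopes
    protocol: ProtocolSpec = field(default_factory=default_protocol)
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if self.sd_b0 < 0 or self.sd_b4 < 0:
            raise ValueError("subject-effect spreads must be nonnegative")


def _subject_ids(spec: CohortSpec):
    for group, n in spec.group_sizes.items():
        for i in range(n):
            yield f"{group}_{i + 1:02d}", group


def generate_mechanistic_cohort(
    spec: CohortSpec,
    grid: GridSpec | None = None,
    network: Network | None = None,
):
    """Simulate one agent per subject from group-region parameter draws.

    Returns ``(records, truth)``: the trial-record table and a per-subject
    table of the true (eta_ach, eta_da) used.
    """
    if spec.generator != "mechanistic":
        raise ValueError("spec.generator must be 'mechanistic'")
    grid = grid or GridSpec()
    network = network or Network.build()
    subjects = list(_subject_ids(spec))
    children = np.random.SeedSequence(spec.seed).spawn(len(subjects) + 1)
    draw_rng = np.random.default_rng(children[0])

    frames, truth_rows = [], []
    for k, (subject, group) in enumerate(subjects):
        region = spec.regions[spec.group_regions[group]]
        if not isinstance(region, ParameterRegion):
            raise ValueError(f"no sampling region for group {group!r}")
        ach, da = sample_group_parameters(region, 1, draw_rng, grid)[0]
        sess = run_session(
            PlasticityParams(eta_ach=ach, eta_da=da),
            protocol=spec.protocol,
            seed=children[k + 1].generate_state(1)[0] & 0x7FFFFFFF,
            network=network,
        )
        frames.append(records_from_session(sess, subject, group))
        truth_rows.append((subject, group, ach, da))
    records = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=["subject", "group", "eta_ach", "eta_da"])
    return validate_records(records), truth


def generate_glm_cohort(spec: CohortSpec):
    """Draw trial outcomes from the logistic model with subject effects.

    Success probability per trial is the inverse logit of the fixed-effects linear
    predictor (light-on reference coding, running trial index within stage)
    plus the subject's Gaussian intercept and trial-slope deviations.
    Returns ``(records, truth)`` where truth holds the generating
    coefficients and the per-subject deviations.
    """
    if spec.generator != "glm":
        raise ValueError("spec.generator must be 'glm'")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    prot = spec.protocol
    beta = np.array([spec.beta[c] for c in DESIGN_COLUMNS])

    frames, truth_rows = [], []
    for subject, group in _subject_ids(spec):
        b0 = rng.normal(0.0, spec.sd_b0) if spec.sd_b0 else 0.0
        b4 = rng.normal(0.0, spec.sd_b4) if spec.sd_b4 else 0.0
        rows = []
        for stage_code, days in ((0, prot.days_initial), (1, prot.days_reversal)):
            for day in range(1, days + 1):
                for trial in range(1, prot.trials_per_day + 1):
                    rows.append((subject, group, stage_code, day, trial, 0))
        df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
        trial_idx = (df["day"] - 1) * prot.trials_per_day + df["trial"]
        g_off = float(group == "light_off")
        g_gfp = float(group == "GFP")
        stage = df["stage"].to_numpy(float)
        lp = (
            beta[0]
            + beta[1] * g_off
            + beta[2] * g_gfp
            + beta[3] * trial_idx
            + beta[4] * stage
            + beta[5] * trial_idx * stage
            + beta[6] * g_off * stage
            + beta[7] * g_gfp * stage
            + b0
            + b4 * trial_idx
        )
        if np.any(np.abs(lp) > 30):
            warnings.warn("saturated linear predictor; probabilities pinned")
        df["outcome"] = (rng.random(len(df)) < expit(lp)).astype(int)
        frames.append(df)
        truth_rows.append((subject, group, b0, b4))
    records = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=["subject", "group", "b0", "b4"])
    truth.attrs["beta"] = dict(spec.beta)
    return validate_records(records), truth
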