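"""Synthetic trial-table generator for affect–physiology similarity analyses.

Emulates the structure of passive picture-viewing style experiments: each
participant rates every stimulus on 1–9 valence and arousal scales (SAM), and
each trial carries a skin-conductance response amplitude (µS) and a startle
eyeblink magnitude (µV, missing allowed).

Two noise regimes are supported:

* ``fingerprint`` — physiological responses are locked to the rating with
  homoskedastic noise, so trials with similar ratings evoke similar responses.
* ``populations`` — the noise standard deviation grows along the rating
  dimension (arousal for SCR, reversed valence for startle), so trials at the
  "active" end of the dimension evoke increasingly variable responses.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeneratorConfig",
    "generate_ratings",
    "generate_physiology",
    "generate_dataset",
    "write_trial_table",
    "read_trial_table",
    "TRIAL_TABLE_COLUMNS",
]

TRIAL_TABLE_COLUMNS = [
    "participant_id",
    "trial_index",
    "stimulus_id",
    "valence_rating",
    "arousal_rating",
    "valence_category",
    "arousal_category",
    "scr_amplitude",
    "startle_magnitude",
]

Regime = Literal["fingerprint", "populations"]


class InvalidConfigError(ValueError):
    """Raised when a GeneratorConfig violates its own invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study.

    Parameters
    ----------
    n_participants : int
        Number of simulated participants.
    n_trials : int
        Trials per participant (36 for picture/sound tasks, 18 for imagery).
    rating_scale_max : int
        Upper bound of the integer rating scale (SAM: 9).
    regime : {"fingerprint", "populations"}
        Noise regime; ``fingerprint`` forces ``hetero_coef == 0``.
    base_response : float
        Mean physiological response (µS for SCR) at the low end of the
        driving dimension.
    slope : float
        Mean response change per rating unit along the driving dimension.
    noise_sd : float
        Homoskedastic component of the trial noise SD.
    hetero_coef : float
        Additional noise SD per rating unit along the driving dimension
        (0 under the fingerprint regime).
    missing_rate : float
        Independent probability that a startle trial is unscorable (missing).
    zero_response_rate : float
        Independent probability that a startle trial is a scored
        zero-response (a valid 0 µV magnitude, distinct from missing).
    direction : {"increasing", "decreasing"}
        Wiring of startle to valence: ``decreasing`` (the physiological
        default) makes startle magnitude fall as rated valence rises.
        SCR always grows with arousal.
    startle_scale : float
        Multiplier mapping the (µS-scale) response parameters onto a
        plausible µV startle-magnitude range.
    seed : int
        Seed for all randomness in generation.
    """

    n_participants: int
    n_trials: int = 36
    rating_scale_max: int = 9
    regime: Regime = "fingerprint"
    base_response: float = 0.3
    slope: float = 0.08
    noise_sd: float = 0.08
    hetero_coef: float = 0.0
    missing_rate: float = 0.0
    zero_response_rate: float = 0.0
    direction: Literal["increasing", "decreasing"] = "decreasing"
    startle_scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_trials < 1:
            raise InvalidConfigError("n_participants and n_trials must be positive")
        if self.rating_scale_max < 2:
            raise InvalidConfigError("rating_scale_max must be at least 2")
        if self.regime not in ("fingerprint", "populations"):
            raise InvalidConfigError(f"unknown regime: {self.regime!r}")
        if self.regime == "fingerprint" and self.hetero_coef != 0:
            raise InvalidConfigError("fingerprint regime requires hetero_coef = 0")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be > 0")
        if self.base_response < 0 or self.hetero_coef < 0:
            raise InvalidConfigError("base_response and hetero_coef must be >= 0")
        if not (0.0 <= self.missing_rate <= 1.0 and 0.0 <= self.zero_response_rate <= 1.0):
            raise InvalidConfigError("rates must be probabilities in [0, 1]")
        if self.direction not in ("increasing", "decreasing"):
            raise InvalidConfigError(f"unknown direction: {self.direction!r}")

    # The two presets below are the study conditions used throughout the
    # package's simulations; see docs/methods.md for the rationale.
    @classmethod
    def fingerprint(cls, n_participants: int, **kwargs) -> "GeneratorConfig":
        """Rating-locked responses with constant noise."""
        defaults = dict(regime="fingerprint", base_response=0.3, slope=0.08,
                        noise_sd=0.08, hetero_coef=0.0)
        defaults.update(kwargs)
        return cls(n_participants=n_participants, **defaults)

    @classmethod
    def populations(cls, n_participants: int, **kwargs) -> "GeneratorConfig":
        """Weak mean trend, noise SD growing along the driving dimension."""
        defaults = dict(regime="populations", base_response=0.3, slope=0.02,
                        noise_sd=0.05, hetero_coef=0.12)
        defaults.update(kwargs)
        return cls(n_participants=n_participants, **defaults)

    @classmethod
    def from_yaml(cls, source) -> "GeneratorConfig":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                payload = yaml.safe_load(fh)
        return cls(**payload)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


def _category_anchors(scale_max: int) -> dict:
    """Normative rating anchors per stimulus category on a 1..scale_max scale.

    Pleasant and unpleasant stimuli sit at the valence extremes and share a
    high arousal anchor; neutral stimuli sit mid-valence with low arousal,
    mimicking the trimodal-valence / bimodal-arousal structure of normed
    affective picture sets.
    """
    hi = scale_max - 1
    lo = 2
    mid = (scale_max + 1) // 2
    return {
        "pleasant": {"valence": hi, "arousal": hi - 1},
        "unpleasant": {"valence": lo, "arousal": hi - 1},
        "neutral": {"valence": mid, "arousal": lo},
    }


def _stimulus_roster(n_trials: int) -> pd.DataFrame:
    """Fixed stimulus set: categories in (almost) equal thirds."""
    cats = ["pleasant", "unpleasant", "neutral"]
    per = [n_trials // 3] * 3
    for k in range(n_trials - sum(per)):
        per[k] += 1
    rows = []
    for cat, n in zip(cats, per):
        for i in range(n):
            rows.append({"stimulus_id": f"{cat[:4]}_{i + 1:02d}", "valence_category": cat})
    return pd.DataFrame(rows)


def generate_ratings(config: GeneratorConfig) -> pd.DataFrame:
    """Generate per-participant integer valence/arousal ratings.

    Ratings are anchored at the stimulus category's normative value plus
    discrete participant-by-trial jitter, clipped to the rating scale.
    Arousal category is a median split on the normative arousal anchors
    (emotional categories high, neutral low). Physiology columns are left
    missing; fill them with :func:`generate_physiology`.
    """
    rng = np.random.default_rng([config.seed, 0])
    anchors = _category_anchors(config.rating_scale_max)
    roster = _stimulus_roster(config.n_trials)
    T = config.n_trials

    frames = []
    for p in range(config.n_participants):
        pid = f"sub-{p + 1:03d}"
        order = rng.permutation(T) + 1  # presentation position of each stimulus
        val_anchor = roster["valence_category"].map(
            {c: a["valence"] for c, a in anchors.items()}
        ).to_numpy()
        aro_anchor = roster["valence_category"].map(
            {c: a["arousal"] for c, a in anchors.items()}
        ).to_numpy()
        jitter_v = np.rint(rng.normal(0.0, 1.0, size=T)).astype(int)
        jitter_a = np.rint(rng.normal(0.0, 1.0, size=T)).astype(int)
        val = np.clip(val_anchor + jitter_v, 1, config.rating_scale_max)
        aro = np.clip(aro_anchor + jitter_a, 1, config.rating_scale_max)
        median_aro = np.median(list({a["arousal"] for a in anchors.values()}))
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "trial_index": order,
            "stimulus_id": roster["stimulus_id"],
            "valence_rating": val,
            "arousal_rating": aro,
            "valence_category": roster["valence_category"],
            "arousal_category": np.where(aro_anchor > median_aro, "high", "low"),
            "scr_amplitude": np.nan,
            "startle_magnitude": np.nan,
        }))
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(["participant_id", "trial_index"], ignore_index=True)


def generate_physiology(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Fill SCR amplitudes and startle magnitudes conditional on the ratings.

    SCR grows with arousal; startle falls with valence when
    ``direction="decreasing"``. Under the populations regime the noise SD
    grows along the same dimension (higher arousal / lower valence →
    noisier), which is what produces one-sided trial-by-trial dissimilarity.
    Responses are truncated at zero; startle trials go missing independently
    with ``missing_rate``.
    """
    if table[["valence_rating", "arousal_rating"]].isna().any().any():
        raise ValueError("ratings must be present before physiology is generated")
    rng = np.random.default_rng([config.seed, 1])
    out = table.copy()

    aro_dev = out["arousal_rating"].to_numpy(float) - 1.0
    scr_mean = config.base_response + config.slope * aro_dev
    scr_sd = config.noise_sd + config.hetero_coef * aro_dev
    out["scr_amplitude"] = np.maximum(
        0.0, rng.normal(scr_mean, scr_sd)
    )

    if config.direction == "decreasing":
        stl_dev = config.rating_scale_max - out["valence_rating"].to_numpy(float)
    else:
        stl_dev = out["valence_rating"].to_numpy(float) - 1.0
    stl_mean = config.startle_scale * (config.base_response + config.slope * stl_dev)
    stl_sd = config.startle_scale * (config.noise_sd + config.hetero_coef * stl_dev)
    startle = np.maximum(0.0, rng.normal(stl_mean, stl_sd))
    zero_mask = rng.random(len(out)) < config.zero_response_rate
    startle[zero_mask] = 0.0
    miss_mask = rng.random(len(out)) < config.missing_rate
    startle[miss_mask] = np.nan
    out["startle_magnitude"] = startle
    return out


def generate_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Ratings plus physiology in one call; fully determined by config.seed."""
    return generate_physiology(generate_ratings(config), config)


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write the canonical trial-table CSV (missing values as empty fields)."""
    table.loc[:, TRIAL_TABLE_COLUMNS].to_csv(path, index=False, na_rep="")


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial-table CSV, validating header and basic invariants."""
    df = pd.read_csv(path, dtype={"participant_id": str, "stimulus_id": str})
    missing_cols = [c for c in TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"trial table is missing columns: {missing_cols}")
    dup = df.duplicated(subset=["participant_id", "trial_index"])
    if dup.any():
        row = int(df.index[dup][0]) + 2  # 1-based plus header line
        raise ValueError(f"duplicate (participant_id, trial_index) at CSV row {row}")
    counts = df.groupby("participant_id").size()
    if counts.nunique() > 1:
        raise ValueError("participants have unequal trial counts")
    return df
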