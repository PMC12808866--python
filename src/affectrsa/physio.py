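"""Preprocessing and RSM construction for trial-level physiology.

Skin-conductance amplitudes are log-transformed (``log[1 + SCR]``); startle
blink magnitudes are t-transformed within participant (mean 50, SD 10 over
non-missing trials, scored zero-responses included as zeros). Participants
with more than 50% startle non-responses (zero or missing) are excluded.

Two averaged physiological RSMs are built:

* **dismissing intraindividual variability** — sort each participant's trials
  by their own rating, average the physiological values across participants
  at each sorted rank position, then apply the NN formula once to the
  averaged vector;
* **considering intraindividual variability** — apply the NN formula to each
  participant's own sorted values (one RSM per participant), then average the
  matrices cellwise, ignoring missing cells.

The two orders of operations coincide only when responses are rating-locked
and noise-free; under trial-to-trial variability they diverge, which is the
phenomenon the analysis is designed to expose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .rsm import RSM, ModelSpec, average_rsms, build_model_rsm, sorted_trial_values

__all__ = [
    "preprocess_scr",
    "t_transform_startle",
    "qc_filter_startle",
    "collapse_repetitions",
    "preprocess_table",
    "build_physio_rsm_dismissing",
    "build_physio_rsm_considering",
]

MEASURE_COLUMNS = {"scr": "scr_amplitude", "startle": "startle_magnitude"}
PREPROCESSED_COLUMNS = {"scr": "scr_log", "startle": "startle_t"}


class ZeroVarianceError(ValueError):
    """Participant-level transform undefined (flags the participant for exclusion)."""


def preprocess_scr(amplitudes) -> np.ndarray:
    """``log(1 + amplitude)`` elementwise; missing propagates."""
    x = np.asarray(amplitudes, dtype=float)
    if np.any(x[~np.isnan(x)] < 0):
        raise ValueError("SCR amplitudes must be non-negative")
    return np.log1p(x)


def t_transform_startle(magnitudes) -> np.ndarray:
    """T-scores (mean 50, SD 10) over a participant's non-missing trials.

    Uses the sample SD (ddof=1). Scored zero-responses enter as zeros;
    missing trials propagate as missing.
    """
    x = np.asarray(magnitudes, dtype=float)
    present = ~np.isnan(x)
    if present.sum() < 2:
        raise ZeroVarianceError("need >= 2 non-missing startle trials to t-transform")
    mu = x[present].mean()
    sd = x[present].std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("zero startle variance; participant should be excluded")
    return 50.0 + 10.0 * (x - mu) / sd


def qc_filter_startle(table: pd.DataFrame, max_nonresponse_frac: float = 0.5,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude participants with *more than* ``max_nonresponse_frac`` startle
    non-responses (zero or missing trials); the inequality is strict, so a
    participant at exactly the threshold is retained.

    Returns the filtered table and an exclusion report with one row per
    participant (columns: participant_id, nonresponse_frac, excluded).
    """
    col = MEASURE_COLUMNS["startle"]
    if col not in table.columns:
        raise ValueError("trial table has no startle_magnitude column")
    rows = []
    keep_ids = []
    for pid, grp in table.groupby("participant_id", sort=True):
        x = grp[col].to_numpy(float)
        frac = float(np.mean(np.isnan(x) | (x == 0)))
        excluded = frac > max_nonresponse_frac
        rows.append({"participant_id": pid, "nonresponse_frac": frac,
                     "excluded": excluded,
                     "reason": "startle_nonresponse" if excluded else ""})
        if not excluded:
            keep_ids.append(pid)
    report = pd.DataFrame(rows)
    filtered = table[table["participant_id"].isin(keep_ids)].reset_index(drop=True)
    return filtered, report


def collapse_repetitions(table: pd.DataFrame, how: Literal["mean", "first"] = "mean",
                         ) -> pd.DataFrame:
    """Collapse repeated presentations of the same stimulus per participant.

    ``mean`` averages ratings and physiology over repetitions (missing
    ignored); ``first`` keeps the earliest presentation. Trial indices are
    re-assigned 1..T in first-presentation order.
    """
    if how not in ("mean", "first"):
        raise ValueError(f"unknown repetition collapse: {how!r}")
    out = []
    for pid, grp in table.groupby("participant_id", sort=True):
        grp = grp.sort_values("trial_index", kind="stable")
        if how == "first":
            coll = grp.drop_duplicates(subset="stimulus_id", keep="first").copy()
        else:
            first = grp.drop_duplicates(subset="stimulus_id", keep="first").copy()
            agg = grp.groupby("stimulus_id").agg(
                valence_rating=("valence_rating", "mean"),
                arousal_rating=("arousal_rating", "mean"),
                scr_amplitude=("scr_amplitude", "mean"),
                startle_magnitude=("startle_magnitude", "mean"),
            )
            coll = first.set_index("stimulus_id")
            coll = coll.astype({c: float for c in agg.columns})
            coll.update(agg)
            coll = coll.reset_index()
        coll = coll.sort_values("trial_index", kind="stable")
        coll["trial_index"] = np.arange(1, len(coll) + 1)
        out.append(coll)
    return pd.concat(out, ignore_index=True)[table.columns.tolist()]


def preprocess_table(table: pd.DataFrame, measure: Literal["scr", "startle"],
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add the preprocessed value column for ``measure``.

    SCR: log1p, all participants retained. Startle: >50% non-response QC
    filter, then within-participant t-transform. Returns the table (filtered
    where applicable) and the exclusion report.
    """
    if measure == "scr":
        out = table.copy()
        out[PREPROCESSED_COLUMNS["scr"]] = preprocess_scr(out[MEASURE_COLUMNS["scr"]])
        report = pd.DataFrame(columns=["participant_id", "nonresponse_frac",
                                       "excluded", "reason"])
        return out, report
    if measure == "startle":
        filtered, report = qc_filter_startle(table)
        parts = []
        for pid, grp in filtered.groupby("participant_id", sort=True):
            grp = grp.copy()
            grp[PREPROCESSED_COLUMNS["startle"]] = t_transform_startle(
                grp[MEASURE_COLUMNS["startle"]])
            parts.append(grp)
        if not parts:
            raise ValueError("no participants survived the startle QC filter")
        return pd.concat(parts, ignore_index=True), report
    raise ValueError(f"unknown measure: {measure!r}")


def _participant_sorted_matrix(table: pd.DataFrame, value_col: str,
                               sort_dimension: str) -> tuple[np.ndarray, list[str]]:
    """Stack each participant's rating-sorted value vector into an N×T matrix."""
    rows, pids = [], []
    T = None
    for pid, grp in table.groupby("participant_id", sort=True):
        vals, _ = sorted_trial_values(grp, sort_dimension, value_col)
        if T is None:
            T = len(vals)
        elif len(vals) != T:
            raise ValueError("participants have unequal trial counts")
        rows.append(vals)
        pids.append(str(pid))
    return np.vstack(rows), pids


def build_physio_rsm_dismissing(table: pd.DataFrame, measure: str,
                                sort_dimension: str) -> RSM:
    """Averaged physiological RSM dismissing intraindividual variability.

    Average first (across participants, at each sorted rank position,
    missing ignored), then apply the NN formula once with ``v_max`` = the
    maximum of the averaged vector.
    """
    value_col = PREPROCESSED_COLUMNS[measure]
    if value_col not in table.columns:
        raise ValueError(f"table lacks preprocessed column {value_col!r}; "
                         "run preprocess_table first")
    mat, _ = _participant_sorted_matrix(table, value_col, sort_dimension)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rank positions
        averaged = np.nanmean(mat, axis=0)
    spec = ModelSpec(kind="NN", sort_dimension=sort_dimension,
                     v_max=float(np.nanmax(averaged)), n_variables=len(averaged))
    out = build_model_rsm(averaged, spec)
    out.meta.update({"model": f"{measure}_dismissing", "measure": measure,
                     "variant": "dismissing", "n_participants": mat.shape[0]})
    return out


def build_physio_rsm_considering(table: pd.DataFrame, measure: str,
                                 sort_dimension: str, min_usable_trials: int = 3,
                                 ) -> tuple[RSM, list[RSM], list[str]]:
    """Averaged physiological RSM considering intraindividual variability.

    Compute first (one NN RSM per participant on their own sorted values,
    with per-participant ``v_max``), then average the matrices cellwise.
    Missing trials yield missing rows/columns in that participant's RSM.
    Participants with fewer than ``min_usable_trials`` non-missing trials
    are excluded with a warning.

    Returns (averaged RSM, per-participant RSMs, participant ids).
    """
    value_col = PREPROCESSED_COLUMNS[measure]
    if value_col not in table.columns:
        raise ValueError(f"table lacks preprocessed column {value_col!r}; "
                         "run preprocess_table first")
    individual: list[RSM] = []
    pids: list[str] = []
    for pid, grp in table.groupby("participant_id", sort=True):
        vals, stims = sorted_trial_values(grp, sort_dimension, value_col)
        usable = np.sum(~np.isnan(vals))
        if usable < min_usable_trials:
            warnings.warn(f"participant {pid}: only {usable} usable trials; excluded")
            continue
        spec = ModelSpec(kind="NN", sort_dimension=sort_dimension,
                         v_max=float(np.nanmax(vals)), n_variables=len(vals))
        r = build_model_rsm(vals, spec)
        r.trial_order = stims
        r.meta.update({"model": f"{measure}_individual", "measure": measure,
                       "variant": "individual", "participant": str(pid)})
        individual.append(r)
        pids.append(str(pid))
    if not individual:
        raise ValueError("no participant had enough usable trials")
    avg = average_rsms(individual)
    avg.trial_order = np.arange(1, individual[0].n_trials + 1)
    avg.meta.update({"model": f"{measure}_considering", "measure": measure,
                     "variant": "considering"})
    return avg, individual, pids
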