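"""Representational similarity matrices (RSMs) and similarity models.

An RSM here is a symmetric trial-by-trial *similarity* matrix (the mirrored
counterpart of the dissimilarity RDM common in neuroimaging RSA), built after
sorting a participant's trials ascending on a rating dimension.

Three dimensional similarity models are implemented:

* **NN (nearest neighbors)** — ``V_max − |V_i − V_j|``: trials close on the
  dimension are similar anywhere on the scale (fingerprint-style prediction).
* **AK (Anna Karenina)** — ``mean(V_i, V_j) / N``: trials at the high end of
  the dimension are similar, trials at the low end dissimilar.
* **inverted AK** — ``1 / (mean(V_i, V_j) · N)``: the rank mirror of AK
  (similar at the low end, dissimilar at the high end).

Control models (category codes, presentation time) reuse the NN formula on
nominal or ordinal codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "RSM",
    "nn_similarity",
    "ak_similarity",
    "inv_ak_similarity",
    "build_model_rsm",
    "average_rsms",
    "sorted_trial_values",
    "participant_model_rsms",
    "MODEL_KINDS",
]

MODEL_KINDS = ("NN", "AK", "invAK", "categorical_valence", "categorical_arousal", "time")

# Nominal codes for the categorical control models.
VALENCE_CODES = {"pleasant": 1, "unpleasant": 2, "neutral": 3}
AROUSAL_CODES = {"high": 1, "low": 2}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a similarity model.

    ``v_max`` defaults to the rating-scale maximum for NN on ratings and to
    the maximum of the value vector for NN on codes/physiology ("the maximum
    value of the dataset"); ``n_variables`` is the trial count entering the
    AK-family denominators.
    """

    kind: str
    sort_dimension: Literal["arousal", "valence"] = "arousal"
    v_max: float | None = None
    n_variables: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind: {self.kind!r}")
        if self.n_variables is not None and self.n_variables < 1:
            raise ValueError("n_variables must be a positive integer")
        if self.sort_dimension not in ("arousal", "valence"):
            raise ValueError(f"unknown sort dimension: {self.sort_dimension!r}")


@dataclass
class RSM:
    """Symmetric T×T similarity matrix over rating-sorted trials.

    ``values`` uses NaN for missing cells (a cell is missing whenever either
    underlying trial value is missing). ``trial_order`` carries the trial
    identifiers in sorted order; ``counts`` (averaged RSMs only) the number
    of participants contributing to each cell.
    """

    values: np.ndarray
    trial_order: np.ndarray
    meta: dict = field(default_factory=dict)
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("RSM values must be a square matrix")
        self.trial_order = np.asarray(self.trial_order)
        if len(self.trial_order) != self.values.shape[0]:
            raise ValueError("trial_order length must match matrix size")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def is_symmetric(self, tol: float = 1e-12) -> bool:
        a = self.values
        both = ~np.isnan(a) & ~np.isnan(a.T)
        return bool(np.all(np.isnan(a) == np.isnan(a.T))) and bool(
            np.allclose(a[both], a.T[both], atol=tol)
        )

    def to_tsv(self, path) -> None:
        """Serialize as TSV with a one-line provenance header comment."""
        prov = " ".join(f"{k}={v}" for k, v in sorted(self.meta.items()))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# RSM {prov}\n")
            fh.write("\t".join(str(t) for t in self.trial_order) + "\n")
            for row in self.values:
                fh.write("\t".join("" if np.isnan(x) else repr(float(x)) for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "RSM":
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().strip()
            meta = {}
            if header.startswith("# RSM"):
                for tok in header[len("# RSM"):].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
            order = fh.readline().rstrip("\n").split("\t")
            rows = []
            for line in fh:
                rows.append([np.nan if x == "" else float(x)
                             for x in line.rstrip("\n").split("\t")])
        return cls(values=np.array(rows, dtype=float), trial_order=np.array(order), meta=meta)


# ---------------------------------------------------------------------------
# pairwise similarity formulas


def nn_similarity(v_i, v_j, v_max):
    """Nearest-neighbors similarity: ``V_max − |v_i − v_j|``.

    ``v_max`` is the maximum value of the dataset the formula is applied to;
    it keeps all similarities non-negative.
    """
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    vm = float(v_max)
    with np.errstate(invalid="ignore"):
        if np.any((v_i > vm) | (v_j > vm)):
            raise ValueError("v_max must be >= every input value")
    return vm - np.abs(v_i - v_j)


def ak_similarity(v_i, v_j, n_variables):
    """Anna-Karenina similarity: ``mean(v_i, v_j) / N``; grows with both values."""
    if n_variables < 1:
        raise ValueError("n_variables must be >= 1")
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    return (v_i + v_j) / 2.0 / float(n_variables)


def inv_ak_similarity(v_i, v_j, n_variables):
    """Inverted AK similarity: ``1 / (mean(v_i, v_j) · N)``.

    A strictly decreasing, rank-inverse transform of :func:`ak_similarity`
    (their Spearman correlation over any pair set with ≥2 distinct means is
    exactly −1). Requires strictly positive values, which integer ratings
    ≥ 1 guarantee.
    """
    if n_variables < 1:
        raise ValueError("n_variables must be >= 1")
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    m = (v_i + v_j) / 2.0
    with np.errstate(invalid="ignore"):
        if np.any(m[~np.isnan(m)] <= 0):
            raise ValueError("inverted AK requires a strictly positive pair mean")
    return 1.0 / (m * float(n_variables))


# ---------------------------------------------------------------------------
# matrix construction


def build_model_rsm(values: Sequence[float], spec: ModelSpec) -> RSM:
    """Apply the spec's pairwise formula to every trial pair of a sorted vector.

    ``values`` is the per-trial score vector already sorted ascending on the
    model's sorting dimension (ratings for NN/AK/invAK, nominal codes for the
    categorical controls, presentation position for the time control).
    Missing values propagate to missing cells.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot build an RSM from an empty value vector")
    n = spec.n_variables if spec.n_variables is not None else v.size
    if n != v.size:
        raise ValueError("spec.n_variables must equal the number of trials")
    vi = v[:, None]
    vj = v[None, :]
    if spec.kind in ("NN", "categorical_valence", "categorical_arousal", "time"):
        v_max = spec.v_max if spec.v_max is not None else np.nanmax(v)
        mat = nn_similarity(vi, vj, v_max)
        used_vmax = float(v_max)
    elif spec.kind == "AK":
        mat = ak_similarity(vi, vj, n)
        used_vmax = None
    elif spec.kind == "invAK":
        mat = inv_ak_similarity(vi, vj, n)
        used_vmax = None
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(spec.kind)
    meta = {"model": spec.kind, "sort_dimension": spec.sort_dimension,
            "n_variables": n}
    if used_vmax is not None:
        meta["v_max"] = used_vmax
    return RSM(values=mat, trial_order=np.arange(1, v.size + 1), meta=meta)


def average_rsms(rsms: Iterable[RSM]) -> RSM:
    """Cellwise mean across same-shaped RSMs, ignoring missing cells.

    A cell missing in every input stays missing; ``counts`` records the
    number of contributing matrices per cell.
    """
    rsms = list(rsms)
    if not rsms:
        raise ValueError("need at least one RSM to average")
    shape = rsms[0].values.shape
    for r in rsms[1:]:
        if r.values.shape != shape:
            raise ValueError("RSMs must share dimensions to be averaged")
    stack = np.stack([r.values for r in rsms])
    counts = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, np.nansum(np.where(np.isnan(stack), 0.0, stack), axis=0)
                        / np.where(counts > 0, counts, 1), np.nan)
    meta = dict(rsms[0].meta)
    meta["participant"] = "averaged"
    meta["n_averaged"] = len(rsms)
    return RSM(values=mean, trial_order=rsms[0].trial_order.copy(), meta=meta,
               counts=counts)


# ---------------------------------------------------------------------------
# trial-table helpers


def sorted_trial_values(participant: pd.DataFrame, sort_dimension: str,
                        value_column: str) -> tuple[np.ndarray, np.ndarray]:
    """Sort one participant's trials ascending on a rating dimension.

    Ties are broken by presentation order (stable sort on ``trial_index``),
    so the ordering is deterministic. Returns (sorted values, sorted
    stimulus ids).
    """
    rating_col = f"{sort_dimension}_rating"
    df = participant.sort_values("trial_index", kind="stable")
    df = df.sort_values(rating_col, kind="stable")
    return df[value_column].to_numpy(), df["stimulus_id"].to_numpy()


def _model_values(participant: pd.DataFrame, kind: str, sort_dimension: str,
                  rating_scale_max: int) -> np.ndarray:
    """Per-trial value vector for a model kind, in rating-sorted order."""
    rating_col = f"{sort_dimension}_rating"
    df = participant.sort_values("trial_index", kind="stable")
    df = df.sort_values(rating_col, kind="stable")
    if kind in ("NN", "AK", "invAK"):
        return df[rating_col].to_numpy(float)
    if kind == "categorical_valence":
        return df["valence_category"].map(VALENCE_CODES).to_numpy(float)
    if kind == "categorical_arousal":
        return df["arousal_category"].map(AROUSAL_CODES).to_numpy(float)
    if kind == "time":
        return df["trial_index"].to_numpy(float)
    raise ValueError(f"unknown model kind: {kind!r}")


def participant_model_rsms(table: pd.DataFrame, kind: str, sort_dimension: str,
                           rating_scale_max: int = 9,
                           alternative_dimension: bool = False,
                           ) -> tuple[list[RSM], list[str]]:
    """One model RSM per participant, trials sorted on ``sort_dimension``.

    For the dimensional models the pairwise formula is applied to the
    ratings of ``sort_dimension`` itself (NN with ``v_max`` = rating-scale
    maximum), or — with ``alternative_dimension=True`` — to the ratings of
    the other dimension while keeping the focal sort order (the
    "alternative dimensional model" control).
    """
    rsms: list[RSM] = []
    pids: list[str] = []
    for pid, grp in table.groupby("participant_id", sort=True):
        if alternative_dimension:
            other = "valence" if sort_dimension == "arousal" else "arousal"
            rating_col = f"{other}_rating"
            df = grp.sort_values("trial_index", kind="stable")
            df = df.sort_values(f"{sort_dimension}_rating", kind="stable")
            vals = df[rating_col].to_numpy(float)
        else:
            vals = _model_values(grp, kind, sort_dimension, rating_scale_max)
        v_max = float(rating_scale_max) if kind == "NN" else None
        spec = ModelSpec(kind=kind, sort_dimension=sort_dimension, v_max=v_max,
                         n_variables=len(vals))
        r = build_model_rsm(vals, spec)
        r.meta["participant"] = pid
        if alternative_dimension:
            r.meta["model"] = f"{kind}_alternative_dimension"
        rsms.append(r)
        pids.append(str(pid))
    return rsms, pids
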