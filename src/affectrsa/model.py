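"""Model and results objects orchestrating the full RSA battery.

:class:`AffectPhysioRSA` is built from a long-format trial table and, on
``fit()``, runs the two analysis batteries — SCR sorted by arousal, startle
sorted by valence — through preprocessing, model/physiological RSM
construction, averaged-level permutation and Bayes-factor tests (raw and
residualized), the representativeness test of the two averaging regimes, and
individual-level model comparisons with control models. ``fit()`` returns an
:class:`RSAResults` carrying a tidy comparison table, the RSMs, and
``summary()``/``save()``/plotting methods.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import physio as _physio
from . import rsm as _rsm
from .inference import (
    _triangle_rho,
    ComparisonResult,
    IndividualLevelResult,
    compare_with_controls,
    correlation_bf_interval,
    individual_level_test,
    lower_triangle,
    per_participant_similarity,
    permutation_test,
    permutation_test_triangle,
    regress_out,
)

__all__ = ["AnalysisConfig", "AffectPhysioRSA", "RSAResults", "run_battery",
           "representativeness_test", "evidence_label"]

#: battery name -> (measure, sorting dimension, default model pair)
BATTERIES = {
    "scr_arousal": ("scr", "arousal", ("NN", "invAK")),
    "startle_valence": ("startle", "valence", ("NN", "AK")),
}
DEFAULT_CONTROLS = ("categorical_valence", "categorical_arousal", "time",
                    "alternative_dimension")


def evidence_label(bf10: float) -> str:
    """Jeffreys-style evidence category for a BF10."""
    if np.isnan(bf10):
        return "undefined"
    if bf10 > 100:
        return "decisive (H1)"
    if bf10 > 10:
        return "strong (H1)"
    if bf10 > 3:
        return "substantial (H1)"
    if bf10 > 1:
        return "anecdotal (H1)"
    if bf10 > 1 / 3:
        return "anecdotal (H0)"
    if bf10 > 1 / 10:
        return "substantial (H0)"
    if bf10 > 1 / 100:
        return "strong (H0)"
    return "decisive (H0)"


@dataclass
class AnalysisConfig:
    """Declarative description of one analysis run."""

    input_path: str | None = None
    battery: str = "both"
    models: tuple[str, ...] | None = None
    controls: tuple[str, ...] = DEFAULT_CONTROLS
    n_perm: int = 10_000
    seed: int = 0
    repetition_collapse: str = "mean"
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 for reportable p-values")
        if self.battery not in ("both", *BATTERIES):
            raise ValueError(f"unknown battery: {self.battery!r}")
        if self.repetition_collapse not in ("mean", "first"):
            raise ValueError(f"unknown repetition_collapse: {self.repetition_collapse!r}")
        if self.models is not None:
            self.models = tuple(self.models)
        self.controls = tuple(self.controls)

    @classmethod
    def from_yaml(cls, source) -> "AnalysisConfig":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                payload = yaml.safe_load(fh)
        return cls(**payload)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models) if self.models else None
        d["controls"] = list(self.controls)
        return yaml.safe_dump(d, sort_keys=False)


def representativeness_test(individual_rsms: Sequence[_rsm.RSM],
                            averaged_dismissing: _rsm.RSM,
                            averaged_considering: _rsm.RSM,
                            ) -> dict[str, IndividualLevelResult]:
    """Which averaging regime better represents the individual RSMs?

    Per participant, the Spearman similarity between the individual
    physiological RSM and each averaged RSM is extracted and aggregated with
    a one-sided t-test; the residualized variant regresses each averaged
    RSM's lower triangle out of the other's first, isolating each regime's
    unique contribution.
    """
    tri_dis = lower_triangle(averaged_dismissing)
    tri_con = lower_triangle(averaged_considering)
    n = len(individual_rsms)
    out: dict[str, IndividualLevelResult] = {}
    for name, tri in (("dismissing", tri_dis), ("considering", tri_con)):
        rhos = [_triangle_rho(lower_triangle(ind), tri) for ind in individual_rsms]
        out[name] = individual_level_test(np.asarray(rhos))
    resid_dis = regress_out(tri_dis, tri_con)
    resid_con = regress_out(tri_con, tri_dis)
    for name, tri in (("dismissing_residual", resid_dis),
                      ("considering_residual", resid_con)):
        rhos = [_triangle_rho(lower_triangle(ind), tri) for ind in individual_rsms]
        out[name] = individual_level_test(np.asarray(rhos))
    return out


class AffectPhysioRSA:
    """RSA of the correspondence between affect ratings and physiology.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format trial table (one row per participant × trial) with the
        canonical columns (see :data:`affectrsa.datagen.TRIAL_TABLE_COLUMNS`).
    battery : {"scr_arousal", "startle_valence", "both"}
        Which measure × sorting-dimension batteries to run.
    models : sequence of str, optional
        Dimensional models per battery; defaults to (NN, invAK) for SCR and
        (NN, AK) for startle.
    controls : sequence of str
        Control models for the individual-level comparisons.
    n_perm : int
        Monte-Carlo permutation iterations for averaged-level tests.
    repetition_collapse : {"mean", "first"}
        How repeated presentations of a stimulus are collapsed.
    """

    def __init__(self, data: pd.DataFrame, battery: str = "both",
                 models: Sequence[str] | None = None,
                 controls: Sequence[str] = DEFAULT_CONTROLS,
                 n_perm: int = 10_000, repetition_collapse: str = "mean",
                 rating_scale_max: int = 9):
        self.config = AnalysisConfig(battery=battery,
                                     models=tuple(models) if models else None,
                                     controls=tuple(controls), n_perm=n_perm,
                                     repetition_collapse=repetition_collapse)
        self.rating_scale_max = rating_scale_max
        self.data = self._validate(data)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "AffectPhysioRSA":
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "AffectPhysioRSA":
        from .datagen import read_trial_table
        return cls(read_trial_table(path), **kwargs)

    def _validate(self, data: pd.DataFrame) -> pd.DataFrame:
        required = ["participant_id", "trial_index", "stimulus_id",
                    "valence_rating", "arousal_rating", "valence_category",
                    "arousal_category"]
        missing = [c for c in required if c not in data.columns]
        if missing:
            raise ValueError(f"trial table is missing columns: {missing}")
        batteries = self._batteries()
        for name in batteries:
            measure = BATTERIES[name][0]
            col = _physio.MEASURE_COLUMNS[measure]
            if col not in data.columns or data[col].isna().all():
                raise ValueError(
                    f"battery {name!r} requires a populated {col!r} column")
        return data.reset_index(drop=True)

    def _batteries(self) -> list[str]:
        if self.config.battery == "both":
            return list(BATTERIES)
        return [self.config.battery]

    # -- fitting -----------------------------------------------------------
    def fit(self, seed: int = 0) -> "RSAResults":
        """Run the requested batteries; deterministic given ``seed``."""
        rng = np.random.default_rng(seed)
        rows: list[dict] = []
        rsms: dict[str, _rsm.RSM] = {}
        detail: dict[str, object] = {}
        exclusions = []

        data = self.data
        if data.duplicated(subset=["participant_id", "stimulus_id"]).any():
            data = _physio.collapse_repetitions(data, self.config.repetition_collapse)

        for battery in self._batteries():
            measure, sort_dim, default_models = BATTERIES[battery]
            models = self.config.models or default_models
            table, report = _physio.preprocess_table(data, measure)
            if len(report):
                exclusions.append(report.assign(battery=battery))

            # physiological RSMs
            dis = _physio.build_physio_rsm_dismissing(table, measure, sort_dim)
            con, individual, pids = _physio.build_physio_rsm_considering(
                table, measure, sort_dim)
            rsms[f"{battery}/physio_dismissing"] = dis
            rsms[f"{battery}/physio_considering"] = con

            # model RSMs (averaged over the same participants as `individual`)
            model_avg: dict[str, _rsm.RSM] = {}
            model_ind: dict[str, list[_rsm.RSM]] = {}
            for kind in models:
                ind, mpids = _rsm.participant_model_rsms(
                    table, kind, sort_dim, self.rating_scale_max)
                by_pid = dict(zip(mpids, ind))
                model_ind[kind] = [by_pid[p] for p in pids]
                model_avg[kind] = _rsm.average_rsms(ind)
                rsms[f"{battery}/model_{kind}"] = model_avg[kind]

            # averaged-level comparisons, raw and residualized
            pair = {models[0]: models[1], models[1]: models[0]} if len(models) == 2 else {}
            for variant, physio_avg in (("dismissing", dis), ("considering", con)):
                for kind in models:
                    res = permutation_test(model_avg[kind], physio_avg,
                                           n_perm=self.config.n_perm, rng=rng,
                                           seed=seed)
                    res.bf10 = correlation_bf_interval(res.rho, res.n_cells,
                                                       res.null_interval)
                    rows.append(self._row(battery, measure, "averaged", variant,
                                          kind, "", res.rho, res.p_perm,
                                          res.bf10, res.n_cells, seed))
                    detail[f"{battery}/{variant}/{kind}"] = res
                    other = pair.get(kind)
                    if other is None:
                        continue
                    resid = regress_out(lower_triangle(model_avg[kind]),
                                        lower_triangle(model_avg[other]))
                    rres = permutation_test_triangle(resid, physio_avg,
                                                     n_perm=self.config.n_perm,
                                                     rng=rng, seed=seed)
                    rres.bf10 = correlation_bf_interval(rres.rho, rres.n_cells,
                                                        rres.null_interval)
                    rows.append(self._row(battery, measure, "averaged", variant,
                                          kind, other, rres.rho, rres.p_perm,
                                          rres.bf10, rres.n_cells, seed))
                    detail[f"{battery}/{variant}/{kind}|{other}"] = rres

            # representativeness of the two averaging regimes
            rep = representativeness_test(individual, dis, con)
            for name, ilr in rep.items():
                variant, _, ctrl = name.partition("_")
                rows.append(self._row(battery, measure, "representativeness",
                                      variant,
                                      "averaged_physio",
                                      "other_variant" if ctrl else "",
                                      ilr.mean_rho, ilr.p_one_sided, ilr.bf10,
                                      ilr.df + 1, seed))
                detail[f"{battery}/representativeness/{name}"] = ilr

            # individual-level model comparisons
            for kind in models:
                ilr = individual_level_test(
                    per_participant_similarity(individual, model_ind[kind]))
                rows.append(self._row(battery, measure, "individual", "individual",
                                      kind, "", ilr.mean_rho, ilr.p_one_sided,
                                      ilr.bf10, ilr.df + 1, seed))
                detail[f"{battery}/individual/{kind}"] = ilr
                other = pair.get(kind)
                if other is None:
                    continue
                mutual = compare_with_controls(individual, model_ind[kind],
                                               {other: model_ind[other]})[other]
                rows.append(self._row(battery, measure, "individual", "individual",
                                      kind, other, mutual.mean_rho,
                                      mutual.p_one_sided, mutual.bf10,
                                      mutual.df + 1, seed))
                detail[f"{battery}/individual/{kind}|{other}"] = mutual

            # focal AK-family model beyond the control models
            focal = models[1] if len(models) > 1 else models[0]
            controls = self._control_rsms(table, sort_dim, pids)
            ctl_results = compare_with_controls(individual, model_ind[focal],
                                                controls)
            for name, ilr in ctl_results.items():
                rows.append(self._row(battery, measure, "individual", "individual",
                                      focal, name, ilr.mean_rho, ilr.p_one_sided,
                                      ilr.bf10, ilr.df + 1, seed))
                detail[f"{battery}/individual/{focal}|{name}"] = ilr

        comparisons = pd.DataFrame(rows)
        comparisons["evidence"] = comparisons["bf10"].map(evidence_label)
        excl = (pd.concat(exclusions, ignore_index=True) if exclusions
                else pd.DataFrame(columns=["participant_id", "nonresponse_frac",
                                           "excluded", "reason", "battery"]))
        return RSAResults(model=self, comparisons=comparisons, rsms=rsms,
                          detail=detail, exclusions=excl, seed=seed)

    def _control_rsms(self, table: pd.DataFrame, sort_dim: str,
                      pids: Sequence[str]) -> dict[str, list[_rsm.RSM]]:
        out: dict[str, list[_rsm.RSM]] = {}
        for name in self.config.controls:
            if name == "alternative_dimension":
                ind, mpids = _rsm.participant_model_rsms(
                    table, "NN", sort_dim, self.rating_scale_max,
                    alternative_dimension=True)
            else:
                ind, mpids = _rsm.participant_model_rsms(
                    table, name, sort_dim, self.rating_scale_max)
            by_pid = dict(zip(mpids, ind))
            out[name] = [by_pid[p] for p in pids]
        return out

    @staticmethod
    def _row(battery, measure, level, variant, model, controlled_for, rho, p,
             bf10, n, seed) -> dict:
        return {"battery": battery, "measure": measure, "level": level,
                "variant": variant, "model": model,
                "controlled_for": controlled_for, "rho": float(rho),
                "p": float(p), "bf10": float(bf10), "n": int(n),
                "seed": int(seed)}


@dataclass
class RSAResults:
    """Fitted results: tidy comparison table, RSMs, per-test detail."""

    model: AffectPhysioRSA
    comparisons: pd.DataFrame
    rsms: Mapping[str, _rsm.RSM]
    detail: Mapping[str, object]
    exclusions: pd.DataFrame
    seed: int

    def summary(self) -> str:
        """Human-readable comparison table."""
        df = self.comparisons.copy()
        for c in ("rho", "p"):
            df[c] = df[c].map(lambda v: f"{v:.3f}")
        df["bf10"] = df["bf10"].map(
            lambda v: ">100" if v > 100 else ("<0.01" if v < 0.01 else f"{v:.2f}"))
        header = (f"Affect–physiology RSA (seed={self.seed}, "
                  f"n_perm={self.model.config.n_perm})")
        return header + "\n" + "=" * len(header) + "\n" + df.to_string(index=False)

    def get(self, key: str):
        return self.detail[key]

    def save(self, output_dir) -> None:
        """Write tidy CSV, JSON report, RSM TSVs, exclusions and a log."""
        import os

        os.makedirs(output_dir, exist_ok=True)
        self.comparisons.to_csv(os.path.join(output_dir, "comparisons.csv"),
                                index=False, float_format="%.10g")
        self.exclusions.to_csv(os.path.join(output_dir, "exclusions.csv"),
                               index=False)
        report = {"seed": self.seed,
                  "n_perm": self.model.config.n_perm,
                  "comparisons": self.comparisons.to_dict(orient="records")}
        with open(os.path.join(output_dir, "report.json"), "w",
                  encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, default=float)
        rsm_dir = os.path.join(output_dir, "rsms")
        os.makedirs(rsm_dir, exist_ok=True)
        for key, r in self.rsms.items():
            fname = key.replace("/", "__") + ".tsv"
            r.to_tsv(os.path.join(rsm_dir, fname))
        with open(os.path.join(output_dir, "run.log"), "w", encoding="utf-8") as fh:
            fh.write(self.summary() + "\n")

    def plot_rsm(self, key: str, ax=None):
        """Heatmap of one stored RSM (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.rsms[key]
        im = ax.imshow(r.values, origin="lower", cmap="viridis")
        ax.set_title(key)
        ax.set_xlabel("trial (sorted)")
        ax.set_ylabel("trial (sorted)")
        ax.figure.colorbar(im, ax=ax, label="similarity")
        return ax


def run_battery(config: AnalysisConfig) -> RSAResults:
    """Load a trial table, run the configured batteries, write report files."""
    if config.input_path is None:
        raise ValueError("config.input_path is required")
    from .datagen import read_trial_table

    data = read_trial_table(config.input_path)
    model = AffectPhysioRSA(data, battery=config.battery, models=config.models,
                            controls=config.controls, n_perm=config.n_perm,
                            repetition_collapse=config.repetition_collapse)
    results = model.fit(seed=config.seed)
    results.save(config.output_dir)
    return results
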