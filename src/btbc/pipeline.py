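"""End-to-end pipeline: cohort in, coupled statistics out.

``run_pipeline`` drives simulate/load → preprocess+couple → surrogates +
group permutation test → mixed model → SVR prediction → lag decoding, and
writes every artifact with a manifest (parameters, seeds, version, input
checksums).  Defaults equal the study parameters (0.5-s smoothing, 10-SD
outlier rule, 30-s windows with 1-s steps, ±5-s lags in 0.04-s steps, 60-s
surrogate segments, 100 surrogates, 1000 label permutations); any override
is echoed into the run log and manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coupling import DyadCoupling, LagGrid, LagProfile
from .inference import (
    build_analysis_table,
    decode_condition_by_lag,
    fit_condition_model,
    predict_outcome_svr,
)
from .motion import read_motion_file
from .simulate import DyadRecord, SimulationConfig, SyntheticCohort, generate_cohort
from .surrogates import test_genuine_vs_surrogate

__all__ = ["PipelineConfig", "run_pipeline", "read_cohort", "save_profiles", "load_profiles"]

logger = logging.getLogger(__name__)

_STUDY_DEFAULTS = dict(
    smooth_window=0.5,
    outlier_k=10.0,
    window=30.0,
    step=1.0,
    max_lag=5.0,
    lag_step=0.04,
    segment=60.0,
    n_surrogates=100,
    n_permutations=1000,
)


@dataclass
class PipelineConfig:
    """All stage parameters plus paths and seeds."""

    outdir: str = "btbc_results"
    input_dir: str | None = None  # cohort of motion files; None → simulate
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    smooth_window: float = 0.5  # s
    outlier_k: float = 10.0  # SD multiplier
    window: float = 30.0  # s
    step: float = 1.0  # s
    max_lag: float = 5.0  # s
    lag_step: float = 0.04  # s
    segment: float = 60.0  # s
    n_surrogates: int = 100
    n_resamples: int = 10_000
    n_permutations: int = 1000
    inner_folds: int = 10
    seed: int = 0
    stages: tuple = ("coupling", "surrogate", "model", "predict", "decode")

    def overrides(self) -> dict:
        return {
            k: getattr(self, k)
            for k, v in _STUDY_DEFAULTS.items()
            if getattr(self, k) != v
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = SimulationConfig(**sim)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(simulation=sim, **d)


def read_cohort(indir: str | Path, sampling_rate: float | None = None) -> SyntheticCohort:
    """Load a cohort directory: per-record ``<dyad>_<condition>.tsv`` motion
    files plus ``metadata.csv`` (dyad_id, condition, personalization, pre,
    post, outcome[, true_coupling])."""
    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.csv")
    records = []
    for _, row in meta.iterrows():
        path = indir / f"{row.dyad_id}_{row.condition}.tsv"
        series = read_motion_file(path, sampling_rate)
        if len(series) < 2:
            raise ValueError(f"{path}: need instructor and learner columns")
        records.append(
            DyadRecord(
                dyad_id=row.dyad_id,
                condition=row.condition,
                personalization=row.personalization,
                instructor=series[0],
                learner=series[1],
                true_coupling=float(row.get("true_coupling", np.nan)),
                pre=float(row.pre),
                post=float(row.post),
                outcome=float(row.outcome),
            )
        )
    cfg = SimulationConfig(sampling_rate=records[0].instructor.sampling_rate,
                           duration=records[0].instructor.duration,
                           n_dyads=max(2, meta.dyad_id.nunique()))
    return SyntheticCohort(records=records, config=cfg)


def save_profiles(profiles, path: str | Path) -> None:
    """Tidy CSV: dyad_id, condition, lag_s, value, n_windows."""
    pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(path, index=False)


def load_profiles(path: str | Path) -> list[LagProfile]:
    df = pd.read_csv(path)
    profiles = []
    for (dyad, cond), g in df.groupby(["dyad_id", "condition"], sort=False):
        g = g.sort_values("lag_s")
        offs = g["lag_s"].to_numpy()
        step = float(np.round(np.median(np.diff(offs)), 10))
        grid = LagGrid(max_lag=float(offs.max()), lag_step=step)
        profiles.append(
            LagProfile(
                grid=grid,
                values=g["value"].to_numpy(),
                n_windows_used=g["n_windows"].to_numpy(),
                dyad_id=str(dyad),
                condition=str(cond),
            )
        )
    return profiles


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the results bundle as a dict
    of in-memory objects, with all artifacts written under ``outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    overrides = config.overrides()
    if overrides:
        logger.info("parameter overrides vs study defaults: %s", overrides)

    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "overrides_vs_study_defaults": overrides,
        "input_checksums": {},
        "outputs": [],
        "seeds": {"master": config.seed},
    }

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)

    # ---- stage: cohort -------------------------------------------------
    stage = "cohort"
    try:
        if config.input_dir:
            cohort = read_cohort(config.input_dir)
            for f in sorted(Path(config.input_dir).iterdir()):
                if f.is_file():
                    manifest["input_checksums"][f.name] = _sha256(f)
        else:
            cohort = generate_cohort(config.simulation)
            cohort.write(out / "cohort")
            manifest["outputs"].append("cohort/")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    grid = LagGrid(max_lag=config.max_lag, lag_step=config.lag_step)
    bundle: dict = {"cohort": cohort, "manifest": manifest}

    # ---- stage: preprocessing + coupling -------------------------------
    results = {}
    if "coupling" in config.stages:
        stage = "coupling"
        profiles, summaries, reports = [], [], []
        for rec in cohort:
            try:
                res = DyadCoupling(
                    rec.instructor,
                    rec.learner,
                    window=config.window,
                    step=config.step,
                    grid=grid,
                    smooth_window=config.smooth_window,
                    outlier_k=config.outlier_k,
                    dyad_id=rec.dyad_id,
                    condition=rec.condition,
                ).fit()
            except Exception as exc:
                raise RuntimeError(
                    f"stage {stage!r} failed on record {rec.dyad_id}/{rec.condition}: {exc}"
                ) from exc
            results[(rec.dyad_id, rec.condition)] = res
            profiles.append(res.profile)
            summaries.append(res.btbc)
            for role, rep in (res.model.preprocess_reports or {}).items():
                reports.append({"dyad_id": rec.dyad_id, "condition": rec.condition,
                                "role": role, **rep.to_dict()})
        _write("lag_profiles.csv", lambda p: save_profiles(profiles, p))
        _write("btbc_summaries.csv",
               lambda p: pd.DataFrame([s.to_dict() for s in summaries]).to_csv(p, index=False))
        _write("preprocess_reports.csv",
               lambda p: pd.DataFrame(reports).to_csv(p, index=False))
        bundle["results"] = results
        bundle["profiles"] = profiles
        bundle["summaries"] = summaries
        table = build_analysis_table(cohort, summaries)
        _write("analysis_table.csv", lambda p: table.to_csv(p, index=False))
        bundle["table"] = table

    # ---- stage: surrogates + permutation test --------------------------
    if "surrogate" in config.stages:
        stage = "surrogate"
        ensembles, rows = [], []
        for rec in cohort:
            res = results[(rec.dyad_id, rec.condition)]
            sseed = int(rng.integers(2**31))
            try:
                ens = res.surrogate_ensemble(
                    n=config.n_surrogates, segment=config.segment, seed=sseed
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage {stage!r} failed on record {rec.dyad_id}/{rec.condition}: {exc}"
                ) from exc
            ensembles.append(ens)
            for k, v in enumerate(ens.values):
                rows.append({"dyad_id": rec.dyad_id, "condition": rec.condition,
                             "surrogate_index": k, "value": v, "seed": sseed})
        _write("surrogate_ensembles.csv",
               lambda p: pd.DataFrame(rows).to_csv(p, index=False))
        perm_seed = int(rng.integers(2**31))
        perm = test_genuine_vs_surrogate(
            [results[(r.dyad_id, r.condition)].overall for r in cohort],
            ensembles,
            n_resamples=config.n_resamples,
            seed=perm_seed,
        )
        manifest["seeds"]["permutation_test"] = perm_seed
        _write("permutation_test.json", lambda p: p.write_text(json.dumps({
            "observed_mean_btbc": perm.observed,
            "null_mean": float(perm.null_values.mean()),
            "p": perm.p,
            "n_resamples": perm.n_resamples,
            "seed": perm_seed,
        }, indent=2)))
        bundle["ensembles"] = ensembles
        bundle["permutation_test"] = perm

    # ---- stage: mixed model --------------------------------------------
    if "model" in config.stages:
        stage = "model"
        try:
            model = fit_condition_model(bundle["table"], response="overall")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _write("condition_model.txt", lambda p: p.write_text(model.summary() + "\n"))
        _write("condition_model.csv", lambda p: model.terms.to_csv(p, index=False))
        bundle["condition_model"] = model

    # ---- stage: SVR prediction -----------------------------------------
    if "predict" in config.stages:
        stage = "predict"
        pseed = int(rng.integers(2**31))
        t = bundle["table"]
        try:
            pred = predict_outcome_svr(
                t["overall"].to_numpy(), t["outcome"].to_numpy(),
                covariate=t["condition"].to_numpy(),
                inner_folds=config.inner_folds, seed=pseed,
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["seeds"]["svr"] = pseed
        _write("prediction.json", lambda p: p.write_text(json.dumps({
            "r": pred.r, "p": pred.p, "r2": pred.r2,
            "residual_r": pred.residual_r, "residual_p": pred.residual_p,
            "seed": pseed,
        }, indent=2)))
        bundle["prediction"] = pred

    # ---- stage: lag decoding -------------------------------------------
    if "decode" in config.stages:
        stage = "decode"
        dseed = int(rng.integers(2**31))
        try:
            dec = decode_condition_by_lag(
                bundle["profiles"],
                labels=[r.condition for r in cohort],
                dyads=[r.dyad_id for r in cohort],
                n_permutations=config.n_permutations,
                seed=dseed,
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["seeds"]["decoding"] = dseed
        _write("decoding.csv", lambda p: dec.to_frame().to_csv(p, index=False))
        _write("decoding.json", lambda p: p.write_text(json.dumps({
            "best_positive_lag_s": dec.best_positive[0],
            "best_positive_auc": dec.best_positive[1],
            "best_negative_lag_s": dec.best_negative[0],
            "best_negative_auc": dec.best_negative[1],
            "n_significant": int(dec.significant.sum()),
            "seed": dseed,
        }, indent=2)))
        bundle["decoding"] = dec

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return bundle
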