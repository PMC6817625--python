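"""Table I/O, validation, configuration and the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acoustics import profiles_from_recordings
from .path_model import (
    build_path_spec,
    fit_path_model,
    invariance_test,
    jackknife_stability,
    permutation_pvalues,
)
from .ratings import summarize_ratings
from . import stats as vstats

__all__ = [
    "ValidationError",
    "PipelineConfig",
    "read_recordings",
    "read_cohort",
    "read_ratings",
    "read_tables",
    "write_csv",
    "assemble_analysis_table",
    "run_pipeline",
]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"  # 12 significant digits for every numeric output


class ValidationError(ValueError):
    """Input failed schema or row-level validation."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


@dataclass(frozen=True)
class PipelineConfig:
    recordings: Path
    cohort: Path
    ratings: Path
    out_dir: Path
    model_spec: Path | None = None
    mediator_basis: str = "f0"
    permutations: int = 1000
    permutation_scheme: str = "columns"
    alpha: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        if self.permutations < 1:
            raise ValidationError(["permutations must be >= 1"])
        if not 0 < self.alpha < 1:
            raise ValidationError(["alpha must be in (0, 1)"])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path, "r", encoding="utf-8-sig") as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def _p(key, default=None):
            if key not in raw or raw[key] is None:
                return default
            return (base / str(raw[key])).resolve()

        missing = [k for k in ("recordings", "cohort", "ratings") if not raw.get(k)]
        if missing:
            raise ValidationError([f"config lacks required key {k!r}" for k in missing])
        return cls(
            recordings=_p("recordings"),
            cohort=_p("cohort"),
            ratings=_p("ratings"),
            out_dir=_p("out_dir", base / "out"),
            model_spec=_p("model_spec"),
            mediator_basis=str(raw.get("mediator_basis", "f0")),
            permutations=int(raw.get("permutations", 1000)),
            permutation_scheme=str(raw.get("permutation_scheme", "columns")),
            alpha=float(raw.get("alpha", 0.05)),
            seed=int(raw.get("seed", 1)),
        )


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError([f"input file not found: {path}"])
    df = pd.read_csv(path, encoding="utf-8-sig")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError([f"{path.name}: missing columns {missing}"])
    return df


def read_recordings(path) -> pd.DataFrame:
    """Validated per-recording measurements (``recordings.csv`` schema)."""
    cols = [
        "recording_id", "person_id", "display", "item",
        "mean_f0_hz", "min_f0_hz", "max_f0_hz", "f1_hz", "f2_hz", "f3_hz", "f4_hz",
    ]
    df = _read_csv(path, cols)
    errors = []
    dup = df["recording_id"][df["recording_id"].duplicated()]
    if len(dup):
        errors.append(f"duplicate recording ids: {sorted(set(dup))}")
    freq_cols = cols[4:]
    for row in df.itertuples():
        line = row.Index + 2  # header + 1-based
        vals = [getattr(row, c) for c in freq_cols]
        if row.display not in ("speech", "singing"):
            errors.append(f"row {line}: bad display {row.display!r}")
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            errors.append(f"row {line}: non-positive or missing frequency")
            continue
        if not (row.min_f0_hz <= row.mean_f0_hz <= row.max_f0_hz):
            errors.append(f"row {line}: F0 summary violates min <= mean <= max")
        fm = [row.f1_hz, row.f2_hz, row.f3_hz, row.f4_hz]
        if any(b <= a for a, b in zip(fm, fm[1:])):
            errors.append(f"row {line}: formants not strictly increasing")
    if errors:
        raise ValidationError(errors)
    return df


def read_cohort(path) -> pd.DataFrame:
    """Validated per-participant covariates (``cohort.csv`` schema)."""
    df = _read_csv(path, ["person_id", "sex", "country"])
    errors = []
    dup = df["person_id"][df["person_id"].duplicated()]
    if len(dup):
        errors.append(f"duplicate person ids: {sorted(set(dup))}")
    bad_sex = sorted(set(df["sex"]) - {"M", "F"})
    if bad_sex:
        errors.append(f"unknown sex codes: {bad_sex}")
    if errors:
        raise ValidationError(errors)
    return df


def read_ratings(path) -> pd.DataFrame:
    """Validated long-format ratings (``ratings.csv`` schema)."""
    df = _read_csv(path, ["rater_id", "rater_country", "target_id", "display", "score"])
    errors = []
    for row in df.itertuples():
        line = row.Index + 2
        if row.display not in ("speech", "singing"):
            errors.append(f"row {line}: bad display {row.display!r}")
        s = row.score
        if not np.isfinite(s) or s != int(s) or not 1 <= s <= 7:
            errors.append(f"row {line}: score {s!r} outside the 1..7 integer scale")
    dup = df.duplicated(subset=["rater_id", "target_id", "display"])
    if dup.any():
        errors.append(f"duplicate rater/target/display rows at lines {sorted(df.index[dup] + 2)}")
    if errors:
        raise ValidationError(errors)
    return df


def read_tables(config: PipelineConfig):
    """All three validated input tables."""
    return read_recordings(config.recordings), read_cohort(config.cohort), read_ratings(config.ratings)


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def assemble_analysis_table(
    cohort: pd.DataFrame, profiles: pd.DataFrame, attract: pd.DataFrame
) -> pd.DataFrame:
    """Merge covariates, recording-derived profiles and aggregated
    attractiveness into the person-level analysis table, adding the
    sex-appropriate body ``ratio`` (WSR for men, WHR for women)."""
    wide = profiles.pivot(index="person_id", columns="display")
    wide.columns = [
        {
            ("mean_f0_st", "speech"): "speech_f0_st",
            ("mean_f0_st", "singing"): "singing_f0_st",
            ("f0_range_st", "speech"): "speech_range_st",
            ("f0_range_st", "singing"): "singing_range_st",
            ("vtl_cm", "speech"): "speech_vtl_cm",
            ("vtl_cm", "singing"): "singing_vtl_cm",
        }.get((a, b), f"{b}_{a}")
        for a, b in wide.columns
    ]
    keep = [c for c in wide.columns if not c.endswith(("delta_f_hz", "n_recordings"))]
    att = attract.pivot(index="target_id", columns="display", values="mean_rating")
    att = att.rename(columns={"speech": "attract_speech", "singing": "attract_singing"})
    att.index.name = "person_id"
    base_cols = [
        c for c in cohort.columns
        if c in ("person_id", "sex", "country", "age", "height_cm", "weight_kg",
                 "wsr", "whr", "soi_total", "liking_to_sing")
    ]
    table = (
        cohort[base_cols]
        .merge(wide[keep], on="person_id", how="inner")
        .merge(att, on="person_id", how="left")
    )
    if "wsr" in table.columns and "whr" in table.columns:
        table["ratio"] = np.where(table["sex"] == "M", table["wsr"], table["whr"])
    return table


_DISPLAY_PAIRS = [
    ("f0", "speech_f0_st", "singing_f0_st"),
    ("range", "speech_range_st", "singing_range_st"),
    ("vtl", "speech_vtl_cm", "singing_vtl_cm"),
    ("attractiveness", "attract_speech", "attract_singing"),
]

_GLM_DVS = [
    "speech_f0_st", "singing_f0_st", "speech_range_st",
    "singing_range_st", "speech_vtl_cm", "singing_vtl_cm",
]


def _stats_report(table: pd.DataFrame) -> pd.DataFrame:
    rows = []

    def add(analysis, statistic, value, df=None, p=None, effect=None, n=None):
        rows.append(
            {"analysis": analysis, "statistic": statistic, "value": value,
             "df": df, "p": p, "effect_size": effect, "n": n}
        )

    for dv in _GLM_DVS:
        res = vstats.two_way_anova_partial_eta(table, dv)
        for term, t in res.terms.items():
            add(f"glm:{dv}", f"F[{term}]", t.F, f"{t.df[0]:g},{t.df[1]:g}", t.p,
                t.partial_eta_sq, res.n)

    for sex, grp in table.groupby("sex"):
        for name, a, b in _DISPLAY_PAIRS:
            sub = grp[[a, b]].dropna()
            if len(sub) >= 4:
                r = vstats.pearson_with_ci(sub[a], sub[b])
                add(f"pearson:{name}:{sex}", "r", r.estimate, r.n - 2, r.p, None, r.n)
        sub = grp[["attract_speech", "attract_singing"]].dropna()
        if len(sub) >= 2:
            t, dof, p = vstats.paired_t_test(sub["attract_speech"], sub["attract_singing"])
            add(f"paired_t:attractiveness:{sex}", "t", t, dof, p, None, len(sub))
        for disp in ("speech", "singing"):
            sub = grp[[f"attract_{disp}", "liking_to_sing"]].dropna()
            if len(sub) >= 3:
                tau = vstats.kendall_tau_b(sub["liking_to_sing"], sub[f"attract_{disp}"])
                add(f"kendall:liking~attract_{disp}:{sex}", "tau_b", tau.estimate,
                    None, tau.p, None, tau.n)
        mod = pd.DataFrame(
            {
                "abs_df0": (grp["singing_f0_st"] - grp["speech_f0_st"]).abs(),
                "abs_drange": (grp["singing_range_st"] - grp["speech_range_st"]).abs(),
                "abs_dvtl": (grp["singing_vtl_cm"] - grp["speech_vtl_cm"]).abs(),
                "attract_speech": grp["attract_speech"],
                "attract_singing": grp["attract_singing"],
            }
        )
        for idxname in ("abs_df0", "abs_drange", "abs_dvtl"):
            for disp in ("speech", "singing"):
                sub = mod[[idxname, f"attract_{disp}"]].dropna()
                if len(sub) >= 4:
                    r = vstats.pearson_with_ci(sub[idxname], sub[f"attract_{disp}"])
                    add(f"pearson:{idxname}~attract_{disp}:{sex}", "r", r.estimate,
                        r.n - 2, r.p, None, r.n)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the full result bundle to ``out_dir``.

    Writes profiles.csv, attractiveness.csv, reliability.csv, stats.csv,
    pathfit.json, invariance.json and manifest.json; removes partial outputs
    if any stage fails. Deterministic given inputs and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_df(df, name):
        p = out / name
        write_csv(df, p)
        written.append(p)

    def _write_json(obj, name):
        p = out / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        written.append(p)

    stage = "read-inputs"
    try:
        recordings, cohort, ratings = read_tables(config)

        stage = "acoustics"
        log.info("stage %s", stage)
        profiles = profiles_from_recordings(recordings)
        _write_df(profiles, "profiles.csv")

        stage = "ratings"
        log.info("stage %s", stage)
        attract, reliability = summarize_ratings(ratings)
        _write_df(attract, "attractiveness.csv")
        _write_df(reliability, "reliability.csv")

        stage = "assemble"
        table = assemble_analysis_table(cohort, profiles, attract)

        stage = "stats"
        log.info("stage %s", stage)
        _write_df(_stats_report(table), "stats.csv")

        stage = "path-model"
        log.info("stage %s (B = %d)", stage, config.permutations)
        spec = build_path_spec(config.mediator_basis)
        pathfit = {}
        for sex, grp in table.groupby("sex"):
            fit = fit_path_model(grp, spec)
            perm = permutation_pvalues(
                grp, spec, B=config.permutations,
                seed=config.seed, scheme=config.permutation_scheme,
            )
            stable = jackknife_stability(grp, spec, alpha=config.alpha)
            pathfit[sex] = {
                "n": fit.n,
                "chi_square": fit.chi_square,
                "df": fit.df,
                "parameters": {
                    name: {
                        "estimate": fit.estimates[name],
                        "permutation_p": perm[name],
                        "analytic_p": fit.analytic_p[name],
                        "stable": stable[name],
                    }
                    for name in fit.param_names
                },
            }
        _write_json(pathfit, "pathfit.json")

        stage = "invariance"
        log.info("stage %s", stage)
        invariance = {"by_sex": _inv_to_dict(invariance_test(table, "sex", spec))}
        for sex, grp in table.groupby("sex"):
            invariance[f"by_country_{sex}"] = _inv_to_dict(invariance_test(grp, "country", spec))
        _write_json(invariance, "invariance.json")

        stage = "manifest"
        cfg = {k: str(v) for k, v in asdict(config).items()}
        manifest = {
            "voxpath_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "n_regressions": len(spec.regressions),
            "n_covariances": len(spec.covariances),
            "invariance_df": len(spec.regressions) + len(spec.covariances),
            "n_participants": int(len(table)),
            "n_recordings": int(len(recordings)),
            "n_ratings": int(len(ratings)),
        }
        _write_json(manifest, "manifest.json")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        log.error("pipeline failed at stage %r", stage)
        raise
    return {"out_dir": str(out), "manifest": manifest, "pathfit": pathfit, "invariance": invariance}


def _inv_to_dict(res) -> dict:
    return {
        "chi2_configural": res.chi2_configural,
        "chi2_invariant": res.chi2_invariant,
        "chi2_diff": res.chi2_diff,
        "df_diff": res.df_diff,
        "p": res.p,
        "n_per_group": res.n_per_group,
    }
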