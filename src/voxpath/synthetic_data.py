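"""Synthetic cohorts and rating matrices with the statistical structure the
analyses assume, calibrated to published group summaries.

All randomness flows from one master seed through named substreams
(:func:`substream`), so any stage is reproducible in isolation.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .acoustics import SPEED_OF_SOUND_CM_S
from .ratings import RatingMatrix

__all__ = [
    "MVN_VARS",
    "GroupCalibration",
    "CohortCalibration",
    "RatingCalibration",
    "substream",
    "default_calibration",
    "load_calibration",
    "generate_group",
    "generate_cohort",
    "generate_rating_matrix",
    "rating_correlation_attenuation",
    "synthesize_recordings",
    "simulate_study",
]

log = logging.getLogger(__name__)

#: variables drawn jointly from the per-group multivariate normal
MVN_VARS = (
    "age",
    "height_cm",
    "weight_kg",
    "ratio",
    "speech_f0_st",
    "singing_f0_st",
    "speech_range_st",
    "singing_range_st",
    "speech_vtl_cm",
    "singing_vtl_cm",
)

_CROSS_PAIRS = {
    "f0": ("speech_f0_st", "singing_f0_st"),
    "range": ("speech_range_st", "singing_range_st"),
    "vtl": ("speech_vtl_cm", "singing_vtl_cm"),
}

_SCALAR_VARS = MVN_VARS + ("attract_speech", "attract_singing", "soi_total", "liking_to_sing")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named child stream of a master seed."""
    return np.random.default_rng([int(seed) & 0xFFFFFFFF, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class GroupCalibration:
    sex: str
    country: str
    n: int
    means: Mapping[str, float]
    sds: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got {self.n}")
        for v in _SCALAR_VARS:
            if v not in self.means or v not in self.sds:
                raise ValueError(f"group {self.sex}/{self.country} lacks calibration for {v!r}")
            if self.sds[v] <= 0:
                raise ValueError(f"SD of {v!r} must be > 0, got {self.sds[v]}")


@dataclass(frozen=True)
class CohortCalibration:
    groups: tuple[GroupCalibration, ...]
    cross_display: Mapping[str, Mapping[str, float]]  # sex -> {f0, range, vtl, attractiveness}
    extra_correlations: Mapping[str, float]
    structural: Mapping[str, Mapping[str, Mapping[str, float]]]
    liking_corr: float = 0.3
    seed: int = 0

    def group(self, sex: str, country: str) -> GroupCalibration:
        for g in self.groups:
            if g.sex == sex and g.country == country:
                return g
        raise KeyError(f"no calibration group for sex={sex!r}, country={country!r}")

    def with_cross_display(self, sex: str, **targets: float) -> "CohortCalibration":
        """Copy with some cross-display targets of one sex replaced."""
        cd = {s: dict(v) for s, v in self.cross_display.items()}
        cd[sex].update(targets)
        return CohortCalibration(
            groups=self.groups,
            cross_display=cd,
            extra_correlations=self.extra_correlations,
            structural=self.structural,
            liking_corr=self.liking_corr,
            seed=self.seed,
        )


def _parse_calibration(raw: Mapping) -> CohortCalibration:
    groups = tuple(
        GroupCalibration(
            sex=str(g["sex"]),
            country=str(g["country"]),
            n=int(g["n"]),
            means=dict(g["means"]),
            sds=dict(g["sds"]),
        )
        for g in raw["groups"]
    )
    return CohortCalibration(
        groups=groups,
        cross_display={s: dict(v) for s, v in raw["cross_display"].items()},
        extra_correlations=dict(raw.get("extra_correlations", {})),
        structural={s: {k: dict(v) for k, v in eqs.items()} for s, eqs in raw["structural"].items()},
        liking_corr=float(raw.get("liking", {}).get("corr_attract_singing", 0.3)),
        seed=int(raw.get("seed", 0)),
    )


def load_calibration(path) -> CohortCalibration:
    with open(path, "r", encoding="utf-8") as fh:
        return _parse_calibration(yaml.safe_load(fh))


def default_calibration() -> CohortCalibration:
    """Calibration shipped with the package (published group summaries)."""
    text = resources.files("voxpath.data").joinpath("default_calibration.yaml").read_text("utf-8")
    return _parse_calibration(yaml.safe_load(text))


def _nearest_pd_correlation(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped nearest positive-definite repair, diagonal kept at 1."""
    vals, vecs = np.linalg.eigh(C)
    if vals.min() < -0.05:
        raise ValueError(
            f"correlation targets are unrepairable: smallest eigenvalue {vals.min():.4f}"
        )
    if vals.min() >= floor:
        return C
    log.info("repairing correlation matrix: min eigenvalue %.3g clipped to %.0e", vals.min(), floor)
    fixed = (vecs * np.maximum(vals, floor)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _group_correlation(calib: CohortCalibration, sex: str) -> np.ndarray:
    pos = {v: i for i, v in enumerate(MVN_VARS)}
    C = np.eye(len(MVN_VARS))

    def put(a: str, b: str, r: float) -> None:
        C[pos[a], pos[b]] = C[pos[b], pos[a]] = float(r)

    cd = calib.cross_display[sex]
    for key, (a, b) in _CROSS_PAIRS.items():
        put(a, b, cd[key])
    for pair, r in calib.extra_correlations.items():
        a, b = pair.split(":")
        put(a, b, r)
    return _nearest_pd_correlation(C)


def _structural_vector(coefs: Mapping[str, float], var_order: tuple[str, ...]) -> np.ndarray:
    vec = np.zeros(len(var_order))
    pos = {v: i for i, v in enumerate(var_order)}
    for v, c in coefs.items():
        if v not in pos:
            raise ValueError(f"structural coefficient refers to unknown variable {v!r}")
        vec[pos[v]] = float(c)
    return vec


def generate_group(
    calib: CohortCalibration, sex: str, country: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw one sex x country group of size ``n``."""
    g = calib.group(sex, country)
    R = _group_correlation(calib, sex)
    means = np.array([g.means[v] for v in MVN_VARS])
    sds = np.array([g.sds[v] for v in MVN_VARS])
    Z = rng.multivariate_normal(np.zeros(len(MVN_VARS)), R, size=n, method="cholesky")
    X = means + Z * sds

    struct = calib.structural[sex]
    b_s = _structural_vector(struct.get("attract_speech", {}), MVN_VARS)
    b_g = _structural_vector(struct.get("attract_singing", {}), MVN_VARS)
    v_s = float(b_s @ R @ b_s)
    v_g = float(b_g @ R @ b_g)
    if v_s >= 1 or v_g >= 1:
        raise ValueError("attractiveness equations explain >= 100% variance; rescale coefficients")
    rho = float(calib.cross_display[sex]["attractiveness"])
    cov_e = rho - float(b_s @ R @ b_g)
    bound = np.sqrt((1 - v_s) * (1 - v_g))
    if abs(cov_e) > bound:
        raise ValueError(
            f"attractiveness target correlation {rho} infeasible given structural parts "
            f"(residual covariance {cov_e:.3f} exceeds bound {bound:.3f})"
        )
    res_cov = np.array([[1 - v_s, cov_e], [cov_e, 1 - v_g]])
    E = rng.multivariate_normal(np.zeros(2), res_cov, size=n, method="cholesky")
    z_attr_s = Z @ b_s + E[:, 0]
    z_attr_g = Z @ b_g + E[:, 1]

    # extended correlation matrix over MVN vars + the two attractiveness scores
    k = len(MVN_VARS)
    Rext = np.eye(k + 2)
    Rext[:k, :k] = R
    Rext[:k, k] = Rext[k, :k] = R @ b_s
    Rext[:k, k + 1] = Rext[k + 1, :k] = R @ b_g
    Rext[k, k + 1] = Rext[k + 1, k] = rho
    ext_order = MVN_VARS + ("attract_speech", "attract_singing")
    g_soi = _structural_vector(struct.get("soi_total", {}), ext_order)
    v_soi = float(g_soi @ Rext @ g_soi)
    if v_soi >= 1:
        raise ValueError("sociosexuality equation explains >= 100% variance; rescale coefficients")
    W = np.column_stack([Z, z_attr_s, z_attr_g])
    z_soi = W @ g_soi + rng.normal(0.0, np.sqrt(1 - v_soi), size=n)

    c = calib.liking_corr
    z_lik = c * z_attr_g + np.sqrt(1 - c * c) * rng.normal(size=n)

    out = pd.DataFrame(X, columns=list(MVN_VARS))
    out.insert(0, "person_id", [f"{sex}{country}{i + 1:03d}" for i in range(n)])
    out.insert(1, "sex", sex)
    out.insert(2, "country", country)
    out["wsr"] = out["ratio"] if sex == "M" else np.nan
    out["whr"] = out["ratio"] if sex == "F" else np.nan
    out["attract_speech"] = g.means["attract_speech"] + g.sds["attract_speech"] * z_attr_s
    out["attract_singing"] = g.means["attract_singing"] + g.sds["attract_singing"] * z_attr_g
    out["soi_total"] = g.means["soi_total"] + g.sds["soi_total"] * z_soi
    lik = g.means["liking_to_sing"] + g.sds["liking_to_sing"] * z_lik
    out["liking_to_sing"] = np.clip(np.round(lik), 1, 10).astype(int)
    return out


def generate_sex_cohort(calib: CohortCalibration, sex: str, n: int, seed: int) -> pd.DataFrame:
    """Single-sex cohort of total size ``n``, countries in the calibration's
    published proportions (at least one participant per country)."""
    groups = [g for g in calib.groups if g.sex == sex]
    if not groups:
        raise KeyError(f"no calibration groups for sex {sex!r}")
    total = sum(g.n for g in groups)
    sizes = [max(int(round(n * g.n / total)), 1) for g in groups]
    sizes[-1] += n - sum(sizes)
    frames = [
        generate_group(calib, g.sex, g.country, k, substream(seed, f"cohort/{g.sex}/{g.country}"))
        for g, k in zip(groups, sizes)
        if k > 0
    ]
    return pd.concat(frames, ignore_index=True)


def generate_cohort(calib: CohortCalibration, seed: int) -> pd.DataFrame:
    """Full two-country, two-sex cohort at the calibration's group sizes."""
    frames = [
        generate_group(calib, g.sex, g.country, g.n, substream(seed, f"cohort/{g.sex}/{g.country}"))
        for g in calib.groups
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# rating matrices


@dataclass
class RatingCalibration:
    """Noise calibration for synthetic rating panels.

    The idiosyncratic noise SD is solved numerically (bisection against
    simulated panels) so the expected Cronbach's alpha of a panel with
    ``k_reference`` raters matches ``target_alpha``.
    """

    n_raters_br: int = 46
    n_raters_cz: int = 46
    target_alpha: float = 0.79
    rater_sd: float = 0.5
    center: float = 4.0
    slope: float = 1.0
    scale: tuple[int, int] = (1, 7)
    _noise_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if min(self.n_raters_br, self.n_raters_cz) < 0 or self.n_raters < 2:
            raise ValueError("need at least 2 raters in total")
        if not 0 < self.target_alpha < 1:
            raise ValueError("target_alpha must be in (0, 1)")

    @property
    def n_raters(self) -> int:
        return self.n_raters_br + self.n_raters_cz

    @property
    def k_reference(self) -> int:
        ks = [k for k in (self.n_raters_br, self.n_raters_cz) if k >= 2]
        return min(ks) if ks else self.n_raters

    def _simulate_alpha(
        self, noise_sd: float, k: int, n_targets: int, rng: np.random.Generator, reps: int
    ) -> float:
        lo, hi = self.scale
        alphas = []
        for _ in range(reps):
            z = rng.normal(size=n_targets)
            scores = (
                self.center
                + self.slope * z
                + rng.normal(0.0, self.rater_sd, size=(k, 1))
                + rng.normal(0.0, noise_sd, size=(k, n_targets))
            )
            scores = np.clip(np.round(scores), lo, hi)
            item_var = scores.var(axis=1, ddof=1).sum()
            tot_var = scores.sum(axis=0).var(ddof=1)
            if tot_var <= 0:
                continue
            alphas.append(k / (k - 1) * (1 - item_var / tot_var))
        if not alphas:
            raise ValueError("degenerate rating simulation (zero total variance)")
        return float(np.mean(alphas))

    def solve_noise_sd(self, n_targets: int, seed: int = 0, reps: int = 40) -> float:
        """Bisection for the noise SD hitting ``target_alpha`` at the
        reference panel size."""
        key = (self.k_reference, n_targets)
        if key in self._noise_cache:
            return self._noise_cache[key]
        k = self.k_reference
        rng = substream(seed, f"rating-calibration/{k}/{n_targets}")
        lo, hi = 1e-3, 25.0
        a_lo = self._simulate_alpha(lo, k, n_targets, rng, reps)
        a_hi = self._simulate_alpha(hi, k, n_targets, rng, reps)
        if not (a_hi < self.target_alpha < a_lo):
            raise ValueError(
                f"target alpha {self.target_alpha} infeasible for {k} raters "
                f"(achievable range ~[{a_hi:.3f}, {a_lo:.3f}])"
            )
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if self._simulate_alpha(mid, k, n_targets, rng, reps) > self.target_alpha:
                lo = mid
            else:
                hi = mid
        sd = 0.5 * (lo + hi)
        self._noise_cache[key] = sd
        return sd


def generate_rating_matrix(
    true_scores: pd.Series,
    calib: RatingCalibration,
    seed: int,
    display: str | None = None,
) -> RatingMatrix:
    """Rating = clip-and-round(scale-mapped true z-score + rater effect + noise).

    ``true_scores`` is indexed by target id; targets must have nonzero
    variance. The same solved noise level applies to all raters; raters are
    labelled by country (BR block first).
    """
    if len(true_scores) < 2:
        raise ValueError("need >= 2 targets")
    vals = np.asarray(true_scores, dtype=float)
    if vals.std(ddof=1) == 0:
        raise ValueError("true scores have zero variance")
    z = (vals - vals.mean()) / vals.std(ddof=1)
    noise_sd = calib.solve_noise_sd(len(z), seed=calib_seed_base(seed))
    rng = substream(seed, f"ratings/{display or 'block'}")
    k = calib.n_raters
    lo, hi = calib.scale
    scores = (
        calib.center
        + calib.slope * z
        + rng.normal(0.0, calib.rater_sd, size=(k, 1))
        + rng.normal(0.0, noise_sd, size=(k, len(z)))
    )
    scores = np.clip(np.round(scores), lo, hi).astype(int)
    countries = ("BR",) * calib.n_raters_br + ("CZ",) * calib.n_raters_cz
    rater_ids = tuple(f"R-{c}-{i + 1:03d}" for i, c in enumerate(countries))
    return RatingMatrix(
        rater_ids=rater_ids,
        target_ids=tuple(str(t) for t in true_scores.index),
        scores=scores,
        rater_country=countries,
        display=display,
    )


def calib_seed_base(seed: int) -> int:
    """Stable sub-seed for noise calibration, independent of the draw seed."""
    return (int(seed) % 997) + 12_345


def rating_correlation_attenuation(
    calib: RatingCalibration,
    n_targets: int,
    rho_probe: float = 0.8,
    reps: int = 40,
    seed: int = 0,
) -> float:
    """Empirical shrinkage factor of a cross-display correlation after the
    rating stage: mean corr(mean ratings) / rho of the underlying truths."""
    rng = substream(seed, "attenuation")
    cov = np.array([[1.0, rho_probe], [rho_probe, 1.0]])
    ratios = []
    for i in range(reps):
        t = rng.multivariate_normal(np.zeros(2), cov, size=n_targets, method="cholesky")
        ms = []
        for d in range(2):
            m = generate_rating_matrix(
                pd.Series(t[:, d], index=[f"t{j}" for j in range(n_targets)]),
                calib,
                seed=int(rng.integers(2**31)),
                display=f"probe{d}",
            )
            ms.append(m.scores.mean(axis=0))
        ratios.append(np.corrcoef(ms[0], ms[1])[0, 1] / rho_probe)
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# calibrated-recovery checks


def replicate_cross_display_correlation(
    calib: CohortCalibration,
    sex: str,
    n: int,
    pair: str,
    reps: int = 200,
    seed: int = 0,
) -> float:
    """Mean Pearson correlation between the speech and singing columns of a
    ``pair`` ('f0', 'range', 'vtl' or 'attractiveness') over ``reps``
    freshly generated single-sex cohorts of size ``n``."""
    if pair == "attractiveness":
        a, b = "attract_speech", "attract_singing"
    else:
        a, b = _CROSS_PAIRS[pair]
    rs = []
    for i in range(reps):
        c = generate_sex_cohort(calib, sex, n, seed=substream(seed, f"rep{i}").integers(2**31))
        rs.append(float(np.corrcoef(c[a], c[b])[0, 1]))
    return float(np.mean(rs))


def replicate_rated_attract_correlation(
    calib: CohortCalibration,
    rating_calib: RatingCalibration,
    sex: str,
    n: int,
    reps: int = 200,
    seed: int = 0,
) -> float:
    """Mean correlation between freshly aggregated speech and singing mean
    ratings over ``reps`` simulated cohorts.

    The rating stage attenuates the latent cross-display correlation, so the
    generator deattenuates first: the shrinkage factor is measured from the
    rating generator itself (seeded) and the latent target is divided by it
    before cohorts are drawn. The returned value is always computed from
    aggregated ratings, never read off the calibration.
    """
    target = float(calib.cross_display[sex]["attractiveness"])
    factor = rating_correlation_attenuation(rating_calib, n, seed=seed)
    boosted = calib.with_cross_display(sex, attractiveness=min(target / factor, 0.99))
    rs = []
    master = substream(seed, "rated-attract")
    for i in range(reps):
        c = generate_sex_cohort(boosted, sex, n, seed=int(master.integers(2**31)))
        means = []
        for disp, col in (("speech", "attract_speech"), ("singing", "attract_singing")):
            truths = pd.Series(c[col].to_numpy(), index=c["person_id"].to_numpy())
            m = generate_rating_matrix(
                truths, rating_calib, seed=int(master.integers(2**31)), display=disp
            )
            means.append(m.scores.mean(axis=0))
        rs.append(float(np.corrcoef(means[0], means[1])[0, 1]))
    return float(np.mean(rs))


# ---------------------------------------------------------------------------
# back-synthesized recordings and the full simulated study


_ITEMS = {"speech": ("self-presentation", "anthem"), "singing": ("birthday-song", "anthem")}


def synthesize_recordings(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Per-recording raw measurements consistent with each person's profile.

    Formants follow the uniform-tube pattern of the person's VTL with small
    jitter; per-recording F0 summaries scatter around the person's semitone
    mean and range.
    """
    rng = substream(seed, "recordings")
    rows = []
    for person in cohort.itertuples():
        for display in ("speech", "singing"):
            f0_st = getattr(person, f"{display}_f0_st")
            rng_st = max(getattr(person, f"{display}_range_st"), 1.0)
            vtl = getattr(person, f"{display}_vtl_cm")
            delta_f = SPEED_OF_SOUND_CM_S / (2.0 * vtl)
            for j, item in enumerate(_ITEMS[display]):
                st = f0_st + rng.normal(0.0, 0.5)
                mean_hz = 440.0 * 2.0 ** (st / 12.0)
                half = max(rng_st + rng.normal(0.0, 1.0), 0.5) / 2.0
                min_hz = mean_hz * 2.0 ** (-half / 12.0)
                max_hz = mean_hz * 2.0 ** (half / 12.0)
                df_rec = delta_f + rng.normal(0.0, 10.0)
                formants = (np.arange(1, 5) - 0.5) * df_rec + rng.normal(0.0, 8.0, size=4)
                formants = np.sort(formants)
                rows.append(
                    {
                        "recording_id": f"{person.person_id}-{display[:2]}{j + 1}",
                        "person_id": person.person_id,
                        "display": display,
                        "item": item,
                        "mean_f0_hz": mean_hz,
                        "min_f0_hz": min_hz,
                        "max_f0_hz": max_hz,
                        "f1_hz": formants[0],
                        "f2_hz": formants[1],
                        "f3_hz": formants[2],
                        "f4_hz": formants[3],
                    }
                )
    return pd.DataFrame(rows)


def simulate_study(
    calib: CohortCalibration,
    seed: int,
    rating_calib_male_targets: RatingCalibration | None = None,
    rating_calib_female_targets: RatingCalibration | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (cohort, recordings, long-format ratings) for a full study.

    Male targets are rated by the female panels and vice versa; each panel
    rates all targets of its assigned sex in both displays.
    """
    rc_m = rating_calib_male_targets or RatingCalibration(n_raters_br=59, n_raters_cz=47)
    rc_f = rating_calib_female_targets or RatingCalibration(n_raters_br=51, n_raters_cz=46)
    cohort = generate_cohort(calib, seed)
    recordings = synthesize_recordings(cohort, seed)
    rating_rows = []
    for sex, rc in (("M", rc_m), ("F", rc_f)):
        targets = cohort.loc[cohort["sex"] == sex]
        for display in ("speech", "singing"):
            truths = pd.Series(
                targets[f"attract_{'speech' if display == 'speech' else 'singing'}"].to_numpy(),
                index=targets["person_id"].to_numpy(),
            )
            matrix = generate_rating_matrix(
                truths, rc, seed=seed + (0 if sex == "M" else 1), display=display
            )
            for i, rater in enumerate(matrix.rater_ids):
                for j, target in enumerate(matrix.target_ids):
                    rating_rows.append(
                        {
                            "rater_id": f"{sex}t-{rater}",
                            "rater_country": matrix.rater_country[i],
                            "target_id": target,
                            "display": display,
                            "score": int(matrix.scores[i, j]),
                        }
                    )
    return cohort, recordings, pd.DataFrame(rating_rows)
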