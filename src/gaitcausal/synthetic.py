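"""Synthetic cohort generator with known causal ground truth.

Samples children from a structural equation model laid over the study DAG:
exogenous age, sex and a latent brain-injury severity propagate through
impairment scores (spasticity, strength, selective and dynamic motor
control), walking speed, gait deviation index (GDI) and net metabolic
power, in topological order.  Default links and coefficients are calibrated
once to the published cohort's marginals (median GDI 71.1, net power
124.2 W, speed 0.79 m/s, ...) and frozen; GDI is sigmoidal in the
impairments (plateaus at the extremes) and power carries an inverted-U
strength term plus mass- and speed-dependent terms.  Ordinal exam items are
produced by thresholding noisy copies of each domain's latent severity, and
missingness masks at the published rates are applied last.

Because the structural equations are known, any do-intervention can be
evaluated by Monte Carlo: regenerate the exogenous draws, pin one factor,
let everything downstream of it respond, and average the power contrast.
That is the ground truth against which the full estimation pipeline
(BART + accumulated local effects) is validated.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "true_total_effect",
    "true_effect_curve",
    "true_effect_range",
    "dataset_summary",
    "DEFAULT_LINKS",
    "ANCHORS",
]

#: Location/scale anchors used to standardize variables inside the links.
ANCHORS = {
    "Age": (9.3, 3.7),
    "Height": (129.5, 20.3),
    "Mass": (26.9, 15.8),
    "Speed": (0.79, 0.25),
    "GDI": (71.1, 12.5),
    "DMC": (83.3, 9.9),
    "SMC": (0.25, 1.1),
    "Spasticity": (-0.25, 1.1),
    "Strength": (0.16, 1.1),
}

#: Structural coefficients and link shapes, calibrated once to the cohort
#: marginals and frozen.  ``link`` may be "linear" or "sigmoid" where noted;
#: the strength->power term is an inverted-U (Gaussian bump).
DEFAULT_LINKS: dict = {
    "height": {"intercept": 80.0, "age": 5.3, "sex": 3.0, "sd": 6.0},
    "mass": {"coef": 2.0e-5, "exponent": 2.9, "log_sd": 0.22},
    # impairment scores: intercept + injury*B + small size terms + noise
    "spasticity": {"intercept": -0.25, "injury": 0.85, "age": -0.10, "height": 0.05, "mass": 0.0, "sd": 0.55},
    "strength": {"intercept": 0.16, "injury": -0.80, "age": 0.20, "height": 0.05, "mass": 0.0, "sd": 0.55},
    "smc": {"intercept": 0.25, "injury": -0.85, "age": 0.10, "height": 0.0, "mass": 0.0, "sd": 0.55},
    "dmc": {"intercept": 83.3, "injury": -7.5, "age": 1.0, "height": 0.0, "mass": 0.0, "sd": 5.0},
    # walking speed, m/s (coefficients on centred/standardized inputs)
    "speed": {
        "intercept": 0.79, "strength": 0.06, "smc": 0.08, "dmc": 0.05,
        "spasticity": -0.06, "age": 0.02, "height": 0.05, "mass": -0.03,
        "sd": 0.12, "floor": 0.05,
    },
    # GDI = intercept + amp * link(gain * u) + noise, u = weighted impairments + speed
    "gdi": {
        "intercept": 71.1, "amp": 14.0, "gain": 0.8, "link": "sigmoid",
        "smc": 0.5, "dmc": 0.45, "strength": 0.15, "spasticity": -0.40,
        "speed": 0.3, "age": 0.0, "height": 0.0, "mass": 0.0, "sd": 6.0,
    },
    # net power, W
    "power": {
        # intercept sits below the target median: the inverted-U strength
        # bump and the quadratic mass term contribute ~+14 W on average
        "intercept": 111.0, "mass": 3.2, "mass2": 0.015, "speed": 70.0,
        "age": 0.5, "height": 0.0,
        "gdi_amp": -31.0, "gdi_gain": 1.0, "gdi_link": "sigmoid",
        "smc_amp": -14.0, "smc_gain": 0.8, "smc_link": "sigmoid",
        "dmc_amp": -9.0, "dmc_gain": 0.9, "dmc_link": "sigmoid",
        "spasticity_amp": 8.5, "spasticity_gain": 0.7, "spasticity_link": "sigmoid",
        "strength_amp": 10.0, "strength_center": 0.3, "strength_width": 1.5,
        "sd": 18.0, "floor": 5.0,
    },
}

#: Published missingness rates per cohort column.
DEFAULT_MISSING_RATES = {
    "DMC": 0.321,
    "Spasticity": 0.183,
    "Strength": 0.177,
    "SMC": 0.175,
    "GDI": 0.006,
}

# GMFCS terciles of the latent injury severity at the published proportions
_GMFCS_CUTS = (stats.norm.ppf(0.307), stats.norm.ppf(0.307 + 0.464))

_EXAM_DOMAINS = {
    # domain: (cohort column, rating offset, thresholds on the item latent)
    "spasticity": ("Spasticity", 1, (-1.2, -0.2, 0.9, 2.0)),
    "strength": ("Strength", 1, (-2.0, -1.1, -0.2, 0.9)),
    "smc": ("SMC", 0, (-0.7, 0.4)),
}
_MUSCLES = (
    "hip_flexors", "hip_adductors", "rectus_femoris",
    "hamstrings", "plantarflexors", "tibialis_posterior",
)

INTERVENABLE = ("GDI", "DMC", "SMC", "Spasticity", "Strength", "Speed")


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the frozen study-like conditions."""

    n: int = 2000
    seed: int = 0
    links: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_LINKS))
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    missing_mechanism: str = "MCAR"  # or "MAR" (DMC missingness tied to GMFCS)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown missingness mechanism {self.missing_mechanism!r}")
        for col, rate in self.missing_rates.items():
            if not (0 <= rate < 1):
                raise ValueError(f"missing rate for {col} outside [0, 1)")
        unknown = set(self.links) - set(DEFAULT_LINKS)
        if unknown:
            raise ValueError(f"unknown link block(s): {sorted(unknown)}")


def _z(name: str, values: np.ndarray) -> np.ndarray:
    mu, sd = ANCHORS[name]
    return (values - mu) / sd


def _shaped(link: str, gain: float, z: np.ndarray) -> np.ndarray:
    if link == "sigmoid":
        return np.tanh(gain * z)
    if link == "linear":
        return gain * z
    raise ValueError(f"invalid link name {link!r}")


def _draw_exogenous(cfg: SyntheticConfig, rng: np.random.Generator, n: int) -> dict:
    age = stats.truncnorm.rvs(
        (2.0 - 9.3) / 3.7, (18.0 - 9.3) / 3.7, loc=9.3, scale=3.7, size=n,
        random_state=rng,
    )
    return {
        "Age": age,
        "Sex": (rng.random(n) < 0.562).astype(float),
        "B": rng.normal(0.0, 1.0, n),
        "e_height": rng.normal(0.0, 1.0, n),
        "e_mass": rng.normal(0.0, 1.0, n),
        "e_spasticity": rng.normal(0.0, 1.0, n),
        "e_strength": rng.normal(0.0, 1.0, n),
        "e_smc": rng.normal(0.0, 1.0, n),
        "e_dmc": rng.normal(0.0, 1.0, n),
        "e_speed": rng.normal(0.0, 1.0, n),
        "e_gdi": rng.normal(0.0, 1.0, n),
        "e_power": rng.normal(0.0, 1.0, n),
    }


def _propagate(links: dict, ex: dict, do: dict | None = None) -> dict:
    """Evaluate the structural equations; ``do`` pins variables by name."""
    do = do or {}

    def pin(name: str, values: np.ndarray) -> np.ndarray:
        if name in do:
            return np.broadcast_to(np.asarray(do[name], dtype=float), values.shape).copy()
        return values

    age, sex, b = ex["Age"], ex["Sex"], ex["B"]
    L = links

    h = L["height"]
    height = h["intercept"] + h["age"] * age + h["sex"] * sex + h["sd"] * ex["e_height"]
    height = np.clip(height, 60.0, 200.0)

    m = L["mass"]
    mass = m["coef"] * height ** m["exponent"] * np.exp(m["log_sd"] * ex["e_mass"])
    mass = np.clip(mass, 5.0, 150.0)

    age_z, height_z, mass_z = _z("Age", age), _z("Height", height), _z("Mass", mass)

    def impairment(key: str) -> np.ndarray:
        c = L[key]
        return (
            c["intercept"] + c["injury"] * b + c["age"] * age_z
            + c["height"] * height_z + c["mass"] * mass_z + c["sd"] * ex[f"e_{key}"]
        )

    spas = pin("Spasticity", impairment("spasticity"))
    strength = pin("Strength", impairment("strength"))
    smc = pin("SMC", impairment("smc"))
    dmc = pin("DMC", impairment("dmc"))

    spas_z, str_z = _z("Spasticity", spas), _z("Strength", strength)
    smc_z, dmc_z = _z("SMC", smc), _z("DMC", dmc)

    s = L["speed"]
    speed = (
        s["intercept"] + s["strength"] * str_z + s["smc"] * smc_z + s["dmc"] * dmc_z
        + s["spasticity"] * spas_z + s["age"] * age_z + s["height"] * height_z
        + s["mass"] * mass_z + s["sd"] * ex["e_speed"]
    )
    speed = pin("Speed", np.clip(speed, s["floor"], None))
    speed_z = _z("Speed", speed)

    g = L["gdi"]
    u = (
        g["smc"] * smc_z + g["dmc"] * dmc_z + g["strength"] * str_z
        + g["spasticity"] * spas_z + g["speed"] * speed_z
        + g["age"] * age_z + g["height"] * height_z + g["mass"] * mass_z
    )
    gdi = g["intercept"] + g["amp"] * _shaped(g["link"], g["gain"], u) + g["sd"] * ex["e_gdi"]
    gdi = pin("GDI", gdi)
    gdi_z = _z("GDI", gdi)

    p = L["power"]
    power = (
        p["intercept"]
        + p["mass"] * (mass - ANCHORS["Mass"][0])
        + p["mass2"] * (mass - ANCHORS["Mass"][0]) ** 2
        + p["speed"] * (speed - ANCHORS["Speed"][0])
        + p["age"] * (age - ANCHORS["Age"][0])
        + p["height"] * (height - ANCHORS["Height"][0])
        + p["gdi_amp"] * _shaped(p["gdi_link"], p["gdi_gain"], gdi_z)
        + p["smc_amp"] * _shaped(p["smc_link"], p["smc_gain"], smc_z)
        + p["dmc_amp"] * _shaped(p["dmc_link"], p["dmc_gain"], dmc_z)
        + p["spasticity_amp"] * _shaped(p["spasticity_link"], p["spasticity_gain"], spas_z)
        + p["strength_amp"] * np.exp(-((str_z - p["strength_center"]) ** 2) / p["strength_width"])
        + p["sd"] * ex["e_power"]
    )
    power = np.clip(power, p["floor"], None)

    out = {
        "Age": age, "Sex": sex, "Height": height, "Mass": mass,
        "Spasticity": spas, "Strength": strength, "SMC": smc, "DMC": dmc,
        "Speed": speed, "GDI": gdi, "MetPower": power, "B": b,
    }
    for name, vals in out.items():
        if not np.isfinite(vals).all():
            raise FloatingPointError(
                f"non-finite values in {name}: check link coefficients"
            )
    return out


@dataclass
class GroundTruth:
    """The structural equations, closed over their configuration.

    Regenerating with the stored seed reproduces the cohort exactly; the
    ``true_*`` helpers evaluate do-interventions by Monte Carlo.
    """

    config: SyntheticConfig

    def simulate(self, n: int, seed: int, do: dict | None = None) -> dict:
        rng = np.random.default_rng(seed)
        ex = _draw_exogenous(self.config, rng, n)
        return _propagate(self.config.links, ex, do)


def true_total_effect(
    truth: GroundTruth, factor: str, from_value: float, to_value: float,
    mc_n: int = 50_000, seed: int = 12345,
) -> float:
    """Mean-power contrast of do(factor=to) vs do(factor=from), in watts.

    Descendants of the factor (speed, GDI, power as applicable) respond to
    the intervention; everything else keeps its sampled value.  Both arms
    share exogenous draws, so the contrast is a paired Monte Carlo estimate.
    """
    if factor not in INTERVENABLE:
        raise KeyError(f"cannot intervene on {factor!r}; one of {INTERVENABLE}")
    rng = np.random.default_rng(seed)
    ex = _draw_exogenous(truth.config, rng, mc_n)
    hi = _propagate(truth.config.links, ex, {factor: to_value})
    lo = _propagate(truth.config.links, ex, {factor: from_value})
    return float(hi["MetPower"].mean() - lo["MetPower"].mean())


def true_effect_curve(
    truth: GroundTruth, factor: str, values, mc_n: int = 50_000, seed: int = 12345,
) -> np.ndarray:
    """E[power | do(factor=v)] for each v, sharing exogenous draws."""
    if factor not in INTERVENABLE:
        raise KeyError(f"cannot intervene on {factor!r}; one of {INTERVENABLE}")
    rng = np.random.default_rng(seed)
    ex = _draw_exogenous(truth.config, rng, mc_n)
    return np.array(
        [
            _propagate(truth.config.links, ex, {factor: float(v)})["MetPower"].mean()
            for v in np.asarray(values, dtype=float)
        ]
    )


def true_effect_range(
    truth: GroundTruth, factor: str, factor_sample, grid_points: int = 41,
    mc_n: int = 50_000, seed: int = 12345,
) -> float:
    """Range of the true do-curve over the factor's middle-95% window."""
    vals = np.asarray(pd.Series(factor_sample).dropna(), dtype=float)
    lo, hi = np.quantile(vals, [0.025, 0.975])
    grid = np.linspace(lo, hi, grid_points)
    curve = true_effect_curve(truth, factor, grid, mc_n=mc_n, seed=seed)
    return float(curve.max() - curve.min())


def _exam_table(rng: np.random.Generator, cohort: pd.DataFrame) -> pd.DataFrame:
    """Ordinal exam items consistent with each child's latent severity."""
    records = []
    child = cohort["child"].to_numpy()
    n = len(cohort)
    for domain, (col, offset, cuts) in _EXAM_DOMAINS.items():
        latent = _z(col, cohort[f"_{col}_complete"].to_numpy())
        for muscle in _MUSCLES:
            for side in ("L", "R"):
                item = 0.8 * latent + 0.6 * rng.normal(0.0, 1.0, n)
                rating = offset + (item[:, None] > np.asarray(cuts)).sum(axis=1)
                records.append(
                    pd.DataFrame(
                        {"child": child, "domain": domain, "muscle": muscle,
                         "side": side, "rating": rating.astype(float)}
                    )
                )
    return pd.concat(records, ignore_index=True)


def generate_cohort(
    config: SyntheticConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Sample a cohort, its item-level exam table, and the ground truth.

    Returns ``(cohort, exams, truth)``.  The cohort has one row per child
    with the usual columns plus GMFCS (severity terciles of the latent
    injury); missingness masks are applied last, and a child whose summary
    score is masked also loses exam items so the two tables agree.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    ex = _draw_exogenous(cfg, rng, cfg.n)
    sim = _propagate(cfg.links, ex, None)

    cohort = pd.DataFrame(
        {
            "child": np.arange(1, cfg.n + 1),
            "Age": sim["Age"], "Sex": sim["Sex"].astype(int),
            "Height": sim["Height"], "Mass": sim["Mass"],
            "Speed": sim["Speed"], "GDI": sim["GDI"], "DMC": sim["DMC"],
            "SMC": sim["SMC"], "Spasticity": sim["Spasticity"],
            "Strength": sim["Strength"], "MetPower": sim["MetPower"],
        }
    )
    b = sim["B"]
    cohort["GMFCS"] = np.select(
        [b < _GMFCS_CUTS[0], b < _GMFCS_CUTS[1]], ["I", "II"], default="III"
    )

    # keep pre-mask copies so the exam items can be generated for everyone
    for col in ("Spasticity", "Strength", "SMC"):
        cohort[f"_{col}_complete"] = cohort[col]

    masks: dict[str, np.ndarray] = {}
    for col, rate in cfg.missing_rates.items():
        if cfg.missing_mechanism == "MAR" and col == "DMC":
            # plausibly, more severely involved children skip the EMG protocol
            per_level = {"I": 0.6, "II": 1.0, "III": 1.5}
            w = cohort["GMFCS"].map(per_level).to_numpy()
            prob = np.clip(rate * w / np.average(w), 0.0, 0.95)
        else:
            prob = np.full(cfg.n, rate)
        masks[col] = rng.random(cfg.n) < prob
        cohort.loc[masks[col], col] = np.nan

    exams = _exam_table(rng, cohort)
    cohort = cohort.drop(columns=[c for c in cohort.columns if c.startswith("_")])

    # agreement between tables: a masked summary score means an incomplete exam
    for domain, (col, _, _) in _EXAM_DOMAINS.items():
        missing_children = cohort.loc[masks.get(col, np.zeros(cfg.n, bool)), "child"]
        if len(missing_children):
            idx = exams.index[
                (exams["domain"] == domain) & exams["child"].isin(missing_children)
            ]
            drop = idx[rng.random(len(idx)) < 0.3]
            # guarantee at least one missing item per masked child
            first = exams.loc[idx].groupby("child").head(1).index
            exams.loc[drop.union(first), "rating"] = np.nan

    return cohort, exams, GroundTruth(config=cfg)


def dataset_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Missing-aware medians, SDs and missing fractions, total and by GMFCS."""
    numeric = [
        c for c in ("Age", "Height", "Mass", "Speed", "GDI", "DMC", "SMC",
                    "Spasticity", "Strength", "MetPower")
        if c in cohort.columns
    ]
    groups: list[tuple[str, pd.DataFrame]] = [("Total", cohort)]
    if "GMFCS" in cohort.columns:
        groups += [(f"GMFCS {lvl}", g) for lvl, g in cohort.groupby("GMFCS")]
    import warnings

    rows = {}
    rows["n"] = {name: len(g) for name, g in groups}
    if "Sex" in cohort.columns:
        rows["male_fraction"] = {
            name: float(pd.to_numeric(g["Sex"]).mean()) for name, g in groups
        }
    with warnings.catch_warnings():
        # a group whose column is entirely missing has no median
        warnings.simplefilter("ignore", RuntimeWarning)
        for col in numeric:
            rows[f"{col}_median"] = {name: float(g[col].median()) for name, g in groups}
            rows[f"{col}_sd"] = {name: float(g[col].std(ddof=1)) for name, g in groups}
            rows[f"{col}_missing"] = {name: float(g[col].isna().mean()) for name, g in groups}
    return pd.DataFrame(rows).T


def write_outputs(
    cohort: pd.DataFrame, exams: pd.DataFrame, truth: GroundTruth, out_dir,
) -> None:
    """Write cohort CSV, exam CSV, and the generator config as JSON."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort.csv", index=False)
    exams.to_csv(out / "exams.csv", index=False)
    payload = {
        "n": truth.config.n, "seed": truth.config.seed,
        "missing_mechanism": truth.config.missing_mechanism,
        "missing_rates": truth.config.missing_rates,
        "links": truth.config.links,
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2))
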