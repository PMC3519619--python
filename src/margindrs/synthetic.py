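"""Seeded synthetic lumpectomy/mastectomy cohorts with known kinetics.

No deposited clinical spectra exist, so the longitudinal analyses are
exercised on generated site time series that reproduce the published
statistical structure of the measured cohorts: per-class baseline endpoint
distributions matched to the site-level quartiles, per-site linear kinetic
rates matched to the published per-class means +/- SDs, the measurement
cadence of each specimen type, and multiplicative measurement noise.  The
generating truth (per-site intercept and slope) is retained for parameter
recovery tests.

Calibration notes.  For benign lumpectomy sites the published summaries
over-determine a simple independent model: the per-class rate mean/SD, the
baseline quartiles, and the median 30-minute percent change (percent change
= 100 * slope / |intercept| * horizon) cannot all hold if slopes and
intercepts are drawn independently.  The generator therefore couples them:
each site draws a fractional rate r ~ N(mu_r, sigma_r) (per minute) and an
intercept B from a scaled log-normal, with slope = r * B.  The median
30-minute percent change is then exactly 3000 * median(r), fixing mu_r; the
intercept scale is fixed by the rate mean (E[slope] = mu_r * E[B]); sigma_r
is solved from the rate SD.  The log-normal shape itself comes from the
published quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

#: normal quartile deviate used to convert quartiles to log-normal sigma
_Q75_Z = 0.6744897501960817

#: site-level quartiles (25/50/75%) per endpoint, clinical units
QUARTILES = {
    "mean_musp": (4.85, 6.68, 9.15),        # cm^-1
    "thb": (16.97, 31.03, 55.09),           # uM
    "beta_carotene": (10.29, 16.29, 24.37),  # uM
}

#: per-class kinetic rates (mean, SD) in units/min
RATES = {
    ("lumpectomy", "benign"): {
        "beta_carotene": (-0.027, 0.143),
        "mean_musp": (-0.034, 0.040),
        "thb": (-0.537, 0.750),
    },
    ("mastectomy", "benign"): {
        "beta_carotene": (0.015, 0.062),
        "mean_musp": (-0.010, 0.019),
        "thb": (-0.036, 0.191),
    },
    ("mastectomy", "malignant"): {
        "beta_carotene": (0.002, 0.045),
        "mean_musp": (-0.008, 0.023),
        "thb": (-0.123, 0.112),
    },
}

#: median 30-minute percent change per endpoint, benign lumpectomy sites
PCT30_MEDIANS = {"beta_carotene": -8.2, "mean_musp": -13.8, "thb": -44.2,
                 "dye": -228.7}

#: histology breakdown of histologically-confirmed sites per class
HISTOLOGY_COUNTS = {
    ("lumpectomy", "benign"): {"FG": 1, "FA": 2, "adipose": 29,
                               "mixed_other": 27},
    ("lumpectomy", "malignant"): {"IDC": 1, "DCIS": 1},
    ("mastectomy", "benign"): {"FG": 1, "FA": 2, "adipose": 4,
                               "mixed_other": 6},
    ("mastectomy", "malignant"): {"IDC": 5, "malignant_mixed": 2},
}

#: percent difference between adipose and positive-malignant sites
#: (negative value: positive sites greater)
PCT_DIFF_A_VS_P = {"beta_carotene": 29.8, "mean_musp": -27.8,
                   "ratio_bc_musp": 14.1, "thb": -101.2,
                   "ratio_thb_musp": -92.2}

GENERATED_ENDPOINTS = ("thb", "beta_carotene", "mean_musp", "dye")


@dataclass(frozen=True)
class EndpointModel:
    """Generating model for one endpoint within one tissue class.

    ``coupled`` draws slope = r * intercept with r ~ N(mu_r, sigma_r);
    ``independent`` draws the slope directly from N(rate_mean, rate_sd).
    Intercepts are log-normal: scale * exp(N(ln(median), sigma)).
    """

    intercept_median: float
    intercept_sigma: float
    intercept_scale: float = 1.0
    mode: str = "coupled"  # coupled | independent
    mu_r: float = 0.0          # fractional rate per min (coupled)
    sigma_r: float = 0.0
    rate_mean: float = 0.0     # units/min (independent)
    rate_sd: float = 0.0

    def draw(self, rng: np.random.Generator, n: int):
        b = (self.intercept_scale
             * np.exp(rng.normal(np.log(self.intercept_median),
                                 self.intercept_sigma, n)))
        if self.mode == "coupled":
            slope = rng.normal(self.mu_r, self.sigma_r, n) * b
        else:
            slope = rng.normal(self.rate_mean, self.rate_sd, n)
        return b, slope


@dataclass(frozen=True)
class Cadence:
    """Measurement timing model for one specimen type (minutes)."""

    first_mean: float
    first_sd: float
    first_range: tuple
    interval_range: tuple
    duration_range: tuple

    def draw_times(self, rng: np.random.Generator) -> np.ndarray:
        t0 = rng.normal(self.first_mean, self.first_sd)
        t0 = float(np.clip(t0, *self.first_range))
        duration = rng.uniform(*self.duration_range)
        times = [t0]
        while times[-1] - t0 < duration:
            times.append(times[-1] + rng.uniform(*self.interval_range))
        return np.asarray(times[:-1] if len(times) > 2 else times)


LUMPECTOMY_CADENCE = Cadence(first_mean=7.0, first_sd=3.0,
                             first_range=(2.0, 12.0),
                             interval_range=(0.86, 1.0),
                             duration_range=(10.0, 21.0))
MASTECTOMY_CADENCE = Cadence(first_mean=17.0, first_sd=4.0,
                             first_range=(10.0, 27.0),
                             interval_range=(0.35, 0.49),
                             duration_range=(10.0, 32.0))


@dataclass(frozen=True)
class ClassConfig:
    """One (specimen type, diagnosis) cell of the cohort."""

    specimen: str
    diagnosis: str
    histology_counts: dict
    cadence: Cadence
    endpoints: dict  # endpoint name -> EndpointModel

    @property
    def n_sites(self) -> int:
        return sum(self.histology_counts.values())


@dataclass(frozen=True)
class GeneratorConfig:
    classes: tuple  # of ClassConfig
    noise_sd: float = 0.02       # multiplicative, per observation
    hbsat_mean: float = 0.65
    hbsat_sd: float = 0.05
    floor: float = 0.0           # physical lower bound for endpoint values

    def class_for(self, specimen: str, diagnosis: str) -> ClassConfig:
        for c in self.classes:
            if c.specimen == specimen and c.diagnosis == diagnosis:
                return c
        raise KeyError((specimen, diagnosis))


@dataclass
class Cohort:
    """Generated observations plus the generating truth, both tidy frames."""

    observations: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig
    seed: int


def _lognormal_sigma(q25: float, q50: float, q75: float) -> float:
    """Log-normal shape parameter matched to both quartile ratios."""
    return 0.5 * (np.log(q75 / q50) + np.log(q50 / q25)) / _Q75_Z


def _coupled_model(endpoint: str, pct30: float, rate: tuple | None,
                   quartiles: tuple | None,
                   dye_median: float = 3.0, dye_sigma: float = 1.0
                   ) -> EndpointModel:
    """Calibrate a coupled endpoint model (see module docstring)."""
    mu_r = pct30 / 100.0 / 30.0  # fractional change per minute
    if quartiles is None:  # dye: baseline quartiles unpublished
        median, sigma = dye_median, dye_sigma
    else:
        median, sigma = quartiles[1], _lognormal_sigma(*quartiles)
    scale = 1.0
    sigma_r = 0.2 * abs(mu_r)
    if rate is not None:
        rate_mean, rate_sd = rate
        if mu_r != 0.0 and rate_mean / mu_r > 0:
            e_base = median * np.exp(0.5 * sigma ** 2)
            scale = (rate_mean / mu_r) / e_base
        e_b = scale * median * np.exp(0.5 * sigma ** 2)
        e_b2 = (scale * median) ** 2 * np.exp(2.0 * sigma ** 2)
        var_b = e_b2 - e_b ** 2
        var_r = (rate_sd ** 2 - mu_r ** 2 * var_b) / e_b2
        sigma_r = float(np.sqrt(max(var_r, (0.2 * mu_r) ** 2)))
    return EndpointModel(intercept_median=median, intercept_sigma=sigma,
                         intercept_scale=scale, mode="coupled",
                         mu_r=mu_r, sigma_r=sigma_r)


def _independent_model(endpoint: str, rate: tuple) -> EndpointModel:
    q = QUARTILES[endpoint]
    return EndpointModel(intercept_median=q[1],
                         intercept_sigma=_lognormal_sigma(*q),
                         mode="independent",
                         rate_mean=rate[0], rate_sd=rate[1])


def calibrate_defaults() -> GeneratorConfig:
    """Default cohort configuration calibrated to the published summaries.

    Benign lumpectomy sites use the coupled rate model so that the implied
    median 30-minute percent changes and the mean rates both match the
    published values; mastectomy classes (and the two malignant lumpectomy
    sites, which borrow the malignant mastectomy rates) draw slopes
    independently from the published class distributions.
    """
    lump_benign = {
        ep: _coupled_model(ep, PCT30_MEDIANS[ep],
                           RATES[("lumpectomy", "benign")].get(ep),
                           QUARTILES.get(ep))
        for ep in GENERATED_ENDPOINTS
    }

    def mast_class(diag):
        out = {}
        for ep in GENERATED_ENDPOINTS:
            if ep == "dye":
                # mapping dye is largely washed out by mastectomy
                # measurement times; model a small static residual
                out[ep] = EndpointModel(intercept_median=0.5,
                                        intercept_sigma=1.0,
                                        mode="independent",
                                        rate_mean=0.0, rate_sd=0.0)
            else:
                out[ep] = _independent_model(
                    ep, RATES[("mastectomy", diag)][ep])
        return out

    classes = (
        ClassConfig("lumpectomy", "benign",
                    HISTOLOGY_COUNTS[("lumpectomy", "benign")],
                    LUMPECTOMY_CADENCE, lump_benign),
        ClassConfig("lumpectomy", "malignant",
                    HISTOLOGY_COUNTS[("lumpectomy", "malignant")],
                    LUMPECTOMY_CADENCE, mast_class("malignant")),
        ClassConfig("mastectomy", "benign",
                    HISTOLOGY_COUNTS[("mastectomy", "benign")],
                    MASTECTOMY_CADENCE, mast_class("benign")),
        ClassConfig("mastectomy", "malignant",
                    HISTOLOGY_COUNTS[("mastectomy", "malignant")],
                    MASTECTOMY_CADENCE, mast_class("malignant")),
    )
    return GeneratorConfig(classes=classes)


def generate_cohort(cfg: GeneratorConfig | None = None, seed: int = 0,
                    classes: tuple | None = None) -> Cohort:
    """Draw a full cohort: per-site baselines, slopes, times, observations.

    Observed value = (intercept + slope * t) * (1 + eps), eps ~ N(0,
    noise_sd), floored at zero; ratio endpoints are derived per observation.
    ``classes`` optionally restricts generation to (specimen, diagnosis)
    pairs.
    """
    cfg = cfg or calibrate_defaults()
    rng = np.random.default_rng(seed)
    obs_rows = []
    truth_rows = []
    site_counter = 0
    for cc in cfg.classes:
        if classes is not None and (cc.specimen, cc.diagnosis) not in classes:
            continue
        n = cc.n_sites
        if n == 0:
            continue
        draws = {ep: cc.endpoints[ep].draw(rng, n)
                 for ep in GENERATED_ENDPOINTS}
        histologies = [h for h, k in cc.histology_counts.items()
                       for _ in range(k)]
        for i in range(n):
            site_id = f"{cc.specimen[:4]}-{cc.diagnosis[:3]}-{site_counter:03d}"
            site_counter += 1
            times = cc.cadence.draw_times(rng)
            hbsat0 = float(np.clip(rng.normal(cfg.hbsat_mean, cfg.hbsat_sd),
                                   0.0, 1.0))
            values = {}
            for ep in GENERATED_ENDPOINTS:
                b, s = draws[ep][0][i], draws[ep][1][i]
                noise = rng.normal(0.0, cfg.noise_sd, times.size)
                values[ep] = np.maximum((b + s * times) * (1.0 + noise),
                                        cfg.floor)
                truth_rows.append({"site_id": site_id, "endpoint": ep,
                                   "intercept": float(b), "slope": float(s)})
            for j, t in enumerate(times):
                obs_rows.append({
                    "site_id": site_id, "specimen_type": cc.specimen,
                    "histology": histologies[i], "diagnosis": cc.diagnosis,
                    "t_min": float(t),
                    "thb": values["thb"][j],
                    "beta_carotene": values["beta_carotene"][j],
                    "mean_musp": values["mean_musp"][j],
                    "dye": values["dye"][j],
                    "hbsat": hbsat0,
                    "ratio_bc_musp": values["beta_carotene"][j]
                    / max(values["mean_musp"][j], 1e-9),
                    "ratio_thb_musp": values["thb"][j]
                    / max(values["mean_musp"][j], 1e-9),
                })
    return Cohort(observations=pd.DataFrame(obs_rows),
                  truth=pd.DataFrame(truth_rows), config=cfg, seed=seed)


def generate_margin_maps(polarity: str, size: int = 32, seed: int = 0,
                         endpoints: tuple = ("beta_carotene", "thb",
                                             "mean_musp", "ratio_bc_musp",
                                             "ratio_thb_musp"),
                         rel_sd: float = 0.10,
                         smooth_sigma: float | None = None) -> dict:
    """Smooth random-field endpoint maps for a negative or positive margin.

    Negative-margin means are the benign-lumpectomy baseline medians;
    positive-margin means apply the published adipose-vs-positive percent
    differences (negative difference: positive sites greater).
    """
    if polarity not in ("negative", "positive"):
        raise ValueError("polarity must be 'negative' or 'positive'")
    cfg = calibrate_defaults()
    lump = cfg.class_for("lumpectomy", "benign").endpoints
    base_means = {
        "beta_carotene": lump["beta_carotene"].intercept_scale
        * lump["beta_carotene"].intercept_median,
        "thb": lump["thb"].intercept_scale * lump["thb"].intercept_median,
        "mean_musp": lump["mean_musp"].intercept_scale
        * lump["mean_musp"].intercept_median,
    }
    base_means["ratio_bc_musp"] = (base_means["beta_carotene"]
                                   / base_means["mean_musp"])
    base_means["ratio_thb_musp"] = base_means["thb"] / base_means["mean_musp"]
    rng = np.random.default_rng(seed)
    sigma = smooth_sigma if smooth_sigma is not None else size / 8.0
    maps = {}
    for ep in endpoints:
        mean = base_means[ep]
        if polarity == "positive":
            mean = mean * (1.0 - PCT_DIFF_A_VS_P[ep] / 100.0)
        field_ = rng.standard_normal((size, size))
        if sigma > 0:
            field_ = ndimage.gaussian_filter(field_, sigma, mode="reflect")
            sd = field_.std()
            if sd > 0:
                field_ = field_ / sd
        maps[ep] = np.maximum(mean * (1.0 + rel_sd * field_), 0.0)
    return maps
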