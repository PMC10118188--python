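"""Seeded synthetic BACI watershed-study generator.

Emulates a paired headwater/downstream study layout: 12 headwater
watersheds nested in four catchments plus four downstream sites, sampled
annually in five pre-treatment and four post-treatment years on nine
positive right-skewed stream attributes.  Values follow a multiplicative
lognormal model

    value = baseline * site_effect * treatment_factor^(period==post) * noise

with mean-one lognormal noise, so an injected post/pre effect factor acts
directly on the expected value.  Percent-scale attributes (canopy closure)
are generated on the logit scale and mapped back to [0, 100], the effect
factor multiplying the odds.  Identical configurations (including the
seed) yield byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .tables import OBSERVATION_COLUMNS

__all__ = ["SimulationConfig", "simulate_study", "default_trask_design", "load_config"]


@dataclass
class SimulationConfig:
    """Study design and effect-injection parameters.

    ``sites`` lists (site-id, catchment-id, group-label).  ``baseline``
    maps (site, attribute) to a positive level; ``effect`` maps (group,
    attribute) to a post/pre multiplicative factor (default 1);
    ``noise_cv`` is the coefficient of variation of the multiplicative
    noise (interpreted as the logit-scale standard deviation for
    ``logit_attributes``); ``site_sd`` the log-scale standard deviation of
    the persistent site random effect.
    """

    sites: list = field(default_factory=list)
    groups: list = field(default_factory=list)
    pre_years: list = field(default_factory=list)
    post_years: list = field(default_factory=list)
    attributes: list = field(default_factory=list)
    replicates_per_attribute: dict = field(default_factory=dict)
    replicate_overrides: dict = field(default_factory=dict)  # (site, attribute) -> count
    baseline: dict = field(default_factory=dict)  # (site, attribute) -> level
    effect: dict = field(default_factory=dict)  # (group, attribute) -> factor
    noise_cv: dict = field(default_factory=dict)
    site_sd: float = 0.0
    year_sd: float = 0.0  # optional common-year multiplier, off by default
    logit_attributes: tuple = ("canopy_closure",)
    seed: int = 0

    def validate(self) -> None:
        if set(self.pre_years) & set(self.post_years):
            raise ValueError("pre_years and post_years must be disjoint")
        site_groups = {g for _, _, g in self.sites}
        missing = site_groups - set(self.groups)
        if missing:
            raise ValueError(f"site groups not declared in groups: {sorted(missing)}")
        for key, v in self.baseline.items():
            if not v > 0:
                raise ValueError(f"non-positive baseline for {key}")
        for key, v in self.effect.items():
            if not v > 0:
                raise ValueError(f"non-positive effect factor for {key}")
        for attr, r in self.replicates_per_attribute.items():
            if r < 1:
                raise ValueError(f"replicates must be >= 1 for {attr}")
        for key, r in self.replicate_overrides.items():
            if r < 1:
                raise ValueError(f"replicates must be >= 1 for {key}")

    def with_effects(self, effects: dict) -> "SimulationConfig":
        """Copy of the config with (group, attribute) -> factor entries merged."""
        merged = dict(self.effect)
        merged.update(effects)
        return replace(self, effect=merged)

    def n_replicates(self, site: str, attribute: str) -> int:
        if (site, attribute) in self.replicate_overrides:
            return self.replicate_overrides[(site, attribute)]
        return self.replicates_per_attribute.get(attribute, 1)


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_study(config: SimulationConfig) -> pd.DataFrame:
    """Generate one long-format observation table from the configuration.

    One record per site x year x attribute x replicate.  Deterministic for
    a given config (all randomness flows from ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    site_eff = {site: rng.normal(0.0, config.site_sd) for site, _, _ in config.sites}
    years = list(config.pre_years) + list(config.post_years)
    year_eff = {yr: rng.normal(0.0, config.year_sd) for yr in years}

    records = []
    for site, _catchment, group in config.sites:
        for year in years:
            period = "post" if year in config.post_years else "pre"
            for attr in config.attributes:
                base = config.baseline.get((site, attr))
                if base is None:
                    raise ValueError(f"no baseline for site {site!r}, attribute {attr!r}")
                factor = config.effect.get((group, attr), 1.0)
                cv = config.noise_cv.get(attr, 0.0)
                n_rep = config.n_replicates(site, attr)
                for rep in range(1, n_rep + 1):
                    if attr in config.logit_attributes:
                        # percent scale: model on logit, effect multiplies odds
                        mu = _logit(base / 100.0) + site_eff[site] + year_eff[year]
                        if period == "post":
                            mu += np.log(factor)
                        eps = rng.normal(0.0, cv)
                        value = 100.0 * _expit(mu + eps)
                    else:
                        sigma = float(np.sqrt(np.log1p(cv**2)))
                        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma))
                        value = base * np.exp(site_eff[site] + year_eff[year]) * noise
                        if period == "post":
                            value *= factor
                    records.append((site, group, period, year, rep, attr, value))
    return pd.DataFrame(records, columns=OBSERVATION_COLUMNS)


HEADWATER_GROUPS = ["clearcut variable", "clearcut uniform", "thinned", "reference"]
DOWNSTREAM_GROUPS = ["downstream harvest", "downstream reference"]

ATTRIBUTES = [
    "canopy_closure",
    "DOC",
    "SRP",
    "DON",
    "DIN",
    "DIN_SRP",
    "epilithon_afdm",
    "chlorophyll_a",
    "surface_sediment",
]

_HEADWATER_SITES = [
    ("UM1", "Upper Main", "reference"),
    ("UM2", "Upper Main", "clearcut variable"),
    ("UM3", "Upper Main", "clearcut variable"),
    ("GS1", "Gus", "reference"),
    ("GS2", "Gus", "thinned"),
    ("GS3", "Gus", "clearcut variable"),
    ("PH1", "Pothole", "clearcut uniform"),
    ("PH2", "Pothole", "clearcut uniform"),
    ("PH3", "Pothole", "reference"),
    ("PH4", "Pothole", "clearcut uniform"),
    ("RK1", "Rock", "reference"),
    ("RK3", "Rock", "reference"),
]

_DOWNSTREAM_SITES = [
    ("UMDS", "Upper Main", "downstream harvest"),
    ("GSDS", "Gus", "downstream harvest"),
    ("PHDS", "Pothole", "downstream harvest"),
    ("RKDS", "Rock", "downstream reference"),
]

# typical early-summer levels in each attribute's reporting units
_BASE_LEVELS = {
    "canopy_closure": 90.0,  # percent
    "DOC": 0.5,  # mg C/L
    "SRP": 0.01,  # mg P/L
    "DON": 0.03,  # mg N/L
    "DIN": 0.02,  # mg N/L
    "DIN_SRP": 10.0,  # molar ratio
    "epilithon_afdm": 8.0,  # g AFDM/m2
    "chlorophyll_a": 2.0,  # mg/m2
    "surface_sediment": 100.0,  # g/m2
}

# watersheds with distinctly higher phosphorus than the rest
_HIGH_SRP_SITES = ("PH2", "PH3", "RK1")


def default_trask_design(seed: int = 0) -> SimulationConfig:
    """The 12-headwater + 4-downstream layout with default null effects.

    Group sizes: 3 clearcut variable, 3 clearcut uniform, 1 thinned,
    5 reference headwater sites; 3 downstream-of-harvest and 1 downstream
    reference.  Pre years 2007-2011, post years 2013-2016.  Replicates:
    4 (headwater) / 6 (downstream) epilithon and chlorophyll composites,
    3/5 sediment samples, one chemistry grab per site-year.
    """
    sites = _HEADWATER_SITES + _DOWNSTREAM_SITES
    baseline = {}
    for site, _, _ in sites:
        for attr in ATTRIBUTES:
            level = _BASE_LEVELS[attr]
            if attr == "SRP" and site in _HIGH_SRP_SITES:
                level *= 5.0
            baseline[(site, attr)] = level

    replicates = {attr: 1 for attr in ATTRIBUTES}
    replicates["epilithon_afdm"] = 4
    replicates["chlorophyll_a"] = 4
    replicates["surface_sediment"] = 3
    overrides = {}
    for site, _, _ in _DOWNSTREAM_SITES:
        overrides[(site, "epilithon_afdm")] = 6
        overrides[(site, "chlorophyll_a")] = 6
        overrides[(site, "surface_sediment")] = 5

    noise_cv = {attr: 0.3 for attr in ATTRIBUTES}
    noise_cv["canopy_closure"] = 0.2  # logit-scale sd

    return SimulationConfig(
        sites=sites,
        groups=HEADWATER_GROUPS + DOWNSTREAM_GROUPS,
        pre_years=[2007, 2008, 2009, 2010, 2011],
        post_years=[2013, 2014, 2015, 2016],
        attributes=list(ATTRIBUTES),
        replicates_per_attribute=replicates,
        replicate_overrides=overrides,
        baseline=baseline,
        effect={},
        noise_cv=noise_cv,
        site_sd=0.4,
        seed=seed,
    )


def load_config(path) -> SimulationConfig:
    """Load a simulation config from YAML/JSON.

    The file may specify any subset of fields; unspecified fields fall
    back to the default study design.  Tuple-keyed maps are written as
    nested mappings, e.g. ``effect: {"clearcut variable": {DIN: 6}}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = default_trask_design()
    simple = {
        "groups", "pre_years", "post_years", "attributes", "site_sd",
        "year_sd", "seed",
    }
    for key in simple & set(raw):
        setattr(cfg, key, raw[key])
    if "sites" in raw:
        cfg.sites = [tuple(s) for s in raw["sites"]]
    if "replicates_per_attribute" in raw:
        cfg.replicates_per_attribute.update(raw["replicates_per_attribute"])
    if "noise_cv" in raw:
        cfg.noise_cv.update(raw["noise_cv"])
    if "logit_attributes" in raw:
        cfg.logit_attributes = tuple(raw["logit_attributes"])
    for field_name in ("effect", "baseline"):
        if field_name in raw:
            target = getattr(cfg, field_name)
            for outer, inner in raw[field_name].items():
                for attr, v in inner.items():
                    target[(outer, attr)] = float(v)
    if "replicate_overrides" in raw:
        for site, inner in raw["replicate_overrides"].items():
            for attr, v in inner.items():
                cfg.replicate_overrides[(site, attr)] = int(v)
    cfg.validate()
    return cfg
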