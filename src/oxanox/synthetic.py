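"""Synthetic lake data with planted regime-shift structure.

Desk-scale stand-ins for a year of monitoring of a small, seasonally
stratified, eutrophic lake:

* :func:`generate_profile_series` — biweekly 0–10 m temperature/oxygen
  profiles: a mixed, oxygen-saturated water column in early spring; a
  two-layer thermal structure between stratification onset and fall
  turnover, with hypolimnetic oxygen drawn down toward anoxia; and a
  configurable turnover outcome — ``"oxic"`` (the mixed column
  re-oxygenates, the seasonal path retraces) or ``"anoxic"`` (the mixed
  column stays oxygen-poor before a late-winter recovery, the path encloses
  a hysteresis loop).
* :func:`generate_abundance_table` — taxon counts at a metalimnion station
  whose planted latent structure mirrors the same cycle: cyanobacteria
  track the mixed/oxic phase, phototrophic sulfur bacteria and sulfate
  reducers track the stratified/anoxic phase (mutual exclusion of CB
  against PB/SB, co-occurrence of PB with SB), remaining taxa are
  independent noise. Counts are negative-binomial (overdispersed), the
  standard stand-in for amplicon relative-abundance data.
* :func:`generate_parameter_set` — lognormal jitter of a model parameter
  set, for robustness experiments.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .params import ModelParameters
from .stratification import (
    DepthProfile,
    ProfileSeries,
    oxygen_saturation_concentration,
)

__all__ = [
    "SyntheticLakeConfig",
    "SyntheticCommunityConfig",
    "generate_profile_series",
    "generate_abundance_table",
    "generate_parameter_set",
]


@dataclass(frozen=True)
class SyntheticLakeConfig:
    """Configuration of the seasonal profile generator.

    The depth grid defaults to every metre from 0 to 10 m; dates run
    biweekly from March of one year to March of the next, with
    stratification from early May to early November — the phenology of a
    small temperate lake.
    """

    n_dates: int = 27
    start: str = "2013-03-01"
    end: str = "2014-03-01"
    depths: Tuple[float, ...] = tuple(float(z) for z in range(11))
    onset: str = "2013-05-01"            # stratification onset
    breakdown: str = "2013-11-01"        # fall turnover
    t_epi_summer: float = 22.0           # peak epilimnion temperature (C)
    t_winter: float = 4.0                # mixed-column winter temperature (C)
    t_hypo: float = 7.0                  # hypolimnion temperature (C)
    thermocline_depth: float = 5.0       # m
    interface_width: float = 0.6         # m, logistic half-width
    o2_drawdown_per_degC: float = 0.2    # hypolimnetic log-drawdown per degC
    turnover: str = "anoxic"             # "oxic" | "anoxic"
    turnover_o2_sat: float = 8.0         # % saturation of the anoxic mixed column
    recovery: str = "2014-01-15"         # late-winter re-oxygenation (anoxic case)
    temp_noise: float = 0.05             # C, measurement noise sd
    o2_noise_frac: float = 0.01          # relative O2 measurement noise sd
    seed: int = 0

    def __post_init__(self):
        if pd.Timestamp(self.onset) >= pd.Timestamp(self.breakdown):
            raise ValueError("stratification onset must precede breakdown")
        if self.turnover not in ("oxic", "anoxic"):
            raise ValueError("turnover outcome must be 'oxic' or 'anoxic'")
        if self.temp_noise < 0 or self.o2_noise_frac < 0:
            raise ValueError("noise scales must be >= 0")


def _season(day_of_year: np.ndarray, t_min: float, t_max: float) -> np.ndarray:
    """Sinusoidal annual surface-temperature cycle peaking in late July."""
    phase = 2.0 * np.pi * (day_of_year - 205) / 365.25
    return t_min + (t_max - t_min) * 0.5 * (1.0 + np.cos(phase))


def generate_profile_series(config: SyntheticLakeConfig) -> ProfileSeries:
    """Generate the seasonal :class:`ProfileSeries` described by *config*.

    The hypolimnetic oxygen saturation during stratification is a pure
    function of the epilimnion–hypolimnion temperature contrast dT,
    ``100*exp(-o2_drawdown_per_degC * dT)`` — i.e. single-valued on the
    stratification strength — so with ``turnover='oxic'`` the seasonal
    (1/N^2, O2 saturation) path retraces itself and encloses ~0 area. With
    ``turnover='anoxic'`` an anoxia latch engages once the saturation first
    falls to ``turnover_o2_sat``: the hypolimnion (and, after breakdown,
    the whole mixed column) stays at that low saturation until *recovery*,
    which opens a hysteresis loop of the planted orientation (breakdown
    limb oxygen-poorer than the stratifying limb).
    """
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(config.start, config.end, periods=config.n_dates)
    onset = pd.Timestamp(config.onset)
    breakdown = pd.Timestamp(config.breakdown)
    recovery = pd.Timestamp(config.recovery)
    z = np.asarray(config.depths, dtype=float)

    profiles = []
    latched = False
    for date in dates:
        doy = float(date.day_of_year)
        t_surface = _season(np.array(doy), config.t_winter, config.t_epi_summer)
        stratified = onset <= date < breakdown
        if stratified:
            # logistic two-layer structure; epilimnion follows the season,
            # with the layer contrast tapering smoothly to zero at onset and
            # breakdown so the stratified limb connects continuously to the
            # mixed state
            frac = (date - onset) / (breakdown - onset)
            dT = max(float(t_surface) - config.t_hypo, 0.0) * float(
                np.sin(np.pi * frac) ** 2
            )
            temp = config.t_hypo + dT / (
                1.0 + np.exp((z - config.thermocline_depth) / config.interface_width)
            )
            hypo_sat = 100.0 * np.exp(-config.o2_drawdown_per_degC * dT)
            if config.turnover == "anoxic" and hypo_sat <= config.turnover_o2_sat:
                latched = True
            if latched:
                hypo_sat = min(hypo_sat, config.turnover_o2_sat)
            sat = 100.0 + (hypo_sat - 100.0) / (
                1.0 + np.exp(-(z - config.thermocline_depth) / config.interface_width)
            )
        else:
            temp = np.full_like(z, float(t_surface))
            if date >= recovery:
                latched = False
            if latched and date >= breakdown:
                sat = np.full_like(z, config.turnover_o2_sat)
            else:
                sat = np.full_like(z, 100.0)
        temp = temp + rng.normal(0.0, config.temp_noise, size=z.shape)
        o2 = sat / 100.0 * oxygen_saturation_concentration(temp)
        o2 = o2 * (1.0 + rng.normal(0.0, config.o2_noise_frac, size=z.shape))
        profiles.append(
            DepthProfile(
                timestamp=date,
                depths=z,
                temperature=temp,
                oxygen=np.maximum(o2, 0.0),
            )
        )
    return ProfileSeries(profiles)


@dataclass(frozen=True)
class SyntheticCommunityConfig:
    """Configuration of the abundance-table generator.

    ``effect_size`` is the amplitude (in natural-log units) of the planted
    seasonal swing of the CB/PB/SB taxa between their favoured and
    disfavoured phases; 2.0 means an e^4 ~ 55-fold abundance contrast,
    comparable to the near-complete seasonal turnover seen in stratified
    eutrophic lakes. ``dispersion`` is the negative-binomial shape k
    (smaller = noisier counts).
    """

    n_taxa: int = 20
    n_samples: int = 24
    effect_size: float = 2.0
    count_depth: int = 20000
    dispersion: float = 5.0
    n_cb: int = 2
    n_pb: int = 2
    n_sb: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < self.n_cb + self.n_pb + self.n_sb:
            raise ValueError("n_taxa too small for the planted groups")
        if self.n_samples < 8:
            raise ValueError("need at least 8 samples")
        if self.effect_size < 0 or self.dispersion <= 0:
            raise ValueError("effect size must be >= 0 and dispersion > 0")


_PLANTED_TAXONOMY = {
    "CB": "Bacteria;Cyanobacteria;Cyanophyceae;Synechococcales",
    "PB": (
        "Bacteria;Chlorobi;Chlorobia;Chlorobiales",
        "Bacteria;Proteobacteria;Gammaproteobacteria;Chromatiales",
    ),
    "SB": (
        "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfobacterales",
        "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfovibrionales",
        "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfuromonadales",
    ),
}

_OTHER_TAXONOMY = (
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodospirillales",
    "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales",
    "Bacteria;Actinobacteria;Actinomycetia;Frankiales",
    "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales",
    "Bacteria;Verrucomicrobia;Verrucomicrobiae;Verrucomicrobiales",
    "Bacteria;Planctomycetes;Planctomycetia;Pirellulales",
)


def _from_table_module():
    # local import: avoid a circular import at module load
    from .network import AbundanceTable

    return AbundanceTable


def generate_abundance_table(config: SyntheticCommunityConfig):
    """Generate an :class:`~oxanox.network.AbundanceTable` with planted
    CB-versus-(PB, SB) mutual exclusion.

    The latent driver ``s(t)`` rises smoothly from 0 (mixed, oxic) to 1
    (stratified, anoxic) and back over the sampling season. CB log-mean
    decreases with s, PB/SB log-means increase with s; all other taxa have
    independent lognormal noise around a flat mean. Sample counts are
    negative-binomial draws around proportional means scaled to
    ``count_depth``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    t = np.linspace(0.0, 1.0, cfg.n_samples)
    # smooth stratified-anoxic indicator: up at ~1/3, down at ~5/6 of the season
    s = 1.0 / (1.0 + np.exp(-(t - 0.33) / 0.06)) * (
        1.0 - 1.0 / (1.0 + np.exp(-(t - 0.85) / 0.04))
    )

    group_of: List[str] = (
        ["CB"] * cfg.n_cb + ["PB"] * cfg.n_pb + ["SB"] * cfg.n_sb
        + ["OTHER"] * (cfg.n_taxa - cfg.n_cb - cfg.n_pb - cfg.n_sb)
    )
    log_mean = np.empty((cfg.n_taxa, cfg.n_samples))
    taxonomy = []
    counters = {"CB": 0, "PB": 0, "SB": 0, "OTHER": 0}
    for i, grp in enumerate(group_of):
        k = counters[grp]
        counters[grp] += 1
        if grp == "CB":
            log_mean[i] = cfg.effect_size * (1.0 - 2.0 * s)
            taxonomy.append(_PLANTED_TAXONOMY["CB"])
        elif grp in ("PB", "SB"):
            log_mean[i] = cfg.effect_size * (2.0 * s - 1.0)
            pool = _PLANTED_TAXONOMY[grp]
            taxonomy.append(pool[k % len(pool)])
        else:
            log_mean[i] = rng.normal(0.0, 0.3, size=cfg.n_samples)
            taxonomy.append(_OTHER_TAXONOMY[k % len(_OTHER_TAXONOMY)])
        log_mean[i] += rng.normal(0.0, 0.25)  # per-taxon baseline offset

    mean = np.exp(log_mean)
    mean = mean / mean.sum(axis=0, keepdims=True) * cfg.count_depth
    # negative binomial via gamma-Poisson mixture
    lam = rng.gamma(shape=cfg.dispersion, scale=mean / cfg.dispersion)
    counts = rng.poisson(lam)

    AbundanceTable = _from_table_module()
    taxa = [f"{grp}_{i}" for i, grp in enumerate(group_of)]
    samples = [f"S{j:02d}" for j in range(cfg.n_samples)]
    meta = pd.DataFrame(
        {"season_position": t, "stratified_anoxic": s}, index=samples
    )
    return AbundanceTable(
        counts=counts, taxa=taxa, taxonomy=taxonomy, samples=samples,
        sample_metadata=meta,
    )


def generate_parameter_set(
    base: ModelParameters, jitter: float, seed: Optional[int] = None
) -> ModelParameters:
    """Multiply every strictly positive parameter by an independent
    lognormal factor with log-sd *jitter* (0 <= jitter < 1)."""
    if not 0.0 <= jitter < 1.0:
        raise ValueError(f"jitter must be in [0, 1), got {jitter}")
    if jitter == 0.0:
        return base
    rng = np.random.default_rng(seed)
    d = base.to_dict()
    for name in sorted(d):
        if d[name] > 0:
            d[name] = d[name] * float(rng.lognormal(mean=0.0, sigma=jitter))
    return ModelParameters(**d)
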