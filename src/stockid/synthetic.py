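"""Synthetic specimen generator for the stock-identification pipeline.

Emulates the statistical structure the downstream analyses assume:

* morphometric characters grow allometrically with total length (TL) —
  ``log(char) = mean(group, sex) + b * (log TL - log TLbar) + eps`` with
  independent Gaussian residuals on the natural-log scale;
* meristic counts are rounded Gaussian marginals, group- and sex-free;
* heart fatty-acid profiles are compositional: multiplicative log-normal
  (logistic-normal) noise around a group mean composition, re-closed to 100%,
  with structurally absent ("ND") components held at exact zero.

Only marginal means and dispersions are emulated; within-group covariance is
diagonal on the log scale (configurable only through the per-character
residual sds). The shipped default parameter set mirrors the magnitudes of
published adult sea-lamprey summary tables and is clearly a magnitudes-only
emulation, not anyone's raw data.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._exceptions import ConfigurationError

__all__ = [
    "SyntheticConfig",
    "default_config",
    "generate_morphometrics",
    "generate_fatty_acids",
    "null_config",
]

METADATA_COLUMNS = ["specimen_id", "group", "river", "sex", "TL_mm", "TM_g"]

#: name of the pseudo-component that closes published mean compositions to 100%
OTHER_FA = "other"

_CLOSURE_TOL = 1e-9  # on the fraction (sum/100) scale


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic sampling design.

    ``char_log_means[char]`` is an ``(n_groups, n_sexes)`` array of natural-log
    scale means at the reference length ``tl_mean_mm``. ``fa_means[group]``
    maps fatty-acid name -> mean percentage; a name absent from a group's
    mapping is structurally absent (ND) in that group and is generated as an
    exact zero.
    """

    n_per_stratum: int
    tl_mean_mm: float
    tl_sd_mm: float
    groups: list[str]
    rivers: dict[str, list[str]]
    sexes: list[str]
    char_log_means: dict[str, np.ndarray]
    char_slopes: dict[str, float]
    char_resid_sd: dict[str, float]
    meristic_means: dict[str, float] = field(default_factory=dict)
    meristic_sds: dict[str, float] = field(default_factory=dict)
    fa_means: dict[str, dict[str, float]] = field(default_factory=dict)
    fa_dispersion: float = 0.0
    total_mass: dict[str, tuple[float, float]] = field(default_factory=dict)
    total_mass_resid_sd: float = 0.0
    seed: int = 0

    # -- derived ---------------------------------------------------------
    @property
    def characters(self) -> list[str]:
        return list(self.char_log_means)

    @property
    def meristics(self) -> list[str]:
        return list(self.meristic_means)

    @property
    def fatty_acid_names(self) -> list[str]:
        names: list[str] = []
        for comp in self.fa_means.values():
            for name in comp:
                if name not in names:
                    names.append(name)
        return names

    def nd_set(self, group: str) -> set[str]:
        """Fatty acids structurally absent (ND) in *group*."""
        return set(self.fatty_acid_names) - set(self.fa_means.get(group, {}))

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_per_stratum <= 0:
            raise ConfigurationError("n_per_stratum must be > 0")
        if self.tl_mean_mm <= 0:
            raise ConfigurationError("tl_mean_mm must be > 0")
        if self.tl_sd_mm < 0:
            raise ConfigurationError("tl_sd_mm must be >= 0")
        if self.fa_dispersion < 0:
            raise ConfigurationError("fa_dispersion must be >= 0")
        if not self.groups:
            raise ConfigurationError("groups must be non-empty")
        for g in self.groups:
            if not self.rivers.get(g):
                raise ConfigurationError(f"rivers missing for group {g!r}")
        ng, ns = len(self.groups), len(self.sexes)
        for char, means in self.char_log_means.items():
            means = np.asarray(means, dtype=float)
            if means.shape != (ng, ns):
                raise ConfigurationError(
                    f"char_log_means[{char!r}] must have shape ({ng}, {ns})"
                )
            if char not in self.char_slopes:
                raise ConfigurationError(f"char_slopes missing for {char!r}")
            sd = self.char_resid_sd.get(char)
            if sd is None or sd < 0:
                raise ConfigurationError(f"char_resid_sd invalid for {char!r}")
        for name, sd in self.meristic_sds.items():
            if sd < 0:
                raise ConfigurationError(f"meristic_sds[{name!r}] must be >= 0")
        for g, comp in self.fa_means.items():
            for name, mean in comp.items():
                if mean < 0:
                    raise ConfigurationError(
                        f"fa_means[{g!r}][{name!r}] is negative"
                    )
            total = sum(comp.values())
            if abs(total / 100.0 - 1.0) > _CLOSURE_TOL:
                raise ConfigurationError(
                    f"fa_means[{g!r}] sums to {total!r}, not 100"
                )

    # -- serialization ---------------------------------------------------
    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticConfig":
        groups = list(raw["groups"])
        sexes = list(raw["sexes"])
        char_log_means: dict[str, np.ndarray] = {}
        char_slopes: dict[str, float] = {}
        char_resid_sd: dict[str, float] = {}
        for char, spec in raw.get("characters", {}).items():
            devs = np.asarray(spec.get("group_dev", [0.0] * len(groups)), float)
            sex_means = np.asarray([spec[s] for s in sexes], float)
            char_log_means[char] = devs[:, None] + sex_means[None, :]
            char_slopes[char] = float(spec.get("slope", 1.0))
            char_resid_sd[char] = float(spec.get("resid_sd", 0.0))
        meristic_means = {}
        meristic_sds = {}
        for name, spec in raw.get("meristics", {}).items():
            meristic_means[name] = float(spec["mean"])
            meristic_sds[name] = float(spec["sd"])
        fa_raw = raw.get("fatty_acids", {})
        fa_means: dict[str, dict[str, float]] = {}
        for g, comp in fa_raw.get("means", {}).items():
            comp = {name: float(v) for name, v in comp.items()}
            remainder = 100.0 - sum(comp.values())
            if remainder < -100.0 * _CLOSURE_TOL:
                raise ConfigurationError(
                    f"fatty_acids.means[{g!r}] sums above 100"
                )
            if abs(remainder) > 100.0 * _CLOSURE_TOL:
                comp[OTHER_FA] = remainder
            fa_means[g] = comp
        tm_raw = raw.get("total_mass", {})
        total_mass = {
            s: tuple(map(float, tm_raw[s])) for s in sexes if s in tm_raw
        }
        cfg = cls(
            n_per_stratum=int(raw["n_per_stratum"]),
            tl_mean_mm=float(raw["tl_mean_mm"]),
            tl_sd_mm=float(raw["tl_sd_mm"]),
            groups=groups,
            rivers={g: list(v) for g, v in raw["rivers"].items()},
            sexes=sexes,
            char_log_means=char_log_means,
            char_slopes=char_slopes,
            char_resid_sd=char_resid_sd,
            meristic_means=meristic_means,
            meristic_sds=meristic_sds,
            fa_means=fa_means,
            fa_dispersion=float(fa_raw.get("dispersion", 0.0)),
            total_mass=total_mass,
            total_mass_resid_sd=float(tm_raw.get("resid_sd", 0.0)),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def copy(self) -> "SyntheticConfig":
        return copy.deepcopy(self)


def default_config(seed: int = 0) -> SyntheticConfig:
    """The shipped default parameter set (magnitudes-only emulation)."""
    ref = importlib.resources.files("stockid.data") / "default_config.yaml"
    cfg = SyntheticConfig.from_dict(yaml.safe_load(ref.read_text("utf-8")))
    cfg.seed = seed
    return cfg


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _strata(config: SyntheticConfig):
    for g in config.groups:
        for river in config.rivers[g]:
            for sex in config.sexes:
                yield g, river, sex


def _draw_lengths(rng: np.random.Generator, n: int, mean: float, sd: float):
    """Normal lengths truncated to positive by resampling."""
    tl = rng.normal(mean, sd, size=n)
    while np.any(tl <= 0):
        bad = tl <= 0
        tl[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return tl


def generate_morphometrics(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a specimen table (metadata, TL/TM, characters, meristics).

    Deterministic given ``config.seed``: one RNG consumed in a fixed stratum
    order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    log_ref = np.log(config.tl_mean_mm)
    rows = []
    counter = 0
    for g, river, sex in _strata(config):
        gi = config.groups.index(g)
        si = config.sexes.index(sex)
        n = config.n_per_stratum
        tl = _draw_lengths(rng, n, config.tl_mean_mm, config.tl_sd_mm)
        if sex in config.total_mass:
            a, b = config.total_mass[sex]
            tm = a * (tl / 10.0) ** b * np.exp(
                rng.normal(0.0, config.total_mass_resid_sd, size=n)
            )
        else:
            tm = np.full(n, np.nan)
        block = {
            "specimen_id": [
                f"{g}-{river}-{sex}-{counter + i:04d}" for i in range(n)
            ],
            "group": g,
            "river": river,
            "sex": sex,
            "TL_mm": tl,
            "TM_g": tm,
        }
        counter += n
        for char in config.characters:
            mu = config.char_log_means[char][gi, si]
            b_char = config.char_slopes[char]
            sd = config.char_resid_sd[char]
            eps = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
            block[char] = np.exp(mu + b_char * (np.log(tl) - log_ref) + eps)
        for name in config.meristics:
            m, sd = config.meristic_means[name], config.meristic_sds[name]
            vals = rng.normal(m, sd, size=n) if sd > 0 else np.full(n, m)
            block[name] = np.maximum(np.rint(vals), 0).astype(int)
        rows.append(pd.DataFrame(block))
    return pd.concat(rows, ignore_index=True)


def generate_fatty_acids(config: SyntheticConfig) -> pd.DataFrame:
    """Generate per-specimen fatty-acid percentage profiles.

    Logistic-normal noise: each detected component is multiplied by
    ``exp(N(0, dispersion^2))`` and the profile is re-closed to 100%. ND
    components stay exactly zero. Deterministic given ``config.seed``.
    """
    config.validate()
    if not config.fa_means:
        raise ConfigurationError("fa_means is empty")
    rng = np.random.default_rng(config.seed)
    names = config.fatty_acid_names
    rows = []
    counter = 0
    for g, river, sex in _strata(config):
        comp = config.fa_means[g]
        mean = np.array([comp.get(name, 0.0) for name in names])
        detected = mean > 0
        n = config.n_per_stratum
        profiles = np.tile(mean, (n, 1))
        if config.fa_dispersion > 0:
            noise = rng.normal(
                0.0, config.fa_dispersion, size=(n, int(detected.sum()))
            )
            profiles[:, detected] *= np.exp(noise)
        profiles *= 100.0 / profiles.sum(axis=1, keepdims=True)
        block = pd.DataFrame(profiles, columns=names)
        block.insert(0, "sex", sex)
        block.insert(0, "river", river)
        block.insert(0, "group", g)
        block.insert(
            0,
            "specimen_id",
            [f"{g}-{river}-{sex}-{counter + i:04d}" for i in range(n)],
        )
        counter += n
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def null_config(config: SyntheticConfig) -> SyntheticConfig:
    """Copy of *config* with all group effects pooled; sex effects preserved.

    Character means are averaged over groups per (sex, character); the fatty
    acid composition becomes the across-group mean composition (re-closed to
    100%), so a component survives if it is detected in at least one group.
    """
    config.validate()
    out = config.copy()
    for char, means in out.char_log_means.items():
        pooled = np.asarray(means, float).mean(axis=0)
        out.char_log_means[char] = np.tile(pooled, (len(out.groups), 1))
    if out.fa_means:
        names = config.fatty_acid_names
        stack = np.array(
            [
                [config.fa_means[g].get(name, 0.0) for name in names]
                for g in config.groups
            ]
        )
        pooled = stack.mean(axis=0)
        pooled *= 100.0 / pooled.sum()
        pooled_comp = {
            name: float(v) for name, v in zip(names, pooled) if v > 0
        }
        out.fa_means = {g: dict(pooled_comp) for g in out.groups}
    return out
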