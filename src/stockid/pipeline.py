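"""Orchestration of the morphometric and fatty-acid pipeline branches.

Each branch reproduces the full analysis chain on one table of specimens:

morphometric: log-log regression vs total length -> residual outlier screen
-> ANCOVA common slopes -> allometric size adjustment -> two-way MANOVA ->
dimorphism filter -> meristic boxplot screen + PERMANOVA -> stratified
subsampling -> stepwise Mahalanobis MDA -> LOOCV -> Press's Q -> potency ->
score-vs-length independence check.

fatty acid: percentage closure -> arcsine transform -> phospholipid variable
rules -> two-way MANOVA (Wilks) -> stratified subsampling -> stepwise MDA ->
LOOCV -> Press's Q -> potency, plus a lipid-class summary table.

A single seed fans out to named substreams (synthesis, subsample,
permutation) so stages can be re-run independently, and every specimen
excluded anywhere appears exactly once in the exclusion log with a
machine-readable reason code. Reports are byte-deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._exceptions import ConfigurationError, SchemaError
from .allometry import (
    SizeAdjuster,
    flag_outliers_boxplot,
    flag_outliers_regression,
    regress_on_length,
)
from .discriminant import (
    StepwiseDiscriminantAnalysis,
    loocv_confusion,
    press_q,
    score_size_independence,
    stratified_subsample,
)
from .fatty_acids import arcsine_transform, class_sums, normalize_percent, \
    select_fa_for_mda, is_parseable
from .io import read_fatty_acid_csv, read_specimen_csv, write_report
from .screening import manova_two_way, per_variable_F, permanova_two_way, \
    select_nondimorphic
from .synthetic import (
    METADATA_COLUMNS,
    SyntheticConfig,
    generate_fatty_acids,
    generate_morphometrics,
)

__all__ = [
    "PipelineConfig",
    "run_morphometric_pipeline",
    "run_fatty_acid_pipeline",
]

_SUBSTREAMS = {"synthesis": 0, "subsample": 1, "permutation": 2}


def substream_seed(seed: int, name: str) -> int:
    """Stable child seed (< 2**31) for a named stochastic stage."""
    child = np.random.SeedSequence([int(seed), _SUBSTREAMS[name]])
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``input_path``/``fa_input_path`` (CSV) or ``synthetic`` (a
    :class:`SyntheticConfig`) supplies the data. ``seed`` is mandatory: every
    stochastic stage draws from a named substream of it.
    """

    seed: int
    branch: str = "both"  # morphometric | fatty_acid | both
    input_path: str | None = None
    fa_input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    characters: list[str] | None = None
    meristics: list[str] | None = None
    alpha: float = 0.05
    outlier_sd: float = 3.0
    outlier_iqr_k: float = 3.0
    f_enter: float = 3.84
    f_remove: float = 2.71
    n_perm: int = 999
    subsample_targets: dict | None = None
    outdir: str | None = None

    def __post_init__(self):
        if self.branch not in {"morphometric", "fatty_acid", "both"}:
            raise ConfigurationError(f"invalid branch {self.branch!r}")
        for name in ("alpha", "outlier_sd", "outlier_iqr_k", "f_enter",
                     "f_remove"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SyntheticConfig.from_dict(syn)
        return cfg


def _default_targets(sizes: pd.Series) -> dict:
    """Reduce the largest group to the size of the runner-up."""
    if len(sizes) < 2:
        return {}
    ranked = sizes.sort_values(ascending=False)
    if ranked.iloc[0] > ranked.iloc[1]:
        return {ranked.index[0]: int(ranked.iloc[1])}
    return {}


def _load_specimens(config: PipelineConfig) -> pd.DataFrame:
    if config.input_path is not None:
        return read_specimen_csv(
            config.input_path, meristic_columns=config.meristics
        )
    if config.synthetic is None:
        raise ConfigurationError("no input_path and no synthetic config")
    syn = config.synthetic.copy()
    syn.seed = substream_seed(config.seed, "synthesis")
    return generate_morphometrics(syn)


def _split_columns(table: pd.DataFrame, config: PipelineConfig):
    if config.synthetic is not None:
        chars = config.characters or config.synthetic.characters
        mers = config.meristics or config.synthetic.meristics
    else:
        chars = config.characters
        mers = config.meristics or []
        if chars is None:
            chars = [
                c for c in table.columns
                if c not in METADATA_COLUMNS and c not in mers
            ]
    missing = [c for c in [*chars, *mers] if c not in table.columns]
    if missing:
        raise SchemaError(f"input table lacks columns: {missing}")
    return list(chars), list(mers)


def run_morphometric_pipeline(config: PipelineConfig) -> dict:
    """Execute the morphometric/meristic branch; returns the report bundle."""
    table = _load_specimens(config)
    chars, mers = _split_columns(table, config)
    exclusions: list[dict] = []

    # -- outlier screen on raw log-log regressions vs TL ------------------
    lengths = table["TL_mm"].to_numpy(float)
    resid = {}
    for char in chars:
        reg = regress_on_length(table[char], lengths, character=char)
        resid[char] = (
            np.log(table[char].to_numpy(float))
            - (reg.intercept + reg.slope * np.log(lengths))
        )
    flags, flag_detail = flag_outliers_regression(
        pd.DataFrame(resid, index=table.index), threshold=config.outlier_sd
    )
    for idx in table.index[flags]:
        exclusions.append({
            "specimen_id": table.loc[idx, "specimen_id"],
            "stage": "morphometric",
            "reason": "outlier_regression_residual",
        })
    clean = table.loc[~flags].reset_index(drop=True)

    # -- allometric size adjustment ---------------------------------------
    adjuster = SizeAdjuster(length_col="TL_mm", alpha=config.alpha)
    char_table = clean[["TL_mm", *chars]]
    adjuster.fit(char_table, clean["group"])
    adjusted = adjuster.transform(char_table)

    # -- MANOVA and dimorphism filter -------------------------------------
    manova = manova_two_way(adjusted, clean["group"], clean["sex"])
    sex_f = per_variable_F(adjusted, clean["sex"], clean["group"])
    retained, removed = select_nondimorphic(sex_f, alpha=config.alpha)

    # -- meristic branch ---------------------------------------------------
    permanova = None
    meristic_flags = None
    if mers:
        counts = table[mers]
        mflags, _ = flag_outliers_boxplot(counts, k=config.outlier_iqr_k)
        for idx in table.index[mflags]:
            exclusions.append({
                "specimen_id": table.loc[idx, "specimen_id"],
                "stage": "meristic",
                "reason": "outlier_boxplot",
            })
        kept = table.loc[~mflags]
        permanova = permanova_two_way(
            kept[mers], kept["group"], kept["sex"],
            n_perm=config.n_perm,
            seed=substream_seed(config.seed, "permutation"),
        )
        meristic_flags = mflags

    # -- stratified subsampling and stepwise MDA --------------------------
    sizes = clean.groupby("group").size()
    targets = (
        config.subsample_targets
        if config.subsample_targets is not None
        else _default_targets(sizes)
    )
    sub = stratified_subsample(
        clean, group_col="group", strata_cols=("river", "sex"),
        targets=targets, seed=substream_seed(config.seed, "subsample"),
    )
    sub_adjusted = adjusted.loc[sub.index, retained]
    mda = StepwiseDiscriminantAnalysis(
        f_enter=config.f_enter, f_remove=config.f_remove
    ).fit(sub_adjusted, sub["group"])

    bundle: dict = {
        "regressions": adjuster.regressions_,
        "ancova": adjuster.ancova_,
        "adjusted": adjusted.join(clean[["specimen_id", "group", "sex"]]),
        "manova": _manova_frame(manova),
        "sex_effects": sex_f,
        "dimorphism": {"retained": retained, "removed": removed},
        "permanova": _permanova_frame(permanova) if permanova else None,
        "subsample_ids": sub["specimen_id"].reset_index(drop=True),
        "selection_trace": mda.step_trace_.to_frame(),
        "exclusions": pd.DataFrame(
            exclusions, columns=["specimen_id", "stage", "reason"]
        ),
    }
    if not mda.selected_:
        bundle["model"] = None
        bundle["summary"] = {
            "note": "no discriminating variables",
            "selected": [],
            "n_subsample": int(len(sub)),
        }
        return _finalize(bundle, config)

    confusion = loocv_confusion(
        sub_adjusted.to_numpy(float)[:, mda.selected_idx_],
        sub["group"].to_numpy(),
    )
    q = press_q(confusion)
    independence = score_size_independence(
        mda.transform(sub_adjusted), sub["TL_mm"].to_numpy(float)
    )
    bundle.update({
        "model": _model_dict(mda),
        "confusion": confusion.counts,
        "press_q": vars(q),
        "size_independence": independence,
        "summary": _summary(mda, confusion, q, len(sub)),
    })
    return _finalize(bundle, config)


def run_fatty_acid_pipeline(config: PipelineConfig) -> dict:
    """Execute the fatty-acid branch; returns the report bundle."""
    if config.fa_input_path is not None:
        table = read_fatty_acid_csv(config.fa_input_path)
    elif config.synthetic is not None:
        syn = config.synthetic.copy()
        syn.seed = substream_seed(config.seed, "synthesis")
        table = generate_fatty_acids(syn)
    else:
        raise ConfigurationError("no fa_input_path and no synthetic config")
    meta = [c for c in ("specimen_id", "group", "river", "sex")
            if c in table.columns]
    fa_cols = [c for c in table.columns if c not in meta]
    profiles = normalize_percent(table[fa_cols])

    # -- lipid-class summary on per-group mean profiles --------------------
    parseable = [c for c in fa_cols if is_parseable(c)]
    group_means = profiles.groupby(table["group"]).mean()
    summary_rows = {
        g: vars(class_sums(group_means.loc[g, parseable]))
        for g in group_means.index
    }
    class_summary = pd.DataFrame(summary_rows)

    # -- variable rules and MANOVA ----------------------------------------
    selected_fas = select_fa_for_mda(profiles)
    transformed = arcsine_transform(profiles[selected_fas])
    manova = manova_two_way(transformed, table["group"], table["sex"])

    # -- subsample + stepwise MDA ------------------------------------------
    sizes = table.groupby("group").size()
    targets = (
        config.subsample_targets
        if config.subsample_targets is not None
        else _default_targets(sizes)
    )
    sub = stratified_subsample(
        table, group_col="group", strata_cols=("river", "sex"),
        targets=targets, seed=substream_seed(config.seed, "subsample"),
    )
    sub_X = transformed.loc[sub.index]
    mda = StepwiseDiscriminantAnalysis(
        f_enter=config.f_enter, f_remove=config.f_remove
    ).fit(sub_X, sub["group"])

    bundle: dict = {
        "profiles": pd.concat([table[meta], profiles], axis=1),
        "class_summary": class_summary,
        "fa_variables": {"selected_for_mda": selected_fas},
        "manova": _manova_frame(manova),
        "subsample_ids": sub["specimen_id"].reset_index(drop=True),
        "selection_trace": mda.step_trace_.to_frame(),
        "exclusions": pd.DataFrame(
            [], columns=["specimen_id", "stage", "reason"]
        ),
    }
    if not mda.selected_:
        bundle["model"] = None
        bundle["summary"] = {
            "note": "no discriminating variables",
            "selected": [],
            "n_subsample": int(len(sub)),
        }
        return _finalize(bundle, config)

    confusion = loocv_confusion(
        sub_X.to_numpy(float)[:, mda.selected_idx_], sub["group"].to_numpy()
    )
    q = press_q(confusion)
    bundle.update({
        "model": _model_dict(mda),
        "confusion": confusion.counts,
        "press_q": vars(q),
        "summary": _summary(mda, confusion, q, len(sub)),
    })
    return _finalize(bundle, config)


# ---------------------------------------------------------------------------
# report shaping
# ---------------------------------------------------------------------------

def _manova_frame(results: dict) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results.values()]).set_index(
        "effect"
    )


def _permanova_frame(results: dict) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results.values()]).set_index("term")


def _model_dict(mda: StepwiseDiscriminantAnalysis) -> dict:
    return {
        "variables": [str(v) for v in mda.selected_],
        "eigenvalues": mda.eigenvalues_.tolist(),
        "variance_shares": mda.explained_variance_ratio_.tolist(),
        "coefficients": mda.scalings_.tolist(),
        "centroids": mda.centroids_.tolist(),
        "loadings": mda.loadings_.tolist(),
        "potency_index": mda.potency_index_.tolist(),
        "wilks_lambda": mda.wilks_lambda_,
        "chi2": mda.chi2_,
        "chi2_df": mda.chi2_df_,
        "chi2_p": mda.chi2_p_,
        "classes": [str(c) for c in mda.classes_],
        "priors": "equal",
    }


def _summary(mda, confusion, q, n_sub) -> dict:
    return {
        "selected": [str(v) for v in mda.selected_],
        "n_subsample": int(n_sub),
        "overall_percent_correct": round(confusion.overall_percent, 1),
        "per_group_percent_correct": {
            str(g): round(float(v), 1)
            for g, v in confusion.percent_correct.items()
        },
        "press_q": round(q.q, 3),
        "press_q_p": q.p_value,
        "wilks_lambda": round(mda.wilks_lambda_, 3),
    }


def _finalize(bundle: dict, config: PipelineConfig) -> dict:
    if config.outdir is not None:
        write_report(bundle, Path(config.outdir))
    return bundle
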