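"""End-to-end orchestration: per-cohort fits, pooling, scans and subgroup tables.

``run_full_analysis`` takes a list of cohorts and produces the full result
bundle: cohort-level substitution/score/interaction estimates on reporting
scales, random- and fixed-effect pooled results for every estimate, the
per-SNP interaction scan, and the energy-balance × score-level protein
intake table — plus a manifest (config hash, seed, package version) so a
run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import Cohort
from .diet import (DesignSpec, DesignError, assemble_design, interaction_column_name,
                   substitution_column_name)
from .inference import FitError, fit_linear, rescale_effect
from .longitudinal import protein_by_subgroup
from .meta import MetaResult, StudyEstimate, pool_fixed, pool_random_dl, se_from_ci
from .panel import SCORE_TYPES, SnpDefinition, build_score, split_at_mean
from .scan import scan_snps

log = logging.getLogger(__name__)

_UNIT = {"dBW": "g/y", "dWC": "mm/y"}


@dataclass(frozen=True)
class RunConfig:
    """What the pipeline runs and where results land."""

    outcomes: tuple[str, ...] = ("dBW", "dWC")
    replaced: tuple[str, ...] = ("carbohydrate", "fat")
    score_types: tuple[str, ...] = SCORE_TYPES
    adjust_age: bool = False
    adjust_followup: bool = False
    include_scan: bool = True
    include_subgroups: bool = True
    seed: int | None = None
    outdir: str | None = None


def fit_cohort_models(cohort: Cohort, defs: list[SnpDefinition], cfg: RunConfig) -> pd.DataFrame:
    """All substitution / score / interaction fits for one cohort, reporting scale."""
    scores = {t: build_score(cohort.genotypes, defs, t) for t in cfg.score_types}
    rows = []
    for outcome in cfg.outcomes:
        if outcome == "dWC" and not cohort.has_waist():
            log.info("%s: no waist data, skipping dWC models", cohort.name)
            continue
        unit = _UNIT[outcome]
        for repl in cfg.replaced:
            sub_col = substitution_column_name(repl)
            int_col = interaction_column_name(repl)
            base = dict(replaced=repl, parameterization="substitution", outcome=outcome,
                        adjust_age=cfg.adjust_age, adjust_followup=cfg.adjust_followup)
            spec = DesignSpec(**base)
            X, y, info = assemble_design(cohort.pheno, spec)
            fits = fit_linear(X, y)
            rows.append(_row(cohort.name, outcome, repl, None, "substitution",
                             rescale_effect(fits[sub_col], outcome_unit=unit), info))
            for st in cfg.score_types:
                spec_i = DesignSpec(score_type=st, **base)
                try:
                    X, y, info = assemble_design(cohort.pheno, spec_i, score=scores[st])
                    fits = fit_linear(X, y)
                except (DesignError, FitError) as exc:
                    log.warning("%s %s/%s/%s failed: %s", cohort.name, outcome, repl, st, exc)
                    continue
                rows.append(_row(cohort.name, outcome, repl, st, "substitution",
                                 rescale_effect(fits[sub_col], outcome_unit=unit), info))
                rows.append(_row(cohort.name, outcome, repl, st, "score",
                                 rescale_effect(fits["score"], per_e_pct=1.0, outcome_unit=unit,
                                                label=f"per risk allele [{unit}]"), info))
                rows.append(_row(cohort.name, outcome, repl, st, "interaction",
                                 rescale_effect(fits[int_col], outcome_unit=unit,
                                                label=f"per 5 E% per risk allele [{unit}]"), info))
    return pd.DataFrame(rows)


def _row(cohort, outcome, repl, score_type, term, f, info):
    return {"cohort": cohort, "outcome": outcome, "replaced": repl,
            "score_type": score_type if score_type is not None else "",
            "term": term, "beta": f.beta, "se": f.se, "lo": f.lo, "hi": f.hi,
            "p": f.p, "n": info["n_used"], "scale": f.scale}


def pool_fits(fits: pd.DataFrame) -> pd.DataFrame:
    """Fixed- and random-effects pooling of every estimate across cohorts."""
    rows = []
    for (outcome, repl, st, term), grp in fits.groupby(
            ["outcome", "replaced", "score_type", "term"], sort=True):
        studies = [StudyEstimate(label=r.cohort, beta=r.beta, se=r.se, n=int(r.n))
                   for r in grp.itertuples()]
        for res in (pool_fixed(studies), pool_random_dl(studies)):
            rows.append({"outcome": outcome, "replaced": repl, "score_type": st,
                         "term": term, "model": res.model, "beta": res.beta,
                         "se": res.se, "lo": res.lo, "hi": res.hi,
                         "Q": res.Q, "df": res.df, "p_Q": res.p_Q, "tau2": res.tau2,
                         "i2_pct": res.i2_pct, "band": res.band,
                         "n_total": int(grp["n"].sum()), "k": len(studies),
                         "weights_pct": ";".join(f"{s.label}={res.weights_pct[s.label]:.2f}"
                                                  for s in studies)})
    return pd.DataFrame(rows)


def pool_estimates(est: pd.DataFrame, model: str = "random") -> dict[tuple, MetaResult]:
    """Meta-only entry point: pool a bare estimates table (label, beta, lo/hi or se).

    Rows are grouped by (outcome, replaced) when those columns are present;
    otherwise everything is pooled together under the key ``("all", "all")``.
    """
    pooler = {"random": pool_random_dl, "fixed": pool_fixed}[model]
    keys = [c for c in ("outcome", "replaced") if c in est.columns]
    groups = est.groupby(keys, sort=True) if keys else [(("all", "all"), est)]
    out = {}
    for key, grp in groups:
        key = key if isinstance(key, tuple) else (key,)
        studies = []
        for r in grp.itertuples():
            se = getattr(r, "se", None)
            if se is None or pd.isna(se):
                se = se_from_ci(r.lo, r.hi)
            studies.append(StudyEstimate(label=r.label, beta=r.beta, se=float(se),
                                         n=int(r.n) if hasattr(r, "n") and pd.notna(r.n) else None))
        out[key] = pooler(studies)
    return out


def subgroup_tables(cohorts: list[Cohort], defs: list[SnpDefinition]) -> pd.DataFrame:
    """Energy-balance × BMI-score-level protein intake, per cohort."""
    tables = []
    for c in cohorts:
        grp = split_at_mean(build_score(c.genotypes, defs, "BMI"))
        t = protein_by_subgroup(c.pheno, grp)
        t.insert(0, "cohort", c.name)
        tables.append(t)
    return pd.concat(tables, ignore_index=True)


def run_full_analysis(cohorts: list[Cohort], defs: list[SnpDefinition],
                      cfg: RunConfig = RunConfig()) -> dict:
    """Run every stage; optionally write TSVs plus a JSON manifest to cfg.outdir."""
    if not cohorts:
        raise ValueError("at least one cohort is required")
    fits = pd.concat([fit_cohort_models(c, defs, cfg) for c in cohorts], ignore_index=True)
    meta = pool_fits(fits)
    bundle = {"fits": fits, "meta": meta}
    if cfg.include_scan:
        scans = []
        for c in cohorts:
            for outcome in cfg.outcomes:
                if outcome == "dWC" and not c.has_waist():
                    continue
                for repl in cfg.replaced:
                    scans.append(scan_snps(c, defs, DesignSpec(
                        replaced=repl, outcome=outcome,
                        adjust_age=cfg.adjust_age, adjust_followup=cfg.adjust_followup)))
        bundle["scan"] = pd.concat(scans, ignore_index=True)
    if cfg.include_subgroups:
        bundle["subgroups"] = subgroup_tables(cohorts, defs)
    bundle["manifest"] = _manifest(cfg, cohorts)
    if cfg.outdir:
        _write_bundle(bundle, cfg.outdir)
    return bundle


def _manifest(cfg: RunConfig, cohorts: list[Cohort]) -> dict:
    cfg_dict = asdict(cfg)
    cfg_dict.pop("outdir", None)   # output location is not an analysis parameter
    digest = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()
    return {"version": __version__, "seed": cfg.seed, "config": cfg_dict,
            "config_sha256": digest,
            "cohorts": {c.name: int(c.n) for c in cohorts}}


def _write_bundle(bundle: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("fits", "meta", "scan", "subgroups"):
        if key in bundle:
            bundle[key].to_csv(outdir / f"{key}.tsv", sep="\t", index=False, float_format="%.10g")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)
        fh.write("\n")
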