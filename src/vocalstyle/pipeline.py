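"""End-to-end orchestration: data -> dominance style -> models -> report.

Runs the two-level analysis over one dataset directory: the three
individual-level Bayesian mixed models (given tolerance, received
tolerance, feeding proximity — each predicting log10 vocal rate) and the
species-level PGLS models (overall repertoire size and hierarchy-related
calls on the composite dominance-style index and mean group size, plus
three single-measure follow-ups).

All intermediate artifacts (rank tables, tolerance profiles, the
individual and species tables) are written alongside the results so every
reported number is recomputable from files, and a stage-granular exclusion
log records every filtered individual or species and why.  Reruns with the
same config and seed reproduce identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import tables, dominance, vocal, lmm, phylo
from .tables import ValidationError


@dataclass
class RunConfig:
    """Paths and analysis settings for one pipeline run."""

    data_dir: str
    out_dir: str
    seed: int = 0
    min_bouts: int = dominance.DEFAULT_MIN_BOUTS
    min_decided: int = dominance.DEFAULT_MIN_DECIDED
    min_scans: int = 10
    dii_mode: str = "pooled"
    ibi_seconds: float = vocal.DEFAULT_IBI_SECONDS
    min_focal_hours: float = vocal.DEFAULT_MIN_FOCAL_HOURS
    log_rate_offset: float = lmm.DEFAULT_LOG_OFFSET
    log_count_offset: float = phylo.DEFAULT_LOG_OFFSET
    pagel_lambda: float = 1.0
    n_iter: int = 13000
    burn_in: int = 3000
    thin: int = 10
    # optional taxon graft: (new_tip, sister_tip, divergence_myr)
    graft: Optional[tuple[str, str, float]] = None


@dataclass
class LoadedData:
    bouts: list
    scans: list
    sessions: list
    events: list
    groups: list
    repertoires: list
    tree: object


def load_data(data_dir: str | Path) -> LoadedData:
    """Load and validate one dataset directory (standard file names)."""
    d = Path(data_dir)
    sessions = tables.read_sessions(d / "sessions.csv")
    return LoadedData(
        bouts=tables.read_bouts(d / "bouts.csv"),
        scans=tables.read_scans(d / "scans.csv"),
        sessions=sessions,
        events=tables.read_vocal_events(d / "vocal_events.csv", sessions),
        groups=tables.read_group_meta(d / "groups.csv"),
        repertoires=tables.read_repertoires(d / "repertoires.csv"),
        tree=phylo.read_newick(d / "tree.nwk"))


# ---------------------------------------------------------------------------
# Individual level
# ---------------------------------------------------------------------------

def individual_table(data: LoadedData, cfg: RunConfig,
                     log: Optional[list[str]] = None) -> pd.DataFrame:
    """Per-individual derived variables for the mixed models.

    One row per focal individual with observation time: tolerance measures
    in both directions, feeding proximity, vocal rate and the 2-h inclusion
    flag.  Missing measures are NaN.  Also returns, via ``log``, every
    exclusion applied along the way.
    """
    log = log if log is not None else []
    meta = {g.group_id: g for g in data.groups}
    bouts_by_group: dict[str, list] = {}
    for b in data.bouts:
        bouts_by_group.setdefault(b.group_id, []).append(b)

    profiles: dict[str, dict[str, dominance.ToleranceProfile]] = {
        "given": {}, "received": {}, "all": {}}
    ranked_groups: dict[str, dominance.RankTable] = {}
    for group_id, gbouts in sorted(bouts_by_group.items()):
        try:
            w = dominance.build_win_matrix(gbouts, min_decided=cfg.min_decided)
        except ValidationError as exc:
            log.append(f"group {group_id}: no ranks ({exc})")
            continue
        all_inds = {b.aggressor_id for b in gbouts} | {b.victim_id for b in gbouts}
        for dropped in sorted(all_inds - set(w.individuals)):
            log.append(f"individual {dropped}: unranked "
                       f"(< {cfg.min_decided} decided bouts)")
        ranks = dominance.modified_davids_score(w)
        ranked_groups[group_id] = ranks
        ranked_bouts = [b for b in gbouts
                        if b.aggressor_id in set(w.individuals)
                        and b.victim_id in set(w.individuals)]
        for direction in ("given", "received", "all"):
            profiles[direction][group_id] = dominance.tolerance_profile(
                ranked_bouts, ranks, direction,  # type: ignore[arg-type]
                min_bouts=cfg.min_bouts, dii_mode=cfg.dii_mode)  # type: ignore[arg-type]

    scans_by_group: dict[str, list] = {}
    for s in data.scans:
        scans_by_group.setdefault(s.group_id, []).append(s)

    focals = sorted({s.focal_id for s in data.sessions})
    rows = []
    for focal in focals:
        rec = vocal.vocal_rate(data.events, data.sessions, focal,
                               ibi=cfg.ibi_seconds,
                               min_focal_hours=cfg.min_focal_hours)
        group_id = rec.group_id
        if group_id not in meta:
            raise ValidationError(f"group {group_id} missing from metadata")
        if not rec.included:
            log.append(f"individual {focal}: excluded from models "
                       f"({rec.obs_hours:.2f} h focal time < "
                       f"{cfg.min_focal_hours} h minimum)")
        row = {"focal_id": focal, "group_id": group_id,
               "species_id": meta[group_id].species_id,
               "group_size": meta[group_id].group_size,
               "n_bouts": rec.n_bouts, "obs_hours": rec.obs_hours,
               "rate": rec.rate, "included": rec.included}
        for direction in ("given", "received", "all"):
            prof = profiles[direction].get(group_id, {}).get(focal)
            suffix = {"given": "_given", "received": "_received", "all": ""}[direction]
            row[f"dii{suffix}"] = prof.dii if prof else None
            row[f"counter{suffix}"] = prof.counter_pct if prof else None
            row[f"intensity{suffix}"] = prof.intensity_pct if prof else None
        row["feeding_prox"] = dominance.feeding_proximity(
            scans_by_group.get(group_id, []), focal, min_scans=cfg.min_scans)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["rank_tables"] = ranked_groups
    df.attrs["profiles"] = profiles
    return df


_MODEL_PREDICTORS = {
    "given": ["dii_given", "counter_given", "intensity_given", "group_size"],
    "received": ["dii_received", "counter_received", "intensity_received",
                 "group_size"],
    "feeding": ["feeding_prox", "group_size"],
}
_MODEL_LABELS = {
    "given": ["intercept", "aggression_symmetry", "counteraggression",
              "aggression_intensity", "group_size"],
    "received": ["intercept", "aggression_symmetry", "counteraggression",
                 "aggression_intensity", "group_size"],
    "feeding": ["intercept", "feeding_proximity", "group_size"],
}


def fit_individual_model(df: pd.DataFrame, model: str, cfg: RunConfig,
                         log: Optional[list[str]] = None,
                         ) -> tuple[lmm.PosteriorResult, pd.DataFrame]:
    """Fit one of the three individual-level models on the complete rows."""
    log = log if log is not None else []
    preds = _MODEL_PREDICTORS[model]
    usable = df[df["included"]].dropna(subset=preds).copy()
    n_dropped = int(df["included"].sum()) - len(usable)
    if n_dropped:
        log.append(f"model {model}: {n_dropped} included individuals dropped "
                   f"for missing predictor values")
    n_species = usable["species_id"].nunique()
    if n_species < 2:
        raise ValidationError(
            f"model {model}: {n_species} species after exclusions (need >= 2)")
    y = lmm.prepare_response(
        [vocal.VocalRateRecord(r.focal_id, r.group_id, r.n_bouts,
                               r.obs_hours, r.rate, r.included)
         for r in usable.itertuples()], offset=cfg.log_rate_offset)
    X = np.column_stack([np.ones(len(usable))]
                        + [usable[p].to_numpy(dtype=float) for p in preds])
    sp_codes = pd.Categorical(usable["species_id"]).codes
    grp_codes = pd.Categorical(
        usable["species_id"].astype(str) + "/" + usable["group_id"].astype(str)).codes
    seed = (cfg.seed * 7919 + {"given": 1, "received": 2, "feeding": 3}[model]) % (2**31)
    result = lmm.fit_lmm(
        y, X, _MODEL_LABELS[model], sp_codes, grp_codes,
        chain=lmm.ChainConfig(n_iter=cfg.n_iter, burn_in=cfg.burn_in,
                              thin=cfg.thin, seed=seed))
    log.append(f"model {model}: n={len(usable)} individuals, "
               f"{usable['group_id'].nunique()} groups, {n_species} species")
    return result, usable


def run_individual(data: LoadedData, cfg: RunConfig,
                   log: Optional[list[str]] = None,
                   ) -> dict[str, lmm.PosteriorResult]:
    """All three individual-level models; writes coefficient tables."""
    log = log if log is not None else []
    df = individual_table(data, cfg, log)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "individual_table.csv", index=False)

    results = {}
    partitions = []
    for model in ("given", "received", "feeding"):
        result, used = fit_individual_model(df, model, cfg, log)
        results[model] = result
        coef = pd.DataFrame(
            [{"variable": f.name, "posterior_mean": f.posterior_mean,
              "l95_ci": f.ci_lower, "u95_ci": f.ci_upper, "pMCMC": f.pmcmc}
             for f in result.fixed])
        coef["n_individuals"] = len(used)
        coef["n_groups"] = used["group_id"].nunique()
        coef["n_species"] = used["species_id"].nunique()
        coef.to_csv(out / f"lmm_{model}.csv", index=False)
        np.savetxt(out / f"lmm_{model}_draws.csv", result.beta_draws,
                   delimiter=",", header=",".join(result.fixed_names),
                   comments="")
        partitions.append({"model": model, **result.variance_partition})
    pd.DataFrame(partitions).to_csv(out / "variance_partition.csv", index=False)
    return results


# ---------------------------------------------------------------------------
# Species level
# ---------------------------------------------------------------------------

def run_species(data: LoadedData, cfg: RunConfig,
                log: Optional[list[str]] = None,
                indiv_df: Optional[pd.DataFrame] = None,
                ) -> dict[str, phylo.PglsResult]:
    """Composite index, species table and the five PGLS models."""
    log = log if log is not None else []
    if indiv_df is None:
        indiv_df = individual_table(data, cfg, log)
    profiles_all = indiv_df.attrs["profiles"]["all"]
    profiles_by_group = {g: list(p.values()) for g, p in profiles_all.items()}
    indices = dominance.composite_index(profiles_by_group, data.groups, log)
    if len(indices) < 3:
        raise ValidationError("species-level models need >= 3 species")

    tree = data.tree
    if cfg.graft is not None:
        new_tip, sister, divergence = cfg.graft
        tree = phylo.graft_taxon(tree, new_tip, sister, divergence)
        log.append(f"grafted {new_tip} sister to {sister} at {divergence} Myr")

    table = phylo.species_table(indices, data.repertoires, data.groups,
                                log_offset=cfg.log_count_offset, log=log)
    in_tree = set(phylo.tip_labels(tree))
    missing = [sp for sp in table.index if sp not in in_tree]
    if missing:
        raise ValidationError(f"species not in tree and not grafted: {missing}")

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([asdict(s) for s in indices]).to_csv(
        out / "composite_index.csv", index=False)
    table.to_csv(out / "species_table.csv")

    species = list(table.index)
    cov = phylo.phylo_covariance(tree, species, lam=cfg.pagel_lambda)
    results = {}
    specs = {
        "total_repertoire": ("log_total_calls", ["composite", "group_size"]),
        "hierarchy_calls": ("log_hierarchy_calls", ["composite", "group_size"]),
        "hierarchy_on_dii": ("log_hierarchy_calls", ["mean_dii", "group_size"]),
        "hierarchy_on_counter": ("log_hierarchy_calls",
                                 ["mean_counter", "group_size"]),
        "hierarchy_on_intensity": ("log_hierarchy_calls",
                                   ["mean_intensity", "group_size"]),
    }
    for name, (resp, preds) in specs.items():
        y = table[resp].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(table))]
                            + [table[p].to_numpy(dtype=float) for p in preds])
        res = phylo.pgls_fit(y, X, cov, names=["intercept"] + preds)
        results[name] = res
        pd.DataFrame({"variable": res.names, "beta": res.beta, "se": res.se,
                      "t": res.t, "p": res.p}).assign(n=res.n).to_csv(
            out / f"pgls_{name}.csv", index=False)
        log.append(f"pgls {name}: n={res.n} species")
    return results


# ---------------------------------------------------------------------------
# Full run and report
# ---------------------------------------------------------------------------

def run_all(cfg: RunConfig) -> dict:
    """validate -> individual models -> species models -> report."""
    log: list[str] = []
    data = load_data(cfg.data_dir)
    indiv = run_individual(data, cfg, log)
    species = run_species(data, cfg, log)
    out = Path(cfg.out_dir)
    (out / "exclusions.log").write_text("\n".join(log) + "\n")
    (out / "run_config.json").write_text(json.dumps(asdict(cfg), indent=1))
    report(cfg.out_dir)
    return {"individual": indiv, "species": species, "log": log}


def report(out_dir: str | Path) -> str:
    """Assemble a human-readable summary from the emitted artifacts."""
    out = Path(out_dir)
    if not out.exists() or not (out / "composite_index.csv").exists():
        raise ValidationError(f"{out}: no completed run to report on")
    lines = ["Dominance style and vocal communication — run summary", ""]

    comp = pd.read_csv(out / "composite_index.csv").sort_values(
        "composite", ascending=False)
    lines.append("Species composite dominance-style index "
                 "(positive = tolerant):")
    for r in comp.itertuples():
        lines.append(f"  {r.species_id:>10s}  {r.composite:+.3f}")
    lines.append("")

    for model in ("given", "received", "feeding"):
        path = out / f"lmm_{model}.csv"
        if not path.exists():
            continue
        coef = pd.read_csv(path)
        lines.append(f"Individual-level model ({model} tolerance), "
                     f"n={coef['n_individuals'].iloc[0]} individuals, "
                     f"{coef['n_groups'].iloc[0]} groups, "
                     f"{coef['n_species'].iloc[0]} species:")
        lines.append(f"  {'variable':<22s}{'post.mean':>10s}{'l95':>9s}"
                     f"{'u95':>9s}{'pMCMC':>8s}")
        for r in coef.itertuples():
            lines.append(f"  {r.variable:<22s}{r.posterior_mean:>10.3f}"
                         f"{r.l95_ci:>9.3f}{r.u95_ci:>9.3f}{r.pMCMC:>8.3f}")
        lines.append("")

    vp = pd.read_csv(out / "variance_partition.csv")
    lines.append("Variance partition (share of total):")
    for r in vp.itertuples():
        lines.append(f"  {r.model:<10s} fixed {r.fixed:.2f}  species "
                     f"{r.species:.2f}  group {r.group:.2f}  "
                     f"residual {r.residual:.2f}")
    lines.append("")

    for name in ("total_repertoire", "hierarchy_calls", "hierarchy_on_dii",
                 "hierarchy_on_counter", "hierarchy_on_intensity"):
        path = out / f"pgls_{name}.csv"
        if not path.exists():
            continue
        coef = pd.read_csv(path)
        lines.append(f"Species-level PGLS ({name}), n={coef['n'].iloc[0]}:")
        for r in coef.itertuples():
            lines.append(f"  {r.variable:<22s}beta {r.beta:>8.3f}  "
                         f"se {r.se:>7.3f}  p {r.p:>7.3f}")
        lines.append("")

    st = pd.read_csv(out / "species_table.csv")
    lines.append("Hierarchy calls vs composite index (scatter data):")
    for r in st.itertuples():
        lines.append(f"  {r.species_id:>10s}  composite {r.composite:+.3f}  "
                     f"hierarchy_calls {r.hierarchy_calls}")
    text = "\n".join(lines) + "\n"
    (out / "summary.txt").write_text(text)
    return text
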