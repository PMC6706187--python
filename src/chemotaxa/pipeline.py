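"""End-to-end orchestration of the cryptic-species analysis.

Runs preprocess -> chemical network -> compositional statistics ->
morphometrics -> population genetics -> environmental association on either
a simulated study (a :class:`~chemotaxa.synthetic.ScenarioConfig`) or
user-supplied files, and emits a machine-readable JSON manifest (stable key
ordering, stamped with the config hash and seed) plus a plain-text report.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import chemnet, compstats, ecoassoc, morpho, popgen, preprocess
from .synthetic import (
    ScenarioConfig,
    gen_chc_profiles,
    gen_coi_alignment,
    gen_env_table,
    gen_morphometrics,
)

log = logging.getLogger("chemotaxa")


@dataclass
class PipelineConfig:
    """Inputs and per-stage parameters for one pipeline run.

    Either ``scenario`` (simulate mode) or ``inputs`` (paths to peak table,
    annotation, sample metadata, FASTA, popmap, morphometrics and
    environment files) must be given.
    """

    scenario: ScenarioConfig | None = None
    inputs: dict[str, str] | None = None
    min_mean: float = 0.001
    min_presence: float = 0.20
    n_perm: int = 199
    mantel_perm: int = 199
    fst_perm: int = 199
    n_boot: int = 100
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.inputs is None):
            raise ValueError("give exactly one of scenario (simulate) or inputs")

    def seed_for(self, stage: str) -> int:
        base = self.scenario.seed if self.scenario is not None else 0
        import zlib

        return int(
            np.random.SeedSequence([base, zlib.crc32(stage.encode())]).generate_state(1)[0]
            & 0x7FFFFFFF
        )

    def config_hash(self) -> str:
        payload = {
            "scenario": self.scenario.to_dict() if self.scenario else None,
            "inputs": self.inputs,
            "min_mean": self.min_mean,
            "min_presence": self.min_presence,
            "n_perm": self.n_perm,
            "mantel_perm": self.mantel_perm,
            "fst_perm": self.fst_perm,
            "n_boot": self.n_boot,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _jsonable(x):
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return None if not np.isfinite(v) else v
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (pd.Series,)):
        return {str(k): _jsonable(v) for k, v in x.items()}
    return x


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                raise StageError(f"stage {name!r} failed: {e}") from e

        wrapper.__name__ = fn.__name__
        return wrapper

    return deco


@_stage("load")
def _load_inputs(cfg: PipelineConfig):
    if cfg.scenario is not None:
        pt = gen_chc_profiles(cfg.scenario)
        aln, popmap = gen_coi_alignment(cfg.scenario)
        mt = gen_morphometrics(cfg.scenario)
        env = gen_env_table(cfg.scenario)
        return pt, aln, popmap, mt, env
    paths = cfg.inputs
    for key in ("peaks", "annotations", "alignment", "popmap", "morphometrics",
                "environment"):
        if key not in paths:
            raise ValueError(f"missing input path {key!r}")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"input file not found: {paths[key]}")
    pt = preprocess.PeakTable.read(
        paths["peaks"], paths["annotations"], paths.get("sample_meta")
    )
    aln = popgen.Alignment.from_fasta(paths["alignment"])
    popmap = pd.read_csv(paths["popmap"], index_col="sample")
    mt = morpho.MorphTable.read_csv(paths["morphometrics"])
    env = pd.read_csv(paths["environment"], index_col="colony")
    return pt, aln, popmap, mt, env


@_stage("preprocess")
def _run_preprocess(cfg: PipelineConfig, pt, groups):
    filtered, report = preprocess.filter_substances(
        pt, groups, min_mean=cfg.min_mean, min_presence=cfg.min_presence
    )
    log.info(
        "filtering: dropped %d substances by the %.3g%%/%.0f%% rule",
        len(report), 100 * cfg.min_mean, 100 * cfg.min_presence,
    )
    cm = preprocess.normalize_closure(filtered)
    agg = preprocess.aggregate_by_class(cm)
    return filtered, report, cm, agg


@_stage("chemnet")
def _run_chemnet(cfg: PipelineConfig, cm, truth):
    net, pca, seqs = chemnet.network_from_composition(cm)
    split = chemnet.cut_longest_mst_edge(net)
    ari = float(
        adjusted_rand_score(truth.loc[split.index], split)
    ) if truth is not None else None
    retained, ks = chemnet.axis_categories(pca.eigen_pct)
    return {
        "n_chemical_types": len(net.types),
        "n_singletons": sum(t.is_singleton for t in net.types),
        "retained_axes": [int(a + 1) for a in retained],
        "categories_per_axis": [int(k) for k in ks],
        "explained_variance_pct": [round(float(pca.eigen_pct[a]), 4) for a in retained],
        "split_ari_vs_truth": ari,
    }, net


@_stage("compstats")
def _run_compstats(cfg: PipelineConfig, cm, agg, groups, meta):
    class_table = compstats.jitter_zero_classes(
        agg.class_totals, seed=cfg.seed_for("jitter")
    )
    d_class = compstats.bray_curtis(class_table)
    f_all, p_all = compstats.permanova(
        d_class, groups, n_perm=cfg.n_perm, seed=cfg.seed_for("permanova")
    )
    per_class = {}
    for i, klass in enumerate(class_table.columns):
        col = class_table[[klass]]
        if col.values.std() == 0:
            continue
        d_k = compstats.DistanceMatrix(
            list(col.index),
            np.abs(col.values - col.values.T),
        )
        f_k, p_k = compstats.permanova(
            d_k, groups, n_perm=cfg.n_perm, seed=cfg.seed_for(f"permanova_{klass}")
        )
        name = klass if isinstance(klass, str) else str(klass)
        per_class[name] = {"pseudo_F": round(f_k, 4), "p": p_k}
    mantel_geo = {}
    if meta is not None and {"lon", "lat"} <= set(meta.columns):
        d_chc = compstats.bray_curtis(cm.proportions)
        for grp in pd.unique(groups):
            ids = [i for i in cm.sample_ids if groups.loc[i] == grp]
            coords = meta.loc[ids, ["lon", "lat"]]
            r, p = compstats.mantel(
                d_chc.subset(ids),
                compstats.geo_distance(coords),
                n_perm=cfg.mantel_perm,
                seed=cfg.seed_for(f"mantel_{grp}"),
            )
            mantel_geo[str(grp)] = {"r": round(r, 4), "p": p}
    return {
        "class_permanova": {"pseudo_F": round(f_all, 4), "p": p_all},
        "per_class_permanova": per_class,
        "mantel_chc_vs_geography": mantel_geo,
    }


@_stage("morpho")
def _run_morpho(cfg: PipelineConfig, mt):
    icc_report, mt_kept = morpho.icc_reliability(mt)
    values = mt_kept.values()
    species = mt_kept.labels("species")
    location = mt_kept.labels("location")
    shape = morpho.shape_pca(values)
    manova = morpho.two_group_manova(
        shape.shape_scores.iloc[:, :2], species, location
    )
    size = shape.iso_size
    t, df, p = morpho.welch_t(
        size[species == species.unique()[0]], size[species == species.unique()[1]]
    )
    spectrum = morpho.pca_ratio_spectrum(
        shape, values, axis=0, n_boot=cfg.n_boot, seed=cfg.seed_for("ratio_boot")
    )
    return {
        "n_variables_kept": int(icc_report["keep"].sum()),
        "n_variables_dropped": int((~icc_report["keep"]).sum()),
        "icc_min": round(float(icc_report["icc"].min()), 4),
        "shape_pc1_pct": round(float(shape.eigen_pct[0]), 4),
        "shape_pc2_pct": round(float(shape.eigen_pct[1]), 4),
        "manova": {
            f: {
                "pillai": round(float(manova.loc[f, "pillai"]), 4),
                "F": round(float(manova.loc[f, "F"]), 4),
                "p": float(manova.loc[f, "p"]),
            }
            for f in manova.index
        },
        "welch_size": {"t": round(t, 4), "df": round(df, 2), "p": p},
        "ratio_spectrum_extremes": [
            str(spectrum.index[0]),
            str(spectrum.index[-1]),
        ],
    }


@_stage("popgen")
def _run_popgen(cfg: PipelineConfig, aln, popmap):
    out: dict = {}
    hs_all = popgen.collapse_haplotypes(aln, popmap)
    net = popgen.haplotype_network(hs_all)
    out["n_haplotypes"] = hs_all.n_haplotypes
    species_of = popmap["species"]
    per_species: dict = {}
    for sp in pd.unique(species_of):
        ids = [i for i in aln.ids if species_of.loc[i] == sp]
        sub = aln.subset(ids)
        hs = popgen.collapse_haplotypes(sub, popmap.loc[ids])
        entry: dict = {"n_haplotypes": hs.n_haplotypes}
        pops = popmap.loc[ids, "population"]
        big_enough = pops.value_counts()
        if (big_enough >= 2).sum() >= 2:
            fst, pv = popgen.pairwise_fst(
                sub, popmap.loc[ids], n_perm=cfg.fst_perm,
                seed=cfg.seed_for(f"fst_{sp}"),
            )
            off = fst.values[np.triu_indices(len(fst), 1)]
            entry["fst_mean"] = round(float(np.nanmean(off)), 4)
            entry["fst_max"] = round(float(np.nanmax(off)), 4)
            entry["n_significant_pairs"] = int(
                (pv.values[np.triu_indices(len(pv), 1)] < 0.05).sum()
            )
        try:
            td = popgen.tajimas_d(sub)
            entry["tajimas_d"] = round(td["D"], 4)
            entry["tajimas_d_p"] = td["p"]
            entry["segregating_sites"] = int(td["S"])
        except ValueError:
            entry["tajimas_d"] = None
        per_species[str(sp)] = entry
    # between-species differentiation on the full alignment
    sp_map = popmap.copy()
    sp_map["population"] = sp_map["species"]
    fst_sp, _ = popgen.pairwise_fst(
        aln, sp_map, n_perm=1, seed=cfg.seed_for("fst_species")
    )
    vals = fst_sp.values[np.triu_indices(len(fst_sp), 1)]
    out["species_phist"] = round(float(vals[0]), 4)
    out["per_species"] = per_species
    return out, net


@_stage("ecoassoc")
def _run_ecoassoc(cfg: PipelineConfig, env):
    counts = pd.crosstab(env["partner"], env["species"])
    chi2, df, p = ecoassoc.contingency_chisq(counts)
    pca = ecoassoc.climate_pca(env)
    data = env.copy()
    data["climate_pc1"] = pca.scores["PC1"]
    plant_cols = [c for c in env.columns if c.startswith("plant_")]
    y = (env["species"] == sorted(env["species"].unique())[-1]).astype(int)
    terms = ["climate_pc1", "canopy", "partner", *plant_cols,
             "climate_pc1:canopy", "climate_pc1:partner"]
    full = ecoassoc.fit_binomial_glm(y, data, terms)
    trace: list = []
    final = ecoassoc.stepwise_aic(full, trace=trace)
    term_tests = {}
    for t in final.terms:
        reduced_terms = [x for x in final.terms if x != t]
        if t in ecoassoc._droppable(final.terms):
            reduced = ecoassoc.fit_binomial_glm(y, data, reduced_terms)
            c2, d, pv = ecoassoc.deviance_term_test(final, reduced)
            term_tests[t] = {"chi2": round(c2, 4), "df": d, "p": pv}
    return {
        "partner_association": {"chi2": round(chi2, 4), "df": df, "p": round(p, 4)},
        "climate_pc1_pct": round(float(pca.eigen_pct[0]), 4),
        "stepwise": {
            "initial_aic": round(full.aic, 4),
            "final_aic": round(final.aic, 4),
            "dropped": [s["dropped"] for s in trace],
            "final_terms": final.terms,
        },
        "term_tests": term_tests,
        "separation_flag": final.separation,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return (and optionally write) the manifest."""
    pt, aln, popmap, mt, env = _load_inputs(cfg)
    meta = pt.samples
    if meta is None or "chemotype" not in meta.columns:
        raise StageError("stage 'preprocess' failed: no chemotype labels available")
    groups = meta["chemotype"]
    filtered, report, cm, agg = _run_preprocess(cfg, pt, groups)
    chem, net = _run_chemnet(cfg, cm, groups)
    comp = _run_compstats(cfg, cm, agg, groups, meta)
    morph = _run_morpho(cfg, mt)
    pop, hapnet = _run_popgen(cfg, aln, popmap)
    eco = _run_ecoassoc(cfg, env)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.scenario.seed if cfg.scenario else None,
        "n_substances_input": len(pt.substances),
        "n_substances_retained": len(filtered.substances),
        "chemnet": chem,
        "compstats": comp,
        "morphometrics": morph,
        "popgen": pop,
        "ecoassoc": eco,
    }
    manifest = _jsonable(manifest)
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        net.node_table().to_csv(out / "chemnet_nodes.csv", index=False)
        net.edge_table().to_csv(out / "chemnet_edges.csv", index=False)
        hapnet.node_table().to_csv(out / "haplotype_nodes.csv", index=False)
        hapnet.edge_table().to_csv(out / "haplotype_edges.csv", index=False)
        report.to_csv(out / "filter_report.csv", index=False)
        (out / "report.txt").write_text(_text_report(manifest))
    return manifest


def _text_report(manifest: dict) -> str:
    lines = [
        "chemotaxa pipeline report",
        f"config hash: {manifest['config_hash']}  seed: {manifest['seed']}",
        "",
        f"substances: {manifest['n_substances_retained']} retained of "
        f"{manifest['n_substances_input']}",
        f"chemical types: {manifest['chemnet']['n_chemical_types']} "
        f"({manifest['chemnet']['n_singletons']} singletons); "
        f"split-vs-truth ARI: {manifest['chemnet']['split_ari_vs_truth']}",
        f"class PERMANOVA: pseudo-F = "
        f"{manifest['compstats']['class_permanova']['pseudo_F']}, "
        f"p = {manifest['compstats']['class_permanova']['p']}",
        f"shape PC1/PC2 %: {manifest['morphometrics']['shape_pc1_pct']} / "
        f"{manifest['morphometrics']['shape_pc2_pct']}",
        f"haplotypes: {manifest['popgen']['n_haplotypes']}; species PhiST: "
        f"{manifest['popgen']['species_phist']}",
        f"partner chi2: {manifest['ecoassoc']['partner_association']['chi2']} "
        f"(p = {manifest['ecoassoc']['partner_association']['p']})",
        "",
    ]
    return "\n".join(lines)
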