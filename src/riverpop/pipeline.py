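"""Config-driven orchestration of the full analysis battery.

A single YAML config names the inputs (aligned FASTA per marker, population
table, optional band phenotypes / geographic distances / clustering
likelihood table), the marker clock rates (%/site/Myr), generation time,
permutation counts and the master seed.  ``run_pipeline`` executes
sequence -> diversity -> AMOVA -> demography -> network (-> microsatellite)
-> spatial stages and writes one CSV per published-table shape plus a JSON
run log recording versions, per-stage seeds and parameters.

Per-stage RNG seeds are spawned from the master seed in a fixed order, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amova import HierarchicalDesign, amova, pairwise_phi_st
from .demography import (
    expansion_gof,
    expansion_time,
    fit_sudden_expansion,
    fs_pvalue,
    fus_fs_from_alignment,
    mismatch_observed,
)
from .diversity import build_nj_tree, k2p_matrix, per_population_report
from .msat import (
    BandPhenotypeMatrix,
    band_diversity,
    binary_fst,
    evanno_delta_k,
    nei_unbiased_distance,
    pcoa,
    phenotypes_to_binary,
)
from .network import export_network, median_joining
from .seqcore import (
    classify_sites,
    collapse_haplotypes,
    concatenate,
    pairwise_differences,
    read_fasta_alignment,
    read_population_table,
    write_haplotype_fasta,
)
from .spatial import mantel_ibd

__all__ = ["PipelineError", "load_config", "run_pipeline"]

_FLOAT_FORMAT = "%.10g"


class PipelineError(RuntimeError):
    """At least one pipeline stage failed; partial outputs are preserved."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("output_dir", "seed", "population_table", "markers"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
    cfg.setdefault("n_permutations", 1000)
    cfg.setdefault("gof_bootstrap", 100)
    cfg.setdefault("fs_simulations", 200)
    cfg.setdefault("generation_time", 10.0)
    return cfg


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format=_FLOAT_FORMAT, **kw)


def _analyse_marker(
    name: str,
    aln,
    pm,
    rate: float | None,
    cfg: dict,
    outdir: Path,
    seeds: dict[str, int],
    log: dict,
) -> None:
    nperm = int(cfg["n_permutations"])
    prefix = outdir / name
    ht = collapse_haplotypes(aln, pm)
    _write(ht.counts, f"{prefix}.haplotypes.csv", index_label="haplotype")
    write_haplotype_fasta(ht, f"{prefix}.haplotypes.fasta")
    classify_sites(aln).table.to_csv(f"{prefix}.sites.csv", index=False)
    _write(per_population_report(aln, pm), f"{prefix}.diversity.csv", index_label="population")

    diffs = pairwise_differences(aln)
    pops = tuple(pm.labels_for(aln.ids))
    regions = {p: pm.region_of_population(p) for p in set(pops)} if pm.region else None
    two_level = regions is not None and len(set(regions.values())) >= 2
    res = amova(
        diffs,
        HierarchicalDesign(pops, regions if two_level else None),
        n_perm=nperm,
        seed=seeds[f"{name}.amova"],
    )
    table, phi_rows = res.table()
    _write(table, f"{prefix}.amova.csv", index=False)
    _write(phi_rows, f"{prefix}.amova_phi.csv", index=False)
    phi_m, p_m, sig = pairwise_phi_st(
        diffs, pops, n_perm=nperm, seed=seeds[f"{name}.pairwise"]
    )
    _write(phi_m, f"{prefix}.pairwise_phist.csv")
    _write(p_m, f"{prefix}.pairwise_phist_p.csv")

    if ht.h >= 3:
        tree = build_nj_tree(k2p_matrix(ht.to_alignment()))
        Path(f"{prefix}.nj.nwk").write_text(tree.newick() + "\n")
    net = median_joining(ht) if ht.h >= 2 else None
    if net is not None:
        export_network(net, f"{prefix}.network.graphml", "graphml")
        export_network(net, f"{prefix}.network.edges.csv", "edgelist")

    obs = mismatch_observed(diffs)
    fit = fit_sudden_expansion(obs)
    fit = expansion_gof(
        obs, fit, B=int(cfg["gof_bootstrap"]), seed=seeds[f"{name}.gof"]
    )
    neut = fs_pvalue(
        fus_fs_from_alignment(aln),
        n_sim=int(cfg["fs_simulations"]),
        seed=seeds[f"{name}.fs"],
    )
    demo = {
        "tau": fit.tau,
        "theta0": fit.theta0,
        "theta1": fit.theta1,
        "SSD": fit.ssd,
        "P_SSD": fit.p_ssd,
        "raggedness": fit.raggedness,
        "P_raggedness": fit.p_raggedness,
        "Fs": neut.fs,
        "P_Fs": neut.p_value,
    }
    if rate is not None:
        timing = expansion_time(
            fit.tau, rate, aln.length, float(cfg["generation_time"])
        )
        demo.update(
            {
                "rate_percent_per_myr": rate,
                "u": timing.u,
                "t_generations": timing.t_generations,
                "T_ma": timing.rounded_ma(),
            }
        )
    _write(pd.DataFrame([demo]), f"{prefix}.demography.csv", index=False)
    log["stages"][name] = {
        "n": aln.n,
        "k": aln.length,
        "haplotypes": ht.h,
        "rate_percent_per_myr": rate,
    }
    # keep pairwise Phi_ST around for the IBD stage
    log.setdefault("_phist", {})[name] = phi_m


def run_pipeline(config, outdir: str | Path | None = None) -> dict:
    """Run all configured stages; raises :class:`PipelineError` if any failed."""
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    outdir = Path(outdir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    stage_names = []
    markers = cfg["markers"]
    for m in markers:
        stage_names += [f"{m['name']}.{s}" for s in ("amova", "pairwise", "gof", "fs")]
    if cfg.get("concatenated"):
        cname = cfg["concatenated"].get("name", "concatenated")
        stage_names += [f"{cname}.{s}" for s in ("amova", "pairwise", "gof", "fs")]
    stage_names += ["msat.fst", "ibd"]
    ss = np.random.SeedSequence(master)
    seeds = {
        nm: int(child.generate_state(1)[0] % (2**31 - 1))
        for nm, child in zip(stage_names, ss.spawn(len(stage_names)))
    }
    log: dict = {
        "version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": master,
        "stage_seeds": seeds,
        "parameters": {
            k: v
            for k, v in cfg.items()
            if k in ("n_permutations", "gof_bootstrap", "fs_simulations", "generation_time")
        },
        "stages": {},
        "failures": {},
    }
    pm = read_population_table(cfg["population_table"])
    alignments = {}
    for m in markers:
        try:
            aln, _ = read_fasta_alignment(m["fasta"], pm)
            alignments[m["name"]] = aln
            _analyse_marker(
                m["name"], aln, pm, m.get("rate_percent_per_myr"), cfg, outdir, seeds, log
            )
        except Exception:
            log["failures"][m["name"]] = traceback.format_exc()
    ibd_source = markers[0]["name"] if markers else None
    if cfg.get("concatenated") and len(alignments) >= 2:
        cname = cfg["concatenated"].get("name", "concatenated")
        try:
            combined = alignments[markers[0]["name"]]
            for m in markers[1:]:
                combined = concatenate(combined, alignments[m["name"]])
            _analyse_marker(
                cname,
                combined,
                pm,
                cfg["concatenated"].get("rate_percent_per_myr"),
                cfg,
                outdir,
                seeds,
                log,
            )
            ibd_source = cname
        except Exception:
            log["failures"][cname] = traceback.format_exc()
    if cfg.get("geo_distances") and ibd_source in log.get("_phist", {}):
        try:
            geo = pd.read_csv(cfg["geo_distances"], index_col=0)
            phi_m = log["_phist"][ibd_source]
            geo = geo.loc[phi_m.index, phi_m.index]
            ibd = mantel_ibd(
                phi_m, geo, n_perm=int(cfg["n_permutations"]), seed=seeds["ibd"]
            )
            _write(
                pd.DataFrame(
                    [
                        {
                            "source": ibd_source,
                            "R": ibd.r,
                            "P": ibd.p_value,
                            "n_populations": ibd.n_populations,
                            "n_perm": ibd.n_perm,
                            "exact": ibd.exact,
                        }
                    ]
                ),
                outdir / "ibd.csv",
                index=False,
            )
            log["stages"]["ibd"] = {"source": ibd_source, "R": ibd.r, "P": ibd.p_value}
        except Exception:
            log["failures"]["ibd"] = traceback.format_exc()
    if cfg.get("bands"):
        try:
            bpm = BandPhenotypeMatrix.read_table(cfg["bands"])
            bmat = phenotypes_to_binary(bpm)
            _write(band_diversity(bmat), outdir / "msat.diversity.csv", index_label="population")
            _write(nei_unbiased_distance(bmat), outdir / "msat.nei_distance.csv")
            region_of = None
            if pm.region:
                try:
                    region_of = {
                        p: pm.region_of_population(p) for p in bmat.populations
                    }
                    if len(set(region_of.values())) < 2:
                        region_of = None
                except KeyError:
                    region_of = None
            res, fst, pvals = binary_fst(
                bmat,
                region_of,
                n_perm=int(cfg["n_permutations"]),
                seed=seeds["msat.fst"],
            )
            table, phi_rows = res.table()
            _write(table, outdir / "msat.amova.csv", index=False)
            _write(phi_rows, outdir / "msat.amova_phi.csv", index=False)
            _write(fst, outdir / "msat.pairwise_fst.csv")
            _write(pvals, outdir / "msat.pairwise_fst_p.csv")
            # combined matrix in the classic layout: F_ST below the
            # diagonal, Nei's unbiased D above
            nei = nei_unbiased_distance(bmat)
            combined = fst.copy()
            for i, a in enumerate(combined.index):
                for j, b in enumerate(combined.columns):
                    if i < j:
                        combined.loc[a, b] = nei.loc[a, b]
                    elif i == j:
                        combined.loc[a, b] = np.nan
            _write(combined, outdir / "msat.fst_nei_matrix.csv")
            coords, eigval, pct = pcoa(
                pd.DataFrame(
                    np.sqrt(np.maximum(nei_unbiased_distance(bmat), 0.0)),
                    index=bmat.populations,
                    columns=bmat.populations,
                )
            )
            _write(coords, outdir / "msat.pcoa.csv", index_label="population")
            log["stages"]["msat"] = {
                "individuals": len(bmat.data),
                "columns": bmat.data.shape[1],
            }
        except Exception:
            log["failures"]["msat"] = traceback.format_exc()
    if cfg.get("structure_lnp"):
        try:
            lnp = pd.read_csv(cfg["structure_lnp"])
            dk = evanno_delta_k(lnp)
            _write(dk, outdir / "delta_k.csv", index_label="K")
            log["stages"]["delta_k"] = {"best_K": dk.attrs.get("best_K")}
        except Exception:
            log["failures"]["delta_k"] = traceback.format_exc()
    log.pop("_phist", None)
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    if log["failures"]:
        raise PipelineError(
            f"stages failed: {sorted(log['failures'])}; see run_log.json"
        )
    return log
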