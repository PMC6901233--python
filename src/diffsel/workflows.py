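"""Named analysis workflows: config validation, seeded runs, TSV outputs.

``run_workflow(name, config, out_dir)`` ties the modules into the standard
analyses. Configs are plain dicts (or YAML files loaded by the caller);
every run writes its outputs plus a ``manifest.json`` recording the package
version, the seeds used and SHA-256 checksums of the outputs, so seeded
runs are byte-reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import diffsel
from diffsel import bgs_sim, differentiation, genesets, pbsnj, sweeps, synthetic
from diffsel.variant_io import (
    GeneAnnotation, GeneticMap, PopulationPanel, annotate_genic, assign_blocks,
    interpolate_rates, filter_by_rate, filter_by_region, polarize, read_variants,
)

#: required config keys per workflow
SCHEMAS = {
    "synth": {"out": str},
    "delta-scan": {"vcf": str, "panel": str, "genes": str, "pair": (list, tuple)},
    "pbsnj-scan": {"vcf": str, "panel": str, "genes": str},
    "simulate": {"msms": str, "n_loci": int, "seed": int},
    "fit-b": {"observed": dict, "library": dict},
    "geneset-test": {"mode": str, "candidates": (list, tuple), "background": (list, tuple),
                     "sets": dict, "snp_genes": dict, "n_resamples": int, "seed": int},
    "sweep-count": {"vcf": str, "panel": str, "genes": str, "population": str,
                    "threshold": float},
}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _validate(name: str, config: dict) -> None:
    if name not in SCHEMAS:
        raise ValueError(f"unknown workflow {name!r}; choose from {sorted(SCHEMAS)}")
    for key, typ in SCHEMAS[name].items():
        if key not in config:
            raise KeyError(f"workflow {name!r}: missing required config key {key!r}")
        if not isinstance(config[key], typ):
            raise TypeError(f"workflow {name!r}: config key {key!r} must be "
                            f"{typ}, got {type(config[key]).__name__}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_snps(config) -> "diffsel.SnpTable":
    panel = PopulationPanel.from_file(config["panel"])
    snps = read_variants(config["vcf"], panel, ancestral_tag=config.get("ancestral_tag", "AA"))
    if "aa" in snps.df.columns:
        snps = polarize(snps, "aa")
    genes_path = config["genes"]
    genes = (GeneAnnotation.from_gff3(genes_path) if str(genes_path).endswith((".gff", ".gff3"))
             else GeneAnnotation.from_bed(genes_path))
    snps = annotate_genic(snps, genes)
    snps = assign_blocks(snps, config.get("block_length", 200_000))
    if config.get("genetic_map"):
        gmap = GeneticMap.from_tsv(config["genetic_map"])
        rates = np.concatenate([
            interpolate_rates(gmap, chrom, sub["pos"].to_numpy())
            for chrom, sub in snps.df.groupby("chrom", sort=False)
        ])
        snps.df["rate"] = rates
        if config.get("max_rate") is not None:
            snps = filter_by_rate(snps, config["max_rate"])
    if config.get("exclude"):
        snps = filter_by_region(snps, [tuple(iv) for iv in config["exclude"]])
    return snps


def run_workflow(name: str, config: dict, out_dir) -> dict:
    """Validate the config, run the named workflow, write outputs + manifest."""
    _validate(name, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    if name == "synth":
        spec = synthetic.SyntheticSpec(**config.get("spec", {}))
        paths = synthetic.emit_dataset(spec, config["out"], seed=config.get("seed"))
        outputs = {k: v for k, v in paths.items() if k != "dataset"}

    elif name == "delta-scan":
        snps = _load_snps(config)
        p1, p2 = config["pair"]
        d = differentiation.delta(snps, p1, p2)
        bins = differentiation.bin_delta(d.values)
        spec_ = differentiation.enrichment_with_ci(snps, bins)
        spec_path = out / f"delta_{p1}_{p2}_spectrum.tsv"
        spec_.to_frame().to_csv(spec_path, sep="\t", index=False)
        try:
            asym = differentiation.tail_asymmetry(snps, p1, p2)
            row = {"pop1": p1, "pop2": p2, "log2_ratio": asym.log2_ratio,
                   "lo95": asym.ci_low, "hi95": asym.ci_high, "p": asym.p_value}
        except ValueError:
            # an empty/non-genic tail leaves the ratio undefined; report NaN
            row = {"pop1": p1, "pop2": p2, "log2_ratio": np.nan,
                   "lo95": np.nan, "hi95": np.nan, "p": np.nan}
        asym_path = out / f"delta_{p1}_{p2}_asymmetry.tsv"
        pd.DataFrame([row]).to_csv(asym_path, sep="\t", index=False)
        outputs = {"spectrum": str(spec_path), "asymmetry": str(asym_path)}

    elif name == "pbsnj-scan":
        snps = _load_snps(config)
        scores, spectra = pbsnj.pbsnj_scan(snps)
        score_path = out / "pbsnj_scores.tsv"
        scores.to_frame().to_csv(score_path, sep="\t", index=False)
        outputs = {"scores": str(score_path)}
        for pop, sp in spectra.items():
            p = out / f"pbsnj_{pop}_spectrum.tsv"
            sp.to_frame().to_csv(p, sep="\t", index=False)
            outputs[f"spectrum_{pop}"] = str(p)

    elif name == "simulate":
        model, n0, length = bgs_sim.parse_msms(config["msms"])
        sim = bgs_sim.simulate_loci(
            model, config["n_loci"], locus_length=length,
            genic_b=config.get("genic_b"), nongenic_b=config.get("nongenic_b"),
            genic_fraction=config.get("genic_fraction", 0.5), seed=config["seed"])
        snp_path = out / "simulated_snps.tsv"
        sim.snps.to_csv(snp_path, sep="\t", index=False)
        fst_path = out / "model_fst.tsv"
        bgs_sim.model_fst_check(sim).to_csv(fst_path, sep="\t", index=False)
        outputs = {"snps": str(snp_path), "fst": str(fst_path)}

    elif name == "fit-b":
        observed = {k: np.asarray(v, float) for k, v in config["observed"].items()}
        library = {float(b): {k: np.asarray(v, float) for k, v in spectra.items()}
                   for b, spectra in config["library"].items()}
        best, table = bgs_sim.fit_b(observed, library, bins=config.get("bins", "all"))
        path = out / "fit_b.tsv"
        table.to_csv(path, sep="\t", index=False)
        (out / "best_b.json").write_text(json.dumps({"best_b": best}))
        outputs = {"table": str(path), "best": str(out / "best_b.json")}

    elif name == "geneset-test":
        sets = genesets.GeneSetCollection({k: frozenset(v) for k, v in config["sets"].items()})
        if config["mode"] == "gene":
            res = genesets.gene_mode_resample(
                config["candidates"], config["background"], config["snp_genes"],
                sets, n_resamples=config["n_resamples"], seed=config["seed"])
            table = res.table
        elif config["mode"] == "snp":
            table = genesets.snp_category_test(
                config["candidates"], config["background"],
                pd.Series(config["snp_genes"]),
                n_resamples=config["n_resamples"], seed=config["seed"])
        else:
            raise ValueError(f"unknown geneset-test mode {config['mode']!r}")
        path = out / "geneset_test.tsv"
        table.to_csv(path, sep="\t", index=False)
        outputs = {"table": str(path)}

    elif name == "sweep-count":
        snps = _load_snps(config)
        scores, _ = pbsnj.pbsnj_scan(snps)
        keep = np.zeros(len(snps), dtype=bool)
        keep[scores.snp_index] = True
        sub = snps.subset(keep)
        tail = scores.tail_mask(config["population"])
        ranking = sweeps.rank_blocks(sub, tail, ordering=config.get("order", "genic"))
        k, traj, reached = sweeps.estimate_sweep_number(
            sub, tail, ranking, config["threshold"])
        path = out / "sweep_count.tsv"
        pd.DataFrame({"removed": np.arange(len(traj)), "enrichment": traj}).to_csv(
            path, sep="\t", index=False)
        (out / "sweep_count.json").write_text(json.dumps(
            {"k": int(k), "threshold_reached": bool(reached)}))
        outputs = {"trajectory": str(path), "summary": str(out / "sweep_count.json")}

    manifest = {
        "workflow": name,
        "version": diffsel.__version__,
        "seed": config.get("seed"),
        "config": {k: v for k, v in config.items()
                   if isinstance(v, (str, int, float, bool, list, type(None)))},
        "outputs": {k: _sha256(Path(v)) for k, v in outputs.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    outputs["manifest"] = str(manifest_path)
    return outputs
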