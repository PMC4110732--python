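"""End-to-end orchestration: inputs -> network -> covariates -> scan -> report.

A run reads the four inputs (aligned FASTA, matrilineage map, pedigree,
phenotype TSV) or generates a synthetic cohort, then executes the stages
in method order: variant extraction and haplotype collapsing, network
construction with loop resolution, kinship and familial adjustment
scores, and the permutation TreeScan (round 1, conditioning re-scan,
conditional round 2).  All results are written as TSV/JSON/GraphML plus
a manifest recording the seed, parameters and input file hashes, so a
run is reproducible bit-for-bit from the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import FormatError, ParameterError
from .hapnet import (
    branch_table,
    build_network,
    enumerate_branches,
    enumerate_loop_resolutions,
)
from .kinship import (
    familial_adjustment_scores,
    kinship_matrix,
    read_pedigree,
    write_fas,
    write_kinship,
)
from .mtvar import (
    collapse_haplotypes,
    extract_variants,
    read_alignment,
    read_matrilineage_map,
    write_haplotype_table,
    write_variant_table,
)
from .synthdata import SimulationConfig, simulate_cohort
from .treescan import PhenotypeTable, ScanResult, scan

log = logging.getLogger("mitotreescan")
if not log.handlers:  # default console logging; callers may reconfigure
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """Everything a full run needs; either file inputs or a synthetic config."""

    outdir: str = "mitotreescan_out"
    seed: int = 0
    n_perm: int = 10000
    min_class: int = 5
    alpha: float = 0.05
    max_resolutions: int = 64
    log_transform: bool = False
    include_self_fas: bool = False
    # file inputs
    fasta: str | None = None
    reference_id: str | None = None
    matrilineage: str | None = None
    pedigree: str | None = None
    phenotype: str | None = None
    # or a synthetic cohort
    synth: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_perm < 1:
            raise ParameterError(f"n_perm must be >= 1, got {self.n_perm}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synth", None)
        cfg = cls(**raw)
        if synth is not None:
            if isinstance(synth, dict):
                for key in ("sibship_sizes", "age_range", "clade_size_range"):
                    if key in synth:
                        synth[key] = tuple(synth[key])
                cfg.synth = SimulationConfig(**synth)
            else:
                cfg.synth = SimulationConfig()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(cfg: RunConfig) -> ScanResult:
    """Execute every stage and write the report under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    input_paths: dict[str, Path] = {}

    if cfg.synth is not None:
        cfg.synth.seed = cfg.synth.seed or cfg.seed
        log.info("stage=simulate seed=%d", cfg.synth.seed)
        cohort = simulate_cohort(cfg.synth)
        input_paths = cohort.write(outdir / "inputs")
        fasta, matrilineage = input_paths["fasta"], input_paths["matrilineage"]
        pedigree_path, phenotype_path = input_paths["pedigree"], input_paths["phenotype"]
        reference_id = "REF"
    else:
        for name in ("fasta", "matrilineage", "pedigree", "phenotype"):
            value = getattr(cfg, name)
            if value is None:
                raise ParameterError(f"run config lacks input path {name!r}")
            p = Path(value)
            if not p.exists():
                raise FormatError(f"input {name} not found: {p}")
            input_paths[name] = p
        fasta, matrilineage = input_paths["fasta"], input_paths["matrilineage"]
        pedigree_path, phenotype_path = input_paths["pedigree"], input_paths["phenotype"]
        reference_id = cfg.reference_id or "REF"

    # --- mtvar ---
    aln = read_alignment(fasta, reference_id)
    sample_ids = [s for s in aln.sequence_ids if s != reference_id]
    variant_sets = {s: extract_variants(aln, s) for s in sample_ids}
    lineage_map = read_matrilineage_map(matrilineage)
    hap_table = collapse_haplotypes(variant_sets, lineage_map)
    log.info("stage=mtvar n_sequenced=%d n_total=%d n_haplotypes=%d",
             hap_table.n_sequenced, hap_table.n_total, hap_table.n_haplotypes)
    write_variant_table(variant_sets, outdir / "variants.tsv")
    write_haplotype_table(hap_table, outdir / "haplotypes.tsv")

    # --- hapnet ---
    network = build_network(hap_table)
    log.info("stage=hapnet n_nodes=%d n_edges=%d n_loops=%d",
             len(network.node_counts), len(network.edges), network.n_loops)
    export_network(network, outdir / "network.graphml", outdir / "network.json")
    resolutions = enumerate_loop_resolutions(network, cfg.max_resolutions)
    pd.concat([branch_table(enumerate_branches(t)) for t in resolutions],
              ignore_index=True).to_csv(outdir / "branches.tsv", sep="\t",
                                        index=False)

    # --- kinship + FAS ---
    ped = read_pedigree(pedigree_path)
    kin = kinship_matrix(ped)
    pheno_df = pd.read_csv(phenotype_path, sep="\t", dtype={"individual": str}) \
        .set_index("individual")
    cohort_ids = sorted(hap_table.membership())
    ages = {m.id: m.age for m in ped.members}
    sexes = {m.id: (1 if m.sex == "M" else 0) for m in ped.members}
    copy_number = pheno_df["copy_number"].reindex(cohort_ids)
    fas = familial_adjustment_scores(
        copy_number.to_dict(), kin.subset(cohort_ids),
        include_self=cfg.include_self_fas)
    table = pd.DataFrame(
        {
            "copy_number": copy_number,
            "age": [ages.get(i, np.nan) for i in cohort_ids],
            "sex": [sexes.get(i, np.nan) for i in cohort_ids],
            "fas": fas,
        },
        index=pd.Index(cohort_ids, name="individual"),
    )
    write_kinship(kin.subset(cohort_ids), outdir / "kinship.tsv")
    write_fas(fas, outdir / "fas.tsv")
    log.info("stage=kinship n_pedigree=%d n_cohort=%d n_phenotyped=%d",
             len(ped.members), len(cohort_ids), int(copy_number.notna().sum()))

    # --- treescan ---
    # the familial adjustment score is outcome-derived, so the kinship matrix
    # is handed to the scan and the score recomputed inside each permutation;
    # fas.tsv above reports the observed-data scores
    pheno = PhenotypeTable(table)
    result = scan(
        hap_table, pheno,
        n_perm=cfg.n_perm, seed=cfg.seed, min_class=cfg.min_class,
        alpha=cfg.alpha, max_resolutions=cfg.max_resolutions,
        log_transform=cfg.log_transform, network=network,
        kin=kin.subset(cohort_ids),
    )
    n_testable = int(result.table.query("round == '1'")["testable"].sum())
    log.info("stage=treescan n_resolutions=%d n_testable=%d n_significant=%d",
             result.n_resolutions, n_testable, len(result.significant()))
    for _, r in result.significant().iterrows():
        log.info("significant clade {%s} variants=%s corrected_p=%.4g",
                 r["signature"], r["variants"], r["corrected_p"])

    write_report(result, outdir)
    manifest = {
        "software": "mitotreescan",
        "version": __version__,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "min_class": cfg.min_class,
        "alpha": cfg.alpha,
        "max_resolutions": cfg.max_resolutions,
        "log_transform": cfg.log_transform,
        "inputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                   for k, p in input_paths.items()},
        "counts": {
            "n_individuals": result.n_individuals,
            "n_complete": result.n_complete,
            "n_haplotypes": hap_table.n_haplotypes,
            "n_branches_testable": n_testable,
            "n_resolutions": result.n_resolutions,
        },
        "elapsed_seconds": round(time.perf_counter() - t0, 2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("stage=done elapsed=%.1fs outdir=%s", manifest["elapsed_seconds"], outdir)
    return result


def export_network(network, graphml_path: str | Path, json_path: str | Path) -> None:
    g = network.to_networkx(expand_latent=True)
    nx.write_graphml(g, str(graphml_path))
    payload = {
        "nodes": [
            {"id": n, "count": d["count"], "observed": bool(d["observed"])}
            for n, d in sorted(g.nodes(data=True))
        ],
        "edges": [
            {"a": e.node_a, "b": e.node_b,
             "variants": sorted(v.label for v in e.variants)}
            for e in sorted(network.edges, key=lambda e: e.key)
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_report(result: ScanResult, outdir: str | Path) -> dict[str, Path]:
    """Per-branch results, the conservative summary, and a JSON bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": outdir / "results.tsv",
        "summary": outdir / "summary.tsv",
        "scan_json": outdir / "scan.json",
    }
    result.table.to_csv(paths["results"], sep="\t", index=False,
                        float_format="%.10g")
    result.summary.to_csv(paths["summary"], sep="\t", index=False,
                          float_format="%.10g")
    sig = result.significant()
    payload = {
        "seed": result.seed,
        "n_perm": result.n_perm,
        "min_class": result.min_class,
        "alpha": result.alpha,
        "n_resolutions": result.n_resolutions,
        "n_complete": result.n_complete,
        "n_individuals": result.n_individuals,
        "n_significant": int(len(sig)),
        "significant": sig.to_dict(orient="records"),
        "table": result.table.to_dict(orient="records"),
        "table_columns": list(result.table.columns),
        "summary": result.summary.to_dict(orient="records"),
        "summary_columns": list(result.summary.columns),
    }
    with open(paths["scan_json"], "w") as fh:
        json.dump(_jsonable(payload), fh, indent=1, sort_keys=True)
    return paths


def read_report(outdir: str | Path) -> ScanResult:
    """Reload a written report into a :class:`ScanResult` (lossless)."""
    outdir = Path(outdir)
    with open(outdir / "scan.json") as fh:
        payload = json.load(fh)
    table = pd.DataFrame(payload["table"], columns=payload["table_columns"])
    summary = pd.DataFrame(payload["summary"], columns=payload["summary_columns"])
    return ScanResult(
        table=table,
        summary=summary,
        seed=payload["seed"],
        n_perm=payload["n_perm"],
        min_class=payload["min_class"],
        alpha=payload["alpha"],
        n_resolutions=payload["n_resolutions"],
        n_complete=payload["n_complete"],
        n_individuals=payload["n_individuals"],
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
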