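"""End-to-end workflow: preprocess -> cluster -> rank -> (optional) modules.

``run_pipeline`` executes the full analysis from a configuration dict and
writes every stage's outputs plus a JSON run manifest (tool version, full
configuration, seeds, input digests, per-stage timings).  The manifest is
sufficient to reproduce a run bitwise: ``replay_manifest`` reruns the stored
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from nmfem import __version__
from nmfem import io
from nmfem.dscore import rank_genes
from nmfem.evaluation import closest_pair, embed_2d
from nmfem.modules import detect_modules, node_statistics
from nmfem.nmf import consensus_cluster, fit_nmf, select_rank
from nmfem.preprocess import (
    compute_fpkm,
    filter_genes,
    filter_samples,
    size_factor_normalize,
)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "replay_manifest", "StageError"]

DEFAULT_CONFIG = {
    "counts": None,            # path to the counts/FPKM matrix (required)
    "lengths": None,           # gene-length TSV or GTF; enables FPKM conversion
    "no_fpkm": False,          # treat the input as FPKM/UMI counts as-is
    "normalize": True,         # median-of-ratios size factors
    "housekeeping": None,      # path; falls back to the packaged default list
    "hk_threshold": 4.0,
    "max_zero_frac": 0.7,
    "k": None,                 # fixed rank; mutually exclusive with k_range
    "k_range": [2, 5],         # inclusive rank scan for cophenetic selection
    "n_runs": 30,
    "seed": 0,
    "top_n": 500,
    "graph": None,             # PPI edge list / GraphML; enables module stage
    "n_perm": 1000,
    "n_top_modules": 5,
    "module_max_size": 50,
    "tsne_perplexity": None,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs):
    df.to_csv(path, sep="\t", **kwargs)


def run_pipeline(config: dict, outdir) -> dict:
    """Run the full workflow; returns the manifest dict (also written to disk).

    Stages: load counts -> FPKM (if lengths given and not ``no_fpkm``) ->
    size-factor normalization -> housekeeping sample filter -> zero-fraction
    gene filter -> consensus NMF (fixed ``k`` or cophenetic scan over
    ``k_range``) -> rank-2 D-score gene ranking (on the closest pair of
    groups when the chosen k exceeds 2) -> seeded PPI module detection when a
    graph is supplied.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    if cfg["counts"] is None:
        raise ValueError("config must name a counts/FPKM matrix ('counts')")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {
        "tool": "nmfem",
        "version": __version__,
        "config": cfg,
        "inputs": {},
        "seeds": {"base": seed},
        "timings_s": {},
        "outputs": [],
    }
    for key in ("counts", "lengths", "housekeeping", "graph"):
        if cfg[key]:
            manifest["inputs"][key] = {"path": str(cfg[key]), "sha256": _sha256(cfg[key])}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("[%s] start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["timings_s"][name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None and not isinstance(exc, (ValueError, FileNotFoundError)):
                    raise StageError(name, exc) from exc
                logger.info("[%s] done (%.2fs)", name, manifest["timings_s"][name])
                return False

        return _Timer()

    with stage("preprocess"):
        m = io.read_expression_matrix(cfg["counts"])
        if cfg["lengths"] and not cfg["no_fpkm"]:
            m = compute_fpkm(m, io.read_gene_lengths(cfg["lengths"]))
        if cfg["normalize"]:
            m, factors = size_factor_normalize(m)
            _write_tsv(factors.to_frame(), outdir / "size_factors.tsv", index_label="sample_id")
            manifest["outputs"].append("size_factors.tsv")
        if cfg["housekeeping"]:
            hk = io.read_gene_list(cfg["housekeeping"])
        else:
            hk = io.default_housekeeping_genes()
            if not set(hk) & set(m.index):
                logger.warning("default housekeeping list shares no gene with the matrix; "
                               "skipping the sample filter")
                hk = None
        if hk is not None:
            m = filter_samples(m, hk, threshold=float(cfg["hk_threshold"]))
        m = filter_genes(m, max_zero_fraction=float(cfg["max_zero_frac"]))
        if m.empty:
            raise ValueError("no genes survived filtering")
        io.write_expression_matrix(m, outdir / "filtered_matrix.tsv")
        manifest["outputs"].append("filtered_matrix.tsv")
        manifest["n_genes"], manifest["n_samples"] = int(m.shape[0]), int(m.shape[1])

    with stage("cluster"):
        n_runs = int(cfg["n_runs"])
        if cfg["k"] is not None:
            chosen_k = int(cfg["k"])
            results = {chosen_k: consensus_cluster(m, chosen_k, n_runs=n_runs, base_seed=seed)}
        else:
            lo, hi = cfg["k_range"]
            chosen_k, results = select_rank(m, range(int(lo), int(hi) + 1),
                                            n_runs=n_runs, base_seed=seed)
        res = results[chosen_k]
        manifest["chosen_k"] = int(chosen_k)
        manifest["cophenetic"] = {int(k): r.cophenetic for k, r in results.items()}
        manifest["seeds"]["nmf_runs"] = {int(k): r.run_seeds for k, r in results.items()}
        labels = pd.Series(res.labels, index=m.columns, name="cluster")
        _write_tsv(labels.to_frame(), outdir / "labels.tsv", index_label="sample_id")
        _write_tsv(pd.DataFrame(res.consensus, index=m.columns, columns=m.columns),
                   outdir / "consensus.tsv", index_label="sample_id")
        _write_tsv(pd.DataFrame({"k": list(manifest["cophenetic"]),
                                 "cophenetic": list(manifest["cophenetic"].values())}),
                   outdir / "cophenetic.tsv", index=False)
        manifest["outputs"] += ["labels.tsv", "consensus.tsv", "cophenetic.tsv"]

    with stage("rank"):
        # D-score needs a rank-2 factorization; for k > 2 isolate the closest
        # pair of consensus groups on the correlation t-SNE plot first.
        if chosen_k == 2:
            pair_matrix, pair_labels = m, labels
        else:
            coords = embed_2d(m, seed=seed, perplexity=cfg["tsne_perplexity"])
            a, b = closest_pair(coords, labels.to_numpy())
            manifest["closest_pair"] = [int(a), int(b)]
            keep = labels.isin([a, b])
            pair_matrix = filter_genes(m.loc[:, keep], float(cfg["max_zero_frac"]))
            pair_labels = labels[keep]
        fac = fit_nmf(pair_matrix, 2, seed=seed)
        table = rank_genes(fac.W_, fac.H_, pair_matrix.index, top_n=int(cfg["top_n"]))
        manifest["lambda"] = table.attrs["lambda"]
        _write_tsv(table, outdir / "genes.tsv", index=False)
        _write_tsv(pd.DataFrame(fac.W_, index=pair_matrix.index,
                                columns=["metagene_1", "metagene_2"]),
                   outdir / "W.tsv", index_label="gene_id")
        _write_tsv(pd.DataFrame(fac.H_, index=["metagene_1", "metagene_2"],
                                columns=pair_matrix.columns),
                   outdir / "H.tsv", index_label="metagene")
        manifest["outputs"] += ["genes.tsv", "W.tsv", "H.tsv"]
        two_group_labels = pd.Series(fac.labels_, index=pair_matrix.columns)

    if cfg["graph"]:
        with stage("modules"):
            g = io.read_ppi(cfg["graph"])
            stats = node_statistics(pair_matrix, two_group_labels.to_numpy())
            seeds_list = table.loc[table["is_feature"], "gene_id"].tolist()
            mods = detect_modules(g, stats, seeds_list, n_top=int(cfg["n_top_modules"]),
                                  n_perm=int(cfg["n_perm"]), seed=seed,
                                  max_size=int(cfg["module_max_size"]))
            summary = pd.DataFrame([{
                "seed_gene": mod.seed_gene, "size": len(mod.members),
                "score": mod.score, "p_value": mod.p_value, "hub": mod.hub,
                "members": ",".join(mod.members)} for mod in mods])
            _write_tsv(summary, outdir / "modules.tsv", index=False)
            manifest["outputs"].append("modules.tsv")
            deg = dict(g.degree)
            for i, mod in enumerate(mods, 1):
                per = pd.DataFrame({
                    "member": mod.members,
                    "t": [mod.t_stats[v] for v in mod.members],
                    "degree": [deg[v] for v in mod.members],
                    "is_seed": [v == mod.seed_gene for v in mod.members],
                    "is_hub": [v == mod.hub for v in mod.members]})
                _write_tsv(per, outdir / f"module_{i}.tsv", index=False)
                manifest["outputs"].append(f"module_{i}.tsv")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def replay_manifest(manifest_path, outdir) -> dict:
    """Rerun the configuration stored in a manifest; outputs are bitwise identical."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return run_pipeline(manifest["config"], outdir)
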