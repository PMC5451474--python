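"""End-to-end orchestration: simulate/load -> normalize -> DE test ->
catalogue/ordination -> target prediction -> profile clustering -> network.

Every stage writes deterministic TSV artifacts into the output directory
and the run ends with a JSON manifest recording the seed, a hash of the
configuration, package and dependency versions, and the SHA-256 of every
output, so a rerun with identical config and seed is byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import CountMatrix, FpkmMatrix
from .de_catalog import (StageGrouping, classify_groups, pca_ordination,
                         top_abundant, venn_overlap)
from .de_test import GLOBAL_RULE, PAIRWISE_RULE, test_matrix
from .network import build_network, node_stats, to_graphml, to_sif
from .normalization import tpm_normalize
from .stem import (generate_model_profiles, profile_significance,
                   select_representative_profiles, assign_profiles)
from .synthetic import (GroundTruth, SimulationConfig, gen_count_libraries,
                        gen_expression_profiles, gen_interaction_table,
                        gen_mirna_sequences, gen_utr_sequences)
from .targets import predict_targets, read_fasta

__all__ = ["PipelineError", "run_pipeline", "default_simulation_config"]

log = logging.getLogger("mirnatime")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False,
               index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format="%.10g", lineterminator="\n")


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_simulation_config(overrides: dict | None = None, seed: int = 0) -> SimulationConfig:
    """The default synthetic scenario: 20 four-fold miRNAs planted at every
    stage among 200, and the first 10 planted miRNAs each targeting 3 genes."""
    opts = dict(overrides or {})
    opts.setdefault("seed", seed)
    cfg = SimulationConfig(**{k: v for k, v in opts.items() if k != "planted_de"})
    if "planted_de" in opts:
        cfg.planted_de = [
            (m, tuple(st), float(e)) for m, st, e in opts["planted_de"]
        ]
    else:
        cfg.planted_de = [
            (mid, cfg.stages, 2.0) for mid in cfg.mirna_ids[:min(20, cfg.n_mirnas)]
        ]
    return cfg


def _default_planted_targets(cfg: SimulationConfig) -> list[tuple[str, str]]:
    planted_mirnas = [m for m, _, _ in cfg.planted_de][:10] or cfg.mirna_ids[:10]
    pairs = []
    gi = 0
    for mid in planted_mirnas:
        for _ in range(3):
            if gi >= cfg.n_genes:
                break
            pairs.append((mid, cfg.gene_ids[gi]))
            gi += 1
    return pairs


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis described by ``config``.

    ``config`` holds either a ``simulate`` block (SimulationConfig fields)
    or an ``inputs`` block with paths (``counts``, ``fpkm_<breed>``,
    ``mirnas``, ``utrs``, ``interactions``), plus optional ``stem``
    (``c``, ``m``), ``network`` (``score_min``), ``rule``
    (``pairwise``/``global``) and ``seed`` entries.  Returns the manifest.
    """
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "mirnatime_out"))
    out.mkdir(parents=True, exist_ok=True)
    stale = out / "_STALE"
    stale.write_text("run in progress\n")

    rule = {"pairwise": PAIRWISE_RULE, "global": GLOBAL_RULE}[config.get("rule", "pairwise")]
    stem_cfg = config.get("stem", {})
    c = int(stem_cfg.get("c", 2))
    m = int(stem_cfg.get("m", 50))
    log2_pseudo = float(stem_cfg.get("log2_pseudocount", 0.001))
    score_min = float(config.get("network", {}).get("score_min", 0.4))
    grouping = StageGrouping()
    outputs: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            log.info("stage %s", name)
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return deco

    profiles4 = generate_model_profiles(4, c)
    selected = select_representative_profiles(profiles4, m)

    # ---------------------------------------------------------------- inputs
    if "simulate" in config or "inputs" not in config:
        sim = default_simulation_config(config.get("simulate"), seed=seed)
        breeds = sim.breeds

        @stage("simulate")
        def _sim():
            counts, truth_de = gen_count_libraries(sim)
            mirna_seqs = gen_mirna_sequences(sim)
            planted_targets = [
                tuple(p) for p in config.get("planted_targets",
                                             _default_planted_targets(sim))
            ]
            utrs, truth_utr = gen_utr_sequences(sim, planted_targets, mirna_seqs)
            templates = selected[:4]
            fpkms, truth = {}, truth_de.merged_with(truth_utr)
            for bi, breed in enumerate(breeds):
                parts = []
                for gi, group in enumerate((sim.embryonic_stages, sim.postnatal_stages)):
                    fp, truth_fp = gen_expression_profiles(
                        sim, templates, stage_labels=group,
                        salt=100 + 10 * bi + gi)
                    parts.append(fp.fpkm)
                    if bi == 0 and gi == 0:
                        truth = truth.merged_with(truth_fp)
                fpkms[breed] = FpkmMatrix(pd.concat(parts, axis=1), pseudocount=0.0)
            target_genes = sorted({g for _, g in planted_targets})
            pairs = list(zip(target_genes, target_genes[1:]))
            interactions = gen_interaction_table(pairs, seed=seed)
            return counts, mirna_seqs, utrs, fpkms, interactions, truth

        counts, mirna_seqs, utrs, fpkms, interactions, truth = _sim
        counts.to_tsv(out / "counts.tsv")
        _write_fasta(mirna_seqs, out / "mirnas.fa")
        _write_fasta(utrs, out / "utrs.fa")
        for breed, fp in fpkms.items():
            _write_tsv(fp.fpkm, out / f"fpkm_{breed}.tsv", index=True,
                       index_label="gene_id")
        _write_tsv(interactions, out / "interactions.tsv")
        gt = {
            "true_de": {k: [sorted(v[0]), v[1]] for k, v in truth.true_de.items()},
            "true_targets": sorted(map(list, truth.true_targets)),
            "planted_sites": {f"{m_}|{g}": v
                              for (m_, g), v in sorted(truth.planted_sites.items())},
            "true_profile_of_gene": truth.true_profile_of_gene,
        }
        (out / "ground_truth.json").write_text(json.dumps(gt, indent=2, sort_keys=True))
        for name in ("counts.tsv", "mirnas.fa", "utrs.fa", "interactions.tsv",
                     "ground_truth.json", *(f"fpkm_{b}.tsv" for b in breeds)):
            outputs[name] = out / name
    else:
        inputs = config["inputs"]
        breeds = tuple(config.get("breeds", ("LR", "LT")))

        def _need(key: str, stage_name: str) -> Path:
            if key not in inputs:
                raise PipelineError(
                    f"stage '{stage_name}' requires missing input {key!r}")
            path = Path(inputs[key])
            if not path.exists():
                raise PipelineError(
                    f"stage '{stage_name}' input {key!r} not found: {path}")
            return path

        counts = CountMatrix.from_tsv(_need("counts", "normalize"))
        mirna_seqs = read_fasta(_need("mirnas", "targets"))
        utrs = read_fasta(_need("utrs", "targets"))
        fpkms = {
            b: FpkmMatrix.from_tsv(_need(f"fpkm_{b}", "stem")) for b in breeds
        }
        interactions = pd.read_csv(_need("interactions", "network"), sep="\t")
        truth = GroundTruth()

    stages_all = [s for s in counts.library_labels if s.startswith(breeds[0] + "_")]
    stage_names = [s.split("_", 1)[1] for s in stages_all]

    # ------------------------------------------------------------- normalize
    @stage("normalize")
    def _tpm():
        return tpm_normalize(counts)

    tpm = _tpm
    tpm.to_tsv(out / "tpm.tsv")
    outputs["tpm.tsv"] = out / "tpm.tsv"

    # ---------------------------------------------------------------- detest
    @stage("detest")
    def _de():
        comparisons = [(f"{breeds[1]}_{s}", f"{breeds[0]}_{s}") for s in stage_names]
        res = test_matrix(counts, comparisons, rule)
        res["stage"] = res["comparison"].str.split("_").str[1]
        return res

    de_results = _de
    _write_tsv(de_results, out / "de_results.tsv")
    outputs["de_results.tsv"] = out / "de_results.tsv"

    # -------------------------------------------------------------- classify
    @stage("classify")
    def _cat():
        catalog = classify_groups(de_results, grouping)
        _write_tsv(catalog.stage_table, out / "stage_table.tsv")
        venn = {}
        names = sorted(catalog.sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                only_a, shared, only_b = venn_overlap(catalog, a, b)
                venn[f"{a}|{b}"] = {"only_a": only_a, "shared": shared,
                                    "only_b": only_b}
        (out / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True))
        _write_tsv(catalog.membership, out / "membership.tsv")
        return catalog

    catalog = _cat
    outputs.update({n: out / n for n in ("stage_table.tsv", "venn.json",
                                         "membership.tsv")})

    de_union = sorted(set().union(*catalog.sets.values()))

    @stage("abundance")
    def _top():
        frames = []
        for group, stages_g in (("G1", grouping.g1), ("G2", grouping.g2)):
            for direction in ("up", "down"):
                for breed in breeds:
                    cols = [f"{breed}_{s}" for s in stages_g
                            if f"{breed}_{s}" in tpm.tpm.columns]
                    ranked = top_abundant(tpm.tpm, catalog.sets[f"{group}_{direction}"],
                                          cols, k=10)
                    ranked.insert(0, "subgroup", f"{group}_{direction}_{breed}")
                    if len(ranked):
                        frames.append(ranked)
        if not frames:
            return pd.DataFrame(columns=["subgroup", "mirna_id", "abundance"])
        return pd.concat(frames, ignore_index=True)

    _write_tsv(_top, out / "top_abundant.tsv")
    outputs["top_abundant.tsv"] = out / "top_abundant.tsv"

    # -------------------------------------------------------------- ordinate
    @stage("ordinate")
    def _pca():
        rows = de_union if len(de_union) >= 2 else list(tpm.tpm.index)
        res = pca_ordination(tpm.tpm.loc[rows])
        scores = res.scores.copy()
        scores.insert(0, "library", scores.index)
        return scores

    _write_tsv(_pca, out / "pca_scores.tsv")
    outputs["pca_scores.tsv"] = out / "pca_scores.tsv"

    # --------------------------------------------------------------- targets
    @stage("targets")
    def _targets():
        de_seqs = {m_: s for m_, s in mirna_seqs.items() if m_ in de_union}
        return predict_targets(de_seqs or mirna_seqs, utrs)

    targets = _targets
    _write_tsv(targets, out / "targets.tsv")
    outputs["targets.tsv"] = out / "targets.tsv"

    # ------------------------------------------------------------------ stem
    @stage("stem")
    def _stem():
        _write_tsv(
            pd.DataFrame({"profile_id": [p.id for p in selected],
                          "values": [",".join(map(str, p.values)) for p in selected]}),
            out / "profiles.tsv")
        target_genes = sorted(set(targets["gene_id"]))
        for breed in breeds:
            fp = fpkms[breed]
            log2 = np.log2(fp.fpkm + log2_pseudo)
            genes = [g for g in target_genes if g in log2.index]
            for group, stages_g in (("G1", grouping.g1), ("G2", grouping.g2)):
                cols = [s for s in stages_g if s in log2.columns]
                if len(cols) != len(stages_g) or not genes:
                    continue
                series = log2.loc[genes, list(cols)]
                assignments = assign_profiles(series, selected)
                enrich = profile_significance(series, selected)
                _write_tsv(assignments, out / f"stem_assignments_{breed}_{group}.tsv")
                _write_tsv(enrich, out / f"stem_enrichment_{breed}_{group}.tsv")
                outputs[f"stem_assignments_{breed}_{group}.tsv"] = \
                    out / f"stem_assignments_{breed}_{group}.tsv"
                outputs[f"stem_enrichment_{breed}_{group}.tsv"] = \
                    out / f"stem_enrichment_{breed}_{group}.tsv"

    _stem
    outputs["profiles.tsv"] = out / "profiles.tsv"

    # --------------------------------------------------------------- network
    @stage("network")
    def _net():
        g = build_network(targets, interactions, score_min=score_min)
        to_sif(g, out / "network.sif")
        to_graphml(g, out / "network.graphml")
        _write_tsv(node_stats(g), out / "degrees.tsv")
        return g

    _net
    outputs.update({n: out / n for n in ("network.sif", "network.graphml",
                                         "degrees.tsv")})

    # -------------------------------------------------------------- manifest
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "seed": seed,
        "config_sha256": cfg_hash,
        "versions": {
            "mirnatime": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    stale.unlink()
    return manifest
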