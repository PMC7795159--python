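"""Pipeline orchestration: simulate -> classify -> filter -> DE -> networks
-> enrichment -> isomiR profile.

Stages communicate through a working directory with fixed file names, so
any stage can be re-run from the command line on its own; ``run_pipeline``
executes them in workflow order and writes a run manifest with per-stage
counts.  Every TSV output carries a provenance header (seed and config
hash).  On user data, the same file-name convention applies and the
simulate stage is skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexp, enrich, io, isomir, normfilter, synthdata, xnet

logger = logging.getLogger("tepomics.pipeline")

COUNT_LAYERS = ("mirna", "isomir", "mrna", "intron")
ALL_LAYERS = COUNT_LAYERS + ("protein",)
GSEA_LAYERS = ("mrna", "intron", "protein")
STAGE_ORDER = ("simulate", "classify", "filter", "de", "network", "enrich", "profile")


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage."""


@dataclass
class PipelineConfig:
    """Thresholds, engine options and paths for one pipeline run."""

    outdir: str = "tepomics_run"
    seed: int = 0
    simulate: bool = True
    alpha: float = 0.05
    lfc_cut: float = 1.0
    min_cpm: float = 1.0
    min_frac: float = 0.40
    bw_max_zero_frac: float = 0.18
    correlation_method: str = "pearson"
    gsea_weight: float = 1.0
    n_perm: int = 1000
    max_offset: int = 3
    max_tail: int = 3
    max_subs: int = 1
    network_candidates: str = "de"  # "de" or "all"
    reads_per_sample: int = 2000
    n_read_samples_per_group: int = 11
    n_gene_sets: int = 25
    generator: synthdata.GeneratorConfig = field(default_factory=synthdata.GeneratorConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_cut < 0 or self.min_cpm < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.min_frac <= 1 or not 0 <= self.bw_max_zero_frac <= 1:
            raise ValueError("fractions must be in [0, 1]")
        if self.network_candidates not in ("de", "all"):
            raise ValueError("network_candidates must be 'de' or 'all'")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError("correlation method must be pearson or spearman")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        return d


def config_hash(cfg: PipelineConfig) -> str:
    d = cfg.to_dict()
    d.pop("outdir")  # the scientific identity of a run is path-independent
    payload = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(cfg: PipelineConfig) -> dict:
    return {"config": config_hash(cfg), "seed": cfg.seed}


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _groups(workdir: Path) -> pd.Series:
    return io.read_sample_sheet(workdir / "sample_sheet.tsv")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"{stage}: required input {path.name} is missing")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, workdir: Path) -> dict:
    """Generate reference, reads, expression layers, truth and gene sets."""
    prov = _provenance(cfg)
    seeds = _subseeds(cfg.seed, 8)
    gcfg = dataclasses.replace(cfg.generator, seed=seeds[0])
    reference = synthdata.generate_reference(gcfg.n_mirna, flank_len=10, seed=seeds[1])
    io.write_reference(reference, workdir / "reference.fasta", workdir / "flanks.tsv", prov)

    matrices, truth = synthdata.generate_expression(gcfg, mirna_names=[r.name for r in reference])
    truth.to_json(workdir / "truth.json")
    for layer, m in matrices.items():
        io.write_count_matrix(m, workdir / f"counts_{layer}.tsv", prov)
    layers_present = {layer: list(m.samples) for layer, m in matrices.items()}
    io.write_sample_sheet(matrices["mirna"].groups, workdir / "sample_sheet.tsv", layers_present, prov)

    reads, labels, read_groups = synthdata.generate_reads(
        reference,
        gcfg.class_probs_by_group,
        reads_per_sample=cfg.reads_per_sample,
        n_samples_per_group=cfg.n_read_samples_per_group,
        seed=seeds[2],
    )
    for sample, rlist in reads.items():
        io.write_collapsed_reads(rlist, workdir / f"reads_{sample}.tsv", prov)

    for k, layer in enumerate(GSEA_LAYERS):
        universe = list(matrices[layer].features)
        up = sorted(f for f, l in truth.de_features[layer].items() if l > 0)
        planted = {"GO_SYN_PLANTED": up} if len(up) >= 3 else None
        sets = synthdata.generate_gene_sets(
            universe, n_sets=cfg.n_gene_sets, seed=seeds[3 + k], planted=planted
        )
        io.write_gmt(sets, workdir / f"gene_sets_{layer}.gmt")
    mirna_sets = synthdata.generate_gene_sets(
        [r.name for r in reference],
        n_sets=cfg.n_gene_sets,
        size_range=(5, 15),
        seed=seeds[6],
        planted={"GO_SYN_PLANTED": sorted(truth.target_map)},
        prefix="MIR_SYN",
    )
    io.write_gmt(mirna_sets, workdir / "gene_sets_mirna.gmt")
    return {
        "simulate": {
            "n_features": {layer: int(len(m.features)) for layer, m in matrices.items()},
            "n_read_samples": len(reads),
            "reads_per_sample": cfg.reads_per_sample,
            "hub_transcript": truth.hub_transcript,
        }
    }


def stage_classify(cfg: PipelineConfig, workdir: Path) -> dict:
    reference = io.read_reference(
        _require(workdir / "reference.fasta", "classify"),
        _require(workdir / "flanks.tsv", "classify"),
    )
    read_files = sorted(workdir.glob("reads_*.tsv"))
    if not read_files:
        raise PipelineError("classify: no reads_*.tsv files found")
    reads_by_sample = {p.stem.removeprefix("reads_"): io.read_collapsed_reads(p) for p in read_files}
    sample_groups = pd.Series({s: ("A" if s.startswith("A") else "B") for s in reads_by_sample})
    canonical, iso, qc = isomir.count_isomirs(
        reads_by_sample, reference, sample_groups,
        max_offset=cfg.max_offset, max_tail=cfg.max_tail, max_subs=cfg.max_subs,
    )
    prov = _provenance(cfg)
    io.write_count_matrix(canonical, workdir / "counts_mirna_reads.tsv", prov)
    io.write_count_matrix(iso, workdir / "counts_isomir_reads.tsv", prov)
    io.write_matrix(qc, workdir / "qc_classification.tsv", prov, index_label="sample")
    return {
        "classify": {
            "n_reads": int(qc["n_reads"].sum()),
            "n_no_call": int(qc["n_no_call"].sum()),
            "n_ambiguous": int(qc["n_ambiguous"].sum()),
            "n_canonical_features": int(len(canonical.features)),
            "n_isomir_features": int(len(iso.features)),
        }
    }


def stage_filter(cfg: PipelineConfig, workdir: Path) -> dict:
    groups = _groups(workdir)
    prov = _provenance(cfg)
    out = {}
    for layer in COUNT_LAYERS:
        m = io.read_count_matrix(_require(workdir / f"counts_{layer}.tsv", "filter"), layer, groups)
        kept, reasons = normfilter.presence_filter(
            m, cfg.min_cpm, cfg.min_frac, cfg.bw_max_zero_frac
        )
        sub = m.subset(features=kept)
        factors = normfilter.tmm_factors(sub)
        sub.set_norm_factors(factors)
        io.write_count_matrix(sub, workdir / f"filtered_{layer}.tsv", prov)
        io.write_matrix(
            reasons.to_frame("reason"), workdir / f"filter_report_{layer}.tsv", prov
        )
        io.write_matrix(factors.to_frame(), workdir / f"factors_{layer}.tsv", prov, index_label="sample")
        io.write_matrix(normfilter.normalize(sub), workdir / f"normalized_{layer}.tsv", prov)
        out[layer] = {"n_before": int(len(m.features)), "n_kept": int(len(kept))}
    prot_path = workdir / "counts_protein.tsv"
    if prot_path.exists():
        m = io.read_count_matrix(prot_path, "protein", groups)
        io.write_matrix(normfilter.cpm(m), workdir / "normalized_protein.tsv", prov)
        out["protein"] = {"n_before": int(len(m.features)), "n_kept": int(len(m.features))}
    return {"filter": out}


def stage_de(cfg: PipelineConfig, workdir: Path) -> dict:
    groups = _groups(workdir)
    prov = _provenance(cfg)
    out = {}
    for layer in COUNT_LAYERS:
        m = io.read_count_matrix(_require(workdir / f"filtered_{layer}.tsv", "de"), layer, groups)
        factors = io.read_tsv(workdir / f"factors_{layer}.tsv", index_col="sample")[
            "tmm_factor"
        ]
        m.set_norm_factors(factors)
        table = diffexp.differential_table(m, "nb_exact", cfg.alpha, cfg.lfc_cut)
        io.write_matrix(table.set_index("feature"), workdir / f"de_{layer}.tsv", prov)
        out[layer] = {
            "n_tested": int(len(table)),
            "n_significant": int(table["significant"].sum()),
            "n_up_a": int((table["significant"] & (table["direction"] == "up_A")).sum()),
            "n_up_b": int((table["significant"] & (table["direction"] == "up_B")).sum()),
        }
    prot_path = workdir / "counts_protein.tsv"
    if prot_path.exists():
        m = io.read_count_matrix(prot_path, "protein", groups)
        table = diffexp.differential_table(m, "beta_binomial", cfg.alpha, cfg.lfc_cut)
        io.write_matrix(table.set_index("feature"), workdir / "de_protein.tsv", prov)
        out["protein"] = {
            "n_tested": int(len(table)),
            "n_significant": int(table["significant"].sum()),
            "n_up_a": int((table["significant"] & (table["direction"] == "up_A")).sum()),
            "n_up_b": int((table["significant"] & (table["direction"] == "up_B")).sum()),
        }
    return {"de": out}


def _read_normalized(workdir: Path, layer: str, stage: str) -> pd.DataFrame:
    return io.read_tsv(
        _require(workdir / f"normalized_{layer}.tsv", stage), index_col="feature"
    )


def _de_significant(workdir: Path, layer: str) -> list[str]:
    df = io.read_tsv(workdir / f"de_{layer}.tsv", index_col="feature")
    return list(df.index[df["significant"]])


def stage_network(cfg: PipelineConfig, workdir: Path) -> dict:
    if not (workdir / "counts_protein.tsv").exists():
        raise PipelineError("network:gene_protein: protein count matrix is required to build networks")
    groups = _groups(workdir)
    # correlations run on log2(CPM + 1): Pearson on raw CPM of overdispersed
    # counts is dominated by single outlying samples
    norm = {
        layer: np.log2(_read_normalized(workdir, layer, "network") + 1.0)
        for layer in ALL_LAYERS
    }
    de_sets = None
    if cfg.network_candidates == "de":
        de_sets = {layer: _de_significant(workdir, layer) for layer in ALL_LAYERS}

    by_group: dict[str, dict[str, pd.DataFrame]] = {}
    for g in ("A", "B"):
        gs = [s for s in groups.index if groups[s] == g]
        by_group[g] = {
            layer: norm[layer][[s for s in norm[layer].columns if s in set(gs)]]
            for layer in ALL_LAYERS
        }
    nets = xnet.build_all_networks(by_group, de_sets, cfg.alpha, cfg.correlation_method)
    prov = _provenance(cfg)
    info = {}
    for net in nets:
        io.write_edges(net, workdir / f"network_{net.label}_edges.tsv", prov)
        io.write_graphml(net, workdir / f"network_{net.label}.graphml")
        info[net.label] = {
            "n_edges": len(net.edges),
            "n_mirna": len(net.nodes_of_type(xnet.NODE_MIRNA)),
            "n_transcript": len(net.nodes_of_type(xnet.NODE_TRANSCRIPT)),
            "n_protein": len(net.nodes_of_type(xnet.NODE_PROTEIN)),
        }
    cores = {}
    for g in ("A", "B"):
        core = xnet.cross_network_core([n for n in nets if n.group == g])
        cores[g] = sorted(core)
    io.write_json(cores, workdir / "network_cores.json")
    return {"network": {"n_networks": len(nets), "networks": info, "cores": cores}}


def stage_enrich(cfg: PipelineConfig, workdir: Path) -> dict:
    seeds = _subseeds(cfg.seed + 1, len(GSEA_LAYERS))
    prov = _provenance(cfg)
    results = {}
    counts = {}
    for k, layer in enumerate(GSEA_LAYERS):
        de_path = workdir / f"de_{layer}.tsv"
        gmt_path = workdir / f"gene_sets_{layer}.gmt"
        if not de_path.exists() or not gmt_path.exists():
            logger.warning("enrich: skipping layer %s (missing inputs)", layer)
            continue
        de = io.read_tsv(de_path)
        ranked = enrich.rank_table(de)
        sets = io.read_gmt(gmt_path)
        universe = set(ranked.index)
        usable = [
            gs for gs in sets
            if 0 < len(gs.members & universe) < len(universe)
        ]
        res = enrich.gsea_preranked(
            ranked, usable, n_perm=cfg.n_perm, seed=seeds[k], w=cfg.gsea_weight, alpha=cfg.alpha
        )
        res.insert(1, "layer", layer)
        io.write_matrix(res.set_index("set_name"), workdir / f"enrichment_{layer}.tsv", prov, "set_name")
        results[layer] = res
        counts[layer] = int(res["significant"].sum())

    mirna_gmt = workdir / "gene_sets_mirna.gmt"
    de_mirna = workdir / "de_mirna.tsv"
    if mirna_gmt.exists() and de_mirna.exists():
        de = io.read_tsv(de_mirna, index_col="feature")
        hits = set(de.index[de["significant"]])
        universe = set(de.index)
        if hits:
            sets = io.read_gmt(mirna_gmt)
            directions = {}
            for gs in sets:
                in_set = [f for f in hits & gs.members]
                if in_set:
                    directions[gs.name] = 1 if de.loc[in_set, "log2fc"].mean() >= 0 else -1
            res = enrich.mirna_ora(hits, universe, sets, directions, alpha=cfg.alpha)
            io.write_matrix(res.set_index("set_name"), workdir / "enrichment_mirna.tsv", prov, "set_name")
            results["mirna"] = res
            counts["mirna"] = int(res["significant"].sum())
        else:
            logger.warning("enrich: no DE miRNAs; ORA skipped")

    overlap_terms: list[str] = []
    if len(results) >= 2:
        overlap = enrich.cross_layer_overlap(results, alpha=cfg.alpha)
        io.write_matrix(overlap.set_index("term"), workdir / "overlap_terms.tsv", prov, "term")
        overlap_terms = sorted(overlap["term"].unique())
    return {"enrich": {"n_significant": counts, "overlap_terms": overlap_terms}}


def stage_profile(cfg: PipelineConfig, workdir: Path) -> dict:
    groups = _groups(workdir)
    iso_path = _require(workdir / "counts_isomir_reads.tsv", "profile")
    iso = io.read_count_matrix(
        iso_path, "isomir",
        pd.Series({s: ("A" if s.startswith("A") else "B")
                   for s in io.read_tsv(iso_path, index_col="feature", nrows=0).columns}),
    )
    de_path = workdir / "de_mirna.tsv"
    de_mirnas: list[str] = []
    if de_path.exists():
        de = io.read_tsv(de_path, index_col="feature")
        de_mirnas = list(de.index[de["significant"]])
    if not de_mirnas:
        logger.warning("profile: no DE canonical miRNAs; profiling all parents")
        de_mirnas = sorted({isomir.parent_of(f) for f in iso.features})
    freq, expr = isomir.class_frequency(iso, de_mirnas)
    prov = _provenance(cfg)
    io.write_matrix(freq, workdir / "class_profile.tsv", prov, index_label="class")
    io.write_matrix(expr.set_index("mirna"), workdir / "class_expression.tsv", prov, "mirna")
    modal = {g: (str(freq[g].idxmax()) if freq[g].sum() > 0 else None) for g in ("A", "B")}
    return {"profile": {"n_de_mirnas": len(de_mirnas), "modal_class": modal}}


STAGES = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "filter": stage_filter,
    "de": stage_de,
    "network": stage_network,
    "enrich": stage_enrich,
    "profile": stage_profile,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the workflow (or a stage subset) and write ``manifest.json``.

    A stage failure raises :class:`PipelineError` naming the stage; the
    manifest accumulated so far is kept as ``manifest.partial.json``.
    """
    workdir = Path(cfg.outdir)
    workdir.mkdir(parents=True, exist_ok=True)
    todo = list(STAGE_ORDER) if stages is None else [s for s in STAGE_ORDER if s in set(stages)]
    if not cfg.simulate and "simulate" in todo:
        todo.remove("simulate")
    unknown = set(stages or []) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stage(s) {sorted(unknown)}")

    manifest: dict = {"seed": cfg.seed, "config_sha": config_hash(cfg), "stages_run": todo}
    for name in todo:
        logger.info("running stage %s", name)
        try:
            manifest.update(STAGES[name](cfg, workdir))
        except PipelineError:
            io.write_json(manifest, workdir / "manifest.partial.json")
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            io.write_json(manifest, workdir / "manifest.partial.json")
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    io.write_json(manifest, workdir / "manifest.json")
    return manifest
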