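"""End-to-end pipeline orchestration.

Runs the stages in the order of the amplicon workflow — simulate (or
load) reads, quality control, frame-corrected translation, window
clipping, depth normalization, OTU clustering, diversity, comparison /
network, phylogeny, qPCR — under a single config with one master seed.
Every stage derives its own seed by stable hashing of the stage name, so
rerunning one stage reproduces its outputs regardless of which other
stages run. A JSON manifest records parameters and output checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster as clmod
from . import compare as cmp
from . import diversity as dvmod
from . import phylo as phmod
from . import preprocess as pp
from . import qpcr as qmod
from . import synthcomm as sc

STAGES = ("simulate", "preprocess", "cluster", "diversity", "compare", "phylo", "qpcr")


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: stable hash of the stage name mixed with the master."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # simulate
    n_taxa: int = 24
    divergence: float = 0.15
    habitats: list[dict] = field(
        default_factory=lambda: [
            {"name": "desert_soil", "richness": 6, "depth_range": [700, 900], "lognormal_sigma": 2.0},
            {"name": "field_soil", "richness": 14, "depth_range": [700, 900], "lognormal_sigma": 1.2},
        ]
    )
    substitution_rate: float = 0.001
    indel_rate: float = 0.05
    # preprocess
    min_mean_q: float = 20.0
    min_len: int = 200
    max_repairs: int = 2
    window_len: int = 108
    normalize_depth: int = 500
    # cluster / diversity
    cutoffs: list[float] = field(default_factory=lambda: [0.0, 0.04, 0.08])
    alpha: float = 0.05
    # compare
    n_perm: int = 1000
    change_threshold: float = 0.01
    ratio_threshold: float = 2.0
    network_habitats: list[str] = field(default_factory=list)
    # phylo
    bootstrap_reps: int = 100
    max_tree_otus: int = 30
    # qpcr
    qpcr_log10_copies: dict[str, float] = field(
        default_factory=lambda: {"desert_soil": 4.4, "field_soil": 6.0}
    )
    qpcr_noise_sd: float = 0.2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise ValueError("stages must respect the pipeline order")
        for h in self.habitats:
            if self.normalize_depth > h.get("depth_range", [500, 500])[0]:
                raise ValueError(
                    f"preprocess: normalize_depth {self.normalize_depth} may exceed reads "
                    f"available for habitat {h['name']}"
                )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages; returns the manifest (also written)."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "params": params,
            "outputs": {f.name: _sha256(f) for f in files},
        }

    # --- simulate -----------------------------------------------------------
    panel = sc.generate_reference_panel(
        config.n_taxa, config.divergence, seed=stage_seed(config.seed, "simulate")
    )
    habitats = [sc.HabitatSpec(**h) for h in (dict(x) for x in config.habitats)]
    for h in habitats:
        h.depth_range = tuple(h.depth_range)
    spec = sc.CommunitySpec(
        habitats=habitats,
        error_model=sc.ErrorModel(
            substitution_rate=config.substitution_rate, indel_rate=config.indel_rate
        ),
        seed=stage_seed(config.seed, "simulate"),
    )
    reads, truth = sc.simulate_reads(panel, spec)
    files: list[Path] = []
    if "simulate" in config.stages:
        sc.panel_to_fasta(panel, out / "panel_peptides.fasta", "peptide")
        sc.reads_to_fastq(reads, out / "reads.fastq")
        truth_rows = [
            {"sample": s, "read_id": rid, "taxon": t}
            for s in sorted(truth.read_taxon)
            for rid, t in truth.read_taxon[s]
        ]
        pd.DataFrame(truth_rows).to_csv(out / "truth_reads.tsv", sep="\t", index=False)
        files = [out / "panel_peptides.fasta", out / "reads.fastq", out / "truth_reads.tsv"]
        record("simulate", {"n_taxa": config.n_taxa, "divergence": config.divergence}, files)

    # --- preprocess ---------------------------------------------------------
    all_reads = [r for s in sorted(reads) for r in reads[s]]
    kept, rej_q = pp.quality_filter(all_reads, config.min_mean_q, config.min_len)
    cropped, rej_p = pp.crop_primers(kept, spec.forward_flank, spec.reverse_flank)
    frags, rej_t = pp.translate_all(cropped, panel, max_repairs=config.max_repairs)
    clipped, rej_c = pp.clip_to_window(frags, panel, config.window_len)
    by_sample: dict[str, list[pp.PeptideFragment]] = {}
    for f in clipped:
        by_sample.setdefault(f.sample, []).append(f)
    normalized = pp.subsample_normalize(
        by_sample, config.normalize_depth, seed=stage_seed(config.seed, "preprocess")
    )
    fragments = [f for s in sorted(normalized) for f in normalized[s]]
    if "preprocess" in config.stages:
        pp.fragments_to_fasta(fragments, out / "peptides.fasta")
        pp.rejections_to_frame(rej_q + rej_p + rej_t + rej_c).to_csv(
            out / "rejections.tsv", sep="\t", index=False
        )
        record(
            "preprocess",
            {
                "min_mean_q": config.min_mean_q,
                "min_len": config.min_len,
                "max_repairs": config.max_repairs,
                "normalize_depth": config.normalize_depth,
            },
            [out / "peptides.fasta", out / "rejections.tsv"],
        )

    # --- cluster ------------------------------------------------------------
    tables = {c: clmod.cluster_fragments(fragments, c) for c in config.cutoffs}
    if "cluster" in config.stages:
        files = []
        for c, table in tables.items():
            f = out / f"otu_table_{int(round(c * 100))}pct.tsv"
            table.counts.to_csv(f, sep="\t")
            files.append(f)
        record("cluster", {"cutoffs": config.cutoffs}, files)

    # --- diversity ----------------------------------------------------------
    if "diversity" in config.stages:
        summary = pd.concat([dvmod.summarize(t) for t in tables.values()], ignore_index=True)
        summary.to_csv(out / "diversity.tsv", sep="\t", index=False)
        record("diversity", {"alpha": config.alpha}, [out / "diversity.tsv"])

    # --- compare ------------------------------------------------------------
    finest = tables[max(config.cutoffs)]
    sample_habitat = truth.sample_habitat
    if "compare" in config.stages:
        files = []
        net_habs = config.network_habitats or sorted(set(sample_habitat.values()))
        if len(net_habs) >= 2:
            seed_c = stage_seed(config.seed, "compare")
            meta = {}
            for i, a in enumerate(net_habs):
                for b in net_habs[i + 1 :]:
                    samples = [s for s, h in sample_habitat.items() if h in (a, b)]
                    meta[(a, b)] = cmp.metastats_test(
                        finest.counts.loc[samples],
                        {s: sample_habitat[s] for s in samples},
                        n_perm=config.n_perm,
                        seed=seed_c,
                    )
            net_samples = {
                s: h for s, h in sample_habitat.items() if h in net_habs
            }
            sub = clmod.OtuTable(
                finest.cutoff,
                finest.counts.loc[sorted(net_samples)],
                finest.representatives,
                finest.members,
            )
            net = cmp.build_profile_network(
                sub,
                net_samples,
                metastats=meta,
                change_threshold=config.change_threshold,
                ratio_threshold=config.ratio_threshold,
                alpha=config.alpha,
            )
            cmp.network_edge_list(net).to_csv(out / "network_edges.tsv", sep="\t", index=False)
            files.append(out / "network_edges.tsv")
        sim = cmp.pearson_similarity_matrix(finest.relative())
        sim.to_csv(out / "similarity.tsv", sep="\t")
        (out / "upgma.nwk").write_text(cmp.upgma(sim).to_newick() + "\n")
        cmp.classical_mds(1.0 - sim).to_csv(out / "mds.tsv", sep="\t")
        files += [out / "similarity.tsv", out / "upgma.nwk", out / "mds.tsv"]
        record("compare", {"n_perm": config.n_perm}, files)

    # --- phylo --------------------------------------------------------------
    if "phylo" in config.stages:
        totals = finest.counts.sum(axis=0).sort_values(ascending=False)
        keep = list(totals.index[: config.max_tree_otus])
        aln = {o: finest.representatives[o] for o in keep}
        for e in panel.entries:
            aln[e.taxon] = e.peptide
        tree = phmod.bootstrap_support(
            aln, n_reps=config.bootstrap_reps, seed=stage_seed(config.seed, "phylo")
        )
        rooted = phmod.root_with_outgroup(tree, panel.outgroup.taxon)
        (out / "nj_tree.nwk").write_text(rooted.to_newick() + "\n")
        rel_tot = (finest.counts.sum(axis=0) / finest.counts.to_numpy().sum()).to_dict()
        assign = phmod.assign_canonical_cluster(
            {o: finest.representatives[o] for o in keep}, panel, rel_tot
        )
        assign.to_csv(out / "cluster_assignments.tsv", sep="\t", index=False)
        record(
            "phylo",
            {"bootstrap_reps": config.bootstrap_reps},
            [out / "nj_tree.nwk", out / "cluster_assignments.tsv"],
        )

    # --- qpcr ---------------------------------------------------------------
    if "qpcr" in config.stages:
        seed_q = stage_seed(config.seed, "qpcr")
        rng_truth = {}
        for h in habitats:
            mean = config.qpcr_log10_copies.get(h.name, 6.0)
            for r in range(h.n_replicates):
                rng_truth[f"{h.name}-{r + 1}"] = 10.0**mean
        ct, dil = sc.simulate_qpcr(
            rng_truth, ct_noise_sd=config.qpcr_noise_sd, seed=seed_q
        )
        curve = qmod.fit_standard_curve(dil)
        res = qmod.absolute_quantify(ct, curve, sample_habitat)
        qmod.quant_table(res).to_csv(out / "qpcr_quant.tsv", sep="\t", index=False)
        pairs = qmod.compare_abundances(res, alpha=config.alpha)
        pairs.to_csv(out / "qpcr_tests.tsv", sep="\t", index=False)
        record(
            "qpcr",
            {"noise_sd": config.qpcr_noise_sd, "efficiency": curve.efficiency},
            [out / "qpcr_quant.tsv", out / "qpcr_tests.tsv"],
        )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
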