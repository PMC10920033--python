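"""Stage orchestration: each stage reads serialized inputs from the run
directory, calls the library, and writes serialized outputs, so a run is
resumable and every artifact is a pure function of (inputs, config, seed)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .codon_neutral import (
    codon_counts_from_seqs,
    compute_rscu,
    extract_4d_sites,
    fit_neutral_model,
    flag_biased_codons,
    select_unbiased_4d_families,
)
from .config import PipelineConfig
from .curation import CurationConfig, curate_pairwise
from .formats_io import (
    read_fasta,
    read_gff3,
    read_maf,
    write_bed,
    write_maf,
)
from .intervals import GenomicInterval
from .model import SubstModel
from .phylo import PhyloTree
from .regions import associate_genes, common_accelerated_genes, summary_report
from .scan import ElementCall, call_elements, correct_fdr, results_to_frame, scan_windows
from .windows import assign_annotation, split_windows, window_stats

logger = logging.getLogger(__name__)


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def write_manifest(config: PipelineConfig, stage: str) -> None:
    out = _outdir(config)
    cfg = asdict(config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest_path = out / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest.setdefault("version", __version__)
    manifest["config_sha256"] = digest
    manifest["seed"] = config.seed
    manifest.setdefault("stages", [])
    if stage not in manifest["stages"]:
        manifest["stages"].append(stage)
    manifest_path.write_text(json.dumps(manifest, indent=2))


def stage_curate(config: PipelineConfig) -> Path:
    """Pairwise MAF -> curated multi-species MAF."""
    out = _outdir(config)
    blocks = read_maf(config.maf)
    per_species: dict[str, list] = {}
    for b in blocks:
        if len(b.rows) != 2:
            raise ValueError("curate expects pairwise blocks (2 rows each)")
        per_species.setdefault(b.rows[1].species, []).append(b)
    cfg = CurationConfig(
        n_run_fraction_threshold=config.n_run_fraction_threshold,
        min_species=config.min_species,
        total_species=config.total_species,
    )
    curated = curate_pairwise(per_species, config.reference, cfg)
    path = out / "curated.maf"
    write_maf(curated, path)
    write_manifest(config, "curate")
    return path


def stage_fit_neutral(config: PipelineConfig, alignments_dir: str) -> Path:
    """Per-species CDS FASTA + codon alignment FASTAs -> neutral model JSON.

    ``cds_dir`` holds one FASTA per species (<species>.fa) for codon counting;
    ``alignments_dir`` holds one FASTA per gene with species as record IDs.
    """
    out = _outdir(config)
    cds_dir = Path(config.cds_dir)
    counts = {
        fa.stem: codon_counts_from_seqs(read_fasta(fa).values())
        for fa in sorted(cds_dir.glob("*.fa")) + sorted(cds_dir.glob("*.fasta"))
    }
    table = flag_biased_codons(
        compute_rscu(counts), low=config.rscu_low, high=config.rscu_high
    )
    families = select_unbiased_4d_families(table, require=config.bias_rule)
    alignments = [
        (fa.stem, read_fasta(fa))
        for fa in sorted(Path(alignments_dir).glob("*.fa"))
        + sorted(Path(alignments_dir).glob("*.fasta"))
    ]
    topology = PhyloTree.from_newick(Path(config.tree).read_text())
    sites = extract_4d_sites(alignments, families, taxa=topology.leaf_labels)
    fit = fit_neutral_model(sites, topology, use_gamma=config.use_gamma)
    path = out / "neutral_model.json"
    fit.model.to_json(path, tree_newick=fit.tree.to_newick())
    (out / "rscu.tsv").write_text(
        pd.DataFrame(table.rscu).to_csv(sep="\t", float_format="%.4f")
    )
    (out / "retained_families.txt").write_text("\n".join(sorted(families)) + "\n")
    write_manifest(config, "fit-neutral")
    return path


def _load_windows(config: PipelineConfig, maf_path=None):
    blocks = read_maf(maf_path or config.maf)
    genes = read_gff3(config.gff3)
    segments = assign_annotation(blocks, genes)
    windows = split_windows(segments)
    return blocks, genes, segments, windows


def stage_window(config: PipelineConfig, maf_path=None) -> Path:
    """Curated MAF + GFF3 -> annotated windows BED and counts report."""
    out = _outdir(config)
    _, _, segments, windows = _load_windows(config, maf_path)
    path = out / "windows.bed"
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f"{w.ref_interval.chrom}\t{w.ref_interval.start}\t"
                f"{w.ref_interval.end}\t{w.window_id}|{w.category}|"
                f"{','.join(sorted(w.gene_ids))}\t0\t+\n"
            )
    (out / "window_stats.json").write_text(
        json.dumps(window_stats(segments, windows), indent=2)
    )
    write_manifest(config, "window")
    return path


def stage_scan(config: PipelineConfig, model_path=None, maf_path=None) -> Path:
    """Windows x neutral model -> per-window LRT results TSV."""
    out = _outdir(config)
    model_path = model_path or (out / "neutral_model.json")
    model, tree_newick = SubstModel.from_json(model_path)
    tree = PhyloTree.from_newick(tree_newick)
    _, _, _, windows = _load_windows(config, maf_path)
    branches = [b for b in config.target_branches]
    results = scan_windows(windows, tree, model, branches)
    correct_fdr(results)
    frame = results_to_frame(results)
    frame["p_conservation"] = [r.p_conservation for r in results]
    frame["p_acceleration"] = [r.p_acceleration for r in results]
    path = out / "scan_results.tsv"
    frame.to_csv(path, sep="\t", index=False)
    write_manifest(config, "scan")
    return path


def _calls_from_results(config: PipelineConfig, results_path) -> list[ElementCall]:
    frame = pd.read_csv(results_path, sep="\t", keep_default_na=False)
    calls = []
    for _, row in frame.iterrows():
        if row["q"] == "" or float(row["q"]) >= config.alpha:
            continue
        mode = row["mode"]
        scale = float(row["scale"])
        if mode == "all_branch":
            if scale >= 1.0:
                continue
            kind, branch = "all_branch_CE", None
        else:
            if scale <= 1.0:
                continue
            kind, branch = "AR", mode.split(":", 1)[1]
        gene_ids = frozenset(
            g for g in str(row["gene_ids"]).split(",") if g
        )
        calls.append(
            ElementCall(
                ref_interval=GenomicInterval(
                    row["chrom"], int(row["start"]), int(row["end"])
                ),
                window_id=row["window_id"],
                kind=kind,
                branch=branch,
                q=float(row["q"]),
                category=row["category"],
                gene_ids=gene_ids,
            )
        )
    return calls


def stage_call(config: PipelineConfig, results_path=None) -> tuple[Path, Path]:
    """Scan results -> CE and AR calls (BED + TSV)."""
    out = _outdir(config)
    results_path = results_path or (out / "scan_results.tsv")
    calls = _calls_from_results(config, results_path)
    ce_path, ar_path = out / "ce_calls.bed", out / "ar_calls.bed"
    write_bed(
        [
            (c.ref_interval, f"CE|{c.window_id}|{c.category}", f"{c.q:.3g}")
            for c in calls
            if c.kind == "all_branch_CE"
        ],
        ce_path,
    )
    write_bed(
        [
            (c.ref_interval, f"AR:{c.branch}|{c.window_id}|{c.category}", f"{c.q:.3g}")
            for c in calls
            if c.kind == "AR"
        ],
        ar_path,
    )
    pd.DataFrame(
        {
            "window_id": [c.window_id for c in calls],
            "kind": [c.kind for c in calls],
            "branch": [c.branch or "" for c in calls],
            "chrom": [c.ref_interval.chrom for c in calls],
            "start": [c.ref_interval.start for c in calls],
            "end": [c.ref_interval.end for c in calls],
            "q": [c.q for c in calls],
            "category": [c.category for c in calls],
            "gene_ids": [",".join(sorted(c.gene_ids)) for c in calls],
        }
    ).to_csv(out / "calls.tsv", sep="\t", index=False)
    write_manifest(config, "call")
    return ce_path, ar_path


def _read_calls(path) -> list[ElementCall]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        ElementCall(
            ref_interval=GenomicInterval(r["chrom"], int(r["start"]), int(r["end"])),
            window_id=r["window_id"],
            kind=r["kind"],
            branch=r["branch"] or None,
            q=float(r["q"]),
            category=r["category"],
            gene_ids=frozenset(g for g in str(r["gene_ids"]).split(",") if g),
        )
        for _, r in frame.iterrows()
    ]


def stage_associate(config: PipelineConfig, calls_path=None) -> Path:
    """Calls + GFF3 -> per-lineage gene association table TSV."""
    out = _outdir(config)
    calls = _read_calls(calls_path or (out / "calls.tsv"))
    genes = read_gff3(config.gff3)
    ces = [c for c in calls if c.kind == "all_branch_CE"]
    rows = []
    assoc_by_branch = {}
    for branch in config.target_branches:
        ars = [c for c in calls if c.kind == "AR" and c.branch == branch]
        assoc = associate_genes(
            ars,
            ces,
            genes,
            ce_overlap_required=config.ce_overlap_required,
            flank_distance=config.flank_distance,
            lineage=branch,
        )
        assoc_by_branch[branch] = assoc
        for cat, gset in assoc.by_category.items():
            for g in sorted(gset):
                rows.append({"lineage": branch, "category": cat, "gene_id": g})
    path = out / "gene_association.tsv"
    pd.DataFrame(rows, columns=["lineage", "category", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )
    # habitat-matched common genes when both members of a pair were scanned
    pairs = [("TC_open", "A_sagrei"), ("A_isolepis", "A_allogus")]
    common_rows = []
    for a, b in pairs:
        if a in assoc_by_branch and b in assoc_by_branch:
            for gene, same in common_accelerated_genes(
                assoc_by_branch[a], assoc_by_branch[b]
            ):
                common_rows.append(
                    {"lineage_a": a, "lineage_b": b, "gene_id": gene,
                     "same_window": same}
                )
    pd.DataFrame(
        common_rows, columns=["lineage_a", "lineage_b", "gene_id", "same_window"]
    ).to_csv(out / "common_genes.tsv", sep="\t", index=False)
    write_manifest(config, "associate")
    return path


def stage_report(config: PipelineConfig, maf_path=None, calls_path=None) -> Path:
    """All artifacts -> summary report JSON (coverage, proportions, enrichment)."""
    out = _outdir(config)
    blocks, genes, _, windows = _load_windows(config, maf_path)
    calls = _read_calls(calls_path or (out / "calls.tsv"))
    ces = [c for c in calls if c.kind == "all_branch_CE"]
    ars_by_branch = {
        b: [c for c in calls if c.kind == "AR" and c.branch == b]
        for b in config.target_branches
    }
    aligned = sum(len(b.ref_interval()) for b in blocks)
    ref_len = max(
        (b.reference.src_size for b in blocks), default=0
    )
    ncrna = [g.span for g in genes if g.is_ncrna]
    report = summary_report(
        aligned_bases=aligned,
        reference_length=ref_len or aligned,
        windows=windows,
        ces=ces,
        ars_by_branch=ars_by_branch,
        ncrna_features=ncrna,
        ncrna_min_frac=config.ncrna_min_frac,
        background_mode=config.background_mode,
    )
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2))
    write_manifest(config, "report")
    return path


def run_pipeline(config: PipelineConfig, maf_is_pairwise: bool = False) -> Path:
    """curate (optional) -> window -> scan -> call -> associate -> report."""
    out = _outdir(config)
    maf_path = config.maf
    if maf_is_pairwise:
        maf_path = stage_curate(config)
    stage_window(config, maf_path)
    stage_scan(config, maf_path=maf_path)
    stage_call(config)
    stage_associate(config)
    stage_report(config, maf_path=maf_path)
    return out
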