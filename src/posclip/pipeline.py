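"""End-to-end orchestration: cross-links -> peaks -> regions ->
enrichment -> occupancy -> clustering -> profiles -> motif export ->
overlap, with per-stage derived seeds and a reproducibility manifest.

Every stochastic stage derives its seed deterministically from the
global seed hashed with the stage name, so inserting or skipping a stage
does not shift the randomness of the others, and re-running an identical
configuration reproduces byte-identical outputs.
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
import yaml

from posclip import clip as clip_mod
from posclip import positional
from posclip.transcriptome import load_annotation

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Inputs and stage parameters of a pipeline run.

    Defaults are the analysis constants used throughout the package:
    50-nt start/stop windows, permutation peak FDR 0.05, binding regions
    kept above 20 reads, enrichment thresholds fold > 2 / adjusted
    p < 0.05 (non-binders |log2fc| < 0.2 and p > 0.1), consensus
    clustering with k = 5 over 200 rounds at 70% occurrence, 20-nt motif
    flanks and k-mer sizes 4/6/8/10.
    """

    annotation: str = ""
    sites_bed: str | None = None  # pre-computed cross-link sites (BED6)
    alignments: str | None = None  # read alignments (BAM/SAM or BED6)
    rna_counts: str = ""
    stemloops: str | None = None  # TSV: gene_id, stemloop_start_tx
    sequences_fasta: str | None = None
    reference_bed: str | None = None  # second RBP's binding regions
    seed: int = 1
    half_window: int = 3
    n_perm: int = 100
    peak_fdr: float = 0.05
    region_max_gap: int = 20
    region_min_reads: int = 20
    k: int = 5
    rounds: int = 200
    occurrence_min: float = 0.70
    metagene_flank: int = 500
    stemloop_window: int = 100
    motif_flank: int = 20
    kmer_sizes: tuple = (4, 6, 8, 10)
    overlap_samples: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        if "kmer_sizes" in data:
            data["kmer_sizes"] = tuple(data["kmer_sizes"])
        return cls(**data)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def map_sites_to_transcripts(sites: pd.DataFrame, models: dict) -> pd.DataFrame:
    """Assign genomic cross-link sites to transcripts and convert to
    transcript coordinates.

    Sites must match a model's chromosome and strand and fall within an
    exon; others are dropped (count logged).  Returns a tidy frame with
    gene_id, tx_pos, count.
    """
    from posclip.transcriptome import genomic_to_transcript

    by_key: dict[tuple, list] = {}
    for m in models.values():
        by_key.setdefault((m.chrom, m.strand), []).append(m)
    for key in by_key:
        by_key[key].sort(key=lambda m: m.exons[0][0])

    rows = []
    dropped = 0
    for (chrom, strand), grp in sites.groupby(["chrom", "strand"]):
        ms = by_key.get((chrom, strand), [])
        if not ms:
            dropped += len(grp)
            continue
        starts = np.array([m.exons[0][0] for m in ms])
        ends = np.array([m.exons[-1][1] for m in ms])
        pos = grp["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        for p, cnt, i in zip(pos, grp["count"].to_numpy(), idx):
            if i < 0 or p >= ends[i]:
                dropped += 1
                continue
            tx = genomic_to_transcript(ms[i], int(p))
            if tx is None:
                dropped += 1
                continue
            rows.append((ms[i].gene_id, int(tx), int(cnt)))
    if dropped:
        logger.info("dropped %d sites outside annotated exons", dropped)
    out = pd.DataFrame(rows, columns=["gene_id", "tx_pos", "count"])
    return (
        out.groupby(["gene_id", "tx_pos"], as_index=False)["count"].sum()
        .sort_values(["gene_id", "tx_pos"], kind="stable").reset_index(drop=True)
    )


def _read_fasta(path) -> dict:
    seqs: dict[str, list] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def _linearize(intervals_by_chrom: dict, chrom_offsets: dict):
    out = []
    for chrom, ivs in intervals_by_chrom.items():
        off = chrom_offsets[chrom]
        out.extend((off + s, off + e) for s, e in ivs)
    return out


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages in order, writing every declared output plus a
    manifest under ``outdir``.  Stages whose inputs are supplied
    pre-computed (e.g. a sites BED) are skipped.  Any stage error aborts
    with the stage name; outputs of completed stages are retained."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "inputs": {}, "seed": config.seed}
    cfg_yaml = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    manifest["config_hash"] = hashlib.sha256(cfg_yaml.encode()).hexdigest()
    for name in ("annotation", "sites_bed", "alignments", "rna_counts",
                 "stemloops", "sequences_fasta", "reference_bed"):
        path = getattr(config, name)
        if path:
            manifest["inputs"][name] = (
                _hash_file(path) if Path(path).is_file() else "missing"
            )

    stage = "annotation"
    try:
        models, n_excluded = load_annotation(config.annotation, dialect="gtf")
        manifest["stages"][stage] = {"n_models": len(models),
                                     "n_excluded_genes": n_excluded}

        stage = "crosslink"
        if config.sites_bed:
            sites_g = pd.read_csv(
                config.sites_bed, sep="\t", header=None,
                names=["chrom", "start", "end", "name", "score", "strand"],
            ).rename(columns={"start": "pos", "score": "count"})[
                ["chrom", "pos", "strand", "count"]
            ]
            manifest["stages"][stage] = {"skipped": True, "n_sites": len(sites_g)}
        else:
            if not config.alignments:
                raise ValueError("neither sites_bed nor alignments supplied")
            sites_g = clip_mod.call_crosslinks(config.alignments)
            manifest["stages"][stage] = {"skipped": False, "n_sites": len(sites_g)}
        sites_g.assign(end=sites_g["pos"] + 1)[
            ["chrom", "pos", "end", "strand", "count"]
        ].rename(columns={"pos": "start"}).to_csv(
            outdir / "sites.bed", sep="\t", header=False, index=False,
            columns=["chrom", "start", "end", "strand", "count"],
        )

        stage = "site_mapping"
        sites = map_sites_to_transcripts(sites_g, models)
        manifest["stages"][stage] = {"n_mapped_sites": len(sites)}

        stage = "peaks"
        grouped = {
            g: (grp["tx_pos"].to_numpy(), grp["count"].to_numpy())
            for g, grp in sites.groupby("gene_id")
        }
        lengths = {g: models[g].length for g in grouped}
        peaks = clip_mod.call_peaks(
            grouped, lengths, half_window=config.half_window,
            n_perm=config.n_perm, fdr_threshold=config.peak_fdr,
            seed=derive_seed(config.seed, "peaks"),
        )
        pd.DataFrame(
            [(p.gene_id, p.start, p.end, p.read_count, p.fdr) for p in peaks],
            columns=["gene_id", "start", "end", "read_count", "fdr"],
        ).to_csv(outdir / "peaks.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_peaks": len(peaks)}

        stage = "regions"
        regions = clip_mod.merge_peaks_to_regions(
            peaks, max_gap=config.region_max_gap, min_reads=config.region_min_reads
        )
        pd.DataFrame(
            [(r.gene_id, r.start, r.end, r.n_peaks, r.read_count) for r in regions],
            columns=["gene_id", "start", "end", "n_peaks", "read_count"],
        ).to_csv(outdir / "regions.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_regions": len(regions)}

        stage = "enrichment"
        rna = pd.read_csv(config.rna_counts, sep="\t")
        rna = rna.rename(columns={rna.columns[0]: "gene_id", rna.columns[1]: "count"})
        rna = rna[rna["gene_id"].isin(models)]
        reads_in_peaks: dict[str, int] = {}
        for p in peaks:
            reads_in_peaks[p.gene_id] = reads_in_peaks.get(p.gene_id, 0) + p.read_count
        clip_counts = pd.DataFrame(
            {"gene_id": rna["gene_id"],
             "count": [reads_in_peaks.get(g, 0) for g in rna["gene_id"]]}
        )
        enrichment = clip_mod.enrichment_test(clip_counts, rna)
        enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        enriched_genes = enrichment.loc[enrichment["status"] == "enriched", "gene_id"]
        manifest["stages"][stage] = {
            "n_tested": int(enrichment["p_value"].notna().sum()),
            "n_enriched": int(len(enriched_genes)),
            "n_non_binder": int((enrichment["status"] == "non_binder").sum()),
        }

        stage = "occupancy"
        occupancy = positional.compute_occupancy(sites, models, enriched_genes)
        occupancy.to_csv(outdir / "occupancy.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_genes": len(occupancy)}

        stage = "clustering"
        if len(occupancy) >= config.k:
            assignments, labels = positional.consensus_cluster(
                occupancy, k=config.k, rounds=config.rounds,
                occurrence_min=config.occurrence_min,
                seed=derive_seed(config.seed, "clustering"),
            )
            assignments.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "n_assigned": int((assignments["label"] != "unassigned").sum()),
                "labels": {str(k_): v for k_, v in sorted(labels.items())},
            }
        else:
            assignments = None
            manifest["stages"][stage] = {"skipped": True,
                                         "reason": "fewer occupancy genes than k"}

        stage = "metagene"
        for anchor in ("start", "stop"):
            prof = positional.metagene_profile(
                sites, models, anchor=anchor, flank=config.metagene_flank
            )
            prof.to_csv(outdir / f"metagene_{anchor}.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"flank": config.metagene_flank}

        stage = "stemloop_profile"
        if config.stemloops:
            sl = pd.read_csv(config.stemloops, sep="\t")
            prof, summary = positional.stemloop_profile(
                sites, sl, window=config.stemloop_window
            )
            prof.to_csv(outdir / "stemloop_profile.tsv", sep="\t", index=False)
            manifest["stages"][stage] = summary
        else:
            manifest["stages"][stage] = {"skipped": True}

        stage = "motifs"
        if config.sequences_fasta:
            seq_by_tx = _read_fasta(config.sequences_fasta)
            targets, bg = positional.select_motif_regions(
                regions, enrichment, seq_by_tx, flank=config.motif_flank
            )
            _write_fasta_records(targets, outdir / "motif_targets.fa")
            _write_fasta_records(bg, outdir / "motif_background.fa")
            if targets and bg:
                hits = positional.kmer_enrichment(targets, bg, sizes=config.kmer_sizes)
                hits.head(500).to_csv(outdir / "kmer_enrichment.tsv", sep="\t",
                                      index=False)
                manifest["stages"][stage] = {
                    "n_targets": len(targets), "n_background": len(bg),
                    "top_kmer": hits.iloc[0]["kmer"] if len(hits) else None,
                }
            else:
                manifest["stages"][stage] = {"n_targets": len(targets),
                                             "n_background": len(bg)}
        else:
            manifest["stages"][stage] = {"skipped": True}

        stage = "overlap"
        if config.reference_bed:
            result = _overlap_stage(config, regions, models)
            (outdir / "overlap.json").write_text(
                json.dumps(dataclasses.asdict(result), indent=2, sort_keys=True)
            )
            manifest["stages"][stage] = dataclasses.asdict(result)
        else:
            manifest["stages"][stage] = {"skipped": True}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest


def _overlap_stage(config: RunConfig, regions, models):
    """Overlap randomization of binding regions against a reference BED,
    on a per-chromosome linearized axis with the exonic workspace."""
    from posclip.transcriptome import transcript_to_genomic

    ref = pd.read_csv(
        config.reference_bed, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(3),
    )
    exons_by_chrom: dict[str, list] = {}
    for m in models.values():
        exons_by_chrom.setdefault(m.chrom, []).extend(m.exons)
    offsets, off = {}, 0
    for chrom in sorted(exons_by_chrom):
        offsets[chrom] = off
        off += max(e for _, e in exons_by_chrom[chrom]) + 1000

    query_by_chrom: dict[str, list] = {}
    for r in regions:
        m = models[r.gene_id]
        g = sorted(
            (int(transcript_to_genomic(m, r.start)),
             int(transcript_to_genomic(m, min(r.end, m.length) - 1)))
        )
        query_by_chrom.setdefault(m.chrom, []).append((g[0], g[1] + 1))
    ref_by_chrom = {
        chrom: list(zip(grp["start"], grp["end"]))
        for chrom, grp in ref.groupby("chrom") if chrom in offsets
    }
    workspace = _linearize(exons_by_chrom, offsets)
    query = _linearize(query_by_chrom, offsets)
    reference = _linearize(ref_by_chrom, offsets)
    return positional.overlap_randomization(
        query, reference, workspace, n_samples=config.overlap_samples,
        seed=derive_seed(config.seed, "overlap"),
    )


def _write_fasta_records(records, path):
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")
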