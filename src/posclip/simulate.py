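"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the positional analysis
assumes, without touching real sequencing data:

* a spliced, stranded coding transcriptome (GTF) with log-normal
  5'UTR/CDS/3'UTR lengths and a subset of "histone-like" transcripts
  carrying a 16-nt 3' stem-loop (6-base stem + 4-nt loop + 6-base stem);
* negative-binomial iCLIP / total-RNA count pairs with planted
  enrichment, and per-nucleotide cross-link sites placed by positional
  archetype (Gaussian around one of the five transcript regions,
  uniform for unbound genes, and immediately upstream of the stem-loop
  for histone-like genes);
* one-site binding curves, one-phase decay series, unwinding progress
  curves and G1/S/G2-M DNA-content histograms for the assay fitters.

All randomness flows through a single integer seed; identical
configurations produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from posclip.transcriptome import (
    REGIONS,
    TranscriptModel,
    region_lengths,
    transcript_to_genomic,
)

ARCHETYPES = REGIONS  # the five positional archetypes
NO_BINDING = "none"
HISTONE = "histone"

_NT = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.  Defaults describe a desk-scale
    cohort in which a minority of genes are bound, archetype prevalences
    are unequal (start and 5'UTR binding commonest, CDS-internal binding
    rare), and counts are moderately overdispersed.

    archetype_mix maps each of the five region archetypes plus ``none``
    (no binding) to a proportion; proportions must sum to 1.  Histone-like
    genes are drawn separately via ``n_histone_like`` and are always
    bound (sites in the 30 nt upstream of their stem-loop).
    """

    seed: int = 1
    n_genes: int = 2000
    archetype_mix: dict = field(
        default_factory=lambda: {
            "five_prime_utr": 0.07,
            "start": 0.09,
            "cds": 0.03,
            "stop": 0.06,
            "three_prime_utr": 0.06,
            "none": 0.69,
        }
    )
    enrichment_fold: float = 4.0
    library_size_clip: int = 1_000_000
    library_size_rna: int = 1_000_000
    nb_dispersion: float = 0.05
    n_histone_like: int = 50
    # transcript geometry (nt); medians of log-normal draws
    utr5_median: float = 150.0
    cds_median: float = 900.0
    utr3_median: float = 400.0
    lognorm_sigma: float = 0.6
    site_sd: float = 15.0  # Gaussian cross-link placement noise
    signal_fraction: float = 0.95  # bound genes: fraction of reads at the anchor
    hotspot_fraction: float = 0.4  # unbound genes: fraction in nonspecific clumps
    planted_motif: str | None = None
    # assay noise
    polarization_sd: float = 5.0  # mP
    ct_sd: float = 0.15  # qPCR cycles
    progress_sd: float = 0.5  # unwinding signal units
    histogram_cv: float = 0.05

    def __post_init__(self):
        mix_keys = set(ARCHETYPES) | {NO_BINDING}
        if set(self.archetype_mix) != mix_keys:
            raise ConfigError(
                f"archetype_mix must have keys {sorted(mix_keys)}, "
                f"got {sorted(self.archetype_mix)}"
            )
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-6 or any(v < 0 for v in self.archetype_mix.values()):
            raise ConfigError(f"archetype_mix proportions must sum to 1 (got {total})")
        for name in ("n_genes", "library_size_clip", "library_size_rna", "n_histone_like"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_histone_like > self.n_genes:
            raise ConfigError("n_histone_like cannot exceed n_genes")
        if self.enrichment_fold <= 0 or self.nb_dispersion <= 0:
            raise ConfigError("enrichment_fold and nb_dispersion must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SyntheticTranscriptome:
    """Models plus the per-gene true structure table."""

    models: dict  # gene_id -> TranscriptModel
    truth: pd.DataFrame  # gene_id, archetype, is_histone_like, stemloop_start_tx, ...
    sequences: dict  # gene_id -> transcript sequence (str)


# ---------------------------------------------------------------------------
# transcriptome


def simulate_transcriptome(config: SimulationConfig) -> SyntheticTranscriptome:
    """Generate a coding, spliced, stranded transcriptome with planted
    archetypes and histone-like genes.

    CDS length is always >= 150 nt so the +/-50 start/stop windows never
    overlap.  Histone-like genes get a short 3'UTR whose last 16 nt are
    the annotated stem-loop.  Archetype labels (including ``none``) are
    assigned here so that sequence simulation can plant a motif at the
    future binding anchor.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    sig = config.lognorm_sigma

    utr5 = np.maximum(20, rng.lognormal(np.log(config.utr5_median), sig, n)).astype(int)
    cds = np.maximum(150, rng.lognormal(np.log(config.cds_median), sig, n)).astype(int)
    utr3 = np.maximum(20, rng.lognormal(np.log(config.utr3_median), sig, n)).astype(int)

    is_histone = np.zeros(n, dtype=bool)
    is_histone[: config.n_histone_like] = True
    # histone-like: short 3'UTR ending in the 16-nt stem-loop
    utr3[is_histone] = rng.integers(50, 81, size=is_histone.sum())

    # archetypes for the non-histone genes
    labels = list(ARCHETYPES) + [NO_BINDING]
    probs = np.array([config.archetype_mix[k] for k in labels])
    probs = probs / probs.sum()
    arch = rng.choice(labels, size=n, p=probs)
    arch = arch.astype(object)
    arch[is_histone] = HISTONE

    models = {}
    seq_by_gene = {}
    rows = []
    cursor = {}
    for i in range(n):
        gene_id = f"G{i:05d}"
        tx_id = f"{gene_id}.t1"
        length = int(utr5[i] + cds[i] + utr3[i])
        chrom = f"chr{(i % 8) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _random_exons(rng, cursor.setdefault(chrom, 1000), length)
        cursor[chrom] = exons[-1][1] + 500
        model = TranscriptModel(
            gene_id, tx_id, chrom, strand, tuple(exons),
            int(utr5[i]), int(utr5[i] + cds[i]),
        )
        models[gene_id] = model

        sl_start = length - 16 if is_histone[i] else -1
        anchor = _archetype_anchor(model, str(arch[i]), sl_start)

        seq = rng.choice(_NT, size=length)
        if config.planted_motif and arch[i] != NO_BINDING:
            motif = list(config.planted_motif.upper().replace("U", "T"))
            pos = min(max(anchor - len(motif) // 2, 0), length - len(motif))
            seq[pos : pos + len(motif)] = motif
        seq_by_gene[gene_id] = "".join(seq)

        rows.append(
            {
                "gene_id": gene_id,
                "transcript_id": tx_id,
                "chrom": chrom,
                "strand": strand,
                "utr5_len": int(utr5[i]),
                "cds_len": int(cds[i]),
                "utr3_len": int(utr3[i]),
                "tx_len": length,
                "archetype": str(arch[i]),
                "is_histone_like": bool(is_histone[i]),
                "stemloop_start_tx": sl_start,
                "anchor_tx": anchor,
            }
        )
    truth = pd.DataFrame(rows)
    return SyntheticTranscriptome(models=models, truth=truth, sequences=seq_by_gene)


def _random_exons(rng, start, length):
    """Split ``length`` spliced nt into 1-4 exons with 100-2000 nt introns."""
    n_exons = int(rng.integers(1, 5))
    n_exons = min(n_exons, max(1, length // 100))
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)) \
        if n_exons > 1 else np.array([], dtype=int)
    sizes = np.diff(np.concatenate([[0], cuts, [length]]))
    exons = []
    g = int(start)
    for sz in sizes:
        exons.append((g, g + int(sz)))
        g += int(sz) + int(rng.integers(100, 2001))
    return exons


def _archetype_anchor(model: TranscriptModel, archetype: str, sl_start: int) -> int:
    """Transcript coordinate around which cross-link sites concentrate."""
    lens = region_lengths(model)
    bounds = np.concatenate([[0], np.cumsum(lens)])
    if archetype == HISTONE:
        return max(sl_start - 15, 0)
    if archetype == NO_BINDING:
        return model.length // 2
    if archetype == "start":
        return model.cds_start_tx
    if archetype == "stop":
        return model.cds_end_tx
    i = REGIONS.index(archetype)
    lo, hi = int(bounds[i]), int(bounds[i + 1])
    if hi <= lo:  # degenerate region; fall back to nearest window edge
        return min(max(lo, 0), model.length - 1)
    return (lo + hi) // 2


# ---------------------------------------------------------------------------
# CLIP counts and cross-link sites


def simulate_clip(config: SimulationConfig, transcriptome: SyntheticTranscriptome):
    """Plant negative-binomial count pairs and positional cross-link sites.

    Per gene, the total-RNA count is NB(mean, dispersion) around a
    log-normal expression level scaled to the RNA library size; the iCLIP
    mean is the RNA-proportional baseline times ``enrichment_fold`` for
    bound genes (archetype other than ``none``).  Cross-link positions
    follow the gene's archetype: Gaussian (sd ``site_sd``) around the
    archetype anchor, the 30 nt upstream of the stem-loop for
    histone-like genes, uniform for unbound genes.

    Returns a dict with ``sites`` (tidy per-gene transcript-coordinate
    site table), ``genomic_sites`` (BED-ready genomic table),
    ``rna_counts`` and ``truth``.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = transcriptome.truth
    n = len(truth)

    expr = rng.lognormal(0.0, 0.8, size=n)
    rna_mean = expr / expr.sum() * config.library_size_rna
    bound = (truth["archetype"] != NO_BINDING).to_numpy()
    fold = np.where(bound, config.enrichment_fold, 1.0)
    depth_ratio = config.library_size_clip / config.library_size_rna
    clip_mean = rna_mean * fold * depth_ratio

    alpha = config.nb_dispersion
    rna_count = _nb_draw(rng, rna_mean, alpha)
    clip_count = _nb_draw(rng, clip_mean, alpha)

    site_rows = []
    genomic_rows = []
    for i, row in enumerate(truth.itertuples(index=False)):
        model = transcriptome.models[row.gene_id]
        n_reads = int(clip_count[i])
        if n_reads == 0:
            continue
        pos = _place_sites(rng, model, row, n_reads, config.site_sd,
                           config.signal_fraction, config.hotspot_fraction)
        upos, counts = np.unique(pos, return_counts=True)
        gpos = transcript_to_genomic(model, upos)
        for p, c, g in zip(upos, counts, gpos):
            site_rows.append((row.gene_id, int(p), int(c)))
            genomic_rows.append(
                (model.chrom, int(g), int(g) + 1, row.gene_id, int(c), model.strand)
            )

    sites = pd.DataFrame(site_rows, columns=["gene_id", "tx_pos", "count"])
    genomic_sites = pd.DataFrame(
        genomic_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    ).sort_values(["chrom", "start", "strand"], kind="stable").reset_index(drop=True)

    rna_counts = pd.DataFrame({"gene_id": truth["gene_id"], "count": rna_count})
    clip_truth = truth.assign(
        enriched=bound & (config.enrichment_fold > 1),
        rna_mean=rna_mean,
        clip_mean=clip_mean,
        rna_count=rna_count,
        clip_count=clip_count,
    )
    return {
        "sites": sites,
        "genomic_sites": genomic_sites,
        "rna_counts": rna_counts,
        "truth": clip_truth,
    }


def _nb_draw(rng, mean, alpha):
    """NB(mean mu, variance mu + alpha*mu^2) via gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * np.clip(mean, 1e-12, None))
    return rng.poisson(lam).astype(np.int64)


def _place_sites(rng, model, row, n_reads, site_sd,
                 signal_fraction=0.95, hotspot_fraction=0.4):
    """Cross-link read positions for one gene.

    Bound genes put ``signal_fraction`` of their reads in a Gaussian at
    the archetype anchor over a uniform floor; unbound genes draw
    ``hotspot_fraction`` of reads from 1-3 nonspecific clumps
    (cross-linking background is clumpy, not uniform) and the rest
    uniformly; histone-like genes place everything in the 30 nt upstream
    of the stem-loop.
    """
    L = model.length
    if row.archetype == NO_BINDING:
        n_hot = int(rng.integers(1, 4))
        centers = rng.integers(0, L, size=n_hot)
        is_hot = rng.random(n_reads) < hotspot_fraction
        pos = rng.integers(0, L, size=n_reads)
        if is_hot.any():
            which = rng.integers(0, n_hot, size=int(is_hot.sum()))
            hot = np.rint(
                rng.normal(centers[which], site_sd)
            ).astype(np.int64)
            pos[is_hot] = np.clip(hot, 0, L - 1)
        return pos
    if row.is_histone_like:
        lo = max(int(row.stemloop_start_tx) - 30, 0)
        hi = int(row.stemloop_start_tx)  # exclusive: never 3' of the stem-loop
        return rng.integers(lo, max(hi, lo + 1), size=n_reads)
    pos = np.rint(rng.normal(row.anchor_tx, site_sd, size=n_reads)).astype(np.int64)
    pos = np.clip(pos, 0, L - 1)
    is_bg = rng.random(n_reads) >= signal_fraction
    if is_bg.any():
        pos[is_bg] = rng.integers(0, L, size=int(is_bg.sum()))
    return pos


# ---------------------------------------------------------------------------
# assay generators


def simulate_binding_curve(kd, fp_free, fp_bound, concentrations, sd, seed):
    """One-site saturation curve: FP(c) = free + (bound-free)*c/(kd+c) + noise.

    Returns a DataFrame with ``concentration_nM`` and ``polarization_mP``.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    fp = fp_free + (fp_bound - fp_free) * conc / (kd + conc)
    fp = fp + rng.normal(0.0, sd, size=conc.shape) if sd > 0 else fp
    return pd.DataFrame({"concentration_nM": conc, "polarization_mP": fp})


def simulate_decay(t_half, plateau, timepoints, sd, n_reps, seed):
    """One-phase decay series: y(t) = (1-plateau)*exp(-ln2 t/t_half) + plateau.

    The t=0 value is exactly 1 before noise.  Returns a DataFrame with
    ``time_h``, ``relative_abundance`` and ``replicate``.
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    if not 0 <= plateau < 1:
        raise ValueError("plateau must be in [0, 1)")
    t = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)
    frames = []
    for rep in range(n_reps):
        y = (1.0 - plateau) * np.exp(-np.log(2) * t / t_half) + plateau
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=t.shape)
        frames.append(
            pd.DataFrame({"time_h": t, "relative_abundance": y, "replicate": rep})
        )
    return pd.concat(frames, ignore_index=True)


def simulate_dna_histogram(fractions_g1_s_g2, g1_mean, cv, n_events, seed, n_bins=128):
    """DNA-content histogram of a G1/S/G2-M mixture.

    G1 events are Normal(g1_mean, cv*g1_mean); G2/M events are
    Normal(2*g1_mean, cv*2*g1_mean); S events are uniform between the two
    means, then blurred multiplicatively with the same CV.  Returns
    ``(bin_centers, counts, truth_fractions)``; counts sum to n_events.
    """
    frac = np.asarray(fractions_g1_s_g2, dtype=float)
    if frac.shape != (3,) or np.any(frac < 0) or abs(frac.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must be three non-negative values summing to 1")
    if not 0 < cv <= 0.2:
        raise ValueError("cv must be in (0, 0.2]")
    rng = np.random.default_rng(seed)
    n = rng.multinomial(n_events, frac)
    g1 = rng.normal(g1_mean, cv * g1_mean, size=n[0])
    s = rng.uniform(g1_mean, 2 * g1_mean, size=n[1])
    s = s * rng.normal(1.0, cv, size=n[1])
    g2 = rng.normal(2 * g1_mean, cv * 2 * g1_mean, size=n[2])
    events = np.concatenate([g1, s, g2])
    edges = np.linspace(0.0, 3.2 * g1_mean, n_bins + 1)
    counts, _ = np.histogram(np.clip(events, edges[0], edges[-1] - 1e-9), bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts.astype(np.int64), frac


def simulate_unwinding(velocity, lag, plateau, timepoints, sd, seed, baseline=0.0):
    """Unwinding progress curve: flat during the lag, then a linear rise at
    ``velocity`` capped at ``plateau``; Gaussian noise, clipped at
    plateau + 3*sd (detector saturation).

    Returns a DataFrame with ``time_min`` and ``signal``.
    """
    if velocity < 0:
        raise ValueError("velocity must be >= 0")
    t = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)
    signal = baseline + np.clip(velocity * (t - lag), 0.0, None)
    signal = np.minimum(signal, plateau)
    if sd > 0:
        signal = signal + rng.normal(0.0, sd, size=t.shape)
        signal = np.minimum(signal, plateau + 3 * sd)
    return pd.DataFrame({"time_min": t, "signal": signal})


# ---------------------------------------------------------------------------
# file emission


def write_gtf(transcriptome: SyntheticTranscriptome, path):
    """Write the synthetic annotation as GTF (1-based closed coordinates).

    CDS features are emitted per exon segment and cover the full coding
    region including the stop codon.
    """
    lines = []
    for gene_id in sorted(transcriptome.models):
        m = transcriptome.models[gene_id]
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
        for s, e in m.exons:
            lines.append(
                f"{m.chrom}\tposclip\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}"
            )
        # genomic CDS span, clipped per exon
        g1 = transcript_to_genomic(m, m.cds_start_tx)
        g2 = transcript_to_genomic(m, m.cds_end_tx - 1)
        lo, hi = (g1, g2 + 1) if g1 <= g2 else (g2, g1 + 1)
        for s, e in m.exons:
            cs, ce = max(s, lo), min(e, hi)
            if cs < ce:
                lines.append(
                    f"{m.chrom}\tposclip\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t.\t{attrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(sequences: dict, path):
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n{sequences[name]}\n")


def simulate_all(config: SimulationConfig, outdir):
    """Emit every pipeline input under ``outdir`` and return the in-memory
    objects.  File set: annotation.gtf, transcripts.fa, sites.bed,
    rna_counts.tsv, truth_genes.tsv, truth_sites.tsv plus assay CSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    txome = simulate_transcriptome(config)
    clip = simulate_clip(config, txome)

    write_gtf(txome, outdir / "annotation.gtf")
    write_fasta(txome.sequences, outdir / "transcripts.fa")
    clip["genomic_sites"].to_csv(
        outdir / "sites.bed", sep="\t", header=False, index=False
    )
    clip["rna_counts"].to_csv(outdir / "rna_counts.tsv", sep="\t", index=False)
    clip["truth"].to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    clip["sites"].to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)

    # stem-loop annotation (transcript coordinates) for histone-like genes
    sl = clip["truth"].query("is_histone_like")[
        ["gene_id", "stemloop_start_tx"]
    ].assign(stemloop_end_tx=lambda d: d["stemloop_start_tx"] + 16)
    sl.to_csv(outdir / "stemloops.tsv", sep="\t", index=False)

    # assay tables at the cohort's reference parameters
    conc = np.array([8, 16, 31, 63, 125, 250, 375, 500, 750, 1000, 1500, 2000.0])
    simulate_binding_curve(
        200.0, 50.0, 250.0, conc, config.polarization_sd, config.seed + 10
    ).assign(replicate=0).to_csv(outdir / "binding_curve.csv", index=False)
    simulate_decay(
        2.0, 0.05, [0, 1, 2, 4, 8.0], 0.05, 3, config.seed + 11
    ).to_csv(outdir / "decay.csv", index=False)
    simulate_unwinding(
        3.0, 5.0, 60.0, np.arange(0, 41.0), config.progress_sd, config.seed + 12
    ).to_csv(outdir / "unwinding.csv", index=False)
    centers, counts, _ = simulate_dna_histogram(
        (0.6, 0.3, 0.1), 100.0, config.histogram_cv, 10_000, config.seed + 13
    )
    pd.DataFrame({"channel": centers, "count": counts}).to_csv(
        outdir / "dna_histogram.csv", index=False
    )
    return {"transcriptome": txome, "clip": clip}
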