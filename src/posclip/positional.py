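"""Five-region occupancy, positional profiles, consensus clustering,
motif region selection, and interval-overlap randomization.

All site tables here are in transcript coordinates (tidy frame with
columns ``gene_id``, ``tx_pos``, ``count``); the pipeline converts
genomic cross-link sites beforehand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from posclip.transcriptome import REGIONS, classify_positions, region_lengths

logger = logging.getLogger(__name__)

OCCUPANCY_READ_MIN = 20  # genes must exceed this many site reads (strict)


# ---------------------------------------------------------------------------
# occupancy


def compute_occupancy(
    sites: pd.DataFrame,
    models: dict,
    enriched_genes,
    library_size: float | None = None,
    min_reads: int = OCCUPANCY_READ_MIN,
) -> pd.DataFrame:
    """Per-gene five-region counts and RPKM.

    Considers enriched genes with strictly more than ``min_reads`` total
    site reads.  RPKM_i = count_i / (region_kb_i * library_millions)
    where the library size defaults to the total site reads over all
    considered genes; zero-length regions get RPKM 0.  Genes failing the
    read filter are excluded (count logged); an enriched gene without a
    model raises.
    """
    enriched_genes = list(enriched_genes)
    missing = sorted(set(enriched_genes) - set(models))
    if missing:
        raise KeyError(f"genes without a model: {missing[:10]}")
    grouped = {g: grp for g, grp in sites.groupby("gene_id")}
    kept, skipped = [], 0
    for g in enriched_genes:
        grp = grouped.get(g)
        total = int(grp["count"].sum()) if grp is not None else 0
        if total > min_reads:
            kept.append((g, grp))
        else:
            skipped += 1
    if skipped:
        logger.info("occupancy: excluded %d genes with <=%d reads", skipped, min_reads)

    rows = []
    for g, grp in kept:
        model = models[g]
        codes = classify_positions(model, grp["tx_pos"].to_numpy())
        counts = np.zeros(len(REGIONS), dtype=np.int64)
        np.add.at(counts, codes, grp["count"].to_numpy())
        rows.append((g, counts, region_lengths(model)))
    if library_size is None:
        library_size = float(sum(r[1].sum() for r in rows))
    lib_m = max(library_size, 1.0) / 1e6

    out = []
    for g, counts, lens in rows:
        kb = lens / 1000.0
        with np.errstate(divide="ignore", invalid="ignore"):
            rpkm = np.where(kb > 0, counts / (kb * lib_m), 0.0)
        rec = {"gene_id": g}
        rec.update({f"count_{r}": int(c) for r, c in zip(REGIONS, counts)})
        rec.update({f"rpkm_{r}": float(v) for r, v in zip(REGIONS, rpkm)})
        out.append(rec)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# profiles


def metagene_profile(sites: pd.DataFrame, models: dict, anchor: str = "start",
                     flank: int = 500) -> pd.DataFrame:
    """Mean normalized site density around the start or stop codon.

    Each gene's per-position counts are normalized to sum to 1 over its
    transcript; offsets are taken relative to the anchor (first CDS base
    for ``start``, first 3'UTR base for ``stop``); the per-offset mean is
    over the genes whose transcript covers that offset.  Returns a frame
    with ``offset``, ``density`` and ``n`` (contributing genes).
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    offsets = np.arange(-flank, flank + 1)
    dens_sum = np.zeros(offsets.size)
    n_genes = np.zeros(offsets.size, dtype=np.int64)
    grouped = dict(tuple(sites.groupby("gene_id")))
    any_gene = False
    for g, model in models.items():
        a = model.cds_start_tx if anchor == "start" else model.cds_end_tx
        lo, hi = -a, model.length - a  # offsets covered by this transcript
        cover = (offsets >= lo) & (offsets < hi)
        if not cover.any():
            continue
        any_gene = True
        n_genes += cover
        grp = grouped.get(g)
        if grp is None:
            continue
        total = grp["count"].sum()
        off = grp["tx_pos"].to_numpy() - a
        sel = (off >= -flank) & (off <= flank)
        np.add.at(dens_sum, off[sel] + flank, grp["count"].to_numpy()[sel] / total)
    if not any_gene:
        raise ValueError("no gene overlaps the requested window")
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(n_genes > 0, dens_sum / n_genes, 0.0)
    return pd.DataFrame({"offset": offsets, "density": density, "n": n_genes})


def stemloop_profile(sites: pd.DataFrame, stemloops: pd.DataFrame,
                     window: int = 100) -> tuple[pd.DataFrame, dict]:
    """Site density relative to the stem-loop start on histone-like genes.

    ``stemloops`` needs columns ``gene_id`` and ``stemloop_start_tx``.
    Offsets run from -window to window-1 (2*window bins; negative =
    upstream of the stem-loop's first base).  Each gene's in-window
    counts are normalized to a per-gene proportion; genes without sites
    contribute zeros.  Returns the averaged profile and a summary with
    the upstream/downstream density split.
    """
    offsets = np.arange(-window, window)
    profile = np.zeros(offsets.size)
    grouped = dict(tuple(sites.groupby("gene_id")))
    n = 0
    for row in stemloops.itertuples(index=False):
        n += 1
        grp = grouped.get(row.gene_id)
        if grp is None:
            continue
        off = grp["tx_pos"].to_numpy() - int(row.stemloop_start_tx)
        sel = (off >= -window) & (off < window)
        w = grp["count"].to_numpy()[sel].astype(float)
        if w.sum() == 0:
            continue
        vec = np.zeros(offsets.size)
        np.add.at(vec, off[sel] + window, w / w.sum())
        profile += vec
    if n == 0:
        raise ValueError("empty stem-loop annotation")
    profile /= n
    total = profile.sum()
    upstream = profile[offsets < 0].sum()
    summary = {
        "n_genes": n,
        "upstream_fraction": float(upstream / total) if total > 0 else np.nan,
        "downstream_fraction": float(1 - upstream / total) if total > 0 else np.nan,
        "peak_offset": int(offsets[np.argmax(profile)]) if total > 0 else 0,
    }
    return pd.DataFrame({"offset": offsets, "density": profile}), summary


# ---------------------------------------------------------------------------
# consensus clustering


@dataclass
class ClusterAssignment:
    gene_id: str
    label: str  # one of REGIONS or "unassigned"
    occurrence: float
    euclidean_fallback: bool = False


def _row_normalize(X):
    totals = X.sum(axis=1, keepdims=True)
    out = np.divide(X, totals, out=np.full_like(X, np.nan, dtype=float),
                    where=totals > 0)
    out[np.isnan(out).any(axis=1)] = 1.0 / X.shape[1]
    return out


def _pearson_to_centers(X, C):
    """Correlation of each row of X with each row of C; nan where either
    side has zero variance."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    cn = np.linalg.norm(Cc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Cc.T) / np.outer(xn, cn)
    r[xn == 0, :] = np.nan
    r[:, cn == 0] = np.nan
    return r


def _assign(X, C):
    """Nearest-centre assignment under 1 - Pearson distance.

    Ties go to the lowest cluster index.  Rows (or centre columns) with
    zero variance fall back to Euclidean distance; returns the flag mask
    for constant gene rows.
    """
    r = _pearson_to_centers(X, C)
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    # scale Euclidean into a fallback score strictly below any real correlation
    fallback = -2.0 - d2 / (d2.max() + 1.0)
    score = np.where(np.isnan(r), fallback, r)
    const_rows = np.isnan(r).all(axis=1)
    score[const_rows] = -d2[const_rows]
    return score.argmax(axis=1), const_rows


def _plusplus_init(X, k, rng):
    """k-means++ seeding under 1 - Pearson distance (squared-distance
    weighting; Euclidean fallback distances for constant rows)."""
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    for _ in range(k - 1):
        C = X[idx]
        r = _pearson_to_centers(X, C)
        d = 1.0 - r
        if np.isnan(d).any():
            d2 = np.sqrt(((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2))
            d = np.where(np.isnan(d), d2, d)
        dmin = d.min(axis=1)
        w = dmin**2
        total = w.sum()
        if total <= 0:
            idx.append(int(rng.integers(n)))
            continue
        idx.append(int(rng.choice(n, p=w / total)))
    return X[idx].copy()


def _kmeans_round(X, k, rng, max_iter=100):
    n = X.shape[0]
    centers = _plusplus_init(X, k, rng)
    assign = np.full(n, -1)
    flagged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        new_assign, flagged = _assign(X, centers)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = X[assign == j]
            if len(members):
                centers[j] = np.median(members, axis=0)
    # round quality: mean correlation of non-constant genes to their centre
    r = _pearson_to_centers(X, centers)
    per_gene = r[np.arange(n), assign]
    quality = float(np.nanmean(per_gene)) if np.any(np.isfinite(per_gene)) else -np.inf
    return assign, centers, flagged, quality


def _greedy_match(ref_centers, centers):
    """Map each cluster of this round onto a reference cluster by greedy
    highest-correlation pairing."""
    k = len(ref_centers)
    r = _pearson_to_centers(centers, ref_centers)
    r = np.where(np.isnan(r), -np.inf, r)
    mapping = np.full(k, -1)
    used_ref = set()
    order = np.dstack(np.unravel_index(np.argsort(r, axis=None)[::-1], r.shape))[0]
    for i, j in order:
        if mapping[i] == -1 and j not in used_ref:
            mapping[i] = j
            used_ref.add(j)
        if len(used_ref) == k:
            break
    return mapping


def _bootstrap_inputs(occupancy: pd.DataFrame, default_depth: int):
    """Per-gene count proportions, depths and region weights for the
    perturbation bootstrap.

    When the occupancy frame carries ``count_*`` columns (as produced by
    :func:`compute_occupancy`) the bootstrap resamples those counts at
    the gene's own read depth and maps them back to the RPKM scale via
    the implied region lengths.  A plain numeric matrix is treated as
    proportions resampled at ``default_depth``.
    """
    count_cols = [f"count_{r}" for r in REGIONS]
    rpkm_cols = [f"rpkm_{r}" for r in REGIONS]
    if all(c in occupancy.columns for c in count_cols + rpkm_cols):
        counts = occupancy[count_cols].to_numpy(dtype=float)
        rpkm = occupancy[rpkm_cols].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_len = np.where(counts > 0, rpkm / counts, 0.0)
        have_counts = True
    else:
        cols = [c for c in occupancy.columns if c.startswith("rpkm_")]
        if len(cols) != len(REGIONS):
            cols = [c for c in occupancy.columns if c != "gene_id"][: len(REGIONS)]
        counts = occupancy[cols].to_numpy(dtype=float)
        inv_len = np.ones_like(counts)
        have_counts = False
    totals = counts.sum(axis=1, keepdims=True)
    p = np.divide(counts, totals, out=np.full_like(counts, 1.0 / len(REGIONS)),
                  where=totals > 0)
    if have_counts:
        depth = np.where(totals[:, 0] > 0.5, np.rint(totals[:, 0]), default_depth)
    else:
        depth = np.full(len(counts), default_depth, dtype=float)
    # inv_len fills for zero-count regions: per-gene mean of known weights
    known = inv_len > 0
    fill = np.where(known.any(axis=1),
                    inv_len.sum(axis=1) / np.maximum(known.sum(axis=1), 1), 1.0)
    inv_len = np.where(known, inv_len, fill[:, None])
    return p, depth.astype(np.int64), inv_len


def consensus_cluster(
    occupancy: pd.DataFrame,
    k: int = 5,
    rounds: int = 200,
    occurrence_min: float = 0.70,
    seed: int = 0,
    bootstrap_depth: int = 50,
) -> tuple[pd.DataFrame, dict]:
    """Perturbation-consensus k-means over five-region occupancy rows.

    ``occupancy`` is the frame from :func:`compute_occupancy` (its
    ``count_*``/``rpkm_*`` columns are used) or any frame with
    ``gene_id`` plus five numeric columns in region order.  Each of
    ``rounds`` rounds (i) parametrically bootstraps every gene's region
    counts at the gene's own read depth (multinomial resampling; a gene
    whose apparent region preference rests on sampling noise changes
    preference between rounds, a genuinely structured gene does not),
    (ii) runs k-means with distance 1 - Pearson correlation and
    component-wise median centres from random initial centres.  Rounds
    are aligned by greedy centre matching to the best round (highest
    mean gene-to-centre correlation); a gene's occurrence is the
    fraction of rounds spent in its modal aligned cluster and genes
    below ``occurrence_min`` are unassigned.  Each consensus cluster is
    labelled by the region of its centre's largest component.

    Constant rows (Pearson undefined) are assigned by Euclidean fallback
    and flagged.  Returns the assignment frame and a dict mapping
    cluster index to region label.
    """
    genes = occupancy["gene_id"].to_numpy()
    if len(genes) < k:
        raise ValueError(f"need at least k={k} genes, got {len(genes)}")
    p, depth, inv_len = _bootstrap_inputs(occupancy, bootstrap_depth)
    rng = np.random.default_rng(seed)

    results = []
    any_flag = np.zeros(len(genes), dtype=bool)
    for _ in range(rounds):
        resampled = rng.multinomial(depth, p) * inv_len
        X = _row_normalize(resampled)
        assign, centers, flagged, quality = _kmeans_round(X, k, rng)
        any_flag |= flagged
        results.append((assign, centers, quality))

    # align every round to the best one so a bad local optimum cannot
    # poison the consensus
    ref_centers = max(results, key=lambda r: r[2])[1]
    tally = np.zeros((len(genes), k), dtype=np.int64)
    for assign, centers, _ in results:
        mapping = _greedy_match(ref_centers, centers)
        tally[np.arange(len(genes)), mapping[assign]] += 1

    modal = tally.argmax(axis=1)
    occurrence = tally[np.arange(len(genes)), modal] / rounds

    X0 = _row_normalize(p * inv_len)
    labels = {}
    for j in range(k):
        members = X0[(modal == j) & (occurrence >= occurrence_min)]
        center = np.median(members, axis=0) if len(members) else ref_centers[j]
        labels[j] = REGIONS[int(np.argmax(center))]

    out = pd.DataFrame(
        {
            "gene_id": genes,
            "cluster": modal,
            "occurrence": occurrence,
            "label": [
                labels[m] if occ >= occurrence_min else "unassigned"
                for m, occ in zip(modal, occurrence)
            ],
            "euclidean_fallback": any_flag,
        }
    )
    return out, labels


# ---------------------------------------------------------------------------
# motif target/background selection and k-mer scoring


def select_motif_regions(
    regions: list,
    enrichment: pd.DataFrame,
    sequences: dict,
    flank: int = 20,
    min_reads: int = 20,
):
    """Target and background sequence windows for motif scoring.

    Targets: for each enriched gene, the single binding region with the
    most peaks (ties: most reads, then 5'-most), trimmed to ``flank`` nt
    on each side of the region centre.  Background: every region with
    more than ``min_reads`` reads on a non-binder gene, trimmed the same
    way.  Returns two lists of ``(header, sequence)`` records with
    transcript coordinates in the headers.
    """
    status = enrichment.set_index("gene_id")["status"]
    by_gene: dict[str, list] = {}
    for r in regions:
        by_gene.setdefault(r.gene_id, []).append(r)

    targets, background = [], []
    n_skipped = 0
    for g in status.index[status == "enriched"]:
        rs = by_gene.get(g)
        if not rs:
            n_skipped += 1
            continue
        best = sorted(rs, key=lambda r: (-r.n_peaks, -r.read_count, r.start))[0]
        rec = _trim_record(best, sequences, flank)
        if rec:
            targets.append(rec)
        else:
            n_skipped += 1
    if n_skipped:
        logger.info("motif targets: skipped %d enriched genes without a usable region",
                    n_skipped)
    for g in status.index[status == "non_binder"]:
        for r in by_gene.get(g, []):
            if r.read_count > min_reads:
                rec = _trim_record(r, sequences, flank)
                if rec:
                    background.append(rec)
    return targets, background


def _trim_record(region, sequences, flank):
    seq = sequences.get(region.gene_id)
    if seq is None:
        return None
    centre = (region.start + region.end) // 2
    lo = max(centre - flank, 0)
    hi = min(centre + flank, len(seq))
    if hi <= lo:
        return None
    return (f"{region.gene_id}:{lo}-{hi}", seq[lo:hi])


def kmer_enrichment(targets, background, sizes=(4, 6, 8, 10)) -> pd.DataFrame:
    """Presence/absence k-mer over-representation in targets vs background.

    ``targets`` and ``background`` are sequences or (header, sequence)
    records.  For each k-mer observed in either set, the one-sided
    hypergeometric p-value tests whether target sequences contain it more
    often than expected; BH adjustment is applied within each k-mer size.
    Sequences shorter than k are skipped for that size.
    """
    tseqs = [s[1] if isinstance(s, tuple) else s for s in targets]
    bseqs = [s[1] if isinstance(s, tuple) else s for s in background]
    if not tseqs or not bseqs:
        raise ValueError("both target and background sets must be non-empty")
    frames = []
    for k in sizes:
        t_use = [s.upper().replace("U", "T") for s in tseqs if len(s) >= k]
        b_use = [s.upper().replace("U", "T") for s in bseqs if len(s) >= k]
        if not t_use or not b_use:
            continue
        t_sets = [{s[i:i + k] for i in range(len(s) - k + 1)} for s in t_use]
        b_sets = [{s[i:i + k] for i in range(len(s) - k + 1)} for s in b_use]
        kmers = sorted(set().union(*t_sets, *b_sets))
        t_hits = np.array([sum(km in st for st in t_sets) for km in kmers])
        b_hits = np.array([sum(km in sb for sb in b_sets) for km in kmers])
        M = len(t_use) + len(b_use)
        p = stats.hypergeom.sf(t_hits - 1, M, t_hits + b_hits, len(t_use))
        frames.append(
            pd.DataFrame(
                {
                    "kmer": kmers,
                    "size": k,
                    "target_frac": t_hits / len(t_use),
                    "background_frac": b_hits / len(b_use),
                    "p_value": p,
                    "p_adj": multipletests(p, method="fdr_bh")[1],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["p_value", "kmer"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# overlap randomization


def _merge_intervals(intervals):
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _overlap_nt(a_starts, a_ends, b_starts, b_ends):
    """Total intersection length between two merged interval sets."""
    total = 0
    j = 0
    for s, e in zip(a_starts, a_ends):
        while j < len(b_starts) and b_ends[j] <= s:
            j += 1
        jj = j
        while jj < len(b_starts) and b_starts[jj] < e:
            total += min(e, b_ends[jj]) - max(s, b_starts[jj])
            jj += 1
    return total


@dataclass
class OverlapTestResult:
    observed_overlap: int
    expected_overlap: float
    fold: float
    p_empirical: float
    n_samples: int


def overlap_randomization(query, reference, workspace, n_samples=1000, seed=0,
                          max_tries=1000) -> OverlapTestResult:
    """Segment-preserving overlap randomization.

    ``query``, ``reference`` and ``workspace`` are interval lists
    ``(start, end)`` on a common axis; query and reference must lie
    within the workspace.  Each of ``n_samples`` draws re-places the
    query segments (lengths preserved, mutually non-overlapping,
    rejection sampling) uniformly at random within the workspace and
    records the nt overlap with the reference.  The empirical p-value is
    ``(#samples with overlap >= observed + 1) / (n_samples + 1)`` and the
    fold is observed over the sampled mean.
    """
    ws = _merge_intervals(workspace)
    q = _merge_intervals(query)
    ref = _merge_intervals(reference)
    ws_len = sum(e - s for s, e in ws)
    q_lens = [e - s for s, e in q]
    if sum(q_lens) > ws_len:
        raise ValueError("workspace smaller than total query length")

    r_starts = [s for s, _ in ref]
    r_ends = [e for _, e in ref]
    observed = _overlap_nt([s for s, _ in q], [e for _, e in q], r_starts, r_ends)

    rng = np.random.default_rng(seed)
    sampled = np.empty(n_samples)
    # place longest segments first so rejection sampling terminates quickly
    order = sorted(q_lens, reverse=True)
    for i in range(n_samples):
        placed = _place_segments(rng, order, ws, max_tries)
        placed.sort()
        sampled[i] = _overlap_nt(
            [s for s, _ in placed], [e for _, e in placed], r_starts, r_ends
        )
    exp = float(sampled.mean())
    p = (float((sampled >= observed).sum()) + 1.0) / (n_samples + 1.0)
    if exp > 0:
        fold = observed / exp
    else:
        fold = 0.0 if observed == 0 else float("inf")
    return OverlapTestResult(
        observed_overlap=int(observed),
        expected_overlap=exp,
        fold=float(fold),
        p_empirical=float(p),
        n_samples=n_samples,
    )


def _place_segments(rng, lengths, workspace, max_tries):
    """Place segments uniformly within the workspace without mutual
    overlap, by rejection."""
    placed: list[tuple[int, int]] = []
    for L in lengths:
        starts_per_iv = [(s, e - L) for s, e in workspace if e - s >= L]
        if not starts_per_iv:
            raise ValueError(f"no workspace interval can hold a segment of length {L}")
        weights = np.array([hi - lo + 1 for lo, hi in starts_per_iv], dtype=float)
        cum = np.cumsum(weights)
        for _ in range(max_tries):
            u = rng.random() * cum[-1]
            idx = int(np.searchsorted(cum, u, side="right"))
            lo, hi = starts_per_iv[idx]
            offset = u - (cum[idx - 1] if idx else 0.0)
            start = lo + int(offset)
            end = start + L
            if all(end <= ps or start >= pe for ps, pe in placed):
                placed.append((start, end))
                break
        else:
            raise ValueError("could not place query segments without overlap; "
                             "workspace too crowded")
    return placed
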