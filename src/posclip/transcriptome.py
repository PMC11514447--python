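"""Gene models, transcript coordinates, and five-region classification.

A transcript is represented as a spliced, stranded gene model.  Transcript
coordinates run 5' to 3' along the mature mRNA (position 0 is the first
transcribed base).  Every transcript position falls into exactly one of
five regions defined around the start and stop codons:

* ``five_prime_utr`` -- more than 50 nt upstream of the start codon,
* ``start``          -- 50 nt on each side of the start codon,
* ``cds``            -- from 50 nt downstream of the start codon to 50 nt
  upstream of the stop codon,
* ``stop``           -- 50 nt on each side of the stop codon,
* ``three_prime_utr``-- more than 50 nt downstream of the stop codon.

The start anchor is the first CDS base; the stop anchor is the first
3'UTR base (the CDS/3'UTR junction), giving a symmetric +/-50 window
around the junction.  Windows are half-open ``[anchor-50, anchor+50)``,
truncated at the transcript ends when a UTR is shorter than 50 nt.  When
the CDS is shorter than 100 nt the two windows overlap; overlapping
positions are labelled ``start`` when strictly closer to the start
anchor and ``stop`` otherwise (ties go to ``stop``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical region order used everywhere downstream (5' to 3').
REGIONS = ("five_prime_utr", "start", "cds", "stop", "three_prime_utr")

#: Half-width of the start/stop windows in nucleotides.
REGION_WINDOW = 50


class AnnotationError(ValueError):
    """Raised when an annotation file cannot be parsed or is inconsistent."""


@dataclass(frozen=True)
class TranscriptModel:
    """Spliced, stranded gene model with CDS boundaries in transcript space.

    Parameters
    ----------
    gene_id, transcript_id : str
        Identifiers from the annotation.
    chrom : str
        Chromosome / contig name.
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (int, int)
        Genomic exon intervals, 0-based half-open, sorted by genomic start
        and non-overlapping.
    cds_start_tx : int
        Transcript coordinate of the first CDS base (equals the 5'UTR
        length).
    cds_end_tx : int
        Transcript coordinate one past the last CDS base (first 3'UTR
        base).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple
    cds_start_tx: int
    cds_end_tx: int
    _starts: np.ndarray = field(init=False, repr=False, compare=False)
    _ends: np.ndarray = field(init=False, repr=False, compare=False)
    _offsets: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise AnnotationError("transcript with no exons")
        starts = np.array([s for s, _ in exons], dtype=np.int64)
        ends = np.array([e for _, e in exons], dtype=np.int64)
        if np.any(ends <= starts) or np.any(starts[1:] < ends[:-1]):
            raise AnnotationError(
                f"{self.transcript_id}: exons must be sorted and non-overlapping"
            )
        lengths = ends - starts
        # cumulative spliced length before each exon, 5'-most exon first
        if self.strand == "+":
            offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        else:
            rev = lengths[::-1]
            offsets = np.concatenate([[0], np.cumsum(rev)[:-1]])[::-1]
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "_starts", starts)
        object.__setattr__(self, "_ends", ends)
        object.__setattr__(self, "_offsets", offsets)
        if not (0 <= self.cds_start_tx < self.cds_end_tx <= self.length):
            raise AnnotationError(
                f"{self.transcript_id}: CDS [{self.cds_start_tx},{self.cds_end_tx}) "
                f"outside transcript of length {self.length}"
            )

    @property
    def length(self) -> int:
        """Spliced transcript length in nt."""
        return int((self._ends - self._starts).sum())

    @property
    def utr5_len(self) -> int:
        return self.cds_start_tx

    @property
    def cds_len(self) -> int:
        return self.cds_end_tx - self.cds_start_tx

    @property
    def utr3_len(self) -> int:
        return self.length - self.cds_end_tx


def genomic_to_transcript(model: TranscriptModel, genomic_pos) -> int | None:
    """Map a 0-based genomic position to a transcript coordinate.

    Returns ``None`` for intronic or out-of-span positions.  Accepts a
    scalar or an array; for arrays an int64 array is returned with -1
    marking unmappable positions.
    """
    pos = np.asarray(genomic_pos, dtype=np.int64)
    scalar = pos.ndim == 0
    pos = np.atleast_1d(pos)
    idx = np.searchsorted(model._starts, pos, side="right") - 1
    valid = (idx >= 0) & (pos < model._ends[np.clip(idx, 0, None)])
    idx = np.clip(idx, 0, None)
    if model.strand == "+":
        tx = model._offsets[idx] + (pos - model._starts[idx])
    else:
        tx = model._offsets[idx] + (model._ends[idx] - 1 - pos)
    tx = np.where(valid, tx, -1)
    if scalar:
        return int(tx[0]) if valid[0] else None
    return tx


def transcript_to_genomic(model: TranscriptModel, tx_pos) -> int | np.ndarray:
    """Map a transcript coordinate back to its genomic position.

    Inverse of :func:`genomic_to_transcript` over exonic bases.
    """
    tx = np.asarray(tx_pos, dtype=np.int64)
    scalar = tx.ndim == 0
    tx = np.atleast_1d(tx)
    if np.any((tx < 0) | (tx >= model.length)):
        raise ValueError("transcript coordinate out of range")
    lengths = model._ends - model._starts
    if model.strand == "+":
        cum = np.concatenate([[0], np.cumsum(lengths)])
        idx = np.searchsorted(cum, tx, side="right") - 1
        g = model._starts[idx] + (tx - cum[idx])
    else:
        rev_len = lengths[::-1]
        cum = np.concatenate([[0], np.cumsum(rev_len)])
        ridx = np.searchsorted(cum, tx, side="right") - 1
        idx = len(lengths) - 1 - ridx
        g = model._ends[idx] - 1 - (tx - cum[ridx])
    return int(g[0]) if scalar else g


# region classification -------------------------------------------------------

_REGION_CODE = {name: i for i, name in enumerate(REGIONS)}


def classify_positions(model: TranscriptModel, tx_pos, window: int = REGION_WINDOW):
    """Vectorized five-region classification of transcript coordinates.

    Returns an int array of region codes indexing into :data:`REGIONS`.
    """
    pos = np.asarray(tx_pos, dtype=np.int64)
    if np.any((pos < 0) | (pos >= model.length)):
        raise ValueError("transcript position out of range")
    a_start = model.cds_start_tx
    a_stop = model.cds_end_tx
    d_start = np.abs(pos - a_start)
    d_stop = np.abs(pos - a_stop)
    in_start = (pos >= a_start - window) & (pos < a_start + window)
    in_stop = (pos >= a_stop - window) & (pos < a_stop + window)
    out = np.empty(pos.shape, dtype=np.int8)
    out[pos < a_start - window] = _REGION_CODE["five_prime_utr"]
    out[pos >= a_stop + window] = _REGION_CODE["three_prime_utr"]
    mid = ~in_start & ~in_stop & (pos >= a_start - window) & (pos < a_stop + window)
    out[mid] = _REGION_CODE["cds"]
    only_start = in_start & ~in_stop
    only_stop = in_stop & ~in_start
    both = in_start & in_stop
    out[only_start] = _REGION_CODE["start"]
    out[only_stop] = _REGION_CODE["stop"]
    # short CDS: windows overlap; nearest anchor wins, ties go to stop
    out[both] = np.where(
        d_start[both] < d_stop[both], _REGION_CODE["start"], _REGION_CODE["stop"]
    )
    return out


def classify_position(model: TranscriptModel, tx_pos: int, window: int = REGION_WINDOW) -> str:
    """Classify a single transcript coordinate into one of the five regions."""
    return REGIONS[int(classify_positions(model, np.int64(tx_pos), window))]


def region_lengths(model: TranscriptModel, window: int = REGION_WINDOW) -> np.ndarray:
    """Lengths in nt of the five regions, in :data:`REGIONS` order.

    Computed by exhaustive classification so the result is exact for any
    truncation/overlap geometry; lengths always sum to the transcript
    length.  They depend only on the UTR/CDS lengths, never on exon
    structure.
    """
    codes = classify_positions(model, np.arange(model.length), window)
    return np.bincount(codes, minlength=len(REGIONS)).astype(np.int64)


# annotation loading ----------------------------------------------------------


def _pick_representative(candidates: list[TranscriptModel]) -> TranscriptModel:
    """One coding transcript per gene: longest total length, tie broken by
    longest CDS, then lexicographically smallest transcript_id."""
    return sorted(
        candidates, key=lambda m: (-m.length, -m.cds_len, m.transcript_id)
    )[0]


def load_annotation(path, dialect: str = "gtf"):
    """Load gene models from a GTF or BED12 annotation.

    Keeps exactly one coding transcript per gene (the longest; ties broken
    by CDS length then transcript_id).  Genes with no coding transcript
    are excluded.  Transcripts whose CDS falls outside their exons are
    rejected and logged.

    Returns
    -------
    (dict, int)
        Mapping ``gene_id -> TranscriptModel`` and the number of genes
        excluded for lacking a coding transcript.
    """
    if dialect == "gtf":
        per_tx = _parse_gtf(path)
    elif dialect == "bed12":
        per_tx = _parse_bed12(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    by_gene: dict[str, list[TranscriptModel]] = {}
    noncoding_genes: set[str] = set()
    for (gene_id, tx_id), rec in per_tx.items():
        exons = sorted(rec["exons"])
        if not exons or rec["cds"] is None:
            noncoding_genes.add(gene_id)
            continue
        cds_lo, cds_hi = rec["cds"]
        model = _build_model(
            gene_id, tx_id, rec["chrom"], rec["strand"], exons, cds_lo, cds_hi
        )
        if model is None:
            noncoding_genes.add(gene_id)
            continue
        by_gene.setdefault(gene_id, []).append(model)

    models = {g: _pick_representative(ms) for g, ms in by_gene.items()}
    n_excluded = len(noncoding_genes - set(models))
    if n_excluded:
        logger.info("excluded %d genes with no usable coding transcript", n_excluded)
    return models, n_excluded


def _build_model(gene_id, tx_id, chrom, strand, exons, cds_lo, cds_hi):
    """Build a TranscriptModel from genomic CDS bounds; None if CDS is not
    fully exonic."""
    try:
        probe = TranscriptModel(gene_id, tx_id, chrom, strand, tuple(exons), 0, 1)
    except AnnotationError as exc:
        logger.warning("rejected %s: %s", tx_id, exc)
        return None
    first = genomic_to_transcript(probe, cds_lo)
    last = genomic_to_transcript(probe, cds_hi - 1)
    if first is None or last is None:
        logger.warning("rejected %s: CDS outside exons", tx_id)
        return None
    cds_start_tx, cds_end_tx = (first, last + 1) if strand == "+" else (last, first + 1)
    # genomic CDS span must be covered by exons (no intronic CDS bases)
    covered = sum(
        max(0, min(e, cds_hi) - max(s, cds_lo)) for s, e in exons
    )
    if cds_end_tx - cds_start_tx != covered:
        logger.warning("rejected %s: inconsistent CDS mapping", tx_id)
        return None
    try:
        return TranscriptModel(
            gene_id, tx_id, chrom, strand, tuple(exons), cds_start_tx, cds_end_tx
        )
    except AnnotationError as exc:
        logger.warning("rejected %s: %s", tx_id, exc)
        return None


def _parse_gtf(path):
    """Minimal-assumption GTF reader via gffutils feature parsing.

    GTF is 1-based closed; coordinates are converted to 0-based half-open.
    Only ``exon`` and ``CDS`` features are used; coding status requires at
    least one CDS feature.
    """
    import gffutils
    from gffutils.exceptions import AttributeStringError

    per_tx: dict[tuple, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line, dialect=None)
            except Exception as exc:  # pragma: no cover - malformed input
                raise AnnotationError(f"{path}:{lineno}: unparseable GTF line ({exc})")
            if feat.featuretype not in ("exon", "CDS"):
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                tx_id = feat.attributes["transcript_id"][0]
            except (KeyError, AttributeStringError) as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: missing gene_id/transcript_id ({exc})"
                )
            rec = per_tx.setdefault(
                (gene_id, tx_id),
                {"chrom": feat.seqid, "strand": feat.strand, "exons": [], "cds": None},
            )
            start0, end0 = feat.start - 1, feat.end  # GTF 1-based closed
            if feat.featuretype == "exon":
                rec["exons"].append((start0, end0))
            else:
                lo, hi = rec["cds"] or (start0, end0)
                rec["cds"] = (min(lo, start0), max(hi, end0))
    return per_tx


def _parse_bed12(path):
    """BED12 reader: one transcript per line, thickStart/thickEnd as CDS."""
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes", "blockStarts",
    ]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    except Exception as exc:
        raise AnnotationError(f"{path}: unparseable BED12 ({exc})")
    per_tx = {}
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        exons = [(row.start + s, row.start + s + sz) for s, sz in zip(starts, sizes)]
        # BED name convention "gene|transcript"; plain names map to themselves
        if "|" in str(row.name):
            gene_id, tx_id = str(row.name).split("|", 1)
        else:
            gene_id = tx_id = str(row.name)
        cds = None
        if int(row.thickEnd) > int(row.thickStart):
            cds = (int(row.thickStart), int(row.thickEnd))
        per_tx[(gene_id, tx_id)] = {
            "chrom": row.chrom, "strand": row.strand, "exons": exons, "cds": cds,
        }
    return per_tx


# UTR length summaries --------------------------------------------------------


def utr_length_stats(models: dict, cluster_assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster distributions of 5'UTR and 3'UTR lengths.

    ``cluster_assignments`` needs columns ``gene_id`` and ``label``.
    Returns a tidy frame with median and quartiles of both UTR lengths per
    cluster label.  Unknown gene ids raise with the offending list; empty
    clusters yield an empty summary.
    """
    unknown = sorted(set(cluster_assignments["gene_id"]) - set(models))
    if unknown:
        raise KeyError(f"unknown gene ids in cluster assignments: {unknown}")
    rows = []
    for label, grp in cluster_assignments.groupby("label"):
        u5 = np.array([models[g].utr5_len for g in grp["gene_id"]], dtype=float)
        u3 = np.array([models[g].utr3_len for g in grp["gene_id"]], dtype=float)
        rows.append(
            {
                "label": label,
                "n_genes": len(grp),
                "utr5_q25": np.percentile(u5, 25) if len(u5) else np.nan,
                "utr5_median": np.median(u5) if len(u5) else np.nan,
                "utr5_q75": np.percentile(u5, 75) if len(u5) else np.nan,
                "utr3_q25": np.percentile(u3, 25) if len(u3) else np.nan,
                "utr3_median": np.median(u3) if len(u3) else np.nan,
                "utr3_q75": np.percentile(u3, 75) if len(u3) else np.nan,
            }
        )
    return pd.DataFrame(rows)
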